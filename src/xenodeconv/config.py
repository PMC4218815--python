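"""Configuration objects for the simulator and the end-to-end pipeline.

The defaults encode the study design the package emulates: two glioma
stem-cell (GSC) lines injected into four animals each, three laser-dissected
regions per animal (A = tumor core, B = area of invasion, C = distal
"normal" brain), with region-B tissue being a human/mouse mixture that is
hybridized on both a human and a mouse array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

REGIONS = ("A", "B", "C")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its documented constraints."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic mixed-species experiment.

    Parameters
    ----------
    n_genes_per_species
        Number of genes (one transcript and one probeset each) simulated for
        each species.
    probes_per_set
        Probes per probeset, as on short-oligo expression arrays.
    probe_length
        Probe length in nucleotides.
    transcript_length
        Length of each simulated transcript; must exceed ``probe_length``.
    n_lines, n_animals_per_line
        Tumor-line and animal replication of the xenograft design.
    frac_de_human, frac_de_mouse
        Fraction of genes with a planted region effect (human: B vs A,
        mouse: B vs C), shared across lines.
    de_log2fc_mean, de_log2fc_sd
        Magnitude distribution of planted log2 fold changes; signs are
        assigned at random.
    frac_xhyb_probes
        Fraction of probes that receive an implanted exact match inside a
        random foreign transcript. Implants are clustered within probesets,
        mimicking homology-driven cross-hybridization which hits most probes
        of an affected probeset.
    xhyb_match_min
        Minimum implant length in nt; implant lengths are drawn uniformly
        from ``[xhyb_match_min, probe_length]``.
    xhyb_coupling
        Leakage coefficient kappa in [0, 1]: the raw-scale fraction of the
        foreign transcript's abundance added to an implanted probe's signal
        in mixed (region-B) tissue.
    mixing_fraction_b
        Human fraction f of region-B tissue (the paper leaves it unstated;
        it is a free parameter of the simulation).
    mixing_jitter_sd
        Per-sample Gaussian jitter on the logit-free mixing fraction,
        truncated into (0, 1).
    noise_sd
        Gaussian measurement noise on log2 intensities.
    seed
        Seed for all randomness in the generator.
    """

    n_genes_per_species: int = 150
    probes_per_set: int = 11
    probe_length: int = 25
    transcript_length: int = 400
    n_lines: int = 2
    n_animals_per_line: int = 4
    regions: tuple[str, ...] = REGIONS
    frac_de_human: float = 0.15
    frac_de_mouse: float = 0.15
    de_log2fc_mean: float = 1.5
    de_log2fc_sd: float = 0.4
    frac_xhyb_probes: float = 0.08
    xhyb_match_min: int = 15
    xhyb_coupling: float = 0.5
    mixing_fraction_b: float = 0.5
    mixing_jitter_sd: float = 0.05
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    affinity_sd: float = 0.5
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        errs = []
        for name in ("frac_de_human", "frac_de_mouse", "frac_xhyb_probes",
                     "xhyb_coupling", "mixing_fraction_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}={v} must lie in [0, 1]")
        if self.probe_length < 15:
            errs.append(f"probe_length={self.probe_length} must be >= 15")
        if self.probes_per_set < 1:
            errs.append("probes_per_set must be >= 1")
        if self.noise_sd <= 0:
            errs.append(f"noise_sd={self.noise_sd} must be > 0")
        if self.probe_length > self.transcript_length:
            errs.append(
                f"probe_length={self.probe_length} exceeds "
                f"transcript_length={self.transcript_length}")
        else:
            # probes tile the transcript head; the tail must keep room for
            # cross-hybridization implants of up to probe_length nt
            zone = self.probes_per_set * (self.probe_length + 2)
            if self.transcript_length < zone + self.probe_length:
                errs.append(
                    f"transcript_length={self.transcript_length} too short for "
                    f"{self.probes_per_set} probes of {self.probe_length} nt "
                    f"plus an implant zone (need >= {zone + self.probe_length})")
        if not (0 < self.xhyb_match_min <= self.probe_length):
            errs.append("xhyb_match_min must lie in (0, probe_length]")
        if self.n_genes_per_species < 2:
            errs.append("n_genes_per_species must be >= 2")
        if self.n_lines < 1 or self.n_animals_per_line < 1:
            errs.append("n_lines and n_animals_per_line must be >= 1")
        if tuple(self.regions) != REGIONS:
            errs.append(f"regions must be {REGIONS}")
        if errs:
            raise ConfigurationError(errs)
        return self

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["regions"] = list(self.regions)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "regions" in d:
            d["regions"] = tuple(d["regions"])
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``simulate`` is true (a fixture bundle is generated into
    ``out_dir/bundle``) or ``input_dir`` points at an existing bundle.
    Stage parameters mirror the module-level defaults.
    """

    out_dir: str = "xenodeconv_run"
    simulate: bool = True
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # probe masking
    l_min: int = 15
    i_min: float = 0.75
    min_probes_per_set: int = 3
    # normalization / summarization
    # "reference" (median of log-ratios to a pseudo-reference),
    # "scale" (plain median centering) or "quantile"
    normalization: str = "reference"
    summarization_method: str = "median"
    # differential expression / consensus
    alpha: float = 0.05
    require_same_direction: bool = True
    use_adjusted_p: bool = False
    # enrichment
    theta: float = 0.30
    p_max: float = 0.05
    overlap_metric: str = "min"
    # concordance
    n_panel_genes: int = 30
    count_dispersion: float = 0.05
    count_depth: float = 5e4
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("simulation"), dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)
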