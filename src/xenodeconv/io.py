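"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython, tabular files through pandas, GMT reading
through gseapy. All tables are tab-separated; intensity and expression
matrices are written with the feature identifier as the index column.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gseapy.parser import read_gmt as _gseapy_read_gmt

PROBE_ANNOTATION_COLUMNS = ["probe_id", "probeset_id", "gene_id", "species"]
SAMPLE_SHEET_COLUMNS = ["sample_id", "line", "animal", "region", "array_species"]
INTERACTION_COLUMNS = ["gene_sym_1", "gene_sym_2", "evidence_tag"]
ORTHOLOGY_COLUMNS = ["human_symbol", "mouse_symbol"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_table(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature-by-sample matrix with the feature id in column 0."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{term: [genes]}``."""
    return _gseapy_read_gmt(str(path))


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in gene_sets.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"animal": str, "line": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns {missing}")
    return df


def read_probe_annotation(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe annotation {path} missing columns {missing}")
    return df
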