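"""Independent brute-force oracles used to validate the fast implementations.

Every oracle here is deliberately naive: dynamic programming over full
matrices, exhaustive loops, or textbook union-find. They share no code with
the package paths they check.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def lcs_dp(a: str, b: str) -> int:
    """Longest common substring length by O(len(a)*len(b)) dynamic programming."""
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(B), dtype=np.int32)
    best = 0
    for ca in A:
        eq = B == ca
        cur = np.zeros(len(B), dtype=np.int32)
        cur[eq] = 1
        idx = np.nonzero(eq[1:])[0] + 1
        cur[idx] += prev[idx - 1]
        if len(cur):
            best = max(best, int(cur.max()))
        prev = cur
    return best


def lcs_both_strands(probe: str, reference: str) -> int:
    """Longest common substring considering the probe's reverse complement."""
    return max(lcs_dp(probe, reference), lcs_dp(revcomp(probe), reference))


def substring_match_count(probes: dict[str, str], reference: str,
                          min_len: int) -> set[str]:
    """Probes sharing a contiguous match >= min_len with the reference,
    found by exhaustive substring search on both strands."""
    hits = set()
    for pid, seq in probes.items():
        for s in (seq, revcomp(seq)):
            if any(s[i:i + min_len] in reference
                   for i in range(len(s) - min_len + 1)):
                hits.add(pid)
                break
    return hits


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def overlap_components(sets: dict[str, set], theta: float) -> list[set]:
    """Connected components of the >=theta overlap graph via union-find,
    restricted to terms with at least one partner."""
    terms = sorted(sets)
    uf = UnionFind(terms)
    degree = {t: 0 for t in terms}
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            ov = len(sets[a] & sets[b]) / min(len(sets[a]), len(sets[b]))
            if ov >= theta:
                uf.union(a, b)
                degree[a] += 1
                degree[b] += 1
    comps: dict[str, set] = {}
    for t in terms:
        if degree[t] >= 1:
            comps.setdefault(uf.find(t), set()).add(t)
    return sorted(comps.values(), key=lambda c: sorted(c)[0])


def crosstalk_triple_loop(human_genes, mouse_genes, pairs, orthology):
    """Exhaustive candidate enumeration: for every human gene, mouse gene
    and reference pair, emit (h, m) if the pair bridges them."""
    m2h = dict(zip(orthology["mouse_symbol"], orthology["human_symbol"]))
    out = set()
    for h in human_genes:
        for m in mouse_genes:
            if m not in m2h:
                continue
            hm = m2h[m]
            for _, row in pairs.iterrows():
                a, b = row["gene_sym_1"], row["gene_sym_2"]
                if {h, hm} == {a, b} or (h == hm and a == b == h):
                    out.add((h, m))
    return out
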