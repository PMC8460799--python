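"""Hypergeometric pathway over-representation with BH q-values.

Candidate gene sets from the integration step are tested against a GMT
pathway collection: for each pathway of size K in a background of N
genes, with n candidates inside the background and k of them in the
pathway, the one-sided over-representation p is P(X >= k) for
X ~ Hypergeometric(N, K, n).  Benjamini-Hochberg adjustment runs across
the pooled collection.  The background defaults to the union of all
pathway genes and can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = ["PathwayDb", "load_gmt", "enrich", "candidate_fraction"]


class GmtParseError(ValueError):
    pass


@dataclass
class PathwayDb:
    pathways: dict  # name -> frozenset of genes
    sources: dict = field(default_factory=dict)  # name -> source label
    background: set = field(default_factory=set)

    def __post_init__(self):
        if not self.background:
            self.background = set().union(*self.pathways.values()) if self.pathways else set()
        for name, genes in self.pathways.items():
            self.pathways[name] = frozenset(genes) & frozenset(self.background)


def load_gmt(path) -> PathwayDb:
    """Load a GMT file (name, description/source, member genes, tab-separated).

    Duplicate genes within a line are collapsed; lines with fewer than
    three fields or no genes raise a parse error naming the line.
    """
    pathways, sources = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtParseError(f"line {lineno}: expected >= 3 tab-separated fields")
            name, source, *genes = parts
            genes = {g for g in genes if g}
            if not genes:
                raise GmtParseError(f"line {lineno}: pathway '{name}' has no genes")
            if name in pathways:
                raise GmtParseError(f"line {lineno}: duplicate pathway name '{name}'")
            pathways[name] = frozenset(genes)
            sources[name] = source
    return PathwayDb(pathways=pathways, sources=sources)


def enrich(candidates, db: PathwayDb) -> pd.DataFrame:
    """One-sided hypergeometric over-representation across the collection.

    Candidates outside the background are dropped with a warning.  Rows
    are sorted by q then p; ``candidate_pct`` follows the reporting
    convention 100 * k / K to one decimal.
    """
    candidates = set(candidates)
    if not candidates:
        warnings.warn("empty candidate set; no enrichment computed", stacklevel=2)
        return pd.DataFrame(columns=["pathway", "source", "set_size",
                                     "n_candidates", "candidate_pct", "p_hyper", "q"])
    outside = candidates - db.background
    if outside:
        warnings.warn(f"{len(outside)} candidate gene(s) outside background dropped",
                      stacklevel=2)
    inside = candidates & db.background
    n = len(inside)
    big_n = len(db.background)
    rows = []
    for name, members in db.pathways.items():
        k_size = len(members)
        k = len(inside & members)
        p = float(stats.hypergeom.sf(k - 1, big_n, k_size, n))
        rows.append({
            "pathway": name,
            "source": db.sources.get(name, ""),
            "set_size": k_size,
            "n_candidates": k,
            "candidate_pct": candidate_fraction(k, k_size),
            "p_hyper": min(p, 1.0),
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p_hyper"].to_numpy())
    return out.sort_values(["q", "p_hyper", "pathway"], ignore_index=True)


def candidate_fraction(k: int, K: int) -> float:
    """Percent of a pathway covered by candidates, one decimal (100k/K)."""
    if K <= 0:
        raise ValueError("pathway size must be positive")
    return round(100.0 * k / K, 1)
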