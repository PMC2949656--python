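"""Hypergeometric over-representation tests for gene sets and signatures.

Given a signature of n genes drawn from a universe of N genes, and a gene
set with K members in the universe, the enrichment p-value is the upper
tail P(X >= k) of the hypergeometric distribution for the observed overlap
k. Tails are computed in log space so that extreme overlaps (p below
1e-300 territory) remain finite and comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, GeneSetCollection

__all__ = ["EnrichmentRow", "hypergeom_tail", "enrich_signature", "signature_overlap"]


@dataclass
class EnrichmentRow:
    set_name: str
    set_size: int
    signature_size: int
    overlap: int
    p_value: float
    log10_p: float
    overlapping_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.signature_size):
            raise DataError("overlap cannot exceed either set size")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N population, K successes,
    n draws), evaluated through the log survival function."""
    log_p = hypergeom_log_tail(k, K, n, N)
    return float(np.exp(log_p))


def hypergeom_log_tail(k: int, K: int, n: int, N: int) -> float:
    """Natural-log upper tail of the hypergeometric distribution."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise DataError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 0.0
    # P(X >= k) = sf(k - 1); logsf keeps extreme tails representable
    return float(stats.hypergeom.logsf(k - 1, N, K, n))


def _row(name: str, members: set, signature: set, universe: set) -> EnrichmentRow:
    K = len(members)
    n = len(signature)
    k_genes = tuple(sorted(members & signature))
    k = len(k_genes)
    log_p = hypergeom_log_tail(k, K, n, len(universe))
    return EnrichmentRow(
        set_name=name,
        set_size=K,
        signature_size=n,
        overlap=k,
        p_value=float(np.exp(log_p)),
        log10_p=log_p / np.log(10.0),
        overlapping_genes=k_genes,
    )


def enrich_signature(
    signature: list[str],
    sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a signature against every gene set.

    Sets and signature are intersected with the universe first; sets
    disjoint from the universe are dropped with a warning. Rows are sorted
    by p-value; a Benjamini-Hochberg column is added for convenience (the
    primary column is the raw hypergeometric p).
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    sig = set(signature) & uni
    rows = []
    for gs in sets:
        members = set(gs.members) & uni
        if not members:
            warnings.warn(f"gene set {gs.name!r} is disjoint from the universe; dropped")
            continue
        rows.append(_row(gs.name, members, sig, uni))
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name", "set_size", "signature_size", "overlap",
                "p_value", "log10_p", "bh_fdr", "overlapping_genes",
            ]
        ).set_index("set_name")
    table = pd.DataFrame(
        {
            "set_name": [r.set_name for r in rows],
            "set_size": [r.set_size for r in rows],
            "signature_size": [r.signature_size for r in rows],
            "overlap": [r.overlap for r in rows],
            "p_value": [r.p_value for r in rows],
            "log10_p": [r.log10_p for r in rows],
            "overlapping_genes": [",".join(r.overlapping_genes) for r in rows],
        }
    ).sort_values(by=["p_value", "set_name"], kind="mergesort").set_index("set_name")
    m = len(table)
    ranked = table["p_value"].to_numpy() * m / np.arange(1, m + 1)
    table["bh_fdr"] = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    return table


def signature_overlap(
    set_a: list[str], set_b: list[str], universe: list[str]
) -> EnrichmentRow:
    """Overlap significance between two signatures within a universe."""
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    a = set(set_a) & uni
    b = set(set_b) & uni
    return _row("overlap", a, b, uni)
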