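"""Nearest-centroid intrinsic-subtype assignment.

Each sample is assigned to the intrinsic subtype (luminal A, luminal B,
basal-like, normal-like, HER2) whose published centroid vector has the
largest Pearson correlation with the sample's expression over the genes
common to the cohort and the centroid table. Probes are matched to
centroid genes through the probe annotation in the namespace the centroid
file declares; multiple probes per gene are collapsed by their mean
expression. By default each matched gene is median-centered across the
cohort before correlation, the usual correction when correlating
single-channel data against two-color-derived centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CentroidSet, DataError, ExpressionMatrix, ProbeAnnotation

__all__ = ["SubtypeAssignment", "match_features", "assign_subtypes"]

_NAMESPACE_COL = {"symbol": "gene_symbol", "unigene": "unigene_id", "entrez": "entrez_id"}


@dataclass
class SubtypeAssignment:
    sample_id: str
    assigned_subtype: str
    correlations: dict[str, float]
    n_common_genes: int
    tie_flag: bool

    def __post_init__(self) -> None:
        best = max(self.correlations.values())
        if self.correlations[self.assigned_subtype] != best:
            raise DataError("assigned subtype must attain the maximal correlation")


def match_features(
    ann: ProbeAnnotation, centroids: CentroidSet
) -> dict[str, list[str]]:
    """Map each centroid gene to the probes annotated to it.

    Returns centroid_gene -> [probe_id, ...] for genes with at least one
    matching probe; genes without a probe are dropped.
    """
    col = _NAMESPACE_COL[centroids.namespace]
    by_gene: dict[str, list[str]] = {}
    ids = ann.table[col]
    for probe, gene in ids.items():
        if gene:
            by_gene.setdefault(gene, []).append(probe)
    mapping = {g: by_gene[g] for g in centroids.gene_ids if g in by_gene}
    if not mapping:
        raise DataError(
            f"no common genes between annotation and centroids "
            f"(namespace {centroids.namespace!r})"
        )
    return mapping


def assign_subtypes(
    X: ExpressionMatrix,
    centroids: CentroidSet,
    ann: ProbeAnnotation,
    center: str = "median",
    min_r: float | None = None,
) -> list[SubtypeAssignment]:
    """Correlate every sample with every centroid over matched genes and
    assign the argmax subtype.

    center='median' subtracts each matched gene's cohort median first;
    center='none' correlates raw values. Exact correlation ties set
    ``tie_flag`` and resolve to the alphabetically first subtype. With
    ``min_r``, samples whose best correlation falls below the threshold
    are labeled 'unclassified'.
    """
    if center not in ("median", "none"):
        raise DataError(f"center must be 'median' or 'none', got {center!r}")
    mapping = match_features(ann, centroids)
    genes = [g for g in centroids.gene_ids if g in mapping]
    if len(genes) < 2:
        raise DataError(f"need >= 2 matched genes, got {len(genes)}")

    frame = X.to_frame()
    rows = []
    for g in genes:
        probes = [p for p in mapping[g] if p in frame.index]
        if not probes:
            continue
        rows.append(frame.loc[probes].mean(axis=0).rename(g))
    if len(rows) < 2:
        raise DataError(f"need >= 2 matched genes present in the matrix, got {len(rows)}")
    expr = pd.DataFrame(rows)  # genes x samples
    genes = list(expr.index)
    if center == "median":
        expr = expr.sub(expr.median(axis=1), axis=0)
    cent = centroids.values.loc[genes]  # genes x subtypes

    subtypes = list(cent.columns)
    E = expr.to_numpy()
    Cm = cent.to_numpy()
    Ez = E - E.mean(axis=0, keepdims=True)
    Cz = Cm - Cm.mean(axis=0, keepdims=True)
    denom = np.outer(
        np.sqrt((Ez**2).sum(axis=0)), np.sqrt((Cz**2).sum(axis=0))
    )
    if (denom == 0).any():
        raise DataError("zero-variance sample or centroid over matched genes")
    R = (Ez.T @ Cz) / denom  # samples x subtypes

    out = []
    order = np.argsort(subtypes)  # alphabetical tie resolution
    for si, sample in enumerate(expr.columns):
        r = R[si]
        best = r.max()
        winners = [subtypes[i] for i in order if r[i] == best]
        assigned = winners[0]
        tie = len(winners) > 1
        if min_r is not None and best < min_r:
            assigned_label = "unclassified"
        else:
            assigned_label = assigned
        corr = {s: float(r[i]) for i, s in enumerate(subtypes)}
        if assigned_label == "unclassified":
            corr["unclassified"] = float(best)
        out.append(
            SubtypeAssignment(
                sample_id=str(sample),
                assigned_subtype=assigned_label,
                correlations=corr,
                n_common_genes=len(genes),
                tie_flag=tie,
            )
        )
    return out


def assignments_to_frame(assignments: list[SubtypeAssignment]) -> pd.DataFrame:
    """Tabular view mirroring SubtypeAssignment fields, one row per sample."""
    rows = []
    for a in assignments:
        row = {
            "sample_id": a.sample_id,
            "assigned_subtype": a.assigned_subtype,
            "n_common_genes": a.n_common_genes,
            "tie_flag": int(a.tie_flag),
        }
        row.update({f"r_{s}": v for s, v in a.correlations.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
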