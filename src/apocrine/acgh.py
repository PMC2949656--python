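"""Array-CGH clone aggregation, gain/loss/amplicon calling and the
per-arm genomic perturbation rate.

Replicate spots of each BAC clone are QC-filtered (signal-to-noise >= 3,
valid flag), summarized by the median Cy3/Cy5 ratio, and discarded as
missing when the surviving spots' log2 ratios spread beyond a replicate-SD
cap. Status thresholds are applied on the linear ratio scale by default
(gain > 1.2, loss < 0.8, amplicon > 2.0, strict inequalities); a
``literal_log`` flag applies the same numbers to the log2 ratio instead.

The genomic perturbation rate of a tumor is the unweighted mean over
chromosome arms of the fraction of informative (non-missing) clones called
gained, lost or amplified on that arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AcghExperiment, CentromereMap, DataError

__all__ = [
    "CloneCall",
    "PerturbationSummary",
    "aggregate_clone",
    "call_status",
    "exclude_sparse_clones",
    "call_tumor",
    "perturbation_rate",
    "genome_plot",
]

ALTERED = frozenset({"loss", "gain", "amplicon"})


@dataclass
class CloneCall:
    clone_id: str
    chromosome: str
    position: float
    arm: str
    median_ratio: float  # linear Cy3/Cy5 scale; NaN when missing
    status: str  # loss | normal | gain | amplicon | missing

    def __post_init__(self) -> None:
        if (self.status == "missing") != (not np.isfinite(self.median_ratio)):
            raise DataError("status 'missing' must coincide with an absent ratio")


@dataclass
class PerturbationSummary:
    per_arm: pd.DataFrame  # index (chromosome, arm): n_informative, n_altered, fraction
    rate: float

    def __post_init__(self) -> None:
        frac = self.per_arm["fraction"].dropna()
        if ((frac < 0) | (frac > 1)).any() or not (0 <= self.rate <= 1):
            raise DataError("perturbation fractions must lie in [0, 1]")


def aggregate_clone(
    spots: pd.DataFrame | list[tuple],
    snr_min: float = 3.0,
    sd_max: float = 0.1,
) -> float:
    """Median Cy3/Cy5 ratio of a clone's replicate spots, or NaN (missing).

    Spots flagged invalid, with snr below ``snr_min``, or with non-positive
    intensities are dropped. If the surviving spots' log2 ratios have a
    standard deviation above ``sd_max`` the clone is missing for this tumor.
    """
    if not isinstance(spots, pd.DataFrame):
        spots = pd.DataFrame(spots, columns=["cy3", "cy5", "snr", "valid"])
    if len(spots) == 0:
        raise DataError("aggregate_clone needs >= 1 spot record")
    cy3 = spots["cy3"].to_numpy(dtype=float)
    cy5 = spots["cy5"].to_numpy(dtype=float)
    snr = spots["snr"].to_numpy(dtype=float)
    valid = spots["valid"].to_numpy(dtype=bool)
    positive = (cy3 > 0) & (cy5 > 0)
    if (~positive & valid).any():
        warnings.warn("spot with non-positive intensity invalidated")
    keep = valid & positive & (snr >= snr_min)
    if not keep.any():
        return float("nan")
    ratios = cy3[keep] / cy5[keep]
    if keep.sum() >= 2 and np.log2(ratios).std(ddof=1) > sd_max:
        return float("nan")
    return float(np.median(ratios))


def call_status(
    median_ratio: float,
    gain: float = 1.2,
    loss: float = 0.8,
    amp: float = 2.0,
    literal_log: bool = False,
) -> str:
    """Copy-number status of one clone from its median ratio.

    Thresholds are strict: ratio > amp -> amplicon; amp >= ratio > gain ->
    gain; ratio < loss -> loss; otherwise normal. With ``literal_log`` the
    same thresholds are applied to log2(ratio).
    """
    if not np.isfinite(median_ratio):
        return "missing"
    value = np.log2(median_ratio) if literal_log else median_ratio
    if value > amp:
        return "amplicon"
    if value > gain:
        return "gain"
    if value < loss:
        return "loss"
    return "normal"


def _ratio_matrix(
    experiment: AcghExperiment, snr_min: float = 3.0, sd_max: float = 0.1
) -> pd.DataFrame:
    """Clones x tumors matrix of aggregated median ratios (NaN = missing)."""
    out = pd.DataFrame(
        np.nan, index=experiment.clones.index, columns=experiment.tumor_ids
    )
    for (clone, tumor), grp in experiment.spots.groupby(["clone_id", "tumor_id"], sort=False):
        out.at[clone, tumor] = aggregate_clone(grp, snr_min=snr_min, sd_max=sd_max)
    return out


def exclude_sparse_clones(
    experiment: AcghExperiment,
    max_missing_fraction: float = 0.5,
    snr_min: float = 3.0,
    sd_max: float = 0.1,
) -> list[str]:
    """Clones retained cohort-wide: those missing in at most
    ``max_missing_fraction`` of tumors (strictly more -> excluded)."""
    ratios = _ratio_matrix(experiment, snr_min=snr_min, sd_max=sd_max)
    if ratios.shape[1] == 0:
        raise DataError("experiment has no tumors")
    missing_frac = ratios.isna().mean(axis=1)
    return list(ratios.index[missing_frac <= max_missing_fraction])


def call_tumor(
    experiment: AcghExperiment,
    tumor_id: str,
    cmap: CentromereMap,
    clones: list[str] | None = None,
    snr_min: float = 3.0,
    sd_max: float = 0.1,
    gain: float = 1.2,
    loss: float = 0.8,
    amp: float = 2.0,
    literal_log: bool = False,
) -> list[CloneCall]:
    """Per-clone status calls for one tumor (all retained clones)."""
    if clones is None:
        clones = list(experiment.clones.index)
    spots = experiment.spots
    spots_t = spots[spots["tumor_id"] == tumor_id]
    calls = []
    grouped = dict(tuple(spots_t.groupby("clone_id", sort=False)))
    for clone in clones:
        info = experiment.clones.loc[clone]
        grp = grouped.get(clone)
        ratio = (
            aggregate_clone(grp, snr_min=snr_min, sd_max=sd_max)
            if grp is not None
            else float("nan")
        )
        status = call_status(ratio, gain=gain, loss=loss, amp=amp, literal_log=literal_log)
        calls.append(
            CloneCall(
                clone_id=clone,
                chromosome=str(info["chromosome"]),
                position=float(info["position"]),
                arm=cmap.arm_of(str(info["chromosome"]), float(info["position"])),
                median_ratio=ratio,
                status=status,
            )
        )
    return calls


def perturbation_rate(calls: list[CloneCall], cmap: CentromereMap) -> PerturbationSummary:
    """Mean over chromosome arms of the altered fraction of informative
    clones. Arms with zero informative clones are excluded from the mean."""
    rows: dict[tuple[str, str], list[int]] = {}
    for c in calls:
        if c.chromosome not in cmap.table.index:
            raise DataError(f"chromosome {c.chromosome!r} absent from centromere map")
        key = (c.chromosome, c.arm)
        inf, alt = rows.setdefault(key, [0, 0])
        if c.status != "missing":
            rows[key][0] += 1
            if c.status in ALTERED:
                rows[key][1] += 1
    per_arm = pd.DataFrame(
        {
            "n_informative": {k: v[0] for k, v in rows.items()},
            "n_altered": {k: v[1] for k, v in rows.items()},
        }
    )
    per_arm.index = pd.MultiIndex.from_tuples(per_arm.index, names=["chromosome", "arm"])
    with np.errstate(invalid="ignore"):
        per_arm["fraction"] = np.where(
            per_arm["n_informative"] > 0,
            per_arm["n_altered"] / per_arm["n_informative"].replace(0, np.nan),
            np.nan,
        )
    informative = per_arm["fraction"].dropna()
    if informative.empty:
        raise DataError("no informative clones on any arm")
    return PerturbationSummary(per_arm=per_arm, rate=float(informative.mean()))


_STATUS_COLORS = {
    "gain": "#d62728",
    "amplicon": "#1f77b4",
    "loss": "#2ca02c",
    "normal": "#bcbd22",
    "missing": "#cccccc",
}


def genome_plot(calls: list[CloneCall], cmap: CentromereMap, path) -> None:
    """Static per-chromosome track of status-colored clones (log2 ratio on
    the y axis, centromere as a dashed line)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [c for c in cmap.chromosomes if any(x.chromosome == c for x in calls)]
    n = max(len(chroms), 1)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.4 * n), squeeze=False, sharey=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = [c for c in calls if c.chromosome == chrom]
        for c in sub:
            y = np.log2(c.median_ratio) if np.isfinite(c.median_ratio) else 0.0
            ax.plot(c.position, y, ".", color=_STATUS_COLORS[c.status], ms=3)
        ax.axvline(cmap.table.at[chrom, "centromere"], ls="--", lw=0.5, color="k")
        ax.axhline(0.0, lw=0.3, color="k")
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        ax.set_xlim(0, cmap.table.at[chrom, "length"])
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def calls_to_frame(calls: list[CloneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in calls],
            "chromosome": [c.chromosome for c in calls],
            "position": [c.position for c in calls],
            "arm": [c.arm for c in calls],
            "median_ratio": [c.median_ratio for c in calls],
            "status": [c.status for c in calls],
        }
    ).set_index("clone_id")
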