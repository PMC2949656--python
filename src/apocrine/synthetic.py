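"""Synthetic cohorts with the statistical structure the pipeline assumes.

Every generator is fully determined by an explicit seed and returns the
planted truth beside the data, so each analysis stage can be checked
against known ground truth without any external download.

The default expression scenario mirrors the study design the pipeline is
built for: 74 tumor samples falling into the five intrinsic subtypes plus
a small 5-sample molecular-apocrine group (3 of them Cowden) that
over-expresses a block of 84 genes. Expression is log2-scale Gaussian:
probe value = baseline + class offset + apocrine-block offset + noise.
Defaults: subtype/block effect 1.5 log2 units (~2.8-fold, typical of
intrinsic marker genes) and residual noise SD 0.5 (typical residual spread
of RMA-normalized arrays).

The aCGH generator emulates quadruplicate-spotted BAC-clone profiles
(5,878 clones by default) with planted gain/loss/amplicon segments and
multiplicative log-normal spot noise; the IHC generator draws per-marker
positivity by group and fills in percent/score pairs consistent with the
scoring bands.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import (
    AcghExperiment,
    CentroidSet,
    CentromereMap,
    ExpressionMatrix,
    DataError,
    ProbeAnnotation,
    SampleAnnotation,
)
from .ihc import IhcScoreTable, MARKER_PANEL, SCORE2_MARKERS

__all__ = [
    "SyntheticTruth",
    "ExpressionScenario",
    "AcghScenario",
    "IhcScenario",
    "SUBTYPES",
    "default_centromere_map",
    "generate_expression",
    "generate_null_with_variant_probes",
    "generate_acgh",
    "generate_ihc",
]

SUBTYPES = ("basal", "her2", "luminal_A", "luminal_B", "normal_like")
DEFAULT_CLASS_PROPORTIONS = {
    "luminal_A": 0.35,
    "luminal_B": 0.20,
    "basal": 0.20,
    "her2": 0.15,
    "normal_like": 0.10,
}

# approximate autosome lengths and centromere positions (bp)
_GENOME_MB = {
    "1": (247.2, 125.0), "2": (242.8, 93.3), "3": (199.5, 91.0),
    "4": (191.3, 50.4), "5": (180.9, 48.4), "6": (170.9, 61.0),
    "7": (158.8, 59.9), "8": (146.3, 45.6), "9": (140.3, 49.0),
    "10": (135.4, 40.2), "11": (134.5, 53.7), "12": (132.3, 35.8),
    "13": (114.1, 17.9), "14": (106.4, 17.6), "15": (100.3, 19.0),
    "16": (88.8, 36.6), "17": (78.8, 24.0), "18": (76.1, 17.2),
    "19": (63.8, 26.5), "20": (62.4, 27.5), "21": (46.9, 13.2),
    "22": (49.7, 14.7),
}

_STATUS_RATIO = {"loss": 0.5, "normal": 1.0, "gain": 1.5, "amplicon": 3.0}


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized beside each generated dataset."""

    sample_class: dict[str, str] | None = None
    cowden_samples: list[str] | None = None
    apocrine_samples: list[str] | None = None
    up_probes: list[str] | None = None
    down_probes: list[str] | None = None
    class_marker_probes: dict[str, list[str]] | None = None
    effect: float | None = None
    noise_sd: float | None = None
    clone_status: dict[str, str] | None = None
    arm_altered_fraction: dict[str, float] | None = None
    perturbation_rate: float | None = None
    positivity_probs: dict[str, dict[str, float]] | None = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class ExpressionScenario:
    expression: ExpressionMatrix
    annotation: ProbeAnnotation
    samples: SampleAnnotation
    centroids: CentroidSet
    truth: SyntheticTruth


@dataclass
class AcghScenario:
    experiment: AcghExperiment
    centromeres: CentromereMap
    truth: SyntheticTruth


@dataclass
class IhcScenario:
    table: IhcScoreTable
    truth: SyntheticTruth


def default_centromere_map() -> CentromereMap:
    t = pd.DataFrame(
        {
            "centromere": {c: cen * 1e6 for c, (_, cen) in _GENOME_MB.items()},
            "length": {c: ln * 1e6 for c, (ln, _) in _GENOME_MB.items()},
        }
    )
    t.index.name = "chromosome"
    return CentromereMap(t)


def generate_expression(
    n_samples: int = 74,
    n_probes: int = 20000,
    n_apocrine: int = 5,
    n_cowden: int = 3,
    apocrine_block: int = 84,
    down_block: int = 0,
    markers_per_class: int = 60,
    effect: float = 1.5,
    noise_sd: float = 0.5,
    n_controls: int = 100,
    class_proportions: dict[str, float] | None = None,
    seed: int | None = None,
) -> ExpressionScenario:
    """Generate a cohort expression matrix with planted subtype structure.

    Non-apocrine samples are multinomial over the five subtypes; apocrine
    samples additionally over-express ``apocrine_block`` probes (and
    under-express ``down_block`` probes) by ``effect`` log2 units. Planted
    probes are given high baselines so they survive intensity filtering.
    A matching centroid table (unigene namespace) is emitted.
    """
    if seed is None:
        raise DataError("generate_expression requires a seed")
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise DataError("class proportions must sum to 1")
    n_planted = apocrine_block + down_block + markers_per_class * len(SUBTYPES)
    if n_planted + n_controls > n_probes:
        raise DataError("planted blocks larger than probe count")
    if n_cowden > n_apocrine or n_apocrine > n_samples:
        raise DataError("need n_cowden <= n_apocrine <= n_samples")
    rng = np.random.default_rng(seed)

    probe_ids = [f"AFFX_{i:05d}" for i in range(n_controls)] + [
        f"P{i:05d}_at" for i in range(n_probes - n_controls)
    ]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    # class assignment: apocrine first, then multinomial subtypes
    classes = np.empty(n_samples, dtype=object)
    classes[:n_apocrine] = "apocrine"
    rest = rng.choice(
        list(props.keys()), size=n_samples - n_apocrine, p=list(props.values())
    )
    classes[n_apocrine:] = rest
    perm = rng.permutation(n_samples)
    classes = classes[perm]
    apocrine_samples = [s for s, c in zip(sample_ids, classes) if c == "apocrine"]
    cowden_samples = apocrine_samples[:n_cowden]

    # planted probe blocks drawn from the non-control probes
    pool = list(range(n_controls, n_probes))
    chosen = rng.choice(pool, size=n_planted, replace=False)
    cursor = 0
    up_idx = chosen[cursor : cursor + apocrine_block]; cursor += apocrine_block
    down_idx = chosen[cursor : cursor + down_block]; cursor += down_block
    marker_idx: dict[str, np.ndarray] = {}
    for st in SUBTYPES:
        marker_idx[st] = chosen[cursor : cursor + markers_per_class]
        cursor += markers_per_class

    baseline = np.clip(rng.normal(9.0, 2.0, size=n_probes), 4.0, 14.0)
    planted_all = np.concatenate([up_idx, down_idx] + [marker_idx[s] for s in SUBTYPES])
    # planted probes sit in the ordinary expressed range: high enough that
    # the 90th-percentile intensity filter keeps them, but not in the top
    # band, where the high mean would mechanically depress rCV (= sd/mean)
    baseline[planted_all.astype(int)] = rng.uniform(10.0, 12.0, size=planted_all.size)

    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_probes, n_samples))
    is_apo = classes == "apocrine"
    values[np.ix_(up_idx.astype(int), is_apo)] += effect
    if down_block:
        values[np.ix_(down_idx.astype(int), is_apo)] -= effect
    for st in SUBTYPES:
        members = classes == st
        if members.any():
            values[np.ix_(marker_idx[st].astype(int), members)] += effect

    X = ExpressionMatrix(values, probe_ids, sample_ids)

    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "gene_symbol": [
                    "" if i < n_controls else f"G{i - n_controls:05d}"
                    for i in range(n_probes)
                ],
                "unigene_id": [
                    "" if i < n_controls else f"Hs.{i - n_controls}"
                    for i in range(n_probes)
                ],
                "entrez_id": [
                    "" if i < n_controls else str(100000 + i - n_controls)
                    for i in range(n_probes)
                ],
                "is_control": [i < n_controls for i in range(n_probes)],
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    samples = SampleAnnotation(
        pd.DataFrame(
            {
                "cowden_status": [
                    "cowden" if s in cowden_samples else "non_cowden" for s in sample_ids
                ],
                "germline_mutation": [
                    "PTEN" if s in cowden_samples else "" for s in sample_ids
                ],
                "true_class": list(classes),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # centroid table over the subtype marker genes, unigene namespace
    centroid_probe_idx = np.concatenate([marker_idx[s] for s in SUBTYPES]).astype(int)
    centroid_genes = [f"Hs.{i - n_controls}" for i in centroid_probe_idx]
    cent = pd.DataFrame(
        {st: baseline[centroid_probe_idx] for st in SUBTYPES},
        index=pd.Index(centroid_genes, name="unigene"),
    )
    for st in SUBTYPES:
        in_class = np.isin(centroid_probe_idx, marker_idx[st])
        cent.loc[in_class, st] += effect
    centroids = CentroidSet(namespace="unigene", values=cent)

    truth = SyntheticTruth(
        sample_class={s: str(c) for s, c in zip(sample_ids, classes)},
        cowden_samples=cowden_samples,
        apocrine_samples=apocrine_samples,
        up_probes=[probe_ids[i] for i in up_idx.astype(int)],
        down_probes=[probe_ids[i] for i in down_idx.astype(int)],
        class_marker_probes={
            st: [probe_ids[i] for i in marker_idx[st].astype(int)] for st in SUBTYPES
        },
        effect=effect,
        noise_sd=noise_sd,
    )
    return ExpressionScenario(X, ann, samples, centroids, truth)


def generate_null_with_variant_probes(
    n_null: int = 5000,
    n_variant: int = 50,
    n_samples: int = 74,
    sd_ratio: float = 3.0,
    baseline: float = 11.0,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ProbeAnnotation, list[str]]:
    """Null i.i.d. Gaussian probes plus a planted high-variance minority
    (SD inflated ``sd_ratio``-fold). Returns (matrix, annotation, planted
    probe ids); used to exercise the variance/rCV selection chain."""
    if seed is None:
        raise DataError("generator requires a seed")
    rng = np.random.default_rng(seed)
    n_probes = n_null + n_variant
    values = baseline + rng.normal(0.0, noise_sd, size=(n_probes, n_samples))
    variant_rows = rng.choice(n_probes, size=n_variant, replace=False)
    values[variant_rows] = baseline + rng.normal(
        0.0, noise_sd * sd_ratio, size=(n_variant, n_samples)
    )
    probe_ids = [f"P{i:05d}_at" for i in range(n_probes)]
    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "gene_symbol": [f"G{i}" for i in range(n_probes)],
                "unigene_id": [f"Hs.{i}" for i in range(n_probes)],
                "entrez_id": [str(i + 1) for i in range(n_probes)],
                "is_control": [False] * n_probes,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )
    planted = [probe_ids[i] for i in sorted(variant_rows)]
    return ExpressionMatrix(values, probe_ids, [f"S{i:03d}" for i in range(n_samples)]), ann, planted


DEFAULT_SEGMENTS = (
    ("1", "q", "gain"),
    ("8", "q", "gain"),
    ("10", "q", "loss"),
    ("16", "p", "loss"),
    ("17", "q", "amplicon"),
)


def generate_acgh(
    n_clones: int = 5878,
    tumor_ids: tuple[str, ...] = ("T1",),
    altered_segments: dict[str, list[tuple[str, float, float, str]]] | None = None,
    noise_sd: float = 0.05,
    n_spots: int = 4,
    low_snr_fraction: float = 0.05,
    snr_min_planted: float = 3.0,
    seed: int | None = None,
    centromeres: CentromereMap | None = None,
) -> AcghScenario:
    """Quadruplicate-spotted BAC-clone profiles with planted segments.

    ``altered_segments`` maps tumor -> list of (chromosome, start_bp,
    end_bp, status); by default whole arms listed in ``DEFAULT_SEGMENTS``
    are altered in every tumor. True ratios are 0.5 / 1.0 / 1.5 / 3.0 for
    loss / normal / gain / amplicon; spot ratios multiply in log-normal
    noise of ``noise_sd`` log2 units, and ``low_snr_fraction`` of spots are
    given sub-threshold signal-to-noise plus heavier noise.
    """
    if seed is None:
        raise DataError("generate_acgh requires a seed")
    rng = np.random.default_rng(seed)
    cmap = centromeres or default_centromere_map()
    lengths = cmap.table["length"]
    weights = lengths / lengths.sum()
    counts = np.maximum(1, np.round(weights.to_numpy() * n_clones).astype(int))

    clone_rows = []
    for chrom, cnt in zip(cmap.chromosomes, counts):
        pos = np.linspace(1e5, lengths[chrom] - 1e5, cnt)
        for p in pos:
            clone_rows.append((f"BAC_{chrom}_{int(p)}", chrom, float(np.round(p))))
    clones = pd.DataFrame(
        clone_rows, columns=["clone_id", "chromosome", "position"]
    ).set_index("clone_id")

    if altered_segments is None:
        altered_segments = {}
        for t in tumor_ids:
            segs = []
            for chrom, arm, status in DEFAULT_SEGMENTS:
                cen = cmap.table.at[chrom, "centromere"]
                ln = cmap.table.at[chrom, "length"]
                if arm == "p":
                    segs.append((chrom, 1.0, cen - 1, status))
                else:
                    segs.append((chrom, cen, ln, status))
            altered_segments[t] = segs

    # validate segments and derive per-clone truth (same segments per tumor
    # produce one truth map per tumor; truth stores the first tumor's)
    def clone_status(tumor: str, chrom: str, pos: float) -> str:
        for c, start, end, status in altered_segments.get(tumor, []):
            if start > end or end > cmap.table.at[c, "length"]:
                raise DataError(f"segment outside chromosome {c}: ({start}, {end})")
            if c == chrom and start <= pos <= end:
                return status
        return "normal"

    spot_rows = []
    truth_status: dict[str, str] = {}
    for tumor in tumor_ids:
        for clone_id, row in clones.iterrows():
            status = clone_status(tumor, row["chromosome"], row["position"])
            if tumor == tumor_ids[0]:
                truth_status[clone_id] = status
            true_ratio = _STATUS_RATIO[status]
            for _ in range(n_spots):
                low = rng.random() < low_snr_fraction
                spot_sd = noise_sd + (0.5 if low else 0.0)
                ratio = true_ratio * 2.0 ** rng.normal(0.0, spot_sd) if spot_sd > 0 else true_ratio
                cy5 = float(rng.uniform(500, 2000))
                snr = float(rng.uniform(0.5, snr_min_planted - 0.1)) if low else float(
                    rng.uniform(snr_min_planted + 2, 50)
                )
                spot_rows.append(
                    (clone_id, tumor, cy5 * ratio, cy5, snr, True)
                )
    spots = pd.DataFrame(
        spot_rows, columns=["clone_id", "tumor_id", "cy3", "cy5", "snr", "valid"]
    )
    experiment = AcghExperiment(clones=clones, spots=spots)

    # per-arm planted altered fraction over all clones (first tumor)
    arm_alt: dict[str, list[int]] = {}
    for clone_id, row in clones.iterrows():
        arm = cmap.arm_of(row["chromosome"], row["position"])
        key = f"{row['chromosome']}{arm}"
        arm_alt.setdefault(key, [0, 0])
        arm_alt[key][0] += 1
        if truth_status[clone_id] != "normal":
            arm_alt[key][1] += 1
    fractions = {k: v[1] / v[0] for k, v in arm_alt.items()}
    truth = SyntheticTruth(
        clone_status=truth_status,
        arm_altered_fraction=fractions,
        perturbation_rate=float(np.mean(list(fractions.values()))),
        noise_sd=noise_sd,
    )
    return AcghScenario(experiment=experiment, centromeres=cmap, truth=truth)


DEFAULT_POSITIVITY = {
    "GGT1": {"cowden": 0.80, "apocrine_noncowden": 1.00, "control": 0.015},
    "GCDFP15": {"cowden": 0.53, "apocrine_noncowden": 1.00, "control": 0.20},
    "PTEN": {"cowden": 0.13, "apocrine_noncowden": 1.00, "control": 0.96},
    "ER": {"cowden": 0.73, "apocrine_noncowden": 0.00, "control": 0.70},
    "PR": {"cowden": 0.67, "apocrine_noncowden": 0.00, "control": 0.65},
    "AR": {"cowden": 1.00, "apocrine_noncowden": 1.00, "control": 0.75},
    "EGFR": {"cowden": 0.27, "apocrine_noncowden": 1.00, "control": 0.10},
    "ERBB2": {"cowden": 0.00, "apocrine_noncowden": 0.50, "control": 0.15},
}


def generate_ihc(
    group_sizes: dict[str, int] | None = None,
    positivity_probs: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
) -> IhcScenario:
    """IHC score tables drawn from per-marker, per-group positivity
    probabilities; percent values are drawn uniformly inside the score
    band implied by the positive/negative draw."""
    if seed is None:
        raise DataError("generate_ihc requires a seed")
    rng = np.random.default_rng(seed)
    sizes = group_sizes or {"cowden": 15, "apocrine_noncowden": 2, "control": 69}
    probs = positivity_probs or DEFAULT_POSITIVITY
    for marker, by_group in probs.items():
        for g, p in by_group.items():
            if not 0 <= p <= 1:
                raise DataError(f"positivity prob out of [0,1] for {marker}/{g}")

    rows = []
    for group, size in sizes.items():
        for i in range(size):
            sample = f"{group}_{i:03d}"
            for marker in MARKER_PANEL:
                if marker not in probs:
                    continue
                positive = rng.random() < probs[marker][group]
                herceptest = ""
                if marker == "ERBB2":
                    herceptest = "+++" if positive else ["0", "+", "++"][rng.integers(3)]
                    score = herceptest
                    percent = np.nan
                    intensity = np.nan
                elif marker in SCORE2_MARKERS:
                    if positive:
                        percent = float(np.round(rng.uniform(11, 100), 1))
                    else:
                        percent = (
                            0.0 if rng.random() < 0.7
                            else float(np.round(rng.uniform(1, 10), 1))
                        )
                    score = score_band(percent)
                    intensity = int(rng.integers(1, 4)) if percent > 0 else np.nan
                else:
                    percent = (
                        float(np.round(rng.uniform(1, 100), 1)) if positive else 0.0
                    )
                    score = score_band(percent)
                    intensity = int(rng.integers(1, 4)) if percent > 0 else np.nan
                rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "marker": marker,
                        "percent_positive_cells": percent,
                        "intensity": intensity,
                        "score": score,
                        "herceptest": herceptest,
                    }
                )
    table = IhcScoreTable(pd.DataFrame(rows))
    truth = SyntheticTruth(positivity_probs={m: dict(g) for m, g in probs.items()})
    return IhcScenario(table=table, truth=truth)


def score_band(percent: float) -> int:
    from .ihc import score_from_percent

    return score_from_percent(percent)
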