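"""End-to-end orchestration with a YAML config, fixed seeds and a
machine-readable run manifest.

Stage order: probe filtering -> unsupervised clustering -> centroid
subtype assignment -> supervised signature -> gene-set enrichment -> PCA
projection, plus aCGH calling and IHC testing when their inputs are
present in the config. Every threshold is surfaced in the config and
echoed into the manifest together with per-stage counts, so a run can be
reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import acgh as acgh_mod
from .centroids import assign_subtypes, assignments_to_frame
from .clustering import correlation_distance, cut_dendrogram, ward_cluster
from .enrichment import enrich_signature
from .filtering import select_clustering_probes
from .io import (
    DataError,
    read_centroids,
    read_centromeres,
    read_clone_table,
    read_expression_matrix,
    read_gene_sets,
    read_probe_annotation,
    read_sample_annotation,
)
from .projection import gmm_cluster, pca_scores
from .signature import derive_signature

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; mirrors the YAML layout."""

    expression: str
    probe_annotation: str
    out_dir: str
    sample_annotation: str | None = None
    centroids: dict[str, str] = field(default_factory=dict)  # scheme name -> path
    gene_sets: str | None = None
    clones: str | None = None
    centromeres: str | None = None
    seed: int | None = None
    p_thresh: float = 0.01
    rcv_cap: float = 10.0
    rcv_percentile: float = 95.0
    intensity_percentile: float = 90.0
    min_log2: float = 10.0
    n_clusters: int = 6
    center: str = "median"
    signature_group_column: str = "cowden_status"
    signature_p: float = 0.01
    signature_keep: int = 200
    n_trees: int = 2000
    acgh_gain: float = 1.2
    acgh_loss: float = 0.8
    acgh_amp: float = 2.0
    acgh_snr_min: float = 3.0
    acgh_sd_max: float = 0.1
    acgh_max_missing: float = 0.5

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("p_thresh", 0, 1),
            ("signature_p", 0, 1),
            ("rcv_percentile", 0, 100),
            ("intensity_percentile", 0, 100),
            ("acgh_max_missing", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise DataError(f"config {name}={v} outside [{lo}, {hi}]")
        if self.acgh_loss >= self.acgh_gain or self.acgh_gain > self.acgh_amp:
            raise DataError("aCGH thresholds must satisfy loss < gain <= amp")
        if self.center not in ("median", "none"):
            raise DataError(f"center must be median|none, got {self.center!r}")
        if self.sample_annotation is not None and self.seed is None:
            # the supervised forest stage will run; it is stochastic
            raise DataError("config must set a seed when the signature stage is enabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written to
    ``out_dir/manifest.json``). Any stage failure aborts with the stage
    name prefixed to the cause."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "p_thresh", "rcv_cap", "rcv_percentile", "intensity_percentile",
                "min_log2", "n_clusters", "center", "signature_p",
                "signature_keep", "n_trees", "acgh_gain", "acgh_loss",
                "acgh_amp", "acgh_snr_min", "acgh_sd_max", "acgh_max_missing",
            )
        },
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise DataError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    X = stage("read")(lambda: read_expression_matrix(config.expression))
    ann = stage("read")(lambda: read_probe_annotation(config.probe_annotation))
    samples = (
        stage("read")(lambda: read_sample_annotation(config.sample_annotation))
        if config.sample_annotation
        else None
    )

    # --- probe filtering -------------------------------------------------
    def _filter():
        return select_clustering_probes(
            X, ann,
            p_thresh=config.p_thresh,
            rcv_cap=config.rcv_cap,
            rcv_percentile=config.rcv_percentile,
            intensity_percentile=config.intensity_percentile,
            min_log2=config.min_log2,
        )
    probes, report = stage("filter")(_filter)
    manifest["stages"]["filter"] = {
        "n_input": report.n_input,
        "n_after_intensity": report.n_after_intensity,
        "n_after_variance": report.n_after_variance,
        "n_after_rcv": report.n_after_rcv,
        "varmed": report.varmed,
    }
    report_path = out / "filter_report.tsv"
    report.table.to_csv(report_path, sep="\t")

    # --- unsupervised clustering -----------------------------------------
    def _cluster():
        Xf = X.subset_probes(probes)
        D = correlation_distance(Xf, axis="samples")
        dend = ward_cluster(D, leaf_ids=Xf.sample_ids)
        labels = cut_dendrogram(dend, config.n_clusters)
        return dend, labels
    dend, cluster_labels = stage("cluster")(_cluster)
    manifest["stages"]["cluster"] = {
        "n_samples": dend.n_leaves,
        "k": config.n_clusters,
        "cluster_sizes": pd.Series(cluster_labels).value_counts().sort_index().tolist(),
    }
    (out / "dendrogram.json").write_text(
        json.dumps(
            {
                "leaf_ids": dend.leaf_ids,
                "merges": [[int(a), int(b)] for a, b in dend.merges],
                "heights": [float(h) for h in dend.heights],
            }
        )
    )
    pd.Series(cluster_labels, name="cluster").rename_axis("sample_id").to_csv(
        out / "clusters.tsv", sep="\t"
    )

    # --- centroid subtype assignment -------------------------------------
    subtype_frames = {}
    for scheme, path in config.centroids.items():
        def _assign(path=path):
            cents = read_centroids(path)
            return assignments_to_frame(
                assign_subtypes(X, cents, ann, center=config.center)
            )
        frame = stage(f"subtype:{scheme}")(_assign)
        subtype_frames[scheme] = frame
        frame.to_csv(out / f"subtypes_{scheme}.tsv", sep="\t")
        manifest["stages"][f"subtype_{scheme}"] = {
            "n_common_genes": int(frame["n_common_genes"].iloc[0]),
            "class_counts": frame["assigned_subtype"].value_counts().to_dict(),
        }

    # --- supervised signature + enrichment --------------------------------
    signature = None
    if samples is not None and config.signature_group_column in samples.table.columns:
        def _signature():
            groups = samples.table[config.signature_group_column]
            return derive_signature(
                X, groups, ann,
                p_thresh=config.signature_p,
                n_keep=config.signature_keep,
                n_trees=config.n_trees,
                seed=config.seed,
                contrast=config.signature_group_column,
            )
        signature = stage("signature")(_signature)
        manifest["stages"]["signature"] = {
            "screen_size": signature.screen_size,
            "n_selected": len(signature.selected_probes),
            "pi0": signature.pi0,
            "lfdr_at_threshold": signature.lfdr_at_threshold,
            "n_genes_up": len(signature.genes_up),
            "n_genes_down": len(signature.genes_down),
        }
        signature.table.to_csv(out / "signature.tsv", sep="\t")
        (out / "signature_provenance.json").write_text(
            json.dumps(
                {
                    "contrast": signature.contrast,
                    "p_thresh": config.signature_p,
                    "n_keep": config.signature_keep,
                    "seed": config.seed,
                    "screen_size": signature.screen_size,
                }
            )
        )

        if config.gene_sets:
            def _enrich():
                sets = read_gene_sets(config.gene_sets)
                universe = ann.genes_for(
                    [p for p in X.probe_ids if not ann.table.at[p, "is_control"]]
                )
                sig_genes = signature.genes_up + signature.genes_down
                return enrich_signature(sig_genes, sets, universe)
            enrich = stage("enrichment")(_enrich)
            enrich.to_csv(out / "enrichment.tsv", sep="\t")
            manifest["stages"]["enrichment"] = {"n_sets": len(enrich)}

        def _project():
            sig_probes = signature.selected_probes
            proj = pca_scores(X, sig_probes, k=2)
            labels, bics, best_k = gmm_cluster(proj.scores, seed=config.seed)
            return proj, labels, best_k
        proj, gmm_labels, best_k = stage("projection")(_project)
        proj.scores.assign(gmm=gmm_labels).to_csv(out / "pca_scores.tsv", sep="\t")
        manifest["stages"]["projection"] = {
            "explained_variance": [float(v) for v in proj.explained_variance_ratio],
            "gmm_k": int(best_k),
        }

    # --- aCGH ---------------------------------------------------------------
    if config.clones and config.centromeres:
        def _acgh():
            exp = read_clone_table(config.clones)
            cmap = read_centromeres(config.centromeres)
            retained = acgh_mod.exclude_sparse_clones(
                exp, config.acgh_max_missing,
                snr_min=config.acgh_snr_min, sd_max=config.acgh_sd_max,
            )
            rates = {}
            frames = []
            for tumor in exp.tumor_ids:
                calls = acgh_mod.call_tumor(
                    exp, tumor, cmap, clones=retained,
                    snr_min=config.acgh_snr_min, sd_max=config.acgh_sd_max,
                    gain=config.acgh_gain, loss=config.acgh_loss, amp=config.acgh_amp,
                )
                summary = acgh_mod.perturbation_rate(calls, cmap)
                rates[tumor] = summary.rate
                frames.append(acgh_mod.calls_to_frame(calls).assign(tumor_id=tumor))
            return pd.concat(frames), rates
        calls_frame, rates = stage("acgh")(_acgh)
        calls_frame.to_csv(out / "acgh_calls.tsv", sep="\t")
        pd.Series(rates, name="perturbation_rate").rename_axis("tumor_id").to_csv(
            out / "perturbation_rates.tsv", sep="\t"
        )
        manifest["stages"]["acgh"] = {
            "n_tumors": len(rates),
            "rates": {k: float(v) for k, v in rates.items()},
        }

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
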