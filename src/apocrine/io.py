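"""Shared domain types and tabular readers/writers.

All tables are UTF-8 TSV with a single header row; missing numeric values
are encoded ``NA``. Genomic positions are 1-based inclusive base pairs.
Readers validate type invariants and raise :class:`DataError` with the
offending identifier or file position rather than silently repairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ExpressionMatrix",
    "ProbeAnnotation",
    "SampleAnnotation",
    "CentroidSet",
    "GeneSet",
    "GeneSetCollection",
    "AcghExperiment",
    "CentromereMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_centroids",
    "write_centroids",
    "read_gene_sets",
    "write_gene_sets",
    "read_clone_table",
    "write_clone_table",
    "read_centromeres",
    "write_centromeres",
    "read_ihc_table",
    "write_ihc_table",
]

CENTROID_NAMESPACES = ("symbol", "unigene", "entrez")


class DataError(ValueError):
    """A file or in-memory table violates a domain-type invariant."""


def _check_unique(ids: Sequence, what: str) -> None:
    seen: dict = {}
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what}: {i!r}")
        seen[i] = True


@dataclass
class ExpressionMatrix:
    """Log2 intensity values, probes x samples.

    ``values`` is a float matrix aligned with ``probe_ids`` (rows) and
    ``sample_ids`` (columns). Missing entries are NaN; everything else must
    be finite.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        if np.isinf(self.values).any():
            raise DataError("expression values must be finite or NA")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in idx]
        if missing:
            raise DataError(f"unknown probe ids: {missing[:5]}")
        rows = [idx[p] for p in probes]
        return ExpressionMatrix(self.values[rows], list(probes), list(self.sample_ids))

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise DataError(f"unknown sample ids: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(self.values[:, cols], list(self.probe_ids), list(samples))


@dataclass
class ProbeAnnotation:
    """Probe -> gene mapping with a control flag.

    ``table`` is indexed by unique probe_id with columns gene_symbol,
    unigene_id, entrez_id (strings, empty string for unannotated) and
    is_control (bool).
    """

    table: pd.DataFrame

    COLUMNS = ("gene_symbol", "unigene_id", "entrez_id", "is_control")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"probe annotation missing columns: {missing}")
        _check_unique(list(self.table.index), "probe id")
        self.table = self.table.copy()
        for c in ("gene_symbol", "unigene_id", "entrez_id"):
            self.table[c] = self.table[c].fillna("").astype(str)
        self.table["is_control"] = self.table["is_control"].astype(bool)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def control_probes(self) -> list[str]:
        return list(self.table.index[self.table["is_control"]])

    def genes_for(self, probes: Iterable[str], namespace: str = "symbol") -> list[str]:
        """De-duplicated, order-preserving gene ids for a probe list."""
        col = {"symbol": "gene_symbol", "unigene": "unigene_id", "entrez": "entrez_id"}[namespace]
        out: list[str] = []
        seen: set[str] = set()
        for p in probes:
            g = self.table.at[p, col]
            if g and g not in seen:
                seen.add(g)
                out.append(g)
        return out


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation: Cowden status, germline mutation,
    plus any number of label-scheme columns (e.g. subtype calls)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "sample id")
        if "cowden_status" in self.table.columns:
            bad = set(self.table["cowden_status"].dropna()) - {"cowden", "non_cowden"}
            if bad:
                raise DataError(f"invalid cowden_status values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class CentroidSet:
    """Published per-subtype mean expression vectors.

    ``namespace`` declares the gene-identifier space (symbol | unigene |
    entrez); ``values`` is genes x subtypes.
    """

    namespace: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.namespace not in CENTROID_NAMESPACES:
            raise DataError(
                f"centroid namespace {self.namespace!r} not in {CENTROID_NAMESPACES}"
            )
        _check_unique(list(self.values.columns), "subtype name")
        _check_unique(list(self.values.index), "centroid gene id")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subtype_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        # de-duplicate, keep first-occurrence order
        seen: set[str] = set()
        out = []
        for m in self.members:
            if m not in seen:
                seen.add(m)
                out.append(m)
        self.members = tuple(out)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise DataError(f"duplicate gene-set name: {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set


@dataclass
class AcghExperiment:
    """Two-color BAC-clone copy-number experiment with replicate spots.

    ``clones`` is indexed by clone_id with columns chromosome (str) and
    position (1-based bp). ``spots`` is a long table with one row per
    replicate spot per tumor: clone_id, tumor_id, cy3, cy5, snr, valid.
    """

    clones: pd.DataFrame
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.clones.index), "clone id")
        if (self.clones["position"] < 0).any():
            bad = self.clones.index[self.clones["position"] < 0][0]
            raise DataError(f"negative genomic position for clone {bad!r}")
        need = {"clone_id", "tumor_id", "cy3", "cy5", "snr", "valid"}
        missing = need - set(self.spots.columns)
        if missing:
            raise DataError(f"spot table missing columns: {sorted(missing)}")
        unknown = set(self.spots["clone_id"]) - set(self.clones.index)
        if unknown:
            raise DataError(f"spots reference unknown clones: {sorted(unknown)[:5]}")

    @property
    def tumor_ids(self) -> list[str]:
        return sorted(set(self.spots["tumor_id"]))

    @property
    def clone_ids(self) -> list[str]:
        return list(self.clones.index)

    def spots_for(self, clone_id: str, tumor_id: str) -> pd.DataFrame:
        s = self.spots
        return s[(s["clone_id"] == clone_id) & (s["tumor_id"] == tumor_id)]


@dataclass
class CentromereMap:
    """Centromere position and chromosome length per chromosome (bp)."""

    table: pd.DataFrame  # index chromosome, columns centromere, length

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "chromosome")
        t = self.table
        bad = t[(t["centromere"] <= 0) | (t["centromere"] >= t["length"])]
        if len(bad):
            raise DataError(
                f"centromere must lie strictly inside (0, length) for {list(bad.index)}"
            )

    def arm_of(self, chromosome: str, position: float) -> str:
        """p if the position precedes the centromere, else q (centromere -> q)."""
        if chromosome not in self.table.index:
            raise DataError(f"chromosome {chromosome!r} absent from centromere map")
        return "p" if position < self.table.at[chromosome, "centromere"] else "q"

    @property
    def chromosomes(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# TSV / GMT readers and writers
# ---------------------------------------------------------------------------

_NA = "NA"


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a probes x samples log2 matrix; first column probe ids, header
    row sample ids, numeric body with NA for missing."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    if frame.shape[1] == 0:
        raise DataError(f"{path}: no sample columns")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna() & (frame[col].astype(str) != _NA)
        if bad.any():
            row = frame.index[bad][0]
            raise DataError(f"{path}: non-numeric value at probe {row!r}, sample {col!r}")
        frame[col] = coerced
    frame.index = frame.index.astype(str)
    return ExpressionMatrix.from_frame(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", na_rep=_NA, index_label="probe_id")


def read_probe_annotation(path) -> ProbeAnnotation:
    t = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[_NA], keep_default_na=False)
    if "is_control" not in t.columns:
        raise DataError(f"{path}: missing is_control column")
    t["is_control"] = t["is_control"].map({"1": True, "0": False, "True": True, "False": False})
    if t["is_control"].isna().any():
        raise DataError(f"{path}: is_control must be 0/1")
    t.index = t.index.astype(str)
    return ProbeAnnotation(t)


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    t = ann.table.copy()
    t["is_control"] = t["is_control"].astype(int)
    t.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_annotation(path) -> SampleAnnotation:
    t = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[_NA], keep_default_na=False)
    t.index = t.index.astype(str)
    return SampleAnnotation(t)


def write_sample_annotation(ann: SampleAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id", na_rep=_NA)


def read_centroids(path) -> CentroidSet:
    """Read a gene x subtype centroid table.

    The header of the first column declares the identifier namespace
    (``symbol``, ``unigene`` or ``entrez``); it is never guessed.
    """
    frame = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    namespace = frame.columns[0]
    if namespace not in CENTROID_NAMESPACES:
        raise DataError(
            f"{path}: first header field {namespace!r} must declare the gene "
            f"namespace, one of {CENTROID_NAMESPACES}"
        )
    frame = frame.set_index(namespace)
    frame.index = frame.index.astype(str)
    frame = frame.astype(float)
    return CentroidSet(namespace=namespace, values=frame)


def write_centroids(centroids: CentroidSet, path) -> None:
    centroids.values.to_csv(path, sep="\t", index_label=centroids.namespace, na_rep=_NA)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then members, tab-separated.

    Duplicate members within a set are dropped (first occurrence kept).
    """
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *members = fields
            members = [m for m in members if m]
            coll.add(GeneSet(name=name, description=desc, members=tuple(members)))
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


_CLONE_COLS = ["clone_id", "chromosome", "position", "tumor_id", "cy3", "cy5", "snr", "valid"]


def read_clone_table(path) -> AcghExperiment:
    """Read a long-format aCGH spot table (one row per replicate spot)."""
    t = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    missing = [c for c in _CLONE_COLS if c not in t.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    t["clone_id"] = t["clone_id"].astype(str)
    t["tumor_id"] = t["tumor_id"].astype(str)
    t["chromosome"] = t["chromosome"].astype(str)
    for c in ("position", "cy3", "cy5", "snr"):
        t[c] = pd.to_numeric(t[c], errors="coerce")
    t["valid"] = t["valid"].astype(int).astype(bool)
    clones = (
        t[["clone_id", "chromosome", "position"]]
        .drop_duplicates(subset="clone_id")
        .set_index("clone_id")
    )
    conflict = t.groupby("clone_id")[["chromosome", "position"]].nunique()
    if (conflict > 1).any().any():
        bad = conflict.index[(conflict > 1).any(axis=1)][0]
        raise DataError(f"{path}: clone {bad!r} mapped to more than one locus")
    spots = t[["clone_id", "tumor_id", "cy3", "cy5", "snr", "valid"]]
    return AcghExperiment(clones=clones, spots=spots)


def write_clone_table(experiment: AcghExperiment, path) -> None:
    t = experiment.spots.merge(
        experiment.clones, left_on="clone_id", right_index=True, how="left"
    )
    t["valid"] = t["valid"].astype(int)
    t[_CLONE_COLS].to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_centromeres(path) -> CentromereMap:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    missing = [c for c in ("centromere", "length") if c not in t.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return CentromereMap(t[["centromere", "length"]].astype(float))


def write_centromeres(cmap: CentromereMap, path) -> None:
    cmap.table.to_csv(path, sep="\t", index_label="chromosome")


def read_ihc_table(path) -> pd.DataFrame:
    """Read an immunohistochemistry score table as a plain DataFrame.

    Scoring semantics (0/1/2 bands, Herceptest) live in :mod:`apocrine.ihc`.
    """
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_ihc_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
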