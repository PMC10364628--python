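"""Readers and writers for the pipeline's external tables.

Canonical dialect is tab-separated UTF-8 with ``#`` comment lines ignored,
matching QIIME2 / PICRUSt2 export conventions: sample metadata as a QIIME2
sample-metadata TSV, feature tables as feature-id-per-row TSVs with an
optional trailing ``taxonomy`` column, and pathway contributions as a
PICRUSt2-style pathways x features TSV.  BIOM-JSON feature tables are
accepted read-only as a convenience.

Taxonomy strings are treated as opaque Greengenes-style labels; they are
split on ``"; "`` only for reporting, never resolved against an ontology.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

VALID_GROUPS = ("GDM", "control")
VALID_TIMEPOINTS = ("t1", "t2", "t3")

METADATA_COLUMNS = ("sample_id", "subject_id", "group", "timepoint")


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample: which subject, arm, and timepoint it belongs to."""

    sample_id: str
    subject_id: str
    group: str  # "GDM" | "control"
    timepoint: str  # "t1" | "t2" | "t3"

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r} for sample {self.sample_id!r}")
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r} for sample {self.sample_id!r}")


@dataclass
class OtuTable:
    """Integer count matrix (samples x features) with lineage annotations."""

    sample_ids: List[str]
    feature_ids: List[str]
    counts: np.ndarray  # (n_samples, n_features) non-negative ints
    lineage: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicated feature ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def shape(self):
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a samples x features DataFrame."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class PathwayDb:
    """Pathway -> feature contribution weights plus pathway -> compound sets."""

    pathway_ids: List[str]
    feature_ids: List[str]
    contributions: np.ndarray  # (n_pathways, n_features), non-negative
    compounds: Dict[str, Set[str]]
    hormone_compounds: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)
        if self.contributions.shape != (len(self.pathway_ids), len(self.feature_ids)):
            raise ValueError("contribution matrix shape mismatch")
        if np.any(self.contributions < 0):
            raise ValueError("negative contribution weights")
        missing = set(self.pathway_ids) ^ set(self.compounds)
        if missing:
            raise ConsistencyError(
                "pathway ids differ between contributions and compound catalog: "
                + ", ".join(sorted(missing))
            )
        for pid, comp in self.compounds.items():
            if not comp:
                raise ValueError(f"pathway {pid!r} has an empty compound set")
        row_sums = self.contributions.sum(axis=1)
        if np.any(row_sums == 0):
            bad = [self.pathway_ids[i] for i in np.nonzero(row_sums == 0)[0]]
            raise ValueError(f"all-zero contribution rows: {', '.join(bad)}")


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    return df


def read_metadata(path, format: str = "tsv") -> List[SampleRecord]:
    """Read sample metadata and validate uniqueness invariants.

    The file must name columns ``sample_id``, ``subject_id``, ``group`` and
    ``timepoint``.  Duplicate sample ids and duplicate (subject, timepoint)
    pairs are rejected.
    """
    if format != "tsv":
        raise ValueError(f"unsupported metadata format {format!r}")
    df = _read_tsv(path)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records: List[SampleRecord] = []
    seen_samples: Set[str] = set()
    seen_pairs: Set[tuple] = set()
    for idx, row in df.iterrows():
        try:
            rec = SampleRecord(
                sample_id=row["sample_id"],
                subject_id=row["subject_id"],
                group=row["group"],
                timepoint=row["timepoint"],
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {idx}: {exc}") from exc
        if rec.sample_id in seen_samples:
            raise ValueError(f"{path} row {idx}: duplicate sample_id {rec.sample_id!r}")
        pair = (rec.subject_id, rec.timepoint)
        if pair in seen_pairs:
            raise ValueError(f"{path} row {idx}: duplicate (subject, timepoint) {pair!r}")
        seen_samples.add(rec.sample_id)
        seen_pairs.add(pair)
        records.append(rec)
    if not records:
        raise FormatError(f"{path}: no data rows")
    return records


def read_feature_table(path) -> OtuTable:
    """Read a QIIME2-style feature table TSV (features as rows).

    First column holds feature ids, the header holds sample ids, and an
    optional final ``taxonomy`` column holds Greengenes-style lineage strings.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a feature-id column and at least one sample column")
    feature_col = df.columns[0]
    feature_ids = df[feature_col].tolist()
    dupes = df[feature_col][df[feature_col].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicated feature ids: {', '.join(sorted(set(dupes)))}")
    lineage: Dict[str, str] = {}
    sample_cols = list(df.columns[1:])
    if sample_cols and sample_cols[-1].lower() == "taxonomy":
        tax = df[sample_cols[-1]].fillna("")
        lineage = dict(zip(feature_ids, tax))
        sample_cols = sample_cols[:-1]
    else:
        lineage = {fid: "" for fid in feature_ids}
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    counts = np.zeros((len(sample_cols), len(feature_ids)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            try:
                val = int(float(raw))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: non-numeric cell at (feature {feature_ids[i]!r}, sample {col!r}): {raw!r}"
                ) from exc
            if val < 0:
                raise ValueError(
                    f"{path}: negative count at (feature {feature_ids[i]!r}, sample {col!r}): {raw!r}"
                )
            counts[j, i] = val
    return OtuTable(sample_ids=sample_cols, feature_ids=feature_ids, counts=counts, lineage=lineage)


def read_feature_table_biom(path) -> OtuTable:
    """Read a BIOM-JSON (format 1.0) feature table, read-only convenience."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        shape = doc["shape"]
        mtype = doc.get("matrix_type", "dense")
        data = doc["data"]
    except KeyError as exc:
        raise FormatError(f"{path}: not a BIOM-JSON table (missing key {exc})") from exc
    counts = np.zeros((shape[1], shape[0]), dtype=np.int64)  # samples x features
    if mtype == "dense":
        for i, row in enumerate(data):
            counts[:, i] = np.asarray(row, dtype=np.int64)
    else:
        for i, j, v in data:
            counts[int(j), int(i)] = int(v)
    lineage = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy", "")
        if isinstance(tax, list):
            tax = "; ".join(tax)
        lineage[r["id"]] = tax
    return OtuTable(sample_ids=cols, feature_ids=rows, counts=counts, lineage=lineage)


def read_pathway_db(contrib_path, compounds_path, hormone_path=None) -> PathwayDb:
    """Read pathway contributions and the pathway -> compound catalog.

    The contribution file is a PICRUSt2-style pathways x features TSV; the
    compound file maps each pathway id to a comma-separated compound list.
    Pathway id sets must agree between the two files.
    """
    contrib = _read_tsv(contrib_path)
    if contrib.shape[1] < 2:
        raise FormatError(f"{contrib_path}: need a pathway-id column and feature columns")
    pathway_ids = contrib.iloc[:, 0].tolist()
    feature_ids = list(contrib.columns[1:])
    try:
        weights = contrib.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{contrib_path}: non-numeric contribution cell: {exc}") from exc

    comp_df = _read_tsv(compounds_path, header=None, names=["pathway_id", "compounds"])
    if comp_df["pathway_id"].iloc[0] == "pathway_id":  # tolerate a header line
        comp_df = comp_df.iloc[1:]
    compounds: Dict[str, Set[str]] = {}
    for _, row in comp_df.iterrows():
        raw = row["compounds"] if pd.notna(row["compounds"]) else ""
        items = {c.strip() for c in str(raw).split(",") if c.strip()}
        compounds[row["pathway_id"]] = items

    only_contrib = set(pathway_ids) - set(compounds)
    only_comp = set(compounds) - set(pathway_ids)
    if only_contrib or only_comp:
        raise ConsistencyError(
            "pathway ids present in one file only: "
            + ", ".join(sorted(only_contrib | only_comp))
        )
    hormone: Set[str] = set()
    if hormone_path is not None:
        with open(hormone_path, "r", encoding="utf-8") as fh:
            hormone = {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}
    return PathwayDb(
        pathway_ids=pathway_ids,
        feature_ids=feature_ids,
        contributions=weights,
        compounds={pid: compounds[pid] for pid in pathway_ids},
        hormone_compounds=hormone,
    )


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.subject_id, r.group, r.timepoint) for r in records],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def write_feature_table(table: OtuTable, path) -> None:
    """Write a feature table in the canonical features-as-rows TSV layout."""
    df = pd.DataFrame(table.counts.T, index=table.feature_ids, columns=table.sample_ids)
    df.index.name = "feature_id"
    if any(table.lineage.get(fid, "") for fid in table.feature_ids):
        df["taxonomy"] = [table.lineage.get(fid, "") for fid in table.feature_ids]
    df.to_csv(path, sep="\t")


def write_pathway_db(db: PathwayDb, contrib_path, compounds_path, hormone_path=None) -> None:
    contrib = pd.DataFrame(db.contributions, index=db.pathway_ids, columns=db.feature_ids)
    contrib.index.name = "pathway_id"
    contrib.to_csv(contrib_path, sep="\t")
    with open(compounds_path, "w", encoding="utf-8") as fh:
        for pid in db.pathway_ids:
            fh.write(f"{pid}\t{','.join(sorted(db.compounds[pid]))}\n")
    if hormone_path is not None:
        with open(hormone_path, "w", encoding="utf-8") as fh:
            for cid in sorted(db.hormone_compounds):
                fh.write(cid + "\n")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> Dict[str, object]:
    """Write one TSV per result table plus a key-value run manifest.

    Floats are written at full repr precision so read-back reproduces values
    to better than 12 decimal digits.  Returns the manifest as a dict.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    files = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        files[name] = str(path)
    manifest: Dict[str, object] = {
        "gutshift_version": _package_version(),
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    if seed is not None:
        manifest["seed"] = seed
    if config:
        for key, value in config.items():
            manifest[f"config.{key}"] = value
    for name, df in tables.items():
        manifest[f"rows.{name}"] = len(df)
    with open(out_dir / "manifest.txt", "w", encoding="utf-8") as fh:
        for key, value in manifest.items():
            fh.write(f"{key}\t{value}\n")
    manifest["files"] = files
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__


def read_result_table(path) -> pd.DataFrame:
    """Read back a result TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
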