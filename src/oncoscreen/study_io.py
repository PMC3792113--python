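"""Reading and writing expression studies, manifests and result tables.

On-disk conventions
-------------------
* Expression matrix: tab-separated text, genes in rows. The first column
  holds gene identifiers (opaque, case-sensitive strings), the header row
  holds sample identifiers. Missing values may be written as an empty field
  or ``NA``; ``NA`` is used on write.
* Sample annotation: two-column TSV ``sample_id<TAB>group`` with
  ``group`` in ``{cancer, normal}``.
* Study manifest: YAML mapping with a ``studies`` list (study_id, matrix,
  annotation, cancer_type, cancer_subtype, optional scale) and an optional
  ``options`` mapping; relative paths are resolved against the manifest.
* All result tables are TSV with one header row, decimal point only,
  scientific notation accepted (``1.72E-24``).

Expression intensities are kept on the linear scale in memory. Matrices
declared ``log2`` on disk are exponentiated on load so all downstream
fold-change arithmetic has a single code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CANCER = "cancer"
NORMAL = "normal"
GROUPS = (CANCER, NORMAL)

#: Columns of the above-threshold records table (one row per gated
#: (gene, study) analysis).
RECORD_COLUMNS = [
    "gene",
    "cancer_type",
    "cancer_subtype",
    "direction",
    "p_value",
    "fold_change",
    "percentile",
    "study_id",
]

#: Columns of the per-study differential-expression results table.
RESULT_COLUMNS = [
    "study_id",
    "gene",
    "t",
    "p",
    "fold_change",
    "direction",
    "rank",
    "n_genes",
    "percentile",
    "q",
]

META_COLUMNS = ["gene", "cancer_subtype", "n_datasets", "median_p", "median_rank", "significant"]
FOLD_COLUMNS = ["gene", "cancer_subtype", "direction", "k", "mean_fold", "sem_fold"]


class StudyFormatError(ValueError):
    """Malformed on-disk study data (header, duplicate ids, bad cells)."""


class StudyValidationError(ValueError):
    """Structurally well-formed input violating a study invariant."""


@dataclass
class ExpressionStudy:
    """One two-group microarray study: a genes x samples intensity matrix.

    ``values`` is linear-scale with NaN marking missing measurements;
    ``groups`` maps every sample to ``cancer`` or ``normal``.
    """

    study_id: str
    cancer_type: str
    cancer_subtype: str
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = self.groups.astype(str)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if self.values.shape[0] == 0:
            raise StudyValidationError(f"{self.study_id}: study has no genes")
        if self.values.index.duplicated().any():
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise StudyFormatError(f"{self.study_id}: duplicate gene identifiers {dups}")
        if not self.values.columns.equals(pd.Index(self.groups.index)):
            missing = [s for s in self.values.columns if s not in self.groups.index]
            if missing:
                raise StudyValidationError(
                    f"{self.study_id}: samples missing from annotation: {missing}"
                )
            self.groups = self.groups.loc[self.values.columns]
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise StudyValidationError(f"{self.study_id}: unknown group labels {bad}")
        for g in GROUPS:
            n = int((self.groups == g).sum())
            if n < 2:
                raise StudyValidationError(
                    f"{self.study_id}: group '{g}' has {n} samples; at least 2 required"
                )
        with np.errstate(invalid="ignore"):
            arr = self.values.to_numpy(float)
        if np.isinf(arr).any():
            raise StudyValidationError(f"{self.study_id}: non-finite intensities present")
        if np.isnan(arr).all(axis=1).any():
            empty = list(self.values.index[np.isnan(arr).all(axis=1)])
            raise StudyValidationError(f"{self.study_id}: all-missing gene rows {empty[:5]}")

    # -- convenience --------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return int(self.values.shape[0])

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class ManifestEntry:
    study_id: str
    matrix: Path
    annotation: Path
    cancer_type: str
    cancer_subtype: str
    scale: str = "linear"


@dataclass
class StudyManifest:
    entries: list[ManifestEntry]
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.study_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise StudyValidationError("duplicate study_id in manifest")


def _parse_matrix(matrix_path: Path) -> pd.DataFrame:
    raw = pd.read_csv(
        matrix_path, sep="\t", dtype=str, index_col=0,
        na_values=["NA"], keep_default_na=False,
    )
    if raw.columns.duplicated().any() or any(c == "" for c in raw.columns):
        raise StudyFormatError(f"{matrix_path}: malformed header (duplicate or empty sample ids)")
    if raw.index.duplicated().any():
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise StudyFormatError(f"{matrix_path}: duplicate gene rows {dups}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cleaned = raw[col].replace("", np.nan)
        numeric = pd.to_numeric(cleaned, errors="coerce")
        bad = numeric.isna() & cleaned.notna()
        if bad.any():
            gene = bad.idxmax()
            raise StudyFormatError(
                f"{matrix_path}: non-numeric cell at gene '{gene}', sample '{col}': "
                f"{raw.loc[gene, col]!r}"
            )
        values[col] = numeric
    return values


def read_expression_study(
    matrix_path: str | Path,
    annotation_path: str | Path,
    *,
    study_id: str,
    cancer_type: str,
    cancer_subtype: str,
    scale: str = "linear",
) -> ExpressionStudy:
    """Load and validate one study from a matrix + annotation TSV pair.

    Gene rows that are missing in every sample carry no information and are
    dropped. ``scale='log2'`` converts intensities to linear on load.
    """
    matrix_path, annotation_path = Path(matrix_path), Path(annotation_path)
    values = _parse_matrix(matrix_path)
    if scale not in ("linear", "log2"):
        raise StudyValidationError(f"unknown scale hint {scale!r}")
    if scale == "log2":
        values = 2.0 ** values

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if list(ann.columns[:2]) != ["sample_id", "group"]:
        raise StudyFormatError(
            f"{annotation_path}: expected header 'sample_id<TAB>group', got {list(ann.columns)}"
        )
    groups = ann.set_index("sample_id")["group"]
    unknown = [s for s in values.columns if s not in groups.index]
    if unknown:
        raise StudyValidationError(
            f"{study_id}: samples in matrix but not in annotation: {unknown}"
        )
    groups = groups.loc[values.columns]

    values = values.loc[~values.isna().all(axis=1)]
    return ExpressionStudy(
        study_id=study_id,
        cancer_type=cancer_type,
        cancer_subtype=cancer_subtype,
        values=values,
        groups=groups,
    )


def write_expression_study(study: ExpressionStudy, matrix_path: str | Path,
                           annotation_path: str | Path) -> None:
    """Write a study back to the matrix/annotation TSV pair (linear scale)."""
    out = study.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t", na_rep="NA")
    ann = pd.DataFrame({"sample_id": study.sample_ids, "group": study.groups.to_numpy()})
    ann.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifests


def read_manifest(path: str | Path) -> StudyManifest:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "studies" not in doc:
        raise StudyFormatError(f"{path}: manifest must be a mapping with a 'studies' list")
    base = path.parent
    entries = []
    for item in doc["studies"]:
        entries.append(
            ManifestEntry(
                study_id=str(item["study_id"]),
                matrix=(base / item["matrix"]).resolve(),
                annotation=(base / item["annotation"]).resolve(),
                cancer_type=str(item.get("cancer_type", "unspecified")),
                cancer_subtype=str(item.get("cancer_subtype", "unspecified")),
                scale=str(item.get("scale", "linear")),
            )
        )
    manifest = StudyManifest(entries=entries, options=doc.get("options", {}) or {})
    for e in manifest.entries:
        for p in (e.matrix, e.annotation):
            if not Path(p).exists():
                raise StudyFormatError(f"manifest entry {e.study_id}: missing file {p}")
    return manifest


def write_manifest(manifest: StudyManifest, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "studies": [
            {
                "study_id": e.study_id,
                "matrix": str(Path(e.matrix).name if Path(e.matrix).parent == path.parent
                              else e.matrix),
                "annotation": str(Path(e.annotation).name
                                  if Path(e.annotation).parent == path.parent else e.annotation),
                "cancer_type": e.cancer_type,
                "cancer_subtype": e.cancer_subtype,
                "scale": e.scale,
            }
            for e in manifest.entries
        ],
        "options": manifest.options,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_studies(manifest: StudyManifest) -> list[ExpressionStudy]:
    return [
        read_expression_study(
            e.matrix, e.annotation,
            study_id=e.study_id, cancer_type=e.cancer_type,
            cancer_subtype=e.cancer_subtype, scale=e.scale,
        )
        for e in manifest.entries
    ]


# ---------------------------------------------------------------------------
# result tables


def sort_records(records: pd.DataFrame) -> pd.DataFrame:
    """Deterministic record order: gene, cancer type, subtype, ascending p."""
    return records.sort_values(
        ["gene", "cancer_type", "cancer_subtype", "p_value"], kind="stable"
    ).reset_index(drop=True)


def write_records_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write above-threshold analysis records; round-trips exactly via
    :func:`read_records_table`. An empty frame yields a header-only file."""
    records = records.reindex(columns=RECORD_COLUMNS)
    if len(records):
        records = sort_records(records)
    records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_records_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise StudyFormatError(f"{path}: records table missing columns {missing}")
    if len(df):
        df["percentile"] = df["percentile"].astype(int)
        df[["p_value", "fold_change"]] = df[["p_value", "fold_change"]].astype(float)
    return df[RECORD_COLUMNS]


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    results.reindex(columns=[c for c in RESULT_COLUMNS if c in results.columns]
                    + [c for c in results.columns if c not in RESULT_COLUMNS]
                    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if len(df):
        for col in ("rank", "n_genes", "percentile"):
            if col in df.columns:
                df[col] = df[col].astype(int)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
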