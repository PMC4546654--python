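"""Reading and writing the study's wide peak-area tables.

The on-disk dialect is a wide CSV: one row per sample, a handful of metadata
columns (sample id, tissue, genotype, diet, ...) and one numeric column per
metabolite holding the integrated LC-MS peak area.  Blank cells are
non-detections and are coerced to zero on read.  Because the dialect's header
spelling is not standardized, the metadata columns are declared explicitly by
the caller rather than sniffed.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ValidationError
from .lipids import parse_lipid_name

TISSUES = (
    "striatum",
    "cerebellum",
    "liver",
    "plasma",
    "white_adipose",
    "brown_adipose",
)
CELL_COMPARTMENTS = ("cell_pellet", "growth_media")
GENOTYPES = ("mutant", "wildtype")
DIETS = ("fat45", "fat60", "none")

#: default mapping from logical metadata field -> CSV column name
DEFAULT_METADATA_COLUMNS = {
    "sample_id": "sample_id",
    "subject_id": "subject_id",
    "tissue": "tissue",
    "genotype": "genotype",
    "diet": "diet",
}

_OPTIONAL_META = ("subject_id", "cag_size", "age_days")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sample (one tissue from one mouse, or one culture)."""

    sample_id: str
    tissue: str
    genotype: str
    diet: str
    subject_id: str | None = None
    cag_size: int | None = None
    age_days: int | None = None

    def __post_init__(self):
        if self.tissue not in TISSUES + CELL_COMPARTMENTS:
            raise ValidationError(f"unknown tissue label {self.tissue!r}")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype label {self.genotype!r}")
        if self.diet not in DIETS:
            raise ValidationError(f"unknown diet label {self.diet!r}")
        if self.tissue in CELL_COMPARTMENTS and self.diet != "none":
            raise ValidationError(
                f"cell sample {self.sample_id!r} must have diet='none'"
            )


@dataclass
class PeakTable:
    """Samples x metabolites matrix of non-negative peak areas.

    ``values`` is a DataFrame indexed by sample_id with one column per
    metabolite; ``samples`` is the aligned metadata frame.  Zero encodes
    not-detected.
    """

    samples: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if len(self.samples) != len(self.values):
            raise ValidationError(
                f"metadata has {len(self.samples)} rows but matrix has "
                f"{len(self.values)}"
            )
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[
                self.samples["sample_id"].duplicated(), "sample_id"
            ].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate metabolite name {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"NaN peak area at sample {self.values.index[r]!r}, "
                f"metabolite {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative peak area {arr[r, c]!r} at sample "
                f"{self.values.index[r]!r}, metabolite {self.values.columns[c]!r}"
            )
        for col in ("tissue", "genotype", "diet"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample metadata lacks {col!r} column")
        for rec in self.samples.itertuples(index=False):
            SampleRecord(
                sample_id=str(rec.sample_id),
                tissue=str(rec.tissue),
                genotype=str(rec.genotype),
                diet=str(rec.diet),
            )

    # ------------------------------------------------------------------
    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_tissue(self, tissue: str) -> "PeakTable":
        if tissue not in set(self.samples["tissue"]):
            raise ValidationError(f"tissue {tissue!r} not present in table")
        mask = (self.samples["tissue"] == tissue).to_numpy()
        return PeakTable(
            self.samples.loc[mask].reset_index(drop=True),
            self.values.iloc[np.flatnonzero(mask)].copy(),
        )

    def subset_metabolites(self, names: list[str]) -> "PeakTable":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown metabolites {missing[:3]!r}")
        return PeakTable(self.samples.copy(), self.values[names].copy())

    def tissues(self) -> list[str]:
        return sorted(set(self.samples["tissue"]))


@dataclass(frozen=True)
class AnnotationRecord:
    """Metadata for one metabolite: identifier, LC-MS method, lipid flag."""

    metabolite: str
    compound_id: str | None
    method: str | None
    is_lipid: bool


# ----------------------------------------------------------------------
def read_peak_table(
    path: str | Path,
    metadata_columns: dict[str, str] | None = None,
) -> PeakTable:
    """Read a wide peak-area CSV into a validated :class:`PeakTable`.

    Parameters
    ----------
    path
        CSV file with one row per sample.
    metadata_columns
        Map from logical field name (``sample_id``, ``tissue``, ``genotype``,
        ``diet``, optionally ``subject_id``/``cag_size``/``age_days``) to the
        CSV column holding it.  All remaining columns are treated as
        metabolite peak areas; blanks are coerced to 0 (not-detected).
    """
    path = Path(path)
    if metadata_columns is None:
        metadata_columns = DEFAULT_METADATA_COLUMNS
    raw = pd.read_csv(path, float_precision="round_trip")
    for logical in ("sample_id", "tissue", "genotype", "diet"):
        if logical not in metadata_columns:
            raise ConfigurationError(
                f"metadata_columns must declare a column for {logical!r}"
            )
        if metadata_columns[logical] not in raw.columns:
            raise ConfigurationError(
                f"declared metadata column {metadata_columns[logical]!r} "
                f"(for {logical!r}) not found in {path.name}"
            )
    meta_cols = {
        logical: col
        for logical, col in metadata_columns.items()
        if col in raw.columns
    }
    samples = pd.DataFrame(
        {logical: raw[col] for logical, col in meta_cols.items()}
    )
    value_cols = [c for c in raw.columns if c not in set(meta_cols.values())]
    values = raw[value_cols].copy()
    for col in value_cols:
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any() and values[col].notna().any():
            bad = values[col][coerced.isna() & values[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"non-numeric peak area {bad.iloc[0]!r} in column {col!r}"
                )
        values[col] = coerced
    values = values.fillna(0.0).astype(float)
    values.index = pd.Index(samples["sample_id"].astype(str), name="sample_id")
    samples["sample_id"] = samples["sample_id"].astype(str)
    return PeakTable(samples.reset_index(drop=True), values)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read metabolite meta-information (name, compound id, LC-MS method).

    The lipid flag is derived from the name via :func:`parse_lipid_name`
    rather than trusted from the file, so the two can never disagree.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        return []
    cols = {c.lower().strip(): c for c in raw.columns}
    name_col = cols.get("metabolite") or cols.get("name")
    if name_col is None:
        raise ValidationError(
            f"annotation file {path.name} has no metabolite-name column"
        )
    id_col = cols.get("compound_id") or cols.get("kegg") or cols.get("compound")
    method_col = cols.get("method")
    records = []
    for _, row in raw.iterrows():
        name = str(row[name_col])
        records.append(
            AnnotationRecord(
                metabolite=name,
                compound_id=(
                    str(row[id_col]) if id_col and pd.notna(row[id_col]) else None
                ),
                method=(
                    str(row[method_col])
                    if method_col and pd.notna(row[method_col])
                    else None
                ),
                is_lipid=parse_lipid_name(name) is not None,
            )
        )
    return records


def write_peak_table(
    table: PeakTable,
    path: str | Path,
    metadata_columns: dict[str, str] | None = None,
) -> None:
    """Write a PeakTable back to the wide CSV dialect (round-trip exact)."""
    if metadata_columns is None:
        metadata_columns = DEFAULT_METADATA_COLUMNS
    out = pd.DataFrame()
    for logical, col in metadata_columns.items():
        if logical in table.samples.columns:
            out[col] = table.samples[logical].to_numpy()
    for met in table.values.columns:
        out[met] = table.values[met].to_numpy()
    out.to_csv(path, index=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    params: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write result tables as TSV plus a JSON run manifest; return the manifest.

    One delimited UTF-8 file per table, column order as given, so diffs are
    stable.  The manifest records parameters, seed and library versions.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    manifest = {
        "tables": {},
        "params": _jsonable(params or {}),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    for name, frame in tables.items():
        fname = f"{name}.tsv"
        frame.to_csv(out_dir / fname, sep="\t", index=False)
        manifest["tables"][name] = {
            "file": fname,
            "n_rows": int(len(frame)),
            "columns": list(map(str, frame.columns)),
        }
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
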