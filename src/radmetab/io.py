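"""Reading, writing and preprocessing of wide-format metabolite abundance tables.

The on-disk conventions are deliberately plain: a wide CSV/TSV whose first
column holds sample ids and whose header row holds metabolite ids; a metadata
CSV with columns ``sample_id, animal_id, tissue, modality, group``; an
ontology CSV with columns ``metabolite, pathway``.  Missing cells are empty
strings.  The measurement scale of an abundance table moves through exactly
three states: ``raw`` (instrument-area units), ``sham_normalized`` (every
metabolite rescaled so its mean over the 0 Gy sham group is 1) and ``log``
(natural log of the sham-normalized values).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_RAW = "raw"
SCALE_SHAM = "sham_normalized"
SCALE_LOG = "log"
_SCALES = (SCALE_RAW, SCALE_SHAM, SCALE_LOG)

TISSUES = ("liver", "plasma")
MODALITIES = ("WLI", "WBI")
#: Dose groups in the order untreated control, sham surgery, low dose, high dose.
GROUPS = ("untreated", "0Gy", "10Gy", "50Gy")

METADATA_COLUMNS = ("sample_id", "animal_id", "tissue", "modality", "group")


class ParseError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class AbundanceTable:
    """Samples x metabolites abundance matrix with a scale tag.

    ``data`` has sample ids as the index and metabolite ids as columns;
    missing measurements are NaN.  ``tissue``/``modality`` record the
    biological context of the whole table (all rows share it).
    """

    data: pd.DataFrame
    scale: str = SCALE_RAW
    tissue: str | None = None
    modality: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {_SCALES}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicate metabolite ids: {dup}")
        values = self.data.to_numpy(dtype=float)
        if self.scale in (SCALE_RAW, SCALE_SHAM) and np.nanmin(values, initial=0.0) < 0:
            raise ValueError(f"negative abundance on {self.scale} scale")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy_with(self, data: pd.DataFrame, scale: str | None = None) -> "AbundanceTable":
        return replace(self, data=data, scale=scale or self.scale)

    def equals(self, other: "AbundanceTable") -> bool:
        return (
            self.scale == other.scale
            and self.tissue == other.tissue
            and self.modality == other.modality
            and self.data.equals(other.data)
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_abundance(path: str | Path, fmt: str | None = None) -> AbundanceTable:
    """Read a wide abundance table (first column = sample id).

    ``fmt`` is "csv" or "tsv"; inferred from the suffix when omitted.  A
    sidecar ``<name>.meta.json`` written by :func:`write_abundance` restores
    the scale tag and tissue/modality context; without it the table is
    assumed raw.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    sep = "\t" if fmt == "tsv" else ","
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    dup_header = pd.Index(header)
    if dup_header.has_duplicates:  # pandas would silently mangle these
        dup = dup_header[dup_header.duplicated()].unique().tolist()
        raise ParseError(f"duplicate metabolite ids: {dup}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad_cols = df.columns[df.dtypes == object]
    for col in bad_cols:  # locate the offending cell precisely
        for idx, raw in df[col].items():
            if isinstance(raw, str) and raw.strip() != "":
                try:
                    float(raw)
                except ValueError:
                    raise ParseError(
                        f"non-numeric cell at row {idx!r}, column {col!r}: {raw!r}"
                    ) from None
    numeric = df.astype(float)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return AbundanceTable(
        numeric,
        scale=meta.get("scale", SCALE_RAW),
        tissue=meta.get("tissue"),
        modality=meta.get("modality"),
    )


def write_abundance(table: AbundanceTable, path: str | Path, fmt: str | None = None) -> Path:
    """Write a table in the wide format plus a sidecar with the scale tag."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    sep = "\t" if fmt == "tsv" else ","
    out = table.data.copy()
    out.index.name = "sample_id"
    # %.17g round-trips IEEE doubles exactly
    out.to_csv(path, sep=sep, na_rep="", float_format="%.17g")
    _sidecar_path(path).write_text(
        json.dumps({"scale": table.scale, "tissue": table.tissue, "modality": table.modality})
    )
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=str)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ParseError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"duplicate sample ids in metadata: {dup}")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ParseError(f"unknown dose groups in metadata: {sorted(bad)}; expected {GROUPS}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.loc[:, list(METADATA_COLUMNS)].to_csv(path, index=False)
    return path


def validate_metadata(table: AbundanceTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Return the metadata rows for the table's samples, in table order."""
    meta = meta.set_index("sample_id", drop=False)
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ParseError(f"samples missing from metadata: {missing[:5]}")
    return meta.loc[table.sample_ids]


def read_ontology(path: str | Path) -> dict[str, str]:
    """Read a two-column metabolite -> pathway map; unknowns simply absent."""
    df = pd.read_csv(path, dtype=str)
    if not {"metabolite", "pathway"} <= set(df.columns):
        raise ParseError("ontology file needs columns 'metabolite' and 'pathway'")
    if df["metabolite"].duplicated().any():
        dup = df.loc[df["metabolite"].duplicated(), "metabolite"].tolist()
        raise ParseError(f"metabolite mapped to more than one pathway: {dup}")
    if (df["pathway"].fillna("") == "").any():
        raise ParseError("empty pathway name in ontology map")
    return dict(zip(df["metabolite"], df["pathway"]))


def write_ontology(ontology: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"metabolite": list(ontology), "pathway": [ontology[m] for m in ontology]}
    ).to_csv(path, index=False)
    return path


def impute_minimum(table: AbundanceTable) -> AbundanceTable:
    """Replace missing cells by the per-metabolite minimum observed value.

    Minimum imputation mirrors the left-censoring interpretation of MS
    missingness: a value below detection is at most as large as the smallest
    observed one.  Metabolites with no observed value at all are dropped
    with a warning.
    """
    if table.scale != SCALE_RAW:
        raise ValueError(f"impute_minimum expects a raw-scale table, got {table.scale!r}")
    data = table.data
    all_missing = data.columns[data.isna().all(axis=0)]
    if len(all_missing):
        warnings.warn(
            f"dropping {len(all_missing)} all-missing metabolite(s): "
            f"{list(all_missing[:5])}",
            stacklevel=2,
        )
        data = data.drop(columns=all_missing)
    filled = data.fillna(data.min(axis=0))
    return table.copy_with(filled)


def normalize_to_sham(
    table: AbundanceTable, meta: pd.DataFrame, sham_group: str = "0Gy"
) -> AbundanceTable:
    """Rescale each metabolite so its mean over the sham (0 Gy) samples is 1.

    Idempotent: normalizing an already sham-normalized table is the identity.
    Metabolites whose sham mean is zero carry no usable reference and are
    dropped with a warning.
    """
    if table.scale == SCALE_LOG:
        raise ValueError("cannot sham-normalize a log-scale table")
    m = validate_metadata(table, meta)
    sham_samples = m.index[m["group"] == sham_group]
    if len(sham_samples) == 0:
        raise ValueError(f"no {sham_group!r} samples for tissue={table.tissue} modality={table.modality}")
    sham_means = table.data.loc[sham_samples].mean(axis=0)
    zero = sham_means.index[(sham_means == 0) | sham_means.isna()]
    data = table.data
    if len(zero):
        warnings.warn(
            f"dropping {len(zero)} metabolite(s) with zero {sham_group} mean: {list(zero[:5])}",
            stacklevel=2,
        )
        data = data.drop(columns=zero)
        sham_means = sham_means.drop(zero)
    return table.copy_with(data / sham_means, scale=SCALE_SHAM)


def log_transform(table: AbundanceTable) -> AbundanceTable:
    """Natural log, elementwise; requires a strictly positive sham-normalized table."""
    if table.scale != SCALE_SHAM:
        raise ValueError(f"log_transform expects a sham_normalized table, got {table.scale!r}")
    values = table.data.to_numpy()
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            "non-positive value at sample "
            f"{table.data.index[i]!r}, metabolite {table.data.columns[j]!r}: {values[i, j]}"
        )
    return table.copy_with(np.log(table.data), scale=SCALE_LOG)


def preprocess(
    table: AbundanceTable, meta: pd.DataFrame, sham_group: str = "0Gy"
) -> tuple[AbundanceTable, AbundanceTable]:
    """Impute -> sham-normalize -> log.  Returns (sham_normalized, log) tables."""
    norm = normalize_to_sham(impute_minimum(table), meta, sham_group=sham_group)
    return norm, log_transform(norm)
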