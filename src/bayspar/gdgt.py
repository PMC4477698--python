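"""TEX86 computation and the surface-sediment core-top database.

Defines the record schema for core-top entries (location, metadata, TEX86,
optional GDGT fractional abundances, matched temperatures), delimited-text
I/O with a configurable column mapping, and assembly of calibration
datasets including the high-Arctic exclusion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import GridSpec, assign_grid_box, normalize_lon

__all__ = [
    "GdgtFractions",
    "CoreTopRecord",
    "CalibrationDataset",
    "compute_tex86",
    "read_coretop_table",
    "write_coretop_table",
    "build_calibration_dataset",
    "variance_explained",
    "residual_latitude_trend",
]

FRACTION_FIELDS = ("f_gdgt0", "f_gdgt1", "f_gdgt2", "f_gdgt3", "f_cren", "f_cren_prime")

#: canonical column order for the delimited-text schema
CANONICAL_COLUMNS = (
    "core_id",
    "core_type",
    "lat",
    "lon",
    "water_depth_m",
    "sample_depth_cm",
    "tex86",
    *FRACTION_FIELDS,
    "sst_woa_C",
    "subT_gamma_C",
    "sst_oisst_C",
    "reference",
    "doi",
)


class UndefinedIndexError(ValueError):
    """Raised when the TEX86 denominator is zero."""


@dataclass(frozen=True)
class GdgtFractions:
    """Fractional abundances of the six main isoprenoidal GDGTs."""

    f_gdgt0: float
    f_gdgt1: float
    f_gdgt2: float
    f_gdgt3: float
    f_cren: float
    f_cren_prime: float

    def validate(self, sum_tol: float = 0.02) -> None:
        vals = [getattr(self, f) for f in FRACTION_FIELDS]
        for name, v in zip(FRACTION_FIELDS, vals):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = sum(vals)
        if abs(total - 1.0) > sum_tol:
            raise ValueError(f"fractions sum to {total:.4f}, outside 1 +/- {sum_tol}")


def compute_tex86(fractions: GdgtFractions) -> float:
    """TEX86 ring-distribution index from GDGT fractional abundances.

    ``(f2 + f3 + cren') / (f1 + f2 + f3 + cren')`` — bounded in [0, 1] and
    invariant to rescaling the four inputs by a common positive factor.
    """
    f1, f2, f3, fc = (
        fractions.f_gdgt1,
        fractions.f_gdgt2,
        fractions.f_gdgt3,
        fractions.f_cren_prime,
    )
    for name, v in (("f_gdgt1", f1), ("f_gdgt2", f2), ("f_gdgt3", f3), ("f_cren_prime", fc)):
        if v < 0:
            raise ValueError(f"{name}={v} is negative")
    denom = f1 + f2 + f3 + fc
    if denom == 0:
        raise UndefinedIndexError("TEX86 undefined: all four index GDGTs are zero")
    return (f2 + f3 + fc) / denom


@dataclass
class CoreTopRecord:
    """One surface-sediment database entry."""

    core_id: str
    lat: float
    lon: float
    tex86: float
    core_type: str = ""
    water_depth_m: float | None = None
    sample_depth_cm: float | None = None
    fractions: GdgtFractions | None = None
    sst_woa_C: float | None = None
    subT_gamma_C: float | None = None
    sst_oisst_C: float | None = None
    reference: str = ""
    doi: str | None = None

    def __post_init__(self) -> None:
        self.lon = float(normalize_lon(self.lon))

    def validate(self, tex_tol: float = 0.01, fraction_sum_tol: float = 0.02) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat={self.lat} outside [-90, 90]")
        if not (0.0 <= self.tex86 <= 1.0):
            raise ValueError(f"tex86={self.tex86} out of range [0,1]")
        for name in ("water_depth_m", "sample_depth_cm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} is negative")
        if self.fractions is not None:
            self.fractions.validate(sum_tol=fraction_sum_tol)
            recomputed = compute_tex86(self.fractions)
            if abs(recomputed - self.tex86) > tex_tol:
                # archived value is authoritative; fractions were optional extras
                warnings.warn(
                    f"core {self.core_id}: stored tex86={self.tex86:.4f} disagrees "
                    f"with value recomputed from fractions ({recomputed:.4f})",
                    stacklevel=2,
                )

    def target_temperature(self, target_kind: str) -> float | None:
        if target_kind == "SST":
            return self.sst_woa_C if self.sst_woa_C is not None else self.sst_oisst_C
        if target_kind == "SubT":
            return self.subT_gamma_C
        raise ValueError(f"unknown target_kind {target_kind!r}")


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("core_id", "lat", "lon", "tex86")
_NUMERIC = {
    "lat",
    "lon",
    "water_depth_m",
    "sample_depth_cm",
    "tex86",
    "sst_woa_C",
    "subT_gamma_C",
    "sst_oisst_C",
    *FRACTION_FIELDS,
}


def _record_to_row(rec: CoreTopRecord) -> dict:
    row = {}
    for col in CANONICAL_COLUMNS:
        if col in FRACTION_FIELDS:
            row[col] = getattr(rec.fractions, col) if rec.fractions is not None else None
        else:
            row[col] = getattr(rec, col)
    return row


def _row_to_record(row: dict, tex_tol: float, fraction_sum_tol: float) -> CoreTopRecord:
    frac_vals = [row.get(c) for c in FRACTION_FIELDS]
    if all(v is not None for v in frac_vals):
        fractions = GdgtFractions(*[float(v) for v in frac_vals])
    elif any(v is not None for v in frac_vals):
        raise ValueError("partial GDGT fractions: all six required when any is present")
    else:
        fractions = None
    rec = CoreTopRecord(
        core_id=str(row["core_id"]),
        core_type=str(row.get("core_type") or ""),
        lat=float(row["lat"]),
        lon=float(row["lon"]),
        water_depth_m=row.get("water_depth_m"),
        sample_depth_cm=row.get("sample_depth_cm"),
        tex86=float(row["tex86"]),
        fractions=fractions,
        sst_woa_C=row.get("sst_woa_C"),
        subT_gamma_C=row.get("subT_gamma_C"),
        sst_oisst_C=row.get("sst_oisst_C"),
        reference=str(row.get("reference") or ""),
        doi=row.get("doi"),
    )
    rec.validate(tex_tol=tex_tol, fraction_sum_tol=fraction_sum_tol)
    return rec


def read_coretop_table(
    path,
    dialect_config: dict | None = None,
    rejects_path=None,
    tex_tol: float = 0.01,
    fraction_sum_tol: float = 0.02,
):
    """Read a delimited core-top table into validated records.

    ``dialect_config`` keys: ``separator`` (default inferred from extension,
    ',' or tab) and ``columns`` — a mapping from canonical field names to the
    file's header names for files with nonstandard headers.

    Rows that fail validation are routed to a rejects report (list of
    ``(row_number, reason)``; written as CSV to ``rejects_path`` when given)
    rather than aborting the read.  Returns ``(records, rejects)``.
    """
    path = Path(path)
    cfg = dict(dialect_config or {})
    sep = cfg.get("separator")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    colmap = cfg.get("columns") or {}

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise KeyError(
            f"required column(s) {missing} not found in {path.name}; "
            "map them via dialect_config['columns']"
        )

    records: list[CoreTopRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, raw in enumerate(df.to_dict(orient="records")):
        row: dict = {}
        try:
            for key in CANONICAL_COLUMNS:
                val = raw.get(key, "")
                if isinstance(val, str):
                    val = val.strip()
                # empty fields and "NaN" both mark missing values
                if val in ("", "NaN", "nan", "NA", None):
                    row[key] = None
                elif key in _NUMERIC:
                    row[key] = float(val)
                else:
                    row[key] = val
            for key in _REQUIRED:
                if row.get(key) is None:
                    raise ValueError(f"missing required field {key}")
            if not (0.0 <= row["tex86"] <= 1.0):
                raise ValueError(f"tex86={row['tex86']} out of range [0,1]")
            records.append(_row_to_record(row, tex_tol, fraction_sum_tol))
        except (ValueError, KeyError) as exc:
            rejects.append((i + 1, str(exc)))

    if rejects_path is not None:
        pd.DataFrame(rejects, columns=["row", "reason"]).to_csv(rejects_path, index=False)
    return records, rejects


def write_coretop_table(records, path, sep: str = ",") -> None:
    """Write records to delimited text; missing values become empty fields."""
    rows = [_record_to_row(r) for r in records]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# calibration-set assembly
# ---------------------------------------------------------------------------


@dataclass
class CalibrationDataset:
    """Aligned proxy/temperature vectors ready for model fitting.

    ``P`` holds TEX86 observations, ``C_diag`` the matched target
    temperatures, and ``box_index`` the grid-box assignment that defines the
    selection structure mapping observations to spatial parameters.
    """

    records: list[CoreTopRecord]
    target_kind: str
    P: np.ndarray
    C_diag: np.ndarray
    box_index: np.ndarray
    grid: GridSpec = field(default_factory=GridSpec)
    lat_cutoff_deg: float = 70.0

    def __post_init__(self) -> None:
        n = len(self.records)
        if not (len(self.P) == len(self.C_diag) == len(self.box_index) == n):
            raise ValueError("P, C_diag, box_index, records must align")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def active_boxes(self) -> np.ndarray:
        return np.unique(self.box_index)


def build_calibration_dataset(
    records,
    target_kind: str = "SST",
    lat_cutoff_deg: float = 70.0,
    grid: GridSpec | None = None,
) -> CalibrationDataset:
    """Assemble a calibration dataset from validated records.

    Drops records strictly north of ``lat_cutoff_deg`` (a site exactly at
    the cutoff is retained) and records lacking the requested target
    temperature, then assigns each survivor to its grid box.
    """
    if grid is None:
        grid = GridSpec()
    kept: list[CoreTopRecord] = []
    for rec in records:
        if rec.lat > lat_cutoff_deg:
            continue
        if rec.target_temperature(target_kind) is None:
            continue
        kept.append(rec)
    if not kept:
        raise ValueError("no records remain after latitude/target filtering")
    P = np.array([r.tex86 for r in kept], dtype=float)
    C = np.array([r.target_temperature(target_kind) for r in kept], dtype=float)
    box = np.array([assign_grid_box(r.lat, r.lon, grid) for r in kept], dtype=int)
    return CalibrationDataset(
        records=kept,
        target_kind=target_kind,
        P=P,
        C_diag=C,
        box_index=box,
        grid=grid,
        lat_cutoff_deg=lat_cutoff_deg,
    )


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------


def variance_explained(P, C_diag) -> float:
    """Squared Pearson correlation between proxy values and temperatures."""
    P = np.asarray(P, dtype=float)
    C = np.asarray(C_diag, dtype=float)
    if len(P) != len(C) or len(P) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(P) == 0 or np.std(C) == 0:
        raise ValueError("variance explained undefined for constant input")
    r = np.corrcoef(P, C)[0, 1]
    return float(r * r)


def residual_latitude_trend(residuals, lats) -> tuple[float, float]:
    """Spearman rank correlation of calibration residuals against latitude.

    Returns (rho, two-sided p-value).
    """
    residuals = np.asarray(residuals, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if len(residuals) != len(lats) or len(residuals) < 10:
        raise ValueError("need equal-length inputs with n >= 10")
    if np.all(residuals == residuals[0]) or np.all(lats == lats[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(residuals, lats)
    if math.isnan(rho):
        raise ValueError("rank correlation undefined (degenerate ties)")
    return float(rho), float(p)
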