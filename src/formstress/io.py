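"""Plain-CSV readers and writers for each assay's tabular layout.

All inputs are long-format CSV; the optional Excel reader targets the
published supporting-data workbook for the tolerance-distribution
check.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dilution import SpotSeries, CfuEstimate
from .errors import ValidationError

SPOT_COLUMNS = ["sample_id", "replicate_id", "condition", "dilution_exponent", "count"]


def write_spot_counts(series_by_condition: Mapping[float, Sequence[SpotSeries]], path) -> None:
    """Write spot-count series as long CSV (one row per spot)."""
    rows = []
    for cond, series_list in series_by_condition.items():
        for s in series_list:
            for e, c in zip(s.dilution_exponents, s.counts):
                rows.append((s.sample_id, s.replicate_id, cond, e, c))
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, index=False)


def read_spot_counts(path, spot_volume_ml: float = 0.010) -> dict[float, list[SpotSeries]]:
    """Read long-format spot counts back into per-condition series.

    Expected columns: sample_id, replicate_id, condition (mM),
    dilution_exponent, count (integer or "TNTC").
    """
    df = pd.read_csv(path, dtype={"count": str})
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"spot-count CSV missing columns: {sorted(missing)}")
    out: dict[float, list[SpotSeries]] = {}
    for (cond, _sid, rid), grp in df.groupby(["condition", "sample_id", "replicate_id"], sort=True):
        grp = grp.sort_values("dilution_exponent", ascending=False)
        counts = [
            c if c.strip().upper() == "TNTC" else int(float(c)) for c in grp["count"]
        ]
        out.setdefault(float(cond), []).append(
            SpotSeries(str(_sid), str(rid), [int(e) for e in grp["dilution_exponent"]],
                       counts, spot_volume_ml)
        )
    return out


def write_cfu_estimates(estimates_by_conc: Mapping[float, Sequence[CfuEstimate]], path) -> None:
    rows = []
    for cond, ests in estimates_by_conc.items():
        for i, e in enumerate(ests):
            rows.append((cond, i + 1, e.cfu_per_ml, e.pooled_count,
                         ";".join(str(d) for d in e.dilutions_used), e.censored))
    pd.DataFrame(
        rows,
        columns=["condition", "replicate", "cfu_per_ml", "pooled_count",
                 "dilutions_used", "censored"],
    ).to_csv(path, index=False)


def read_cfu_estimates(path) -> dict[float, list[CfuEstimate]]:
    df = pd.read_csv(path)
    out: dict[float, list[CfuEstimate]] = {}
    for _, row in df.iterrows():
        used = tuple(int(x) for x in str(row.get("dilutions_used", "")).split(";") if x not in ("", "nan"))
        out.setdefault(float(row["condition"]), []).append(
            CfuEstimate(float(row["cfu_per_ml"]), used,
                        int(row.get("pooled_count", 0)), bool(row.get("censored", False)))
        )
    return out


def read_competition(path) -> pd.DataFrame:
    """Competition CSV: sample, positives_t0, total_t0, positives_t1, total_t1, expansion."""
    df = pd.read_csv(path)
    needed = {"sample", "positives_t0", "total_t0", "positives_t1", "total_t1", "expansion"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"competition CSV missing columns: {sorted(missing)}")
    return df


def read_itc_heats(path) -> tuple[np.ndarray, np.ndarray]:
    """ITC CSV: injection, sample_heat_uJ, blank_heat_uJ (one row per injection)."""
    df = pd.read_csv(path).sort_values("injection")
    for col in ("sample_heat_uJ", "blank_heat_uJ"):
        if col not in df.columns:
            raise ValidationError(f"ITC CSV missing column {col}")
    return df["sample_heat_uJ"].to_numpy(float), df["blank_heat_uJ"].to_numpy(float)


def read_mst(path) -> tuple[np.ndarray, np.ndarray]:
    """MST CSV: concentration_mM, f_norm (replicate column optional)."""
    df = pd.read_csv(path)
    for col in ("concentration_mM", "f_norm"):
        if col not in df.columns:
            raise ValidationError(f"MST CSV missing column {col}")
    return df["concentration_mM"].to_numpy(float), df["f_norm"].to_numpy(float)


def read_standards(path) -> tuple[np.ndarray, np.ndarray]:
    """Standards CSV: concentration_mM, absorbance."""
    df = pd.read_csv(path)
    for col in ("concentration_mM", "absorbance"):
        if col not in df.columns:
            raise ValidationError(f"standards CSV missing column {col}")
    return df["concentration_mM"].to_numpy(float), df["absorbance"].to_numpy(float)


def read_growth(path) -> pd.DataFrame:
    """Growth CSV: strain, concentration, replicate, time_h, od600."""
    df = pd.read_csv(path)
    needed = {"time_h", "od600"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"growth CSV missing columns: {sorted(missing)}")
    return df


def read_s1_frequencies(
    path,
    sheet_name,
    concentration_col: str,
    frequency_cols: Sequence[str],
) -> pd.DataFrame:
    """Read tolerant-cell frequencies from a supporting-data Excel workbook.

    Generic by design: the caller names the sheet, the concentration
    column and the per-genotype frequency columns.  Requires openpyxl.
    """
    df = pd.read_excel(Path(path), sheet_name=sheet_name)
    cols = [concentration_col, *frequency_cols]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"sheet {sheet_name!r} lacks columns {missing}")
    return df[cols].dropna()
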