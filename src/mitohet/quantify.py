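"""Per-cell fluorescence quantification.

Converts raw two-channel intensities from segmented, tracked time-lapse
movies into normalized intensities and heteroplasmy values (h).  The
normalization chain per channel is: subtract the background measured in
cell-free areas (floored at zero — intensities are physical), divide by
cell volume, then divide by the median of that quantity over all cells
of the same frame, which removes photobleaching and acquisition drift.

The heteroplasmy value of a cell is

    h = I_mKate2 / (I_NG + I_mKate2)

so h > 0.5 means the mKate2-encoding mtDNA variant predominates, and
the homoplasmy extremes tend toward 0 (NeonGreen) and 1 (mKate2).
h is invariant under any common positive rescaling of both channels,
so the symmetric parts of the normalization chain cannot change it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: required columns of a per-cell, per-frame record table
CELL_RECORD_COLUMNS = [
    "frame",
    "time_h",
    "cell_id",
    "parent_id",
    "volume",
    "i_ng",
    "i_mkate",
    "bg_ng",
    "bg_mkate",
    "bud_ratio",
]

_CHANNELS = {"ng": ("i_ng", "bg_ng"), "mkate": ("i_mkate", "bg_mkate")}


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-record schema; raise ``ValueError`` naming missing columns."""
    missing = [c for c in CELL_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"cell record table is missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("cell record table is empty")
    if (records["volume"] <= 0).any():
        raise ValueError("cell volumes must be positive")
    return records


def normalize_intensities(records: pd.DataFrame) -> pd.DataFrame:
    """Background-correct, volume- and median-normalize both channels.

    Returns a copy of ``records`` with added columns ``ng_norm`` and
    ``mkate_norm``.  Per frame and channel the median of the normalized
    values is 1 whenever any nonzero corrected signal exists; a frame
    whose corrected intensities are all zero in a channel keeps zeros
    and is logged (division-by-zero guard).
    """
    records = validate_records(records).copy()
    for channel, (icol, bgcol) in _CHANNELS.items():
        corrected = np.maximum(records[icol] - records[bgcol], 0.0)
        per_volume = corrected / records["volume"]
        out = np.empty(len(records))
        for frame, idx in records.groupby("frame").groups.items():
            vals = per_volume.loc[idx]
            med = float(vals.median())
            if med <= 0:
                logger.warning(
                    "frame %s: all-zero corrected %s intensities; normalized values set to 0",
                    frame,
                    channel,
                )
                out[records.index.get_indexer(idx)] = 0.0
            else:
                out[records.index.get_indexer(idx)] = vals / med
        records[f"{channel}_norm"] = out
    return records


def compute_h(i_ng_norm, i_mkate_norm):
    """Heteroplasmy value h = mKate2 / (NG + mKate2), elementwise.

    Cells with zero signal in both channels get ``NaN`` (undefined —
    they are excluded from h distributions rather than assigned 0.5).
    """
    ng = np.asarray(i_ng_norm, dtype=float)
    mk = np.asarray(i_mkate_norm, dtype=float)
    if (ng < 0).any() or (mk < 0).any():
        raise ValueError("normalized intensities must be non-negative")
    total = ng + mk
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(total > 0, mk / np.where(total > 0, total, 1.0), np.nan)
    n_undef = int(np.isnan(h).sum())
    if n_undef:
        logger.warning("%d cells with zero signal in both channels excluded from h", n_undef)
    if h.ndim == 0:
        return float(h)
    return h


def h_table(records: pd.DataFrame) -> pd.DataFrame:
    """Full quantification: normalize both channels and attach h per cell per frame."""
    out = normalize_intensities(records)
    out["h"] = np.clip(compute_h(out["ng_norm"], out["mkate_norm"]), 0.0, 1.0)
    return out


def compute_cv(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / mean)


def normalize_to_first_timepoint(
    series: pd.DataFrame,
    value_col: str = "intensity",
    time_col: str = "time_h",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Divide every value by the median of its replicate's first timepoint.

    Used for bleaching/decay time courses: the first-timepoint median of
    each replicate maps to 1, and normalization is independent between
    replicates.
    """
    out = series.copy()
    normed = np.empty(len(out))
    for rep, grp in out.groupby(replicate_col):
        t0 = grp[time_col].min()
        med = float(grp.loc[grp[time_col] == t0, value_col].median())
        if med <= 0:
            raise ValueError(f"replicate {rep}: zero median at first timepoint")
        normed[out.index.get_indexer(grp.index)] = grp[value_col] / med
    out[value_col + "_norm"] = normed
    return out
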