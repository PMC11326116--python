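"""Measurement statistics for batch-coculture IDC experiments.

Covers the normalization conventions for plate-reader traces, normalized
donor-to-recipient (D:R) ratios, the log-log GLM relating D:R to IDC counts
(with detection-limit exclusions), per-day slopes, Li's intensity
correlation quotient (ICQ) for two-channel colony images, the fold-decrease
statistic for kill assays, and CFU counting conventions (lawn cap 500,
estimate flag at >= 200, detection floor 0.1 on log-scale displays).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, InvalidParameterError

logger = logging.getLogger(__name__)

CFU_LAWN_VALUE = 500.0
CFU_ESTIMATE_THRESHOLD = 200.0
CFU_DETECTION_FLOOR = 0.1
LAWN_SENTINEL = "lawn"

TRACE_COLUMNS = ["well", "t_h", "channel", "value"]


# ---------------------------------------------------------------------------
# trace normalization and ratios
# ---------------------------------------------------------------------------

def normalize_after_day1(traces: pd.DataFrame, day1_cutoff_h: float = 24.0,
                         per_well: bool = False) -> pd.DataFrame:
    """Divide each reading by the post-day-1 maximum of its measurement type.

    The maximum is taken over all wells sharing a channel (one experiment),
    over time points at or after the cutoff; readings before the cutoff may
    therefore exceed 1.  Set ``per_well`` to normalize each well separately.
    """
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if missing:
        raise DataError(f"traces missing columns {missing}")
    if traces.empty:
        raise DataError("empty trace table")
    out = traces.copy()
    keys = ["channel", "well"] if per_well else ["channel"]
    post = out[out["t_h"] >= day1_cutoff_h]
    if post.empty:
        raise DataError(f"no readings at t >= {day1_cutoff_h} h")
    maxima = post.groupby(keys)["value"].max()
    if (maxima <= 0).any():
        bad = maxima[maxima <= 0].index.tolist()
        raise DataError(f"all-zero post-cutoff readings for {bad}")
    denom = out.set_index(keys).index.map(maxima)
    out["value"] = out["value"].to_numpy() / np.asarray(denom, dtype=float)
    return out


def donor_recipient_ratio(donor: Sequence[float], recipient: Sequence[float]
                          ) -> np.ndarray:
    """Normalized D:R series: each species divided by its own maximum first.

    Entries with zero normalized recipient are flagged as missing (NaN),
    never infinity.
    """
    d = np.asarray(donor, dtype=float)
    r = np.asarray(recipient, dtype=float)
    if d.shape != r.shape:
        raise DataError("donor and recipient series must be paired")
    if d.size == 0:
        raise DataError("empty count series")
    dmax, rmax = d.max(), r.max()
    if dmax <= 0 or rmax <= 0:
        raise DataError("species maximum must be positive to normalize")
    dn, rn = d / dmax, r / rmax
    out = np.full(d.shape, np.nan)
    ok = rn > 0
    out[ok] = dn[ok] / rn[ok]
    return out


# ---------------------------------------------------------------------------
# log-log GLM of D:R vs IDC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogLogFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_p: float
    intercept_p: float
    conf_int: tuple          # ((lo, hi) intercept, (lo, hi) slope), 95%
    n_used: int
    n_excluded: int


def fit_loglog_glm(dr: Sequence[float], idc: Sequence[float]) -> LogLogFit:
    """Normal-family, identity-link GLM of log10(IDC) on log10(D:R).

    Points at the CFU detection limits (floor 0.1 per 100 µL or lawn cap
    500) and non-positive or missing entries are excluded before fitting, as
    in the source convention.
    """
    dr = np.asarray(dr, dtype=float)
    idc = np.asarray(idc, dtype=float)
    if dr.shape != idc.shape:
        raise DataError("dr and idc must be paired")
    at_limit = (idc <= CFU_DETECTION_FLOOR) | (idc >= CFU_LAWN_VALUE)
    usable = (~at_limit) & (dr > 0) & np.isfinite(dr) & np.isfinite(idc)
    n_excluded = int(dr.size - usable.sum())
    if usable.sum() < 3:
        raise DataError(f"need >= 3 usable points, have {int(usable.sum())}")
    x = np.log10(dr[usable])
    y = np.log10(idc[usable])
    res = sm.GLM(y, sm.add_constant(x), family=sm.families.Gaussian()).fit()
    ci = res.conf_int(alpha=0.05)
    return LogLogFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
        slope_p=float(res.pvalues[1]), intercept_p=float(res.pvalues[0]),
        conf_int=(tuple(np.asarray(ci)[0]), tuple(np.asarray(ci)[1])),
        n_used=int(usable.sum()), n_excluded=n_excluded)


def daily_slopes(data: pd.DataFrame) -> pd.DataFrame:
    """One log-log fit per day; underpowered days are skipped with a flag.

    ``data`` needs columns (day, dr, idc).  Returns a table sorted by day
    with columns (day, slope, slope_se, n_used, n_excluded).
    """
    for c in ("day", "dr", "idc"):
        if c not in data.columns:
            raise DataError(f"missing column {c!r}")
    rows = []
    for day, grp in data.groupby("day", sort=True):
        try:
            fit = fit_loglog_glm(grp["dr"], grp["idc"])
        except DataError as err:
            logger.warning("day %s skipped: %s", day, err)
            continue
        rows.append({"day": day, "slope": fit.slope, "slope_se": fit.slope_se,
                     "n_used": fit.n_used, "n_excluded": fit.n_excluded})
    return pd.DataFrame(rows, columns=["day", "slope", "slope_se",
                                       "n_used", "n_excluded"])


# ---------------------------------------------------------------------------
# Li's intensity correlation quotient
# ---------------------------------------------------------------------------

def compute_icq(channel_a: np.ndarray, channel_b: np.ndarray,
                mask: Optional[np.ndarray] = None) -> float:
    """Li's ICQ: fraction of pixels with positive mean-centered cross product,
    minus one half.

    +0.5 means complete colocalization between channels, -0.5 complete
    spatial segregation.  Pixels whose product is exactly zero count as
    non-positive.  Raises on constant channels (undefined statistic).
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise DataError("mask shape must match channels")
        a, b = a[mask], b[mask]
    a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise DataError("need >= 2 masked pixels")
    # max == min, not mean-centering, detects constancy: the float mean of
    # identical values need not equal them exactly
    if a.max() == a.min() or b.max() == b.min():
        raise DataError("ICQ undefined for a constant channel")
    da = a - a.mean()
    db = b - b.mean()
    return float(np.mean(da * db > 0) - 0.5)


# ---------------------------------------------------------------------------
# fold decrease and CFU conventions
# ---------------------------------------------------------------------------

def fold_decrease(norm_mono: float, norm_co: float) -> float:
    """Kill-assay statistic: -(normalized monoculture)/(normalized coculture).

    The sign convention is kept exactly as reported (values are negative);
    a zero coculture reading yields NaN (flagged missing value).
    """
    if norm_co == 0:
        logger.warning("fold_decrease undefined for zero coculture signal")
        return float("nan")
    return -norm_mono / norm_co


def adjust_cfu(raw_counts: Sequence) -> pd.DataFrame:
    """Apply CFU counting conventions and flags to raw plate counts.

    Input entries are non-negative numbers or the string ``"lawn"``.
    Returns columns (value, log_display, flags): lawns are stored at 500;
    zeros keep value 0 with the 0.1 floor substituted only in
    ``log_display``; counts >= 200 carry the estimate flag.
    """
    rows = []
    for raw in raw_counts:
        flags = []
        if isinstance(raw, str):
            if raw != LAWN_SENTINEL:
                raise DataError(f"unknown count sentinel {raw!r}")
            value = CFU_LAWN_VALUE
            flags = ["lawn_500", "estimate_ge200"]
        else:
            value = float(raw)
            if value < 0:
                raise InvalidParameterError(f"negative CFU count {raw}")
            if value >= CFU_LAWN_VALUE:
                value = CFU_LAWN_VALUE
                flags = ["lawn_500", "estimate_ge200"]
            elif value >= CFU_ESTIMATE_THRESHOLD:
                flags = ["estimate_ge200"]
            elif value == 0:
                flags = ["detection_floor_0.1"]
        rows.append({"value": value,
                     "log_display": CFU_DETECTION_FLOOR if value == 0 else value,
                     "flags": ";".join(flags)})
    return pd.DataFrame(rows, columns=["value", "log_display", "flags"])
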