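"""Single-cell fluorescence preprocessing and pool-level statistics.

Event tables are DataFrames with columns FSC, SSC, GFP, mCherry (arbitrary
fluorescence units), read from TSV. Fluorescence is corrected for cell size
by taking residuals of a loess regression of the channel on forward scatter
(FSC), which avoids assuming any functional form for the size dependence.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "read_events",
    "filter_outliers",
    "size_correct",
    "channel_correlation",
    "heritability_ttest",
]

EVENT_COLUMNS = ["FSC", "SSC", "GFP", "mCherry"]
MIN_EVENTS = 30


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event table from TSV with columns FSC, SSC, GFP, mCherry."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if not np.isfinite(frame[EVENT_COLUMNS].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite event values")
    return frame


def filter_outliers(
    events: pd.DataFrame, lower: float = 0.01, upper: float = 0.99
) -> pd.DataFrame:
    """Drop events outside the given FSC and SSC percentile band."""
    keep = np.ones(len(events), dtype=bool)
    for col in ("FSC", "SSC"):
        lo, hi = events[col].quantile([lower, upper])
        keep &= (events[col] >= lo) & (events[col] <= hi)
    return events.loc[keep].reset_index(drop=True)


def _loess_residuals(
    y: np.ndarray, fsc: np.ndarray, span: float, log: bool
) -> np.ndarray:
    if log:
        y = np.log(y)
        fsc = np.log(fsc)
    if np.ptp(fsc) == 0:
        warnings.warn("constant FSC; falling back to mean-centering")
        return y - y.mean()
    fit = lowess(y, fsc, frac=span, it=0, return_sorted=False)
    return y - fit


def size_correct(
    events: pd.DataFrame,
    channel: str,
    span: float = 0.3,
    log: bool = False,
) -> np.ndarray:
    """Residuals of a loess regression of `channel` on FSC (local-linear).

    With `log` the regression runs on natural-log fluorescence and FSC.
    Requires at least 30 events; residuals have mean approximately zero.
    """
    if len(events) < MIN_EVENTS:
        raise ValueError(f"need at least {MIN_EVENTS} events, got {len(events)}")
    return _loess_residuals(
        events[channel].to_numpy(dtype=float),
        events["FSC"].to_numpy(dtype=float),
        span,
        log,
    )


def channel_correlation(
    events: pd.DataFrame,
    channels: tuple[str, str] = ("GFP", "mCherry"),
    span: float = 0.3,
    log: bool = False,
) -> float:
    """Pearson correlation of size-corrected fluorescence in two channels.

    High correlation indicates shared (cell-wide or transcriptional) drivers
    of both reporters; protein- or mRNA-specific variation lowers it.
    """
    res_a = size_correct(events, channels[0], span=span, log=log)
    res_b = size_correct(events, channels[1], span=span, log=log)
    if res_a.std() == 0 or res_b.std() == 0:
        raise ValueError("zero variance after size correction; correlation undefined")
    return float(np.corrcoef(res_a, res_b)[0, 1])


def heritability_ttest(
    high: pd.DataFrame,
    low: pd.DataFrame,
    channel: str,
    span: float = 0.3,
    log: bool = False,
) -> tuple[float, float]:
    """Welch t-test on size-corrected fluorescence between regrown pools.

    The loess size regression is fitted on the pooled events of both tables
    (a per-table fit would re-center each pool at zero and absorb the very
    difference being tested). A significant difference between pools sorted
    from opposite fluorescence tails demonstrates heritable variation.
    Returns (t statistic, two-sided p-value).
    """
    if len(high) < 2 or len(low) < 2:
        raise ValueError("both pools need at least 2 events")
    combined = pd.concat([high, low], ignore_index=True)
    res = _loess_residuals(
        combined[channel].to_numpy(dtype=float),
        combined["FSC"].to_numpy(dtype=float),
        span,
        log,
    )
    res_high, res_low = res[: len(high)], res[len(high):]
    if res_high.std() == 0 and res_low.std() == 0:
        warnings.warn("degenerate variance in both pools; t-test unreliable")
    t, p = stats.ttest_ind(res_high, res_low, equal_var=False)
    return float(t), float(p)
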