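"""Allele-frequency tracks: AF computation, extreme filtering, smoothing, ΔAF.

Tracks are plain DataFrames with columns ``chrom, pos, af, depth`` (``af`` is
the BY/reference allele frequency, NaN where depth is zero). ΔAF tracks add a
``delta_af`` column: high-pool AF minus low-pool AF, so positive ΔAF means
the BY allele is enriched among high-fluorescence cells, i.e. the BY allele
increases expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .pool_io import PooledCounts

__all__ = ["compute_af", "filter_extreme", "smooth_af", "delta_af"]

TRACK_COLUMNS = ["chrom", "pos", "af", "depth"]


def compute_af(counts: PooledCounts) -> pd.DataFrame:
    """BY-allele frequency per marker: ref/(ref+alt); NaN at zero depth."""
    depth = counts.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, counts.ref / np.maximum(depth, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": counts.markers.chrom,
            "pos": counts.markers.pos,
            "af": af,
            "depth": depth,
        }
    )


def filter_extreme(
    track: pd.DataFrame, low: float = 0.1, high: float = 0.9
) -> pd.DataFrame:
    """Drop markers with AF strictly above `high` or strictly below `low`.

    Boundary values are retained; markers with missing AF are kept (they carry
    no frequency evidence either way).
    """
    if low >= high:
        raise ValueError(f"low bound {low} must be below high bound {high}")
    af = track["af"].to_numpy()
    keep = ~((af > high) | (af < low))
    return track.loc[keep].reset_index(drop=True)


def _local_linear(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Depth-weighted local-linear fit with tri-cube kernel of fixed physical
    bandwidth, evaluated at every x."""
    out = np.empty_like(y)
    left = np.searchsorted(x, x - bandwidth, side="left")
    right = np.searchsorted(x, x + bandwidth, side="right")
    for i in range(len(x)):
        sl = slice(left[i], right[i])
        xs, ys, ws = x[sl], y[sl], w[sl]
        u = np.abs(xs - x[i]) / bandwidth
        k = ws * (1.0 - u**3) ** 3
        sw = k.sum()
        if sw <= 0:
            out[i] = y[i]
            continue
        xc = xs - x[i]
        sx = (k * xc).sum()
        sxx = (k * xc * xc).sum()
        sy = (k * ys).sum()
        sxy = (k * xc * ys).sum()
        denom = sw * sxx - sx * sx
        if denom <= 1e-12 * max(sw * sxx, 1e-300):
            out[i] = sy / sw  # degenerate design: fall back to local mean
        else:
            out[i] = (sxx * sy - sx * sxy) / denom
    return out


def smooth_af(
    track: pd.DataFrame, bandwidth_bp: float = 20_000.0, min_markers: int = 5
) -> pd.DataFrame:
    """Smooth counting noise with a per-chromosome local regression.

    Local-linear, tri-cube weights over a fixed physical bandwidth,
    depth-weighted; smoothed values are clipped to [0, 1]. Chromosomes with
    fewer than `min_markers` informative markers pass through unsmoothed.
    """
    pieces = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.copy()
        ok = sub["af"].notna().to_numpy()
        if ok.sum() < min_markers:
            warnings.warn(
                f"chromosome {chrom}: only {int(ok.sum())} informative markers; "
                "passed through unsmoothed"
            )
            pieces.append(sub)
            continue
        x = sub.loc[ok, "pos"].to_numpy(dtype=float)
        y = sub.loc[ok, "af"].to_numpy(dtype=float)
        w = sub.loc[ok, "depth"].to_numpy(dtype=float)
        smoothed = np.clip(_local_linear(x, y, w, bandwidth_bp), 0.0, 1.0)
        af = sub["af"].to_numpy(dtype=float).copy()
        af[ok] = smoothed
        sub["af"] = af
        pieces.append(sub)
    return pd.concat(pieces, ignore_index=True)


def delta_af(high: pd.DataFrame, low: pd.DataFrame) -> pd.DataFrame:
    """ΔAF = AF_high − AF_low per marker. Marker sets must be identical."""
    hk = list(zip(high["chrom"], high["pos"]))
    lk = list(zip(low["chrom"], low["pos"]))
    if hk != lk:
        extra_h = set(hk) - set(lk)
        extra_l = set(lk) - set(hk)
        raise ValueError(
            "marker mismatch between pools: "
            f"{len(extra_h)} only in high, {len(extra_l)} only in low, "
            f"examples: {sorted(extra_h)[:3]} / {sorted(extra_l)[:3]}"
        )
    return pd.DataFrame(
        {
            "chrom": high["chrom"].to_numpy(),
            "pos": high["pos"].to_numpy(),
            "delta_af": high["af"].to_numpy() - low["af"].to_numpy(),
            "depth_high": high["depth"].to_numpy(),
            "depth_low": low["depth"].to_numpy(),
        }
    )
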