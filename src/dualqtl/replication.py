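"""Replicate merging, significance filtering, reproducibility, and the
replicate-null FDR curve.

Merging is a three-step procedure: peaks are called
per replicate at a permissive threshold (LOD > 3), each peak position is
re-read from *every* replicate's track without a per-replicate LOD filter and
averaged, and peaks whose positions lie within 75 kb of each other are
collapsed (single-linkage) into one merged QTL whose LOD, ΔAF, position and
confidence interval are the arithmetic means over members. The false
discovery rate is estimated from "null" contrasts of same-gate pools across
replicates, where any apparent QTL must be noise:

    FDR(thr) = (NrepQTL_thr / Nrep) / (NfluoQTL_thr / Nfluo)
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .peak_calling import call_peaks

__all__ = [
    "merge_replicates",
    "filter_significant",
    "fraction_overlap",
    "fdr_curve",
]

MERGED_COLUMNS = [
    "chrom",
    "pos",
    "lod",
    "delta_af",
    "ci_start",
    "ci_end",
    "n_replicates_detected",
    "n_replicates_total",
    "member_replicates",
]


def _track_value_at(track: pd.DataFrame, chrom: str, pos: float, column: str) -> float:
    sub = track.loc[track["chrom"] == chrom]
    if len(sub) == 0:
        raise ValueError(f"track has no bins on {chrom}")
    x = sub["bin_mid"].to_numpy(dtype=float)
    y = sub[column].to_numpy(dtype=float)
    return float(np.interp(pos, x, y))


def _group_positions(pos: np.ndarray, window: float, clique: bool) -> np.ndarray:
    """Group sorted positions; returns a group id per element.

    Single-linkage: break wherever the gap to the previous peak exceeds the
    window (chain closure of the pairwise within-window rule). Clique mode
    instead starts a new group when the span from the group's first member
    would exceed the window (strict mutual proximity, for sensitivity checks).
    """
    ids = np.zeros(len(pos), dtype=int)
    gid = 0
    anchor = pos[0] if len(pos) else 0.0
    for i in range(1, len(pos)):
        if clique:
            if pos[i] - anchor > window:
                gid += 1
                anchor = pos[i]
        elif pos[i] - pos[i - 1] > window:
            gid += 1
        ids[i] = gid
    return ids


def merge_replicates(
    peaks: Mapping[str, pd.DataFrame],
    tracks: Mapping[str, pd.DataFrame],
    window: float = 75_000.0,
    clique: bool = False,
) -> pd.DataFrame:
    """Merge per-replicate peak calls for one gene + channel.

    `peaks` maps replicate id -> peak frame (permissive threshold);
    `tracks` maps replicate id -> LOD track frame (used to re-read LOD and
    ΔAF at every member position in every replicate). With a single replicate
    the merged QTLs equal the input peaks.
    """
    if window <= 0:
        raise ValueError("merge window must be positive")
    if set(peaks) - set(tracks):
        raise ValueError("every replicate with peaks needs a track")
    rep_ids = sorted(tracks)
    rows = []
    for rep in sorted(peaks):
        frame = peaks[rep]
        for r in frame.itertuples(index=False):
            rows.append(
                {
                    "replicate": rep,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ci_start": r.ci_start,
                    "ci_end": r.ci_end,
                }
            )
    if not rows:
        return pd.DataFrame(columns=MERGED_COLUMNS)
    members = pd.DataFrame(rows)

    merged = []
    for chrom, sub in members.groupby("chrom", sort=False):
        sub = sub.sort_values("pos").reset_index(drop=True)
        gids = _group_positions(sub["pos"].to_numpy(dtype=float), window, clique)
        for gid in np.unique(gids):
            grp = sub.loc[gids == gid]
            # cross-replicate averages of LOD and dAF at each member position
            lods, dafs = [], []
            for p in grp["pos"]:
                lods.append(
                    np.mean([_track_value_at(tracks[r], chrom, p, "lod") for r in rep_ids])
                )
                dafs.append(
                    np.mean(
                        [_track_value_at(tracks[r], chrom, p, "delta_af") for r in rep_ids]
                    )
                )
            merged.append(
                {
                    "chrom": chrom,
                    "pos": float(grp["pos"].mean()),
                    "lod": float(np.mean(lods)),
                    "delta_af": float(np.mean(dafs)),
                    "ci_start": float(grp["ci_start"].mean()),
                    "ci_end": float(grp["ci_end"].mean()),
                    "n_replicates_detected": int(grp["replicate"].nunique()),
                    "n_replicates_total": len(rep_ids),
                    "member_replicates": ",".join(sorted(map(str, grp["replicate"]))),
                }
            )
    return pd.DataFrame(merged, columns=MERGED_COLUMNS)


def filter_significant(merged: pd.DataFrame, threshold: float = 4.5) -> pd.DataFrame:
    """Retain merged QTLs whose replicate-averaged LOD is ≥ threshold."""
    if len(merged) == 0:
        return merged
    return merged.loc[merged["lod"] >= threshold].reset_index(drop=True)


def fraction_overlap(merged: pd.DataFrame) -> float:
    """Reproducibility statistic: mean of (NshareQTL − 1) / (Nrep − 1).

    Averaged over significant merged QTLs of genes with at least two
    replicates; a QTL detected in a single replicate contributes zero.
    """
    eligible = merged.loc[merged["n_replicates_total"] >= 2]
    if len(eligible) == 0:
        raise ValueError("no merged QTLs from genes with ≥ 2 replicates")
    num = eligible["n_replicates_detected"].to_numpy(dtype=float) - 1.0
    den = eligible["n_replicates_total"].to_numpy(dtype=float) - 1.0
    return float(np.mean(num / den))


def fdr_curve(
    null_peak_lods: np.ndarray,
    signal_peak_lods: np.ndarray,
    n_null_comparisons: int = 80,
    n_signal_comparisons: int = 48,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Replicate-null FDR as a function of the LOD threshold.

    `null_peak_lods` are peak LODs from same-gate replicate-pair contrasts
    (all such peaks are false positives); `signal_peak_lods` are peak LODs
    from high-vs-low contrasts. Per threshold:

        FDR = (n_null ≥ thr / Nrep) / (n_signal ≥ thr / Nfluo)

    Raw values are reported as computed (possibly > 1); `fdr_isotonic` is the
    non-increasing envelope (running minimum over increasing thresholds),
    since empirical ratios at sparse thresholds are noisy. Thresholds where
    no signal peak survives leave the FDR undefined (NaN) with a warning.
    """
    if n_null_comparisons <= 0 or n_signal_comparisons <= 0:
        raise ValueError("comparison counts must be positive")
    null_lods = np.asarray(null_peak_lods, dtype=float)
    signal_lods = np.asarray(signal_peak_lods, dtype=float)
    if thresholds is None:
        thresholds = np.arange(3.0, 10.01, 0.25)
    thresholds = np.asarray(thresholds, dtype=float)

    n_null = np.array([(null_lods >= t).sum() for t in thresholds])
    n_signal = np.array([(signal_lods >= t).sum() for t in thresholds])
    null_rate = n_null / n_null_comparisons
    signal_rate = n_signal / n_signal_comparisons
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_null == 0, 0.0, null_rate / signal_rate)
    undefined = (n_signal == 0) & (n_null > 0)
    if undefined.any():
        warnings.warn(
            f"FDR undefined at {int(undefined.sum())} threshold(s) with null "
            "peaks but no signal peaks"
        )
        fdr = np.where(undefined, np.nan, fdr)

    iso = fdr.copy()
    running = np.inf
    for i in range(len(iso)):
        if np.isfinite(iso[i]):
            running = min(running, iso[i])
            iso[i] = running
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "n_null_qtl": n_null,
            "n_signal_qtl": n_signal,
            "fdr": fdr,
            "fdr_isotonic": iso,
        }
    )
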