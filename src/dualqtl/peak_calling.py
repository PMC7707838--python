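"""Convert LOD tracks into discrete QTL peaks with 2-LOD support intervals."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["call_peaks", "write_peaks_bed"]

PEAK_COLUMNS = [
    "chrom",
    "pos",
    "lod",
    "delta_af",
    "ci_start",
    "ci_end",
]


def call_peaks(track: pd.DataFrame, threshold: float, drop: float = 2.0) -> pd.DataFrame:
    """Call one peak per maximal contiguous super-threshold run of bins.

    The peak is the highest-LOD bin of the run (ties break to the smallest
    coordinate); its support interval extends from the peak in both directions
    to the outer edge of the first bin whose LOD falls to `peak − drop` or
    below, clamped to the track's extent on that chromosome. ΔAF is read at
    the peak bin. The track is expected to hold informative bins sorted by
    position (as produced by `lod_model.lod_track`).
    """
    peaks: list[dict] = []
    if len(track) == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("bin_start").reset_index(drop=True)
        lod = sub["lod"].to_numpy(dtype=float)
        above = lod >= threshold
        if not above.any():
            continue
        # maximal runs of consecutive above-threshold bins
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            run = slice(start, stop)
            peak_offset = start + int(np.argmax(lod[run]))
            peak_lod = lod[peak_offset]
            cutoff = peak_lod - drop

            left = peak_offset
            while left > 0 and lod[left] > cutoff:
                left -= 1
            right = peak_offset
            while right < len(lod) - 1 and lod[right] > cutoff:
                right += 1
            ci_start = int(sub.loc[left, "bin_start"]) if lod[left] <= cutoff else int(
                sub.loc[0, "bin_start"]
            )
            ci_end = int(sub.loc[right, "bin_end"]) if lod[right] <= cutoff else int(
                sub.loc[len(sub) - 1, "bin_end"]
            )
            peaks.append(
                {
                    "chrom": chrom,
                    "pos": float(sub.loc[peak_offset, "bin_mid"]),
                    "lod": float(peak_lod),
                    "delta_af": float(sub.loc[peak_offset, "delta_af"]),
                    "ci_start": ci_start,
                    "ci_end": ci_end,
                }
            )
    return pd.DataFrame(peaks, columns=PEAK_COLUMNS)


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """Support intervals as BED (0-based half-open), score = LOD."""
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.itertuples(index=False)):
            fh.write(
                f"{row.chrom}\t{int(row.ci_start) - 1}\t{int(row.ci_end)}\t"
                f"peak{i + 1}\t{row.lod:.3f}\n"
            )
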