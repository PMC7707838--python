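"""Binned hidden-frequency model and contrast LOD score for two sorted pools.

Model
-----
Marker counts are summed into fixed-width genomic bins. Within each pool, the
(unobserved) pool allele frequency follows a Markov chain along the
chromosome: over a gap of d bp the recombination fraction is
r = min(0.5, d / (bp_per_cM × 100)), and the frequency moves with mean
p + r(1−2p) (decay toward 0.5 as linkage to any selected site breaks down)
and variance r(1−r)/N, where N is the effective number of segregants in the
pool. The chain is discretized on a uniform frequency grid; bin emissions are
Binomial(n, p) in the reference-allele read count (beta-binomial with
overdispersion ρ when ρ > 0); the prior at the first bin of each chromosome
is uniform on the grid.

LOD score
---------
The per-bin LOD contrasts "the two pools have unconstrained frequencies"
against "the two pools have equal frequency at this bin". With γ_h, γ_l the
two pools' posterior frequency distributions at bin t (each aggregating all
linked bins of its pool through the chain) and m_t the chain's no-data
marginal at t, the likelihood ratio reduces to a Savage–Dickey density
ratio:

    LOD(t) = −log10 Σ_p γ_h,t(p) · γ_l,t(p) / m_t(p)

Because the posteriors pool evidence across linked bins, LOD grows with both
read depth and the physical extent of the allele-frequency divergence, which
is what gives tail-sorted pools their mapping power at ~13× coverage.
Negative values (evidence for equality) are clipped to zero. A localized
single-bin diagnostic (`local_lod`) contrasting leave-one-out predictive
likelihoods of the bin's own counts is available as well; it is bounded by
one bin's depth and is not used for peak calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LODParams", "bin_counts", "hmm_posteriors", "lod_track"]

_FLOOR = 1e-300


@dataclass(frozen=True)
class LODParams:
    """Parameters of the binned hidden-frequency model."""

    bin_size: int = 100
    bp_per_cM: float = 2200.0
    effective_pool_size: int = 1000
    grid_points: int = 201
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin size must be at least 1")
        if self.effective_pool_size < 2:
            raise ValueError("effective pool size must be at least 2")
        if self.grid_points < 11:
            raise ValueError("frequency grid needs at least 11 points")
        if not 0 <= self.rho < 1:
            raise ValueError("overdispersion rho must lie in [0, 1)")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.grid_points)


def bin_counts(
    counts,
    params: LODParams,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sum marker counts into fixed-width bins tiling each chromosome.

    Bin b covers positions [(b−1)·w+1, b·w]; a marker at position p belongs
    to bin ⌈p/w⌉. Bins without markers carry zero counts. Accepts a
    PooledCounts or any frame with columns chrom, pos, ref_count, alt_count.
    """
    frame = counts.to_frame() if hasattr(counts, "to_frame") else counts
    w = params.bin_size
    pieces = []
    for chrom, sub in frame.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        length = (chrom_lengths or {}).get(chrom, int(pos.max()) if len(pos) else w)
        n_bins = int(np.ceil(length / w))
        bin_idx = np.ceil(pos / w).astype(np.int64) - 1
        ref = np.bincount(bin_idx, weights=sub["ref_count"], minlength=n_bins)
        alt = np.bincount(bin_idx, weights=sub["alt_count"], minlength=n_bins)
        starts = np.arange(n_bins, dtype=np.int64) * w + 1
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": starts,
                    "bin_end": starts + w - 1,
                    "ref": ref.astype(np.int64),
                    "alt": alt.astype(np.int64),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


@lru_cache(maxsize=4096)
def _transition_matrix_cached(
    gap: float, bp_per_cM: float, n_pool: int, grid_points: int
) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, grid_points)
    r = min(0.5, gap / (bp_per_cM * 100.0))
    if r >= 0.5:  # unlinked: reset to the flat prior
        return np.full((grid_points, grid_points), 1.0 / grid_points)
    if r <= 0:
        return np.eye(grid_points)
    mu = grid + r * (1.0 - 2.0 * grid)
    sd = np.sqrt(r * (1.0 - r) / n_pool)
    half = 0.5 * (grid[1] - grid[0])
    edges = np.concatenate(([-np.inf], grid[:-1] + half, [np.inf]))
    cdf = stats.norm.cdf((edges[None, :] - mu[:, None]) / sd)
    T = np.diff(cdf, axis=1)
    T /= T.sum(axis=1, keepdims=True)
    return T


def _transition(gap: float, params: LODParams) -> np.ndarray:
    return _transition_matrix_cached(
        float(gap), params.bp_per_cM, params.effective_pool_size, params.grid_points
    )


def _emissions(ref: np.ndarray, depth: np.ndarray, params: LODParams) -> np.ndarray:
    """(n_bins × grid) emission likelihood matrix; all-ones rows at zero depth."""
    grid = params.grid
    k = np.asarray(ref, dtype=np.int64)[:, None]
    n = np.asarray(depth, dtype=np.int64)[:, None]
    if params.rho > 0:
        conc = 1.0 / params.rho - 1.0
        p = np.clip(grid, 1e-9, 1.0 - 1e-9)[None, :]
        E = stats.betabinom.pmf(k, n, p * conc, (1.0 - p) * conc)
    else:
        E = stats.binom.pmf(k, n, grid[None, :])
    E[np.asarray(depth) == 0] = 1.0
    return np.maximum(E, 0.0)


def _normalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s <= 0 or not np.isfinite(s):
        raise FloatingPointError("probability vector underflow in HMM recursion")
    return v / s


def _run_chain(
    emissions: np.ndarray, gaps: np.ndarray, params: LODParams
) -> dict[str, np.ndarray]:
    """Scaled forward–backward for one chromosome.

    Returns per-bin arrays on the grid: `posterior` γ_t, leave-one-out
    `predictive` q_t (all data except bin t), and the no-data `marginal` m_t.
    """
    T, G = emissions.shape
    trans = [_transition(g, params) for g in gaps]
    uniform = np.full(G, 1.0 / G)

    pred = np.empty((T, G))
    alpha = np.empty((T, G))
    pred[0] = uniform
    alpha[0] = _normalize(pred[0] * emissions[0])
    for t in range(1, T):
        pred[t] = trans[t - 1].T @ alpha[t - 1]
        alpha[t] = _normalize(pred[t] * emissions[t])

    beta = np.empty((T, G))
    beta[-1] = uniform
    for t in range(T - 2, -1, -1):
        beta[t] = _normalize(trans[t] @ (beta[t + 1] * emissions[t + 1]))

    marginal = np.empty((T, G))
    marginal[0] = uniform
    for t in range(1, T):
        marginal[t] = trans[t - 1].T @ marginal[t - 1]

    posterior = np.array([_normalize(alpha[t] * beta[t]) for t in range(T)])
    predictive = np.array([_normalize(pred[t] * beta[t]) for t in range(T)])
    out = {
        "posterior": posterior,
        "predictive": predictive,
        "marginal": marginal,
    }
    if not all(np.isfinite(v).all() for v in out.values()):
        raise FloatingPointError("non-finite values in HMM recursion")
    return out


def _split_chromosomes(binned: pd.DataFrame):
    for chrom, sub in binned.groupby("chrom", sort=False):
        yield chrom, sub.reset_index(drop=True)


def hmm_posteriors(
    binned: pd.DataFrame | Sequence[pd.DataFrame], params: LODParams
) -> dict[str, dict[str, np.ndarray]]:
    """Leave-one-out predictive / posterior / marginal per bin and chromosome.

    `binned` is one BinnedCounts frame, or a sequence of frames with identical
    binning whose emissions are multiplied (a shared-trajectory chain emitting
    every pool's counts). Returns {chrom: {"predictive", "posterior",
    "marginal", "grid", "bin_mid"}}.
    """
    frames = [binned] if isinstance(binned, pd.DataFrame) else list(binned)
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, sub in _split_chromosomes(frames[0]):
        mids = 0.5 * (sub["bin_start"] + sub["bin_end"]).to_numpy(dtype=float)
        emissions = np.ones((len(sub), params.grid_points))
        for frame in frames:
            fs = frame.loc[frame["chrom"] == chrom].reset_index(drop=True)
            emissions *= _emissions(
                fs["ref"].to_numpy(), (fs["ref"] + fs["alt"]).to_numpy(), params
            )
        gaps = np.diff(mids)
        res = _run_chain(emissions, gaps, params)
        res["grid"] = params.grid
        res["bin_mid"] = mids
        out[chrom] = res
    return out


def _check_same_binning(high: pd.DataFrame, low: pd.DataFrame) -> None:
    same = (
        len(high) == len(low)
        and (high["chrom"].to_numpy() == low["chrom"].to_numpy()).all()
        and (high["bin_start"].to_numpy() == low["bin_start"].to_numpy()).all()
    )
    if not same:
        raise ValueError("high and low pools are not binned identically")


def lod_track(
    high: pd.DataFrame,
    low: pd.DataFrame,
    params: LODParams | None = None,
    compute_local: bool = False,
    include_empty: bool = False,
) -> pd.DataFrame:
    """Per-bin contrast LOD between a high and a low pool.

    Inference runs on the informative bins (nonzero depth in either pool);
    empty bins carry no evidence and are omitted from the output unless
    `include_empty` is set, in which case they appear with LOD 0. The
    `delta_af` column is the difference of posterior mean frequencies
    (a model-smoothed ΔAF); pipelines may overwrite it with a loess-smoothed
    value at the bin midpoint. The track is symmetric in the two pools.
    """
    params = params or LODParams()
    _check_same_binning(high, low)
    pieces = []
    for chrom, sub_h in _split_chromosomes(high):
        sub_l = low.loc[low["chrom"] == chrom].reset_index(drop=True)
        depth_h = (sub_h["ref"] + sub_h["alt"]).to_numpy()
        depth_l = (sub_l["ref"] + sub_l["alt"]).to_numpy()
        informative = (depth_h + depth_l) > 0
        ih = sub_h.loc[informative].reset_index(drop=True)
        il = sub_l.loc[informative].reset_index(drop=True)
        mids = 0.5 * (ih["bin_start"] + ih["bin_end"]).to_numpy(dtype=float)
        gaps = np.diff(mids)
        grid = params.grid

        E_h = _emissions(ih["ref"].to_numpy(), ih["ref"].to_numpy() + ih["alt"].to_numpy(), params)
        E_l = _emissions(il["ref"].to_numpy(), il["ref"].to_numpy() + il["alt"].to_numpy(), params)
        chain_h = _run_chain(E_h, gaps, params)
        chain_l = _run_chain(E_l, gaps, params)
        marginal = chain_h["marginal"]  # identical transitions for both pools

        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                marginal > 0,
                chain_h["posterior"] * chain_l["posterior"] / np.maximum(marginal, _FLOOR),
                0.0,
            )
        overlap = np.maximum(ratio.sum(axis=1), _FLOOR)
        lod = np.maximum(-np.log10(overlap), 0.0)

        piece = pd.DataFrame(
            {
                "chrom": chrom,
                "bin_start": ih["bin_start"].to_numpy(),
                "bin_end": ih["bin_end"].to_numpy(),
                "bin_mid": mids,
                "lod": lod,
                "delta_af": chain_h["posterior"] @ grid - chain_l["posterior"] @ grid,
                "depth_high": ih["ref"].to_numpy() + ih["alt"].to_numpy(),
                "depth_low": il["ref"].to_numpy() + il["alt"].to_numpy(),
            }
        )

        if compute_local:
            chain_s = _run_chain(E_h * E_l, gaps, params)
            num = (chain_h["predictive"] * E_h).sum(axis=1) * (
                chain_l["predictive"] * E_l
            ).sum(axis=1)
            den = (chain_s["predictive"] * E_h * E_l).sum(axis=1)
            piece["local_lod"] = np.log10(np.maximum(num, _FLOOR)) - np.log10(
                np.maximum(den, _FLOOR)
            )

        if include_empty:
            empty = sub_h.loc[~informative, ["chrom", "bin_start", "bin_end"]].copy()
            empty["bin_mid"] = 0.5 * (empty["bin_start"] + empty["bin_end"])
            empty["lod"] = 0.0
            empty["delta_af"] = np.nan
            empty["depth_high"] = 0
            empty["depth_low"] = 0
            if compute_local:
                empty["local_lod"] = 0.0
            piece = (
                pd.concat([piece, empty], ignore_index=True)
                .sort_values("bin_start")
                .reset_index(drop=True)
            )
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    if not np.isfinite(out["lod"].to_numpy()).all():
        raise FloatingPointError("non-finite LOD values")
    return out


def write_track_tsv(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False)


def write_track_bedgraph(track: pd.DataFrame, path, value: str = "lod") -> None:
    """BedGraph (0-based half-open) for genome browsers."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="dualqtl {value}"\n')
        for row in track.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.bin_start - 1}\t{row.bin_end}\t"
                f"{getattr(row, value):.6g}\n"
            )
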