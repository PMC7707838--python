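"""End-to-end orchestration: simulate → map → merge → classify.

These functions wire the modules together in analysis order:
per replicate and channel, pooled counts from the high and low fluorescence
tails are turned into allele-frequency tracks, extreme frequencies are
filtered, counts are binned, the contrast LOD track is computed, peaks are
called at the permissive threshold, replicates are merged, the stringent
threshold is applied, and mRNA/protein loci are paired and classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import afd_track, concordance, lod_model, peak_calling, replication
from .pool_io import PoolMeta, PooledCounts, Region
from .synthetic_cross import (
    CrossConfig,
    DepthModel,
    SortConfig,
    TraitModel,
    default_config,
    default_trait_model,
    sequence_pool,
    simulate_phenotypes,
    simulate_segregants,
    sort_pools,
    truth_table,
)

__all__ = [
    "SimulatedStudy",
    "MapResult",
    "simulate_study",
    "map_contrast",
    "map_gene_channel",
    "classify_study",
    "summarize_classes",
]

PERMISSIVE_LOD = 3.0
STRINGENT_LOD = 4.5
MERGE_WINDOW = 75_000.0
AF_BOUNDS = (0.1, 0.9)
LOESS_BANDWIDTH = 20_000.0

CHANNELS = ("mRNA", "protein")
GATES = ("high", "low", "unsorted")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


@dataclass
class SimulatedStudy:
    """One simulated gene: pools per channel / replicate / gate, plus truth."""

    config: CrossConfig
    trait_model: TraitModel
    sort: SortConfig
    depth: DepthModel
    gene: str
    pools: dict  # channel -> replicate -> gate -> PooledCounts
    truth: pd.DataFrame
    n_gated: int

    @property
    def replicates(self) -> list[str]:
        return sorted(next(iter(self.pools.values())).keys())


def simulate_study(
    config: CrossConfig | None = None,
    trait_model: TraitModel | None = None,
    sort: SortConfig | None = None,
    depth: DepthModel | None = None,
    seed: int = 0,
    n_replicates: int = 1,
    gene: str = "GENE1",
) -> SimulatedStudy:
    """Simulate a full sorting experiment for one tagged gene.

    Each biological replicate is an independent segregant population
    (biological replicates come from independent sporulations), independently
    phenotyped, sorted and sequenced. Deterministic given `seed`.
    """
    config = config or default_config()
    sort = sort or SortConfig()
    depth = depth or DepthModel()
    seeds = iter(_child_seeds(seed, n_replicates * 12))
    pools: dict = {c: {} for c in CHANNELS}
    trait = trait_model
    n_gated = 0
    for rep in range(1, n_replicates + 1):
        rep_id = str(rep)
        geno_cfg = CrossConfig(
            chromosomes=config.chromosomes,
            markers=config.markers,
            n_segregants=config.n_segregants,
            bp_per_cM=config.bp_per_cM,
            seed=next(seeds),
        )
        genotypes = simulate_segregants(geno_cfg)
        if trait is None:
            trait = default_trait_model(config)
        phen = simulate_phenotypes(genotypes, trait, next(seeds))
        for channel in CHANNELS:
            members = sort_pools(phen, sort, channel, seed=next(seeds))
            n_gated = len(members.gated)
            pools[channel][rep_id] = {}
            for gate in GATES:
                meta = PoolMeta(
                    gene=gene,
                    channel="mCherry" if channel == "mRNA" else "GFP",
                    gate=gate,
                    replicate=rep_id,
                )
                pools[channel][rep_id][gate] = sequence_pool(
                    genotypes, getattr(members, gate), depth, next(seeds), meta
                )
    truth = truth_table(trait, sort, n_gated=n_gated)
    return SimulatedStudy(
        config=config,
        trait_model=trait,
        sort=sort,
        depth=depth,
        gene=gene,
        pools=pools,
        truth=truth,
        n_gated=n_gated,
    )


@dataclass
class MapResult:
    """Tracks and peaks for one high-vs-low contrast."""

    lod: pd.DataFrame  # binned LOD track
    smoothed_delta: pd.DataFrame  # marker-level loess-smoothed ΔAF
    peaks: pd.DataFrame  # permissive-threshold peak calls
    n_markers_filtered: int = 0


def map_contrast(
    high: PooledCounts,
    low: PooledCounts,
    params: lod_model.LODParams | None = None,
    af_bounds: tuple[float, float] = AF_BOUNDS,
    loess_bandwidth: float = LOESS_BANDWIDTH,
    permissive_lod: float = PERMISSIVE_LOD,
    chrom_lengths: dict[str, int] | None = None,
) -> MapResult:
    """Map one pool pair: AF → filter → smooth/ΔAF → bin → LOD → peaks.

    A marker with an extreme allele frequency (outside `af_bounds`, strict)
    in either pool of the pair is excluded from both before binning and
    smoothing. Peak ΔAF is read from the loess-smoothed ΔAF track at the
    peak position.
    """
    params = params or lod_model.LODParams()
    af_h = afd_track.compute_af(high)
    af_l = afd_track.compute_af(low)
    lo, hi = af_bounds

    def extreme(track: pd.DataFrame) -> np.ndarray:
        af = track["af"].to_numpy()
        return (af > hi) | (af < lo)

    keep = ~(extreme(af_h) | extreme(af_l))
    n_filtered = int((~keep).sum())
    af_h = af_h.loc[keep].reset_index(drop=True)
    af_l = af_l.loc[keep].reset_index(drop=True)

    sm_h = afd_track.smooth_af(af_h, loess_bandwidth)
    sm_l = afd_track.smooth_af(af_l, loess_bandwidth)
    smoothed_delta = afd_track.delta_af(sm_h, sm_l)

    frame_h = high.to_frame().loc[keep]
    frame_l = low.to_frame().loc[keep]
    binned_h = lod_model.bin_counts(frame_h, params, chrom_lengths)
    binned_l = lod_model.bin_counts(frame_l, params, chrom_lengths)
    lod = lod_model.lod_track(binned_h, binned_l, params)

    # report ΔAF from the loess-smoothed frequency tracks: the HMM posterior
    # mean difference is shrunk toward zero by the chain's no-selection prior
    # and would understate effect sizes
    for chrom, sub in lod.groupby("chrom", sort=False):
        src = smoothed_delta.loc[smoothed_delta["chrom"] == chrom]
        lod.loc[sub.index, "delta_af"] = np.interp(
            sub["bin_mid"].to_numpy(dtype=float),
            src["pos"].to_numpy(dtype=float),
            src["delta_af"].to_numpy(dtype=float),
        )

    peaks = peak_calling.call_peaks(lod, permissive_lod)
    return MapResult(
        lod=lod,
        smoothed_delta=smoothed_delta,
        peaks=peaks,
        n_markers_filtered=n_filtered,
    )


@dataclass
class ChannelMapping:
    """Per-replicate results plus merged QTLs for one gene + channel."""

    results: dict  # replicate -> MapResult
    merged: pd.DataFrame  # permissive merged QTLs
    significant: pd.DataFrame  # merged QTLs with mean LOD >= stringent

    def delta_tracks(self) -> list[pd.DataFrame]:
        return [r.smoothed_delta for r in self.results.values()]


def map_gene_channel(
    pools_by_replicate: dict,
    params: lod_model.LODParams | None = None,
    merge_window: float = MERGE_WINDOW,
    stringent_lod: float = STRINGENT_LOD,
    **contrast_kwargs,
) -> ChannelMapping:
    """Map every replicate of one gene + channel and merge the peak calls."""
    results = {
        rep: map_contrast(gates["high"], gates["low"], params, **contrast_kwargs)
        for rep, gates in pools_by_replicate.items()
    }
    merged = replication.merge_replicates(
        {rep: r.peaks for rep, r in results.items()},
        {rep: r.lod for rep, r in results.items()},
        window=merge_window,
    )
    significant = replication.filter_significant(merged, stringent_lod)
    return ChannelMapping(results=results, merged=merged, significant=significant)


def classify_study(
    mrna: ChannelMapping,
    protein: ChannelMapping,
    gene: str = "GENE1",
    overrides=(),
    region: Region | None = None,
    stringent_lod: float = STRINGENT_LOD,
) -> pd.DataFrame:
    """Pair and classify one gene's mRNA and protein merged QTLs.

    Both channels' permissive merged lists are cleaned of the excluded region
    (when given), paired by CI overlap, filtered to loci with at least one
    stringent member, and classified. Missing effect values of single-member
    loci are filled from the other channel's smoothed ΔAF at the peak.
    """
    merged_m, merged_p = mrna.merged, protein.merged
    if region is not None:
        merged_m = concordance.exclude_region(merged_m, region)
        merged_p = concordance.exclude_region(merged_p, region)
    pairs = concordance.pair_qtls(merged_m, merged_p, gene=gene, overrides=overrides)
    loci = concordance.classify(pairs, stringent_lod)
    if len(loci) == 0:
        return loci
    fill_m = loci["delta_af_mrna"].isna()
    fill_p = loci["delta_af_protein"].isna()
    loci = loci.copy()
    for idx in loci.index[fill_m]:
        loci.loc[idx, "delta_af_mrna"] = concordance.effect_at_peak(
            loci.loc[idx], mrna.delta_tracks()
        )
    for idx in loci.index[fill_p]:
        loci.loc[idx, "delta_af_protein"] = concordance.effect_at_peak(
            loci.loc[idx], protein.delta_tracks()
        )
    return loci


def summarize_classes(loci: pd.DataFrame) -> dict:
    """Class counts and direction agreement for a classified locus table."""
    counts = {c: 0 for c in ("concordant", "discordant", "mrna_specific", "protein_specific")}
    if len(loci):
        counts.update(loci["qtl_class"].value_counts().to_dict())
    summary = {"n_loci": int(len(loci)), "class_counts": counts}
    try:
        prop, p, n = concordance.direction_agreement(loci)
        summary["direction_agreement"] = {
            "proportion_same_sign": prop,
            "p_value": p,
            "n": n,
        }
    except ValueError:
        summary["direction_agreement"] = None
    return summary
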