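"""Synthetic BY×RM cross: segregants, dual-reporter phenotypes, sorting, sequencing.

The simulator produces every input the mapping pipeline consumes, with known
ground truth. It emulates a haploid yeast segregant population from a
two-parent cross (allele 0 = BY = reference, allele 1 = RM), single-cell
mRNA (mCherry) and protein (GFP) reporter signals driven by planted QTLs,
FACS tail sorting of the fluorescence extremes within a cell-size gate, and
pooled whole-genome sequencing at Poisson depth.

Planted QTL classes
-------------------
Each planted locus has a transcription effect ``a`` and a protein-specific
effect ``b`` (both in trait SD-scale units; positive = BY allele increases
the trait). With transmission coefficient κ (protein units per mRNA unit):

* concordant:        a ≠ 0, b = 0          (protein effect κ·a, same sign)
* protein-specific:  a = 0, b ≠ 0
* mRNA-specific:     b = −κ·a              (perfect buffering; no net protein effect)
* discordant:        b < −κ·a              (overcompensation; opposite protein sign)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pool_io import MarkerList, PoolMeta, PooledCounts

__all__ = [
    "CrossConfig",
    "GenotypeMatrix",
    "PlantedQTL",
    "TraitModel",
    "CellPhenotypes",
    "SortConfig",
    "DepthModel",
    "PoolMembership",
    "simulate_segregants",
    "simulate_phenotypes",
    "sort_pools",
    "sequence_pool",
    "expected_delta_af",
    "default_config",
    "default_trait_model",
    "truth_table",
]

QTL_CLASSES = ("concordant", "protein_specific", "mrna_specific", "discordant")


@dataclass(frozen=True)
class CrossConfig:
    """Genome layout and cross parameters.

    chromosomes: ordered mapping name -> length (bp).
    markers: mapping name -> strictly increasing 1-based positions (bp).
    bp_per_cM: physical-to-genetic scaling (2,200 bp/cM in the BY×RM cross).
    """

    chromosomes: Mapping[str, int]
    markers: Mapping[str, np.ndarray]
    n_segregants: int
    bp_per_cM: float = 2200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bp_per_cM <= 0:
            raise ValueError("bp_per_cM must be positive")
        if self.n_segregants < 1:
            raise ValueError("n_segregants must be at least 1")
        markers = {c: np.asarray(p, dtype=np.int64) for c, p in self.markers.items()}
        object.__setattr__(self, "markers", markers)
        for chrom, pos in markers.items():
            if chrom not in self.chromosomes:
                raise ValueError(f"markers given for unknown chromosome {chrom}")
            if len(pos) and pos.max() > self.chromosomes[chrom]:
                raise ValueError(f"marker beyond the end of {chrom}")
            if len(pos) > 1 and (np.diff(pos) <= 0).any():
                raise ValueError(f"marker positions on {chrom} must strictly increase")

    def marker_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": pos})
            for chrom, pos in self.markers.items()
            if len(pos)
        ]
        return pd.concat(frames, ignore_index=True)

    def marker_list(self) -> MarkerList:
        frame = self.marker_frame()
        frame["ref"] = "A"
        frame["alt"] = "T"
        return MarkerList(frame)


@dataclass
class GenotypeMatrix:
    """Haploid segregant alleles (0 = BY, 1 = RM) at ordered markers."""

    alleles: np.ndarray  # (n_segregants, n_markers) int8
    markers: pd.DataFrame  # columns chrom, pos

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.markers):
            raise ValueError("allele matrix does not match the marker index")
        if self.alleles.size and (self.alleles.min() < 0 or self.alleles.max() > 1):
            raise ValueError("alleles must be 0 or 1")

    @property
    def n_segregants(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def by_frequency(self, rows: np.ndarray | None = None) -> np.ndarray:
        """BY-allele frequency per marker, optionally within a subset of cells."""
        sub = self.alleles if rows is None else self.alleles[rows]
        return 1.0 - sub.mean(axis=0)

    def marker_index(self, chrom: str, pos: int) -> int:
        mask = (self.markers["chrom"] == chrom) & (self.markers["pos"] == pos)
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) != 1:
            raise KeyError(f"marker {chrom}:{pos} not found")
        return int(idx[0])


def simulate_segregants(config: CrossConfig) -> GenotypeMatrix:
    """Draw independent meiotic products on a linear map without interference.

    The first marker of each chromosome is Bernoulli(0.5); between adjacent
    markers d bp apart the allele switches with recombination fraction
    r = min(0.5, d / (bp_per_cM × 100)). Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_segregants
    blocks: list[np.ndarray] = []
    frames: list[pd.DataFrame] = []
    for chrom in config.chromosomes:
        pos = config.markers.get(chrom, np.empty(0, dtype=np.int64))
        if len(pos) == 0:
            warnings.warn(f"chromosome {chrom} has no markers and was skipped")
            continue
        m = len(pos)
        first = (rng.random(n) < 0.5).astype(np.int8)
        if m > 1:
            d = np.diff(pos).astype(float)
            r = np.minimum(0.5, d / (config.bp_per_cM * 100.0))
            switches = rng.random((n, m - 1), dtype=np.float32) < r.astype(np.float32)
            # uint8 cumsum wraps mod 256 (even), which preserves parity
            parity = np.cumsum(switches, axis=1, dtype=np.uint8) & 1
            alleles = np.empty((n, m), dtype=np.int8)
            alleles[:, 0] = first
            alleles[:, 1:] = first[:, None] ^ parity.astype(np.int8)
        else:
            alleles = first[:, None]
        blocks.append(alleles)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    if not blocks:
        raise ValueError("no chromosome had any markers")
    return GenotypeMatrix(
        np.concatenate(blocks, axis=1), pd.concat(frames, ignore_index=True)
    )


@dataclass(frozen=True)
class PlantedQTL:
    """One planted locus, identified by its marker."""

    chrom: str
    pos: int
    qtl_class: str
    a: float  # transcription effect
    b: float  # protein-specific effect

    def __post_init__(self) -> None:
        if self.qtl_class not in QTL_CLASSES:
            raise ValueError(f"unknown QTL class {self.qtl_class!r}")

    def protein_effect(self, kappa: float) -> float:
        return kappa * self.a + self.b


@dataclass
class TraitModel:
    """Generative model for correlated single-cell mRNA / protein signals.

    Per cell i with genotypes x_ij (0 = BY contributes +effect/2):

        t_i = Σ_j a_j (1/2 − x_ij)            latent transcription value
        s_i = Σ_j b_j (1/2 − x_ij)            latent protein-specific value
        R_i = t_i + γ·log(FSC_i) + ε_R        mRNA reporter (mCherry)
        G_i = κ·t_i + s_i + γ·log(FSC_i) + ε_G  protein reporter (GFP)

    with log(FSC) ~ Normal(size_log_mean, size_log_sd), ε ~ Normal(0, σ).
    """

    a: np.ndarray
    b: np.ndarray
    kappa: float = 1.0
    sigma_r: float = 1.0
    sigma_g: float = 1.0
    gamma: float = 1.0
    size_log_mean: float = 4.0
    size_log_sd: float = 0.25
    planted: tuple[PlantedQTL, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("effect vectors a and b must have equal length")
        if self.sigma_r < 0 or self.sigma_g < 0:
            raise ValueError("noise SDs must be non-negative")

    @classmethod
    def from_planted(
        cls,
        genotypes_markers: pd.DataFrame,
        planted: Sequence[PlantedQTL],
        **kwargs,
    ) -> "TraitModel":
        m = len(genotypes_markers)
        a = np.zeros(m)
        b = np.zeros(m)
        kappa = kwargs.get("kappa", 1.0)
        for q in planted:
            mask = (genotypes_markers["chrom"] == q.chrom) & (
                genotypes_markers["pos"] == q.pos
            )
            idx = np.flatnonzero(mask.to_numpy())
            if len(idx) != 1:
                raise KeyError(f"planted QTL marker {q.chrom}:{q.pos} not found")
            a[idx[0]] = q.a
            b[idx[0]] = q.b
        return cls(a=a, b=b, planted=tuple(planted), **kwargs)

    def channel_effect(self, qtl: PlantedQTL, channel: str) -> float:
        """Net additive effect of one planted locus on a channel (BY − RM mean)."""
        if channel == "mRNA":
            return qtl.a
        if channel == "protein":
            return self.kappa * qtl.a + qtl.b
        raise ValueError(f"unknown channel {channel!r}")


@dataclass
class CellPhenotypes:
    """Single-cell reporter signals and latent values."""

    R: np.ndarray  # mRNA reporter (mCherry)
    G: np.ndarray  # protein reporter (GFP)
    FSC: np.ndarray
    t: np.ndarray
    s: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        if name == "mRNA":
            return self.R
        if name == "protein":
            return self.G
        raise ValueError(f"unknown channel {name!r}; use 'mRNA' or 'protein'")

    def __len__(self) -> int:
        return len(self.R)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, model: TraitModel, seed: int
) -> CellPhenotypes:
    """Draw one cell per segregant from the trait model. Deterministic given seed."""
    if len(model.a) != genotypes.n_markers:
        raise ValueError(
            f"effect vectors have length {len(model.a)} but there are "
            f"{genotypes.n_markers} markers"
        )
    rng = np.random.default_rng(seed)
    n = genotypes.n_segregants

    def genetic_value(effects: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(effects)
        if len(idx) == 0:
            return np.zeros(n)
        x = genotypes.alleles[:, idx].astype(np.float64)
        return 0.5 * effects[idx].sum() - x @ effects[idx]

    t = genetic_value(model.a)
    s = genetic_value(model.b)
    log_fsc = rng.normal(model.size_log_mean, model.size_log_sd, n)
    eps_r = rng.normal(0.0, model.sigma_r, n) if model.sigma_r > 0 else 0.0
    eps_g = rng.normal(0.0, model.sigma_g, n) if model.sigma_g > 0 else 0.0
    R = t + model.gamma * log_fsc + eps_r
    G = model.kappa * t + s + model.gamma * log_fsc + eps_g
    return CellPhenotypes(R=R, G=G, FSC=np.exp(log_fsc), t=t, s=s)


@dataclass(frozen=True)
class SortConfig:
    """FACS emulation: FSC gate, tail fraction and pool size."""

    q: float = 0.03
    pool_size: int = 10_000
    fsc_band: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if not 0 < self.q < 0.5:
            raise ValueError("tail fraction q must lie in (0, 0.5)")
        if self.pool_size < 1:
            raise ValueError("pool size must be at least 1")
        lo, hi = self.fsc_band
        if not 0 <= lo < hi <= 1:
            raise ValueError("fsc_band must be an increasing quantile pair in [0,1]")


@dataclass
class PoolMembership:
    """Disjoint cell-index pools from one sort."""

    high: np.ndarray
    low: np.ndarray
    unsorted: np.ndarray
    gated: np.ndarray
    channel: str


def sort_pools(
    phenotypes: CellPhenotypes,
    sort: SortConfig,
    channel: str,
    seed: int = 0,
) -> PoolMembership:
    """Gate cells to the central FSC band, then take the fluorescence tails.

    The high pool is the min(pool_size, floor(q·n_gated)) gated cells with the
    largest channel signal; the low pool is the analogous smallest; the
    unsorted pool is a random gate sample disjoint from both.
    """
    values = phenotypes.channel(channel)
    fsc = phenotypes.FSC
    lo, hi = np.quantile(fsc, sort.fsc_band)
    gated = np.flatnonzero((fsc >= lo) & (fsc <= hi))
    n_gated = len(gated)
    k = min(sort.pool_size, int(np.floor(sort.q * n_gated)))
    if k < 1:
        required = int(np.ceil(1.0 / sort.q))
        raise ValueError(
            f"only {n_gated} gated cells; at least {required} are required "
            f"for a {sort.q:.0%} tail"
        )
    order = gated[np.argsort(values[gated], kind="stable")]
    low = order[:k]
    high = order[-k:]
    rng = np.random.default_rng(seed)
    remaining = order[k:-k]
    n_uns = min(sort.pool_size, len(remaining))
    unsorted = rng.choice(remaining, size=n_uns, replace=False)
    return PoolMembership(
        high=high, low=low, unsorted=unsorted, gated=gated, channel=channel
    )


@dataclass(frozen=True)
class DepthModel:
    """Pooled sequencing depth: Poisson(λ) reads/marker, error rate e."""

    mean_depth: float = 13.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean depth must be non-negative")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")


def sequence_pool(
    genotypes: GenotypeMatrix,
    members: np.ndarray,
    depth: DepthModel,
    seed: int,
    meta: PoolMeta | None = None,
) -> PooledCounts:
    """Sequence one pool: depth ~ Poisson(λ); reference reads ~ Binomial.

    The per-marker reference-read probability is p·(1−e) + (1−p)·e where p is
    the BY-allele frequency among the pool members.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("pool has no members")
    rng = np.random.default_rng(seed)
    p = genotypes.by_frequency(members)
    n = rng.poisson(depth.mean_depth, genotypes.n_markers)
    p_read = p * (1.0 - depth.error_rate) + (1.0 - p) * depth.error_rate
    k = rng.binomial(n, p_read)
    markers = genotypes.markers
    frame = markers.copy()
    frame["ref"] = "A"
    frame["alt"] = "T"
    return PooledCounts(MarkerList(frame), k, n - k, meta or PoolMeta())


def expected_delta_af(
    effect: float,
    residual_sd: float,
    q: float = 0.03,
) -> float:
    """Expected ΔAF of a biallelic locus under symmetric two-tail truncation.

    `effect` is the difference between the two genotype means on the sorted
    channel; `residual_sd` is the within-genotype SD; `q` is the effective
    tail fraction. Computed from the Gaussian mixture: the upper cutoff c
    solves ½·S((c−δ/2)/σ) + ½·S((c+δ/2)/σ) = q with S the normal survival
    function, and ΔAF = 2·P(BY | high) − 1 by symmetry.
    """
    if residual_sd <= 0:
        return float(np.sign(effect))
    delta, sd = float(effect), float(residual_sd)
    if delta == 0:
        return 0.0

    def tail(c: float) -> float:
        return 0.5 * (
            stats.norm.sf((c - delta / 2) / sd) + stats.norm.sf((c + delta / 2) / sd)
        ) - q

    hi = sd * 10 + abs(delta)
    c = optimize.brentq(tail, -hi, hi)
    p_by_high = stats.norm.sf((c - delta / 2) / sd) / (2 * q)
    return 2.0 * p_by_high - 1.0


def channel_sd(model: TraitModel, sort: SortConfig) -> dict[str, float]:
    """Approximate phenotypic SD per channel inside the FSC gate.

    Treats planted loci as unlinked (they are placed far apart), and uses the
    truncated-normal variance of log-size within the gate band.
    """
    lo, hi = sort.fsc_band
    a_q, b_q = stats.norm.ppf(lo), stats.norm.ppf(hi)
    var_logf = stats.truncnorm.var(a_q, b_q) * model.size_log_sd**2
    var = {}
    for channel in ("mRNA", "protein"):
        if channel == "mRNA":
            effects = model.a
            noise = model.sigma_r
        else:
            effects = model.kappa * model.a + model.b
            noise = model.sigma_g
        var[channel] = float(
            (effects**2).sum() / 4.0 + noise**2 + model.gamma**2 * var_logf
        )
    return {c: float(np.sqrt(v)) for c, v in var.items()}


def truth_table(
    model: TraitModel,
    sort: SortConfig,
    n_gated: int | None = None,
) -> pd.DataFrame:
    """Expected per-locus ΔAF for both channels, one row per planted QTL."""
    sds = channel_sd(model, sort)
    q_eff = sort.q
    if n_gated is not None:
        q_eff = min(sort.q, sort.pool_size / n_gated)
    rows = []
    for qtl in model.planted:
        row = {
            "chrom": qtl.chrom,
            "pos": qtl.pos,
            "class": qtl.qtl_class,
            "a": qtl.a,
            "b": qtl.b,
        }
        for channel in ("mRNA", "protein"):
            delta = model.channel_effect(qtl, channel)
            sd = np.sqrt(max(sds[channel] ** 2 - delta**2 / 4.0, 1e-12))
            row[f"expected_delta_af_{channel}"] = expected_delta_af(
                delta, sd, q_eff
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "class",
            "a",
            "b",
            "expected_delta_af_mRNA",
            "expected_delta_af_protein",
        ],
    )


def default_config(n_segregants: int = 50_000, seed: int = 0) -> CrossConfig:
    """Desk-scale genome: 4 × 500 kb chromosomes with markers every 1 kb."""
    positions = np.arange(500, 500_000, 1000, dtype=np.int64)
    return CrossConfig(
        chromosomes={c: 500_000 for c in ("chrI", "chrII", "chrIII", "chrIV")},
        markers={c: positions.copy() for c in ("chrI", "chrII", "chrIII", "chrIV")},
        n_segregants=n_segregants,
        seed=seed,
    )


def default_trait_model(config: CrossConfig, **kwargs) -> TraitModel:
    """One planted locus per QTL class, each on its own chromosome.

    Effect sizes are chosen to give expected |ΔAF| ≈ 0.25–0.4 in the affected
    channel at a 3% tail sort — the middle of the range real trans-acting
    loci show in such crosses. One locus per chromosome keeps the
    super-threshold LOD runs of distinct loci separate (pool-frequency
    divergence relaxes toward zero over only ~110 kb of linkage decay).
    """
    kappa = kwargs.get("kappa", 1.0)
    planted = (
        PlantedQTL("chrI", 250_500, "concordant", a=0.30, b=0.0),
        PlantedQTL("chrII", 250_500, "protein_specific", a=0.0, b=0.35),
        PlantedQTL("chrIII", 250_500, "mrna_specific", a=0.35, b=-kappa * 0.35),
        PlantedQTL("chrIV", 250_500, "discordant", a=0.35, b=-1.75 * kappa * 0.35),
    )
    return TraitModel.from_planted(config.marker_frame(), planted, **kwargs)
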