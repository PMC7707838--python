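"""Pairing of mRNA-QTLs and protein-QTLs, curation, and locus classification.

For each gene, merged QTLs called at the permissive threshold (LOD > 3) in
the two channels are paired when their confidence intervals overlap; loci are
then retained when at least one member reaches the stringent threshold
(LOD ≥ 4.5) and classified:

* concordant       — both members present, same ΔAF sign
* discordant       — both members present, opposite ΔAF signs
* mrna_specific    — mRNA member only
* protein_specific — protein member only

A pleiotropic region on chromosome XIV (350–550 kb) that affects the mCherry
reporter independently of the tagged gene is excluded before pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pool_io import Region

__all__ = [
    "CurationOverride",
    "MCHERRY_ARTIFACT_REGION",
    "default_curation_overrides",
    "exclude_region",
    "pair_qtls",
    "classify",
    "effect_at_peak",
    "direction_agreement",
    "effect_correlations",
]

#: Region whose QTLs are dropped: affects mCherry for every tagged gene.
MCHERRY_ARTIFACT_REGION = Region("chrXIV", 350_000, 550_000)

LOCUS_COLUMNS = [
    "gene",
    "chrom",
    "pos_mrna",
    "pos_protein",
    "lod_mrna",
    "lod_protein",
    "delta_af_mrna",
    "delta_af_protein",
    "ci_start_mrna",
    "ci_end_mrna",
    "ci_start_protein",
    "ci_end_protein",
    "pairing",
]


@dataclass(frozen=True)
class CurationOverride:
    """Manual curation of the CI-overlap analysis for one gene + chromosome."""

    gene: str
    chrom: str
    forced: str  # pair | mrna_specific | protein_specific

    def __post_init__(self) -> None:
        if self.forced not in {"pair", "mrna_specific", "protein_specific"}:
            raise ValueError(f"unknown forced status {self.forced!r}")


def default_curation_overrides() -> tuple[CurationOverride, ...]:
    """The six manual curation calls shipped with the pipeline."""
    return (
        CurationOverride("ARO8", "chrXV", "pair"),
        CurationOverride("MTD1", "chrVIII", "pair"),
        CurationOverride("CYC1", "chrXIII", "pair"),
        CurationOverride("RPS10A", "chrXIII", "pair"),
        CurationOverride("GPD1", "chrV", "mrna_specific"),
        CurationOverride("MTD1", "chrXIV", "mrna_specific"),
    )


def exclude_region(
    merged: pd.DataFrame, region: Region = MCHERRY_ARTIFACT_REGION
) -> pd.DataFrame:
    """Drop merged QTLs whose mean peak position lies inside `region` (inclusive)."""
    if len(merged) == 0:
        return merged
    inside = region.contains(
        region.chrom, merged["pos"].to_numpy(dtype=float)
    ) & (merged["chrom"] == region.chrom).to_numpy()
    n = int(inside.sum())
    if n:
        warnings.warn(f"excluded {n} QTL(s) inside {region.chrom}:{region.start}-{region.end}")
    return merged.loc[~inside].reset_index(drop=True)


def _ci_overlap(row_a, row_b) -> bool:
    return row_a["ci_start"] <= row_b["ci_end"] and row_b["ci_start"] <= row_a["ci_end"]


def pair_qtls(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    gene: str = "unknown",
    overrides: Sequence[CurationOverride] = (),
    tie_break: str = "lod",
) -> pd.DataFrame:
    """Pair mRNA and protein merged QTLs of one gene by CI overlap.

    When a QTL's interval overlaps several partners, the highest-LOD partner
    wins (`tie_break="closest"` instead prefers the nearest peak); the others
    stay single. Curation overrides are applied last; an override that
    matches no locus raises. Unpaired QTLs become single-member loci.
    """
    mrna = mrna.reset_index(drop=True)
    protein = protein.reset_index(drop=True)

    candidates = []
    for i, mr in mrna.iterrows():
        for j, pr in protein.iterrows():
            if mr["chrom"] != pr["chrom"] or not _ci_overlap(mr, pr):
                continue
            if tie_break == "lod":
                score = mr["lod"] + pr["lod"]
            elif tie_break == "closest":
                score = -abs(mr["pos"] - pr["pos"])
            else:
                raise ValueError(f"unknown tie_break {tie_break!r}")
            candidates.append((score, i, j))
    candidates.sort(reverse=True)
    used_m: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[int, int, str]] = []
    for _, i, j in candidates:
        if i in used_m or j in used_p:
            continue
        pairs.append((i, j, "ci_overlap"))
        used_m.add(i)
        used_p.add(j)

    pairs = _apply_overrides(pairs, mrna, protein, gene, overrides)

    rows = []
    paired_m = {i for i, _, _ in pairs}
    paired_p = {j for _, j, _ in pairs}
    for i, j, basis in pairs:
        rows.append(_locus_row(gene, mrna.loc[i], protein.loc[j], basis))
    for i in mrna.index.difference(paired_m):
        rows.append(_locus_row(gene, mrna.loc[i], None, "single"))
    for j in protein.index.difference(paired_p):
        rows.append(_locus_row(gene, None, protein.loc[j], "single"))
    out = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    return out.sort_values(["chrom", "pos_mrna", "pos_protein"]).reset_index(drop=True)


def _apply_overrides(pairs, mrna, protein, gene, overrides):
    pairs = list(pairs)
    for ov in overrides:
        if ov.gene != gene:
            continue
        m_idx = [i for i in mrna.index if mrna.loc[i, "chrom"] == ov.chrom]
        p_idx = [j for j in protein.index if protein.loc[j, "chrom"] == ov.chrom]
        if ov.forced == "pair":
            if not m_idx or not p_idx:
                raise ValueError(
                    f"override {ov} references no (mRNA, protein) QTL pair on {ov.chrom}"
                )
            # keep an existing pairing on this chromosome, else force top-LOD pair
            existing = [
                (i, j, b)
                for i, j, b in pairs
                if mrna.loc[i, "chrom"] == ov.chrom
            ]
            if not existing:
                best_m = max(m_idx, key=lambda i: mrna.loc[i, "lod"])
                best_p = max(p_idx, key=lambda j: protein.loc[j, "lod"])
                pairs = [
                    (i, j, b)
                    for i, j, b in pairs
                    if i != best_m and j != best_p
                ]
                pairs.append((best_m, best_p, "curation"))
        elif ov.forced == "mrna_specific":
            if not m_idx:
                raise ValueError(f"override {ov} references no mRNA-QTL on {ov.chrom}")
            pairs = [
                (i, j, b) for i, j, b in pairs if mrna.loc[i, "chrom"] != ov.chrom
            ]
        elif ov.forced == "protein_specific":
            if not p_idx:
                raise ValueError(f"override {ov} references no protein-QTL on {ov.chrom}")
            pairs = [
                (i, j, b) for i, j, b in pairs if protein.loc[j, "chrom"] != ov.chrom
            ]
    return pairs


def _locus_row(gene, mr, pr, basis) -> dict:
    row = {c: np.nan for c in LOCUS_COLUMNS}
    row["gene"] = gene
    row["pairing"] = basis
    if mr is not None:
        row.update(
            chrom=mr["chrom"],
            pos_mrna=mr["pos"],
            lod_mrna=mr["lod"],
            delta_af_mrna=mr["delta_af"],
            ci_start_mrna=mr["ci_start"],
            ci_end_mrna=mr["ci_end"],
        )
    if pr is not None:
        row.update(
            chrom=pr["chrom"],
            pos_protein=pr["pos"],
            lod_protein=pr["lod"],
            delta_af_protein=pr["delta_af"],
            ci_start_protein=pr["ci_start"],
            ci_end_protein=pr["ci_end"],
        )
    return row


def classify(pairs: pd.DataFrame, stringent_threshold: float = 4.5) -> pd.DataFrame:
    """Drop loci where no member reaches the stringent LOD, then classify.

    Applying the stringent threshold only after pairing keeps a pair whose
    weaker member narrowly misses significance, rather than declaring the
    stronger member specific. A both-member locus with a ΔAF of exactly zero
    cannot be assigned a direction and is labelled ``undetermined`` with a
    warning (never silently classified).
    """
    if len(pairs) == 0:
        out = pairs.copy()
        out["qtl_class"] = pd.Series(dtype=str)
        return out
    lod_m = pairs["lod_mrna"].fillna(-np.inf)
    lod_p = pairs["lod_protein"].fillna(-np.inf)
    keep = (lod_m >= stringent_threshold) | (lod_p >= stringent_threshold)
    out = pairs.loc[keep].reset_index(drop=True).copy()

    classes = []
    for r in out.itertuples(index=False):
        has_m = r.lod_mrna == r.lod_mrna  # NaN-safe presence check
        has_p = r.lod_protein == r.lod_protein
        if has_m and has_p:
            sm, sp = np.sign(r.delta_af_mrna), np.sign(r.delta_af_protein)
            if sm == 0 or sp == 0:
                warnings.warn(
                    f"locus {r.gene} {r.chrom}: ΔAF of exactly zero; class undetermined"
                )
                classes.append("undetermined")
            elif sm == sp:
                classes.append("concordant")
            else:
                classes.append("discordant")
        elif has_m:
            classes.append("mrna_specific")
        else:
            classes.append("protein_specific")
    out["qtl_class"] = classes
    return out


def effect_at_peak(
    locus: pd.Series,
    other_channel_delta_tracks: Sequence[pd.DataFrame],
) -> float:
    """Smoothed ΔAF of the other channel at the locus's reference peak.

    The reference peak is the significant member's position (for single-member
    loci, the member itself). Each track is a marker-level frame with columns
    chrom, pos, delta_af; values are averaged across replicate tracks.
    """
    if np.isfinite(locus.get("pos_mrna", np.nan)):
        chrom, pos = locus["chrom"], locus["pos_mrna"]
    else:
        chrom, pos = locus["chrom"], locus["pos_protein"]
    values = []
    for track in other_channel_delta_tracks:
        sub = track.loc[track["chrom"] == chrom]
        if len(sub) == 0:
            raise ValueError(f"no track data on {chrom}")
        x = sub["pos"].to_numpy(dtype=float)
        if not (x.min() <= pos <= x.max()):
            raise ValueError(f"position {pos} outside track extent on {chrom}")
        values.append(np.interp(pos, x, sub["delta_af"].to_numpy(dtype=float)))
    return float(np.mean(values))


def direction_agreement(
    loci: pd.DataFrame,
    mrna_col: str = "delta_af_mrna",
    protein_col: str = "delta_af_protein",
    alternative: str = "two-sided",
) -> tuple[float, float, int]:
    """Proportion of loci with same-sign mRNA and protein effects.

    Returns (proportion, exact binomial p-value against 0.5, n loci used).
    Loci missing either effect are excluded; the denominator is explicit.
    """
    sub = loci.dropna(subset=[mrna_col, protein_col])
    n = len(sub)
    if n == 0:
        raise ValueError("no loci with both effect values")
    same = int(
        (np.sign(sub[mrna_col].to_numpy()) == np.sign(sub[protein_col].to_numpy())).sum()
    )
    test = stats.binomtest(same, n, 0.5, alternative=alternative)
    return same / n, float(test.pvalue), n


def effect_correlations(
    loci: pd.DataFrame,
    mrna_col: str = "delta_af_mrna",
    protein_col: str = "delta_af_protein",
) -> pd.DataFrame:
    """Pearson correlation of (ΔAF_mRNA, ΔAF_protein) overall and per class."""
    rows = []
    groups = [("all", loci)]
    if "qtl_class" in loci.columns:
        groups += list(loci.groupby("qtl_class", sort=False))
    for name, sub in groups:
        sub = sub.dropna(subset=[mrna_col, protein_col])
        if len(sub) < 3:
            rows.append({"group": name, "n": len(sub), "r": np.nan, "p_value": np.nan})
            continue
        r, p = stats.pearsonr(sub[mrna_col], sub[protein_col])
        rows.append({"group": name, "n": len(sub), "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
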