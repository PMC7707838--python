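"""Binned hidden-frequency model: binning, predictives, and the contrast LOD.

The key check is the brute-force oracle: on instances of up to 3 bins over a
21-point grid, the LOD from the scaled forward–backward recursions must equal
direct evaluation of the same likelihood-ratio formula over the full joint
hidden-state tensor.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from dualqtl.lod_model import (
    LODParams,
    _emissions,
    _transition,
    bin_counts,
    hmm_posteriors,
    lod_track,
)


def _binned(starts, ref, alt, chrom="chrI"):
    starts = np.asarray(starts)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "bin_start": starts,
            "bin_end": starts + 99,
            "ref": ref,
            "alt": alt,
        }
    )


class TestBinCounts:
    def _counts(self, pos, ref, alt):
        return pd.DataFrame(
            {"chrom": "chrI", "pos": pos, "ref_count": ref, "alt_count": alt}
        )

    def test_bin_assignment(self):
        binned = bin_counts(self._counts([50, 149], [1, 1], [0, 0]), LODParams())
        nonzero = binned.loc[binned["ref"] > 0]
        assert list(nonzero["bin_start"]) == [1, 101]

    def test_counts_summed_within_bin(self):
        binned = bin_counts(self._counts([10, 60], [3, 2], [1, 4]), LODParams())
        assert binned.loc[0, "ref"] == 5 and binned.loc[0, "alt"] == 5

    def test_empty_bins_present_with_zero_counts(self):
        binned = bin_counts(
            self._counts([50, 250], [1, 1], [1, 1]),
            LODParams(),
            chrom_lengths={"chrI": 300},
        )
        assert len(binned) == 3
        assert binned.loc[1, "ref"] == 0 and binned.loc[1, "alt"] == 0


class TestHMMPosteriors:
    def test_single_empty_bin_gives_uniform_predictive(self):
        params = LODParams(grid_points=21)
        res = hmm_posteriors(_binned([1], [0], [0]), params)["chrI"]
        np.testing.assert_allclose(res["predictive"][0], 1 / 21)

    def test_tightly_linked_neighbor_concentrates_predictive(self):
        # 50/50 reference reads one bin away (r ~ 5e-7): the empty bin's
        # predictive must put almost all mass above 0.9
        params = LODParams(grid_points=21)
        res = hmm_posteriors(_binned([1, 101], [0, 50], [0, 0]), params)["chrI"]
        grid = res["grid"]
        mass_high = res["predictive"][0][grid > 0.9].sum()
        assert mass_high > 0.95

    def test_unlinked_bins_are_independent(self):
        # gap of 200 kb => r capped at 0.5 => prior resets to uniform
        params = LODParams(grid_points=21)
        res = hmm_posteriors(_binned([1, 200_001], [0, 50], [0, 0]), params)["chrI"]
        np.testing.assert_allclose(res["predictive"][0], 1 / 21, atol=1e-12)

    def test_posteriors_follow_data(self):
        params = LODParams(grid_points=21)
        res = hmm_posteriors(_binned([1], [18], [2]), params)["chrI"]
        mean = res["posterior"][0] @ res["grid"]
        assert mean == pytest.approx(18 / 20, abs=0.05)


def _brute_force_lod(high, low, params):
    """Direct evaluation over the full joint hidden-state tensor (≤ 3 bins)."""
    G = params.grid_points
    rows = []
    for chrom in high["chrom"].unique():
        h = high.loc[high["chrom"] == chrom].reset_index(drop=True)
        l = low.loc[low["chrom"] == chrom].reset_index(drop=True)
        informative = ((h["ref"] + h["alt"] + l["ref"] + l["alt"]) > 0).to_numpy()
        h, l = h.loc[informative], l.loc[informative]
        mids = 0.5 * (h["bin_start"] + h["bin_end"]).to_numpy(dtype=float)
        T = len(h)
        E_h = _emissions(h["ref"].to_numpy(), (h["ref"] + h["alt"]).to_numpy(), params)
        E_l = _emissions(l["ref"].to_numpy(), (l["ref"] + l["alt"]).to_numpy(), params)
        trans = [_transition(g, params) for g in np.diff(mids)]
        prior = np.full(G, 1.0 / G)

        def state_marginals(E):
            joint = np.zeros((G,) * T)
            for seq in itertools.product(range(G), repeat=T):
                w = prior[seq[0]] * E[0][seq[0]]
                for t in range(1, T):
                    w *= trans[t - 1][seq[t - 1], seq[t]] * E[t][seq[t]]
                joint[seq] = w
            marginals = []
            for t in range(T):
                axes = tuple(i for i in range(T) if i != t)
                marginals.append(joint.sum(axis=axes) if axes else joint)
            return np.array(marginals), joint.sum()

        gh, Lh = state_marginals(E_h)
        gl, Ll = state_marginals(E_l)
        m = [prior]
        for t in range(1, T):
            m.append(trans[t - 1].T @ m[-1])
        for t in range(T):
            post_h, post_l = gh[t] / Lh, gl[t] / Ll
            s = np.where(
                m[t] > 0, post_h * post_l / np.maximum(m[t], 1e-300), 0.0
            ).sum()
            rows.append(max(-np.log10(max(s, 1e-300)), 0.0))
    return np.array(rows)


class TestLODTrack:
    def test_matches_brute_force_oracle_on_small_instances(self):
        params = LODParams(grid_points=21)
        rng = np.random.default_rng(1)
        for trial in range(12):
            T = int(rng.integers(1, 4))
            starts = np.sort(rng.choice(np.arange(1, 5000, 100), T, replace=False))

            def draw():
                n = rng.poisson(15, T)
                k = rng.binomial(n, rng.uniform(0.2, 0.8))
                return _binned(starts, k, n - k)

            high, low = draw(), draw()
            got = lod_track(high, low, params)["lod"].to_numpy()
            expected = _brute_force_lod(high, low, params)
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_identical_pools_give_near_zero_lod(self):
        rng = np.random.default_rng(2)
        starts = np.arange(1, 100_000, 1000)
        n = rng.poisson(13, len(starts))
        k = rng.binomial(n, 0.5)
        binned = _binned(starts, k, n - k)
        track = lod_track(binned, binned.copy(), LODParams())
        assert track["lod"].abs().max() <= 0.2

    def test_symmetric_in_pool_order(self):
        rng = np.random.default_rng(3)
        starts = np.arange(1, 20_000, 500)
        def draw(p):
            n = rng.poisson(13, len(starts))
            return _binned(starts, rng.binomial(n, p), n - rng.binomial(n, p))
        high, low = draw(0.7), draw(0.3)
        forward = lod_track(high, low, LODParams())
        backward = lod_track(low, high, LODParams())
        np.testing.assert_allclose(forward["lod"], backward["lod"], atol=1e-9)

    def test_doubling_depth_increases_lod_at_divergent_bin(self):
        params = LODParams(grid_points=41)
        starts = np.array([1, 101, 201])
        base_h = _binned(starts, [13, 13, 13], [7, 7, 7])
        base_l = _binned(starts, [7, 7, 7], [13, 13, 13])
        lod1 = lod_track(base_h, base_l, params)["lod"].iloc[1]
        deep_h = _binned(starts, [26, 26, 26], [14, 14, 14])
        deep_l = _binned(starts, [14, 14, 14], [26, 26, 26])
        lod2 = lod_track(deep_h, deep_l, params)["lod"].iloc[1]
        assert lod2 > lod1

    def test_invariant_to_per_chromosome_splitting(self):
        rng = np.random.default_rng(4)
        frames_h, frames_l = [], []
        for chrom in ("chrI", "chrII"):
            starts = np.arange(1, 30_000, 1000)
            n = rng.poisson(13, len(starts))
            k = rng.binomial(n, 0.6)
            frames_h.append(_binned(starts, k, n - k, chrom=chrom))
            n2 = rng.poisson(13, len(starts))
            k2 = rng.binomial(n2, 0.4)
            frames_l.append(_binned(starts, k2, n2 - k2, chrom=chrom))
        joint = lod_track(
            pd.concat(frames_h, ignore_index=True),
            pd.concat(frames_l, ignore_index=True),
            LODParams(),
        )
        separate = pd.concat(
            [lod_track(h, l, LODParams()) for h, l in zip(frames_h, frames_l)],
            ignore_index=True,
        )
        np.testing.assert_allclose(joint["lod"], separate["lod"], atol=1e-9)

    def test_empty_bins_zero_lod_when_included(self):
        high = _binned([1, 101, 201], [10, 0, 10], [0, 0, 0])
        low = _binned([1, 101, 201], [0, 0, 0], [10, 0, 10])
        track = lod_track(high, low, LODParams(grid_points=21), include_empty=True)
        assert len(track) == 3
        assert track.loc[track["bin_start"] == 101, "lod"].iloc[0] == 0.0

    def test_binning_mismatch_rejected(self):
        a = _binned([1, 101], [5, 5], [5, 5])
        b = _binned([1, 201], [5, 5], [5, 5])
        with pytest.raises(ValueError, match="not binned identically"):
            lod_track(a, b, LODParams(grid_points=21))

    def test_all_outputs_finite_under_extreme_counts(self):
        starts = np.arange(1, 10_000, 100)
        n = np.full(len(starts), 200)
        high = _binned(starts, n, n - n)  # all reference
        low = _binned(starts, n - n, n)  # all alternate
        track = lod_track(high, low, LODParams())
        assert np.isfinite(track["lod"]).all()

    def test_local_lod_is_depth_bounded_diagnostic(self):
        # the single-bin contrast cannot exceed the evidence of one bin's reads
        starts = np.arange(1, 50_000, 1000)
        n = np.full(len(starts), 13)
        high = _binned(starts, (0.85 * n).astype(int), n - (0.85 * n).astype(int))
        low = _binned(starts, (0.15 * n).astype(int), n - (0.15 * n).astype(int))
        track = lod_track(high, low, LODParams(), compute_local=True)
        assert track["local_lod"].max() < track["lod"].max()
        assert track["local_lod"].max() < 8.0
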