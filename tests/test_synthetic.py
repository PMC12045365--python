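import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from peristroma import (
    SyntheticConfig,
    assign_marker,
    cell_distances,
    generate_dataset,
    generate_stroma,
    place_cells,
    read_sample,
    write_sample,
)
from peristroma.avatar import expected_null_summary


class TestConfigValidation:
    def test_fraction_sum_invariant(self):
        with pytest.raises(ValueError, match="must be < 1"):
            SyntheticConfig(target_stroma_fraction=0.15, necrosis_fraction=0.95)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pixel_size": 0.0},
            {"stroma_thickness": 0},
            {"positive_fraction": 1.5},
            {"bias_length": 0.0},
            {"target_stroma_fraction": 1.0},
        ],
    )
    def test_invalid_fields(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenerateStroma:
    def test_no_seeds_no_stroma(self):
        geom = generate_stroma(SyntheticConfig(n_stroma_seeds=0, target_stroma_fraction=0.0))
        assert not geom.raster.any()

    def test_no_seeds_nonzero_target_unreachable(self):
        with pytest.raises(ValueError, match="unreachable"):
            generate_stroma(SyntheticConfig(n_stroma_seeds=0, target_stroma_fraction=0.15))

    def test_realized_fraction_within_band(self):
        cfg = SyntheticConfig(width=512, height=512, target_stroma_fraction=0.15, seed=5)
        frac = generate_stroma(cfg).area_fraction
        assert 0.12 <= frac <= 0.18

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(seed=9)
        a = generate_stroma(cfg).raster
        b = generate_stroma(cfg).raster
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_stroma(SyntheticConfig(seed=1)).raster
        b = generate_stroma(SyntheticConfig(seed=2)).raster
        assert (a != b).any()


class TestPlaceCells:
    def test_zero_cells(self):
        geom = generate_stroma(SyntheticConfig(seed=0))
        assert place_cells(geom, None, 0, 1).shape == (0, 2)

    def test_all_stroma_errors(self):
        with pytest.raises(ValueError, match="no admissible"):
            place_cells(np.ones((8, 8), bool), None, 5, 1)

    def test_no_cell_on_stroma_or_exclusion(self):
        geom = generate_stroma(SyntheticConfig(seed=3))
        excl = np.zeros(geom.shape, bool)
        excl[:40] = True
        xy = place_cells(geom, excl, 500, 7)
        ii = xy[:, 1].astype(int)
        jj = xy[:, 0].astype(int)
        assert not geom.raster[ii, jj].any()
        assert not excl[ii, jj].any()

    def test_uniform_density_chi_square(self):
        # density over admissible pixels should be uniform: chi-square on a
        # 4x4 coarse grid with expected counts proportional to admissible area
        cfg = SyntheticConfig(width=256, height=256, target_stroma_fraction=0.3,
                              stroma_thickness=10, seed=11)
        geom = generate_stroma(cfg)
        xy = place_cells(geom, None, 4000, 13)
        admissible = ~geom.raster
        block = 64
        obs, exp = [], []
        for bi in range(4):
            for bj in range(4):
                in_block = (
                    (xy[:, 1] >= bi * block) & (xy[:, 1] < (bi + 1) * block)
                    & (xy[:, 0] >= bj * block) & (xy[:, 0] < (bj + 1) * block)
                )
                obs.append(in_block.sum())
                exp.append(admissible[bi * block:(bi + 1) * block,
                                      bj * block:(bj + 1) * block].sum())
        exp = np.array(exp) / np.sum(exp) * 4000
        res = stats.chisquare(obs, exp)
        assert res.pvalue > 0.01


class TestAssignMarker:
    def test_f_one_all_positive(self):
        d = np.linspace(0, 50, 20)
        assert assign_marker(d, 1.0, 5.0, 0).all()

    def test_f_zero_all_negative(self):
        assert not assign_marker(np.arange(10.0), 0.0, math.inf, 0).any()

    @given(
        n=st.integers(1, 300),
        f=st.floats(0.0, 1.0),
        lam=st.sampled_from([2.0, 50.0, math.inf]),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_positive_count(self, n, f, lam, seed):
        d = np.random.default_rng(0).random(n) * 100
        flags = assign_marker(d, f, lam, seed)
        assert flags.sum() == int(round(f * n))

    def test_uniform_when_unbiased_exhaustive_frequencies(self):
        # lambda = inf, N=4, K=2: each of the 6 labelings equally likely
        d = np.array([1.0, 2.0, 3.0, 4.0])
        subsets = list(combinations(range(4), 2))
        counts = dict.fromkeys(subsets, 0)
        rng = np.random.default_rng(2024)
        n_draws = 60_000
        for _ in range(n_draws):
            flags = assign_marker(d, 0.5, math.inf, rng)
            counts[tuple(np.flatnonzero(flags))] += 1
        p = 1 / 6
        se = math.sqrt(p * (1 - p) / n_draws)
        for subset, c in counts.items():
            assert abs(c / n_draws - p) <= 3 * se, (subset, c / n_draws)

    def test_bias_pulls_positives_toward_stroma(self, default_sample):
        sample, _ = default_sample
        profile = cell_distances(sample)
        d = profile.distances
        wins = 0
        for seed in range(100):
            flags = assign_marker(d, 0.1, 10.0, seed)
            wins += np.median(d[flags]) < np.median(d)
        assert wins >= 99

    def test_bias_monotone_in_length_scale(self):
        # mean (observed - null) median delta non-decreasing toward 0 in lambda
        deltas = []
        for lam in [5.0, 20.0, 80.0, math.inf]:
            per_sample = []
            for seed in range(10):
                sample, _ = generate_dataset(
                    SyntheticConfig(seed=100 + seed, bias_length=lam)
                )
                prof = cell_distances(sample)
                null_median, _ = expected_null_summary(prof)
                per_sample.append(np.median(prof.positive_distances) - null_median)
            deltas.append(np.mean(per_sample))
        rho = stats.spearmanr(np.arange(4), deltas).statistic
        assert rho == pytest.approx(1.0)
        assert deltas[0] < deltas[-1] <= 1.0  # strong bias most negative, null ~ 0


class TestGenerateDataset:
    def test_contract_and_truth(self, default_sample):
        sample, truth = default_sample
        cfg = truth.config
        assert sample.n_cells == cfg.n_cells
        assert truth.n_positive == round(cfg.positive_fraction * cfg.n_cells)
        assert sample.n_positive == truth.n_positive
        assert sample.stroma.raster.shape == (cfg.height, cfg.width)
        ii = sample.cells["y"].astype(int)
        jj = sample.cells["x"].astype(int)
        assert not sample.stroma.raster[ii, jj].any()

    def test_determinism_bitwise(self):
        cfg = SyntheticConfig(seed=77, necrosis_fraction=0.1)
        s1, t1 = generate_dataset(cfg)
        s2, t2 = generate_dataset(cfg)
        assert s1.cells.equals(s2.cells)
        np.testing.assert_array_equal(s1.stroma.raster, s2.stroma.raster)
        np.testing.assert_array_equal(s1.exclusion, s2.exclusion)
        assert t1 == t2

    def test_necrosis_excludes_cells(self):
        sample, truth = generate_dataset(SyntheticConfig(seed=5, necrosis_fraction=0.2))
        assert truth.realized_necrosis_fraction > 0.1
        ii = sample.cells["y"].astype(int)
        jj = sample.cells["x"].astype(int)
        assert not sample.exclusion[ii, jj].any()

    def test_round_trip_through_io(self, tmp_path):
        sample, _ = generate_dataset(SyntheticConfig(seed=8, necrosis_fraction=0.1))
        write_sample(sample, tmp_path / "b")
        back = read_sample(tmp_path / "b")
        assert sample.cells.equals(back.cells)
        np.testing.assert_array_equal(sample.stroma.raster, back.stroma.raster)
        np.testing.assert_array_equal(sample.exclusion, back.exclusion)
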