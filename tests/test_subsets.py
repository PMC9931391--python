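"""Seed-based subset discovery, correlation spectra, time-shift surrogates."""

import numpy as np
import pytest

from scalefree import (
    build_subset,
    correlation_spectrum,
    extract_events,
    fit_power_law_range,
    shotgun_search,
    time_shift_surrogate,
)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(0)
    base = rng.normal(size=300)
    return np.stack([
        base,                      # 0: seed
        base.copy(),               # 1: duplicate of seed
        -base,                     # 2: negation
        rng.normal(size=300),      # 3: independent
        0.5 * base + rng.normal(size=300),  # 4: partially correlated
    ])


class TestCorrelationSpectrum:
    def test_duplicate_ranks_first_negation_last(self, toy_matrix):
        order, r = correlation_spectrum(toy_matrix, 0)
        assert order[0] == 1
        assert r[0] == pytest.approx(1.0)
        assert order[-1] == 2
        assert r[-1] == pytest.approx(-1.0)

    def test_matches_brute_force(self, toy_matrix):
        order, r = correlation_spectrum(toy_matrix, 0)
        full = np.corrcoef(toy_matrix)
        expect = {i: full[0, i] for i in range(1, 5)}
        for idx, val in zip(order, r):
            assert val == pytest.approx(expect[idx], abs=1e-12)
        assert list(r) == sorted(r, reverse=True)

    def test_constant_row_warns_and_gets_zero(self, toy_matrix):
        mat = toy_matrix.copy()
        mat[3] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            order, r = correlation_spectrum(mat, 0)
        assert r[list(order).index(3)] == 0.0

    def test_tie_break_by_index(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=100)
        mat = np.stack([base, base, base, rng.normal(size=100)])
        order, r = correlation_spectrum(mat, 0)
        assert list(order[:2]) == [1, 2]  # equal r = 1 resolves by index


class TestBuildSubset:
    def test_planted_block_recovery(self, planted):
        sub = build_subset(planted.activity, seed_id=3, k=50, dt=1 / 3)
        assert np.all(planted.membership[sub.member_ids] == "groupA")
        assert 3 not in sub.member_ids  # seed excluded by default

    def test_include_seed_flag(self, planted):
        sub = build_subset(planted.activity, seed_id=3, k=50, dt=1 / 3, include_seed=True)
        assert 3 in sub.member_ids
        assert sub.member_ids.size == 50

    def test_k_equals_all_others_gives_population_mean(self, toy_matrix):
        sub = build_subset(toy_matrix, 0, k=4)
        z = (toy_matrix - toy_matrix.mean(1, keepdims=True)) / toy_matrix.std(1, keepdims=True)
        assert np.allclose(sub.subset_series.values, z[1:].mean(axis=0))

    def test_canceling_mode_on_mirrored_population(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=400)
        mat = np.stack([base] * 6 + [-base] * 6)
        sub = build_subset(mat, 0, k=10, mode="canceling")
        assert np.allclose(sub.subset_series.values, 0.0, atol=1e-12)

    def test_canceling_odd_k_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="even"):
            build_subset(toy_matrix, 0, k=3, mode="canceling")

    def test_k_too_large_errors(self, toy_matrix):
        with pytest.raises(ValueError):
            build_subset(toy_matrix, 0, k=5)

    def test_canceling_shrinks_power_law_range(self, planted):
        corr = build_subset(planted.activity, 3, k=50, dt=1 / 3)
        canc = build_subset(planted.activity, 3, k=50, mode="canceling", dt=1 / 3)
        r_corr = fit_power_law_range(
            extract_events(corr.subset_series, "median").sizes, rng_seed=5
        ).range_decades
        r_canc = fit_power_law_range(
            extract_events(canc.subset_series, "median").sizes, rng_seed=5
        ).range_decades
        assert r_canc < r_corr


class TestTimeShiftSurrogate:
    def test_rows_are_cyclic_rotations(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(4, 50))
        out = time_shift_surrogate(mat, rng_seed=7)
        for row, orig in zip(out, mat):
            assert np.array_equal(np.sort(row), np.sort(orig))  # permutation
            assert any(np.allclose(row, np.roll(orig, s)) for s in range(50))

    def test_identical_rows_decorrelate(self):
        rng = np.random.default_rng(5)
        t = 3000
        base = rng.normal(size=t)
        ok = 0
        for trial in range(20):
            out = time_shift_surrogate(np.stack([base, base]), rng_seed=100 + trial)
            r = np.corrcoef(out[0], out[1])[0, 1]
            ok += abs(r) < 3 / np.sqrt(t)
        assert ok >= 17  # identity correlation destroyed to chance level

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(3, 40))
        assert np.array_equal(time_shift_surrogate(mat, 9), time_shift_surrogate(mat, 9))


class TestShotgunSearch:
    def test_single_seed_composition(self, planted):
        # with one seed the search is exactly build_subset -> events -> fit
        rng = np.random.default_rng(21)
        results, controls = shotgun_search(
            planted.activity, behaviors=planted.behaviors,
            n_seeds=1, k=50, rng_seed=rng, dt=1 / 3, n_surrogate=200,
        )
        assert len(results) == 1 and len(controls) == 1
        res = results[0]
        manual = build_subset(planted.activity, res.seed_id, k=50, dt=1 / 3)
        assert np.array_equal(res.member_ids, manual.member_ids)
        assert np.allclose(res.subset_series.values, manual.subset_series.values)
        assert set(res.behavior_corr) == set(planted.behaviors)

    def test_too_many_seeds_error(self, toy_matrix):
        with pytest.raises(ValueError):
            shotgun_search(toy_matrix, n_seeds=6, k=2)

    def test_membership_deterministic(self, planted):
        a, _ = shotgun_search(planted.activity, n_seeds=3, k=50, rng_seed=33,
                              dt=1 / 3, with_surrogate=False, n_surrogate=50)
        b, _ = shotgun_search(planted.activity, n_seeds=3, k=50, rng_seed=33,
                              dt=1 / 3, with_surrogate=False, n_surrogate=50)
        for x, y in zip(a, b):
            assert x.seed_id == y.seed_id
            assert np.array_equal(x.member_ids, y.member_ids)
            assert x.fit.range_decades == y.fit.range_decades

    def test_planted_seeds_beat_noise_seeds(self, planted):
        group_seeds = [3, 50, 120, 150]
        noise_seeds = [300, 500, 900]
        r_group = []
        r_noise = []
        for s in group_seeds + noise_seeds:
            sub = build_subset(planted.activity, s, k=50, dt=1 / 3)
            ev = extract_events(sub.subset_series, "median")
            r = fit_power_law_range(ev.sizes, rng_seed=s).range_decades
            (r_group if s in group_seeds else r_noise).append(r)
        assert np.median(r_group) > 3.0
        assert min(r_group) > 2.5
        assert max(r_noise) < 2.0

    def test_behavior_correlation_tracks_membership(self, planted):
        # group-A subsets correlate with behavior far above noise subsets
        sub_a = build_subset(planted.activity, 3, k=50, dt=1 / 3)
        sub_n = build_subset(planted.activity, 500, k=50, dt=1 / 3)
        beh = planted.behaviors["run_speed"].values

        def corr(sub):
            return np.corrcoef(sub.subset_series.values, beh)[0, 1]

        assert corr(sub_a) > 0.5
        assert abs(corr(sub_n)) < 0.2
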