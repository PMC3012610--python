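"""Signal conditioning: floor, baseline, rank-invariant normalization, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

import cypwaves as cw
from cypwaves.preprocess import (
    NormalizationError,
    ProbeMatrix,
    QCReport,
    average_duplicates,
    fit_normalization,
    fit_normalization_curve,
    floor_signal,
    normalize_arrays,
    preprocess_pipeline,
    qc_filter_probes,
    rank_invariant_probes,
    select_baseline_array,
)
from cypwaves.simulate import ArrayDesign, generate_timecourse


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id", "spot_index", "array_id", "timepoint_hpf",
            "replicate", "signal", "saturated", "above_background",
        ],
    )


class TestFloor:
    @pytest.mark.parametrize("signal,expected", [(3.0, 5.0), (5.0, 5.0), (4096.0, 4096.0)])
    def test_floor_values(self, signal, expected):
        table = _table([["p", 0, "a", 3.0, "A", signal, False, True]])
        assert floor_signal(table)["signal"].iloc[0] == expected

    def test_nonpositive_floor_rejected(self):
        with pytest.raises(ValueError):
            floor_signal(_table([]), floor=0)


class TestBaselineSelection:
    def _three_arrays(self, medians):
        rows = []
        for i, med in enumerate(medians):
            for j, v in enumerate([med - 1, med, med + 1]):
                rows.append([f"p{j}", 0, f"arr{i}", 3.0, "A", v, False, True])
        return _table(rows)

    def test_median_of_medians(self):
        table = self._three_arrays([10, 20, 30])
        assert select_baseline_array(table) == "arr1"

    def test_all_identical_picks_first(self):
        table = self._three_arrays([10, 10, 10])
        assert select_baseline_array(table) == "arr0"

    def test_empty_table_errors(self):
        with pytest.raises(NormalizationError):
            select_baseline_array(_table([]))

    def test_matches_brute_force_on_24_synthetic_arrays(self):
        table, _ = generate_timecourse(design=ArrayDesign(n_probes=60), seed=12)
        table = floor_signal(table)
        # independent oracle: sort per-array medians, lower median, lowest index
        order = list(dict.fromkeys(table["array_id"]))
        med = {a: float(np.median(table.loc[table.array_id == a, "signal"])) for a in order}
        target = sorted(med.values())[(len(med) - 1) // 2]
        expected = next(a for a in order if med[a] == target)
        assert select_baseline_array(table) == expected


def oracle_rank_invariant(target, baseline, threshold_fraction, max_iter=30):
    """Naive loop-based reimplementation of the iterative selection."""
    current = list(target.index)
    for _ in range(max_iter):
        t_rank = rankdata([target[p] for p in current])
        b_rank = rankdata([baseline[p] for p in current])
        kept = [
            p for p, tr, br in zip(current, t_rank, b_rank)
            if abs(tr - br) <= threshold_fraction * len(current)
        ]
        if len(kept) == len(current):
            break
        current = kept
        if not current:
            raise NormalizationError("empty")
    return frozenset(current)


class TestRankInvariant:
    def test_identical_arrays_keep_all_probes(self, rng):
        v = pd.Series(rng.normal(8, 2, 40), index=[f"p{i}" for i in range(40)])
        assert rank_invariant_probes(v, v.copy()) == frozenset(v.index)

    def test_monotone_transform_keeps_all_probes(self, rng):
        v = pd.Series(rng.normal(8, 2, 40), index=[f"p{i}" for i in range(40)])
        assert rank_invariant_probes(v, 0.9 * v + 0.5) == frozenset(v.index)

    def test_planted_rank_swaps_match_exhaustive_oracle(self, rng):
        n = 50
        base = pd.Series(np.sort(rng.normal(8, 2, n)), index=[f"p{i}" for i in range(n)])
        target = base.copy()
        # swap five probes far across the rank range
        for lo, hi in [(2, 47), (5, 44), (10, 40), (15, 35), (20, 30)]:
            target.iloc[[lo, hi]] = target.iloc[[hi, lo]].to_numpy()
        got = rank_invariant_probes(target, base, threshold_fraction=0.05)
        expected = oracle_rank_invariant(target, base, threshold_fraction=0.05)
        assert got == expected
        assert len(got) > 0

    def test_matches_oracle_on_noisy_instances(self, rng):
        for trial in range(5):
            n = int(rng.integers(20, 100))
            idx = [f"p{i}" for i in range(n)]
            base = pd.Series(rng.normal(8, 2, n), index=idx)
            target = pd.Series(base + rng.normal(0, 0.3, n), index=idx)
            try:
                got = rank_invariant_probes(target, base, threshold_fraction=0.1)
            except NormalizationError:
                with pytest.raises(NormalizationError):
                    oracle_rank_invariant(target, base, threshold_fraction=0.1)
                continue
            assert got == oracle_rank_invariant(target, base, threshold_fraction=0.1)

    def test_empty_result_advises_larger_threshold(self):
        idx = [f"p{i}" for i in range(10)]
        up = pd.Series(np.arange(10.0), index=idx)
        down = pd.Series(np.arange(10.0)[::-1].copy(), index=idx)
        with pytest.raises(NormalizationError, match="threshold"):
            rank_invariant_probes(up, down, threshold_fraction=0.01)


class TestCurve:
    def test_identity_pairs_give_identity_curve(self):
        x = np.linspace(4, 14, 200)
        curve = fit_normalization_curve(x, x, window=11)
        assert np.allclose(curve(x), x, atol=1e-9)

    def test_constant_offset(self):
        x = np.linspace(4, 14, 200)
        curve = fit_normalization_curve(x, x + 1.0, window=11)
        assert np.allclose(curve(x), x + 1.0, atol=1e-9)

    def test_planted_affine_warp_recovered_within_tolerance(self, rng):
        x = rng.uniform(4, 14, 500)
        y = 0.9 * x + 0.5 + rng.normal(0, 0.05, 500)
        curve = fit_normalization_curve(x, y)
        lo, hi = np.quantile(x, [0.05, 0.95])
        grid = np.linspace(lo, hi, 200)
        assert np.max(np.abs(curve(grid) - (0.9 * grid + 0.5))) < 0.1

    def test_too_few_pairs_errors(self):
        with pytest.raises(NormalizationError):
            fit_normalization_curve(np.arange(5.0), np.arange(5.0), window=11)

    def test_curve_is_monotone(self, rng):
        x = rng.uniform(4, 14, 300)
        y = x + rng.normal(0, 0.5, 300)
        curve = fit_normalization_curve(x, y)
        grid = np.linspace(2, 16, 500)
        assert (np.diff(curve(grid)) >= -1e-12).all()


class TestNormalize:
    def test_baseline_is_fixed_point(self):
        table, _ = generate_timecourse(design=ArrayDesign(n_probes=200), seed=3)
        floored = floor_signal(table)
        model = fit_normalization(floored)
        norm = normalize_arrays(floored, model)
        base = norm[norm["array_id"] == model.baseline_array_id]
        assert np.allclose(base["log2_norm"], np.log2(base["signal"]), atol=1e-9)

    def test_missing_array_errors(self):
        table, _ = generate_timecourse(design=ArrayDesign(n_probes=50), seed=3)
        floored = floor_signal(table)
        model = fit_normalization(floored)
        del model.curves[next(iter(model.curves))]
        with pytest.raises(NormalizationError, match="missing"):
            normalize_arrays(floored, model)

    def test_monotone_order_preserved_per_array(self):
        table, _ = generate_timecourse(design=ArrayDesign(n_probes=150), seed=4)
        floored = floor_signal(table)
        model = fit_normalization(floored)
        norm = normalize_arrays(floored, model)
        for _, sub in norm.groupby("array_id"):
            order = np.argsort(sub["signal"].to_numpy(), kind="stable")
            assert (np.diff(sub["log2_norm"].to_numpy()[order]) >= -1e-12).all()

    def test_planted_warp_recovery_flat_probes(self):
        """With warps as the only cross-array difference, normalization
        brings flat probes within 0.1 log2 of the baseline."""
        table, _ = generate_timecourse(
            design=ArrayDesign(n_probes=1000),
            archetype_mix={"flat": 1.0},
            noise=(0.0, 0.05),
            seed=3,
        )
        matrix, _, model = preprocess_pipeline(table)
        lv = np.log2(matrix.values)
        delta = lv.sub(lv[model.baseline_array_id], axis=0).drop(
            columns=model.baseline_array_id
        )
        assert float(delta.abs().stack().median()) < 0.1

    def test_between_array_cv_of_flat_probes_decreases(self):
        table, _ = generate_timecourse(
            design=ArrayDesign(n_probes=600),
            archetype_mix={"flat": 1.0},
            noise=(0.0, 0.05),
            seed=8,
        )
        floored = floor_signal(table)
        raw = average_duplicates(floored).values
        matrix, _, _ = preprocess_pipeline(table)
        cv_raw = raw.std(axis=1) / raw.mean(axis=1)
        cv_norm = matrix.values.std(axis=1) / matrix.values.mean(axis=1)
        frac = float((cv_norm < cv_raw.loc[cv_norm.index]).mean())
        assert frac >= 0.95


class TestAverageDuplicates:
    def test_mean_of_spots(self):
        table = _table(
            [
                ["p", 0, "a", 3.0, "A", 4.0, False, True],
                ["p", 1, "a", 3.0, "A", 6.0, False, True],
            ]
        )
        assert average_duplicates(table).values.loc["p", "a"] == 5.0

    def test_single_spot_unchanged(self):
        table = _table([["p", 0, "a", 3.0, "A", 7.0, False, True]])
        assert average_duplicates(table).values.loc["p", "a"] == 7.0

    def test_any_spot_saturation_propagates(self):
        table = _table(
            [
                ["p", 0, "a", 3.0, "A", 65535.0, True, True],
                ["p", 1, "a", 3.0, "A", 100.0, False, True],
            ]
        )
        assert bool(average_duplicates(table).saturated.loc["p", "a"])


class TestQcFilter:
    def _matrix(self, n, sat_idx=(), bg_idx=(), n_arrays=4):
        probes = [f"p{i}" for i in range(n)]
        arrays = [f"a{j}" for j in range(n_arrays)]
        values = pd.DataFrame(100.0, index=probes, columns=arrays)
        sat = pd.DataFrame(False, index=probes, columns=arrays)
        abg = pd.DataFrame(True, index=probes, columns=arrays)
        for i in sat_idx:
            sat.iloc[i, 0] = True
        for i in bg_idx:
            abg.iloc[i, :] = False
        return ProbeMatrix(values, sat, abg)

    def test_worked_example_counts(self):
        pm = self._matrix(100, sat_idx=range(3), bg_idx=range(10, 15))
        filtered, report = qc_filter_probes(pm)
        assert report.to_dict() == {
            "n_input_probes": 100,
            "n_removed_saturated": 3,
            "n_removed_background": 5,
            "n_retained": 92,
        }
        assert len(filtered.probes) == 92

    def test_single_above_background_instance_retains_probe(self):
        pm = self._matrix(2, n_arrays=48)
        pm.above_background.iloc[0, :] = False
        pm.above_background.iloc[0, 7] = True
        _, report = qc_filter_probes(pm)
        assert report.n_retained == 2

    def test_no_adverse_flags_keeps_all(self):
        _, report = qc_filter_probes(self._matrix(20))
        assert report.n_retained == 20

    def test_saturation_takes_precedence_over_background(self):
        pm = self._matrix(1)
        pm.saturated.iloc[0, 0] = True
        pm.above_background.iloc[0, :] = False
        _, report = qc_filter_probes(pm)
        assert report.n_removed_saturated == 1
        assert report.n_removed_background == 0

    @settings(deadline=None, max_examples=25)
    @given(
        n=st.integers(1, 40),
        sat=st.sets(st.integers(0, 39)),
        bg=st.sets(st.integers(0, 39)),
    )
    def test_conservation_identity(self, n, sat, bg):
        pm = self._matrix(
            n, sat_idx=[i for i in sat if i < n], bg_idx=[i for i in bg if i < n]
        )
        filtered, report = qc_filter_probes(pm)
        assert (
            report.n_retained
            == report.n_input_probes
            - report.n_removed_saturated
            - report.n_removed_background
        )
        assert len(filtered.probes) == report.n_retained
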