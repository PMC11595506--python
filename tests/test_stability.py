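"""Relative-error stability analysis and condition comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fishrad as fr
from fishrad.errors import PairingError
from fishrad.stability import (
    ErrorMatrix,
    compare_conditions,
    error_matrix,
    relative_error,
    summarize,
)
from fishrad.study import FeatureTable


def _table(values: np.ndarray, feats=None, regions=("a", "b", "c")):
    """values: (n_masks, n_features)."""
    n_masks, n_feats = values.shape
    feats = feats or [f"original_shape_F{i}" for i in range(n_feats)]
    rows = []
    for j in range(n_masks):
        rows.append({"specimen": f"s{j}", "region": regions[j % len(regions)],
                     "label": "low", **dict(zip(feats, values[j]))})
    return FeatureTable(pd.DataFrame(rows))


class TestRelativeError:
    def test_ten_percent(self):
        assert relative_error(110.0, 100.0) == pytest.approx(10.0)

    def test_magnitude_not_sign(self):
        assert relative_error(90.0, 100.0) == pytest.approx(10.0)

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_identity_is_zero(self, x):
        assert relative_error(x, x) == 0.0

    def test_zero_reference_rules(self):
        assert relative_error(0.0, 0.0) == 0.0
        assert np.isnan(relative_error(5.0, 0.0))


class TestErrorMatrix:
    def test_table_against_itself_is_zero(self, rng):
        t = _table(rng.random((6, 10)) * 100)
        em = error_matrix(t, t)
        assert em.delta.shape == (10, 6)
        assert np.all(em.delta.to_numpy() == 0.0)

    def test_dimensions_are_features_by_masks(self, rng):
        cond = _table(rng.random((6, 107)) + 1)
        ref = _table(rng.random((6, 107)) + 1)
        em = error_matrix(cond, ref)
        assert em.delta.shape == (107, 6)

    def test_rows_matched_by_key_not_order(self, rng):
        vals = rng.random((4, 5)) + 1
        ref = _table(vals)
        cond = _table(vals)
        cond.data = cond.data.iloc[::-1].reset_index(drop=True)  # shuffle rows
        em = error_matrix(cond, ref)
        assert np.all(em.delta.to_numpy() == 0.0)

    def test_missing_specimen_is_pairing_error(self, rng):
        ref = _table(rng.random((4, 5)) + 1)
        cond = _table(rng.random((3, 5)) + 1)
        with pytest.raises(PairingError):
            error_matrix(cond, ref)

    def test_zero_reference_exclusion_bookkeeping(self):
        ref = _table(np.array([[0.0, 2.0]]))
        cond = _table(np.array([[5.0, 2.0]]))
        em = error_matrix(cond, ref)
        assert em.excluded.to_numpy().tolist() == [[True], [False]]


class TestSummarize:
    def test_hand_arithmetic(self):
        delta = pd.DataFrame([[10.0, 20.0], [30.0, 50.0]],
                             index=["f1", "f2"], columns=["m1", "m2"])
        rep = summarize(ErrorMatrix(delta))
        assert rep.delta_i.tolist() == [15.0, 40.0]
        assert rep.M == pytest.approx(27.5)
        assert rep.flagged == ["f1", "f2"]

    def test_all_zero_matrix(self):
        delta = pd.DataFrame(np.zeros((5, 3)))
        rep = summarize(ErrorMatrix(delta))
        assert rep.M == 0.0
        assert rep.flagged == []

    def test_fully_excluded_feature_dropped_from_M(self):
        delta = pd.DataFrame([[np.nan, np.nan], [10.0, 20.0]],
                             index=["dead", "ok"], columns=["m1", "m2"])
        rep = summarize(ErrorMatrix(delta))
        assert rep.excluded_features == ["dead"]
        assert rep.M == pytest.approx(15.0)

    def test_flag_threshold_is_strict_greater(self):
        delta = pd.DataFrame([[2.0], [2.0001]], index=["at", "above"], columns=["m"])
        rep = summarize(ErrorMatrix(delta), flag_threshold=2.0)
        assert rep.flagged == ["above"]

    def test_M_invariant_under_reordering(self, rng):
        delta = pd.DataFrame(rng.random((8, 4)) * 10)
        rep = summarize(ErrorMatrix(delta))
        shuffled = delta.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        assert summarize(ErrorMatrix(shuffled)).M == pytest.approx(rep.M)


class TestCompareConditions:
    def _report(self, deltas, name="r"):
        delta = pd.DataFrame({f"m": deltas})
        return summarize(ErrorMatrix(delta), condition=name)

    def test_identical_reports_degenerate(self, rng):
        d = rng.random(20) * 10
        a = self._report(d, "a")
        b = self._report(d, "b")
        comp = compare_conditions(a, b)
        assert comp.wins_a == 0 and comp.wins_b == 0 and comp.ties == 20
        assert comp.p_value == 1.0

    def test_uniform_shift_wins_everything_p_zero(self, rng):
        d = rng.random(107) * 10
        a = self._report(d, "a")
        b = self._report(d + 1.0, "b")
        comp = compare_conditions(a, b)
        assert comp.wins_a == 107 and comp.wins_b == 0
        assert comp.p_value == 0.0  # infinite paired t on constant differences

    def test_win_counts_are_antisymmetric(self, rng):
        a = self._report(rng.random(30) * 5, "a")
        b = self._report(rng.random(30) * 5, "b")
        ab = compare_conditions(a, b)
        ba = compare_conditions(b, a)
        assert ab.wins_a == ba.wins_b
        assert ab.wins_a + ab.wins_b == 30 - ab.ties

    def test_paired_t_matches_sign_flip_permutation(self, rng):
        d1 = rng.normal(5.0, 2.0, size=30)
        d2 = d1 + rng.normal(0.8, 1.0, size=30)
        a = self._report(d1, "a")
        b = self._report(d2, "b")
        comp = compare_conditions(a, b)
        diffs = d1 - d2
        # sign-flip permutation null for the paired t statistic
        perm_rng = np.random.default_rng(0)
        t_obs = abs(diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs))))
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            flip = perm_rng.choice([-1.0, 1.0], size=len(diffs)) * diffs
            t = abs(flip.mean() / (flip.std(ddof=1) / np.sqrt(len(flip))))
            count += t >= t_obs
        p_perm = count / n_perm
        assert comp.p_value == pytest.approx(p_perm, abs=0.02)

    def test_inventory_mismatch_raises(self, rng):
        a = self._report(rng.random(5), "a")
        delta = pd.DataFrame({"m": rng.random(5)},
                             index=[f"other{i}" for i in range(5)])
        b = summarize(ErrorMatrix(delta), condition="b")
        with pytest.raises(PairingError):
            compare_conditions(a, b)


@pytest.fixture(scope="module")
def small_study(tmp_path_factory):
    root = tmp_path_factory.mktemp("stab")
    return fr.stability_cohort(n=3, out_dir=root, seed=21)


class TestStabilityExperiment:
    def test_identity_condition_gives_zero_M(self, small_study, tmp_path):
        reports, _ = fr.stability_experiment(
            small_study, [fr.PreprocessSpec(mode="none", bin_count=64)]
        )
        assert reports[0].M == 0.0
        assert reports[0].flagged == []

    def test_condition_grid_produces_reports_and_comparisons(self, small_study, tmp_path):
        conditions = [
            fr.PreprocessSpec(mode="resample", bin_count=64),
            fr.PreprocessSpec(mode="resize", bin_count=64),
            fr.PreprocessSpec(mode="resample", bin_count=1),
        ]
        reports, comps = fr.stability_experiment(
            small_study, conditions, out_dir=tmp_path / "out"
        )
        assert len(reports) == 3
        assert len(comps) == 3  # all pairs
        for rep in reports:
            assert rep.M >= 0.0
            assert np.isfinite(rep.M)
        assert (tmp_path / "out" / "per_feature_delta.csv").exists()
        assert (tmp_path / "out" / "comparisons.csv").exists()

    def test_replicate_cohort_is_distinct_but_same_shape(self, small_study, tmp_path):
        replicate = fr.stability_cohort(n=3, out_dir=tmp_path / "rep", seed=22)
        p1 = [r.metadata["phantom_spec"]["curvature_deg"] for r in small_study.specimens]
        p2 = [r.metadata["phantom_spec"]["curvature_deg"] for r in replicate.specimens]
        assert p1 != p2
        assert len(p1) == len(p2) == 3
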