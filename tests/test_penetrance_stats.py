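import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from seroprofiler.array_io import IntensityMatrix, SampleManifest
from seroprofiler.penetrance_stats import (
    PenetranceConfig,
    classify_markers,
    compute_penetrance_records,
    group_t_test,
    individual_fold_changes,
    overall_fold_change,
    penetrance_fold_change,
    penetrance_frequencies,
    volcano_classes,
)


def _matrix(values, manifest):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return IntensityMatrix(
        proteins=[f"P{i}" for i in range(values.shape[0])],
        samples=manifest.sample_ids,
        values=values,
        stage="normalized",
    )


def _masks(manifest):
    case = np.array([manifest.groups[s] == "case" for s in manifest.sample_ids])
    return case, ~case


class TestIndividualFoldChanges:
    def test_toy8_hand_values(self, toy_manifest):
        m = _matrix([4, 4, 1, 1, 1, 1, 1, 1], toy_manifest)
        h, m_p = individual_fold_changes(m, toy_manifest)
        assert m_p[0] == pytest.approx(1.75)
        np.testing.assert_allclose(h[0, :2], 16 / 7)
        np.testing.assert_allclose(h[0, 2:], 4 / 7)

    def test_all_equal_gives_unit_h(self, toy_manifest):
        h, _ = individual_fold_changes(
            _matrix(np.full(8, 3.0), toy_manifest), toy_manifest
        )
        np.testing.assert_allclose(h, 1.0)

    def test_scale_invariance(self, toy_manifest):
        base = np.array([4.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        h1, _ = individual_fold_changes(_matrix(base, toy_manifest), toy_manifest)
        h2, _ = individual_fold_changes(_matrix(2 * base, toy_manifest), toy_manifest)
        np.testing.assert_allclose(h1, h2)

    @given(
        values=hnp.arrays(float, (3, 8), elements=st.floats(0.5, 1e5)),
    )
    @settings(deadline=None, max_examples=50,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_h_row_means_are_one(self, values, toy_manifest):
        h, _ = individual_fold_changes(_matrix(values, toy_manifest), toy_manifest)
        np.testing.assert_allclose(h.mean(axis=1), 1.0, atol=1e-9)


class TestPenetranceFrequencies:
    def test_toy8_frequencies(self, toy_manifest):
        m = _matrix([4, 4, 1, 1, 1, 1, 1, 1], toy_manifest)
        h, _ = individual_fold_changes(m, toy_manifest)
        case, ctrl = _masks(toy_manifest)
        fc, fctl = penetrance_frequencies(h, case, ctrl, 2.0)
        assert fc[0] == 50.0 and fctl[0] == 0.0

    def test_inclusive_boundary_toy8c(self, toy_manifest):
        # h_case = [2, 2, 1, 1]: the h == theta samples count as penetrant
        m = _matrix([4, 4, 2, 2, 1, 1, 1, 1], toy_manifest)
        h, _ = individual_fold_changes(m, toy_manifest)
        case, ctrl = _masks(toy_manifest)
        fc, _ = penetrance_frequencies(h, case, ctrl, 2.0)
        assert fc[0] == 50.0

    def test_nobody_penetrant(self, toy_manifest):
        m = _matrix(np.full(8, 5.0), toy_manifest)
        h, _ = individual_fold_changes(m, toy_manifest)
        case, ctrl = _masks(toy_manifest)
        fc, fctl = penetrance_frequencies(h, case, ctrl, 2.0)
        assert fc[0] == 0.0 and fctl[0] == 0.0


class TestPenetranceFoldChange:
    @pytest.mark.parametrize(
        "values, pfc_case, diff",
        [
            ([4, 4, 1, 1, 1, 1, 1, 1], 4.0, 3.75),  # control H-bar via fallback
            ([4, 4, 2, 2, 1, 1, 1, 1], 4.0, 3.75),
        ],
    )
    def test_toy_hand_values(self, toy_manifest, values, pfc_case, diff):
        m = _matrix(values, toy_manifest)
        h, _ = individual_fold_changes(m, toy_manifest)
        case, ctrl = _masks(toy_manifest)
        pc, pctl, d, _, _ = penetrance_fold_change(h, case, ctrl, 2.0)
        assert pc[0] == pytest.approx(pfc_case)
        assert pctl[0] == pytest.approx(1 / pfc_case)
        assert d[0] == pytest.approx(diff)

    def test_symmetric_data_gives_unit_pfc(self, toy_manifest):
        m = _matrix([2, 3, 4, 5, 2, 3, 4, 5], toy_manifest)
        h, _ = individual_fold_changes(m, toy_manifest)
        case, ctrl = _masks(toy_manifest)
        pc, pctl, d, _, _ = penetrance_fold_change(h, case, ctrl, 2.0)
        assert pc[0] == pytest.approx(1.0)
        assert d[0] == pytest.approx(0.0)

    @given(values=hnp.arrays(float, (4, 8), elements=st.floats(0.5, 1e4)))
    @settings(deadline=None, max_examples=50,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_pfc_product_is_one_and_swap_antisymmetry(self, values, toy_manifest):
        m = _matrix(values, toy_manifest)
        h, _ = individual_fold_changes(m, toy_manifest)
        case, ctrl = _masks(toy_manifest)
        pc, pctl, d, _, _ = penetrance_fold_change(h, case, ctrl, 2.0)
        np.testing.assert_allclose(pc * pctl, 1.0, rtol=1e-12)
        # swapping the group labels negates the difference
        pc2, pctl2, d2, _, _ = penetrance_fold_change(h, ctrl, case, 2.0)
        np.testing.assert_allclose(d2, -d, rtol=1e-9, atol=1e-12)


class TestGroupTTest:
    @pytest.mark.parametrize(
        "values, t_expected, p_expected",
        [
            ([4, 4, 1, 1, 1, 1, 1, 1], 1.7321, 0.134),
            ([4, 4, 2, 2, 1, 1, 1, 1], 3.4641, 0.0134),
        ],
    )
    def test_toy_hand_values(self, toy_manifest, values, t_expected, p_expected):
        case, ctrl = _masks(toy_manifest)
        t, p, deg = group_t_test(
            np.atleast_2d(np.array(values, float)), case, ctrl
        )
        assert t[0] == pytest.approx(t_expected, abs=1e-4)
        assert p[0] == pytest.approx(p_expected, abs=5e-4)
        assert not deg[0]

    def test_identical_groups_t_zero_p_one(self, toy_manifest):
        case, ctrl = _masks(toy_manifest)
        t, p, deg = group_t_test(
            np.array([[1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]]), case, ctrl
        )
        assert t[0] == 0.0 and p[0] == 1.0 and not deg[0]

    def test_zero_variance_unequal_means_degenerate(self, toy_manifest):
        case, ctrl = _masks(toy_manifest)
        t, p, deg = group_t_test(
            np.array([[2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0]]), case, ctrl
        )
        assert p[0] == 0.0 and deg[0] and np.isinf(t[0])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            group_t_test(
                np.array([[1.0, 2.0, 3.0]]),
                np.array([True, False, False]),
                np.array([False, True, True]),
            )


class TestOverallFoldChange:
    def test_toy_values(self, toy_manifest):
        case, ctrl = _masks(toy_manifest)
        fc, log2fc = overall_fold_change(
            np.array([[4, 4, 1, 1, 1, 1, 1, 1], [4, 4, 2, 2, 1, 1, 1, 1]], float),
            case,
            ctrl,
        )
        assert fc[0] == pytest.approx(2.5)
        assert log2fc[0] == pytest.approx(1.3219, abs=1e-4)
        assert fc[1] == pytest.approx(3.0)

    def test_identical_groups_unit_fc(self, toy_manifest):
        case, ctrl = _masks(toy_manifest)
        fc, log2fc = overall_fold_change(np.full((1, 8), 2.0), case, ctrl)
        assert fc[0] == 1.0 and log2fc[0] == 0.0


class TestClassification:
    def test_toy8c_increased(self, toy_matrix, toy_manifest):
        records = compute_penetrance_records(toy_matrix, toy_manifest)
        by_id = {r.protein_id: r for r in records}
        assert by_id["toy8c"].classification == "increased"

    def test_toy8_fails_on_p_value_alone(self, toy_matrix, toy_manifest):
        records = compute_penetrance_records(toy_matrix, toy_manifest)
        by_id = {r.protein_id: r for r in records}
        r = by_id["toy8"]
        assert r.classification == "not_significant"
        assert r.pfc_difference >= 2  # only criterion (i) failed
        assert r.p_value >= 0.05

    def test_all_equal_not_significant(self, toy_manifest):
        m = _matrix(np.full(8, 2.0), toy_manifest)
        records = compute_penetrance_records(m, toy_manifest)
        r = records[0]
        assert r.classification == "not_significant"
        assert r.p_value == 1.0 and r.pfc_difference == pytest.approx(0.0)

    def test_decreased_mirror(self, toy_manifest):
        # enriched in controls: mirror image of toy8c
        m = _matrix([1, 1, 1, 1, 4, 4, 2, 2], toy_manifest)
        records = compute_penetrance_records(m, toy_manifest)
        r = records[0]
        assert r.classification == "decreased"
        assert r.pfc_difference == pytest.approx(-3.75)

    def test_increased_definition_invariant(self, toy_manifest):
        rng = np.random.default_rng(42)
        m = _matrix(rng.lognormal(0, 1, size=(50, 8)), toy_manifest)
        cfg = PenetranceConfig()
        for r in compute_penetrance_records(m, toy_manifest, cfg):
            if r.classification == "increased":
                assert r.p_value < cfg.alpha and r.pfc_difference >= 2

    def test_min_frequency_screen_blocks_call(self, toy_manifest):
        records = compute_penetrance_records(
            _matrix([4, 4, 2, 2, 1, 1, 1, 1], toy_manifest),
            toy_manifest,
            PenetranceConfig(min_freq_pct=75.0),
        )
        assert records[0].classification == "not_significant"

    def test_config_validation(self):
        with pytest.raises(ValueError, match="penetrance_threshold"):
            PenetranceConfig(penetrance_threshold=1.0)
        with pytest.raises(ValueError, match="alpha"):
            PenetranceConfig(alpha=1.5)


class TestVolcanoClasses:
    def test_labels_and_inclusive_boundary(self, toy_matrix, toy_manifest):
        records = compute_penetrance_records(toy_matrix, toy_manifest)
        counts, labels = volcano_classes(records)
        assert labels["toy8"] == "up"  # log2 FC 1.3219
        assert counts["up"] == 2

    @pytest.mark.parametrize(
        "log2fc, expected",
        [(0.0, "neither"), (0.58, "up"), (-0.58, "down"), (0.5799, "neither")],
    )
    def test_boundary_rules(self, log2fc, expected, toy_matrix, toy_manifest):
        records = compute_penetrance_records(toy_matrix, toy_manifest)[:1]
        records[0].log2_overall_fc = log2fc
        _, labels = volcano_classes(records)
        assert labels[records[0].protein_id] == expected
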