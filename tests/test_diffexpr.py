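import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexnet.diffexpr import (
    DEResult,
    PooledTTestDE,
    bh_adjust,
    classify_status,
    de_counts,
    differential_expression,
    read_de_table,
    t_test_two_group,
    volcano_table,
    write_de_table,
)
from coexnet.errors import StateError, ValidationError
from coexnet.io_formats import ExpressionMatrix
from tests.conftest import make_annotation


class TestTTest:
    def test_pinned_reference_case(self):
        # frozen from an independent pooled-t oracle (scipy.stats.ttest_ind)
        t, p, flag = t_test_two_group((2.1, 2.5, 2.3, 2.7, 2.4), (1.0, 1.2, 1.1))
        assert t == pytest.approx(9.296260245144522, abs=1e-10)
        assert p == pytest.approx(8.76731767708685e-05, abs=1e-10)
        assert not flag

    def test_zero_variance_equal_means(self):
        t, p, flag = t_test_two_group((3.0, 3.0, 3.0), (3.0, 3.0))
        assert (t, p, flag) == (0.0, 1.0, True)

    def test_zero_variance_unequal_means(self):
        t, p, flag = t_test_two_group((3.0, 3.0), (1.0, 1.0))
        assert t == np.inf and p == 0.0 and flag
        t, _, _ = t_test_two_group((1.0, 1.0), (3.0, 3.0))
        assert t == -np.inf

    def test_identical_multisets_nonzero_variance(self):
        t, p, flag = t_test_two_group((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))
        assert (t, p, flag) == (0.0, 1.0, False)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            t_test_two_group((1.0,), (1.0, 2.0))

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(2, 9))
            y = rng.normal(size=rng.integers(2, 9))
            t, p, _ = t_test_two_group(x, y)
            t_ref, p_ref = stats.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_welch_matches_scipy(self, rng):
        x, y = rng.normal(size=6), rng.normal(scale=3.0, size=4)
        t, p, _ = t_test_two_group(x, y, equal_var=False)
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=False)
        assert (t, p) == (pytest.approx(t_ref, abs=1e-10), pytest.approx(p_ref, abs=1e-10))


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_constant_vector_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=50)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


def _two_group_matrix(case, control, probe_ids):
    """case/control: arrays (probes x samples)."""
    case = np.asarray(case, float)
    control = np.asarray(control, float)
    data = np.hstack([case, control])
    cols = [f"T{i}" for i in range(case.shape[1])] + [
        f"H{i}" for i in range(control.shape[1])
    ]
    groups = {c: ("tibetan" if c.startswith("T") else "han") for c in cols}
    return ExpressionMatrix(
        pd.DataFrame(data, index=probe_ids, columns=cols), groups, "log2"
    )


class TestDifferentialExpression:
    ann = staticmethod(
        lambda: make_annotation(
            {
                "P1": ("GA", "mRNA", "chr1", 0, 10, "+"),
                "P2": ("LB", "lncRNA", "chr1", 100, 200, "+"),
            }
        )
    )

    def test_status_rule_boundaries(self):
        # strict inequalities on both axes
        fc = np.array([1.5, 1.0, -2.0, -1.2, 0.2])
        p = np.array([0.01, 0.001, 0.20, 0.04, 0.001])
        assert list(classify_status(fc, p)) == ["up", "ns", "ns", "down", "ns"]

    def test_results_carry_biotype_and_direction(self):
        case = np.array([[5.0, 5.1, 4.9], [1.0, 1.1, 0.9]])
        control = np.array([[1.0, 1.2, 1.1], [5.0, 5.2, 5.1]])
        m = _two_group_matrix(case, control, ["P1", "P2"])
        res = differential_expression(m, self.ann(), "tibetan", "han")
        by_probe = {r.probe_id: r for r in res}
        assert by_probe["P1"].status == "up" and by_probe["P1"].biotype == "mRNA"
        assert by_probe["P2"].status == "down" and by_probe["P2"].biotype == "lncRNA"
        assert by_probe["P1"].log2fc == pytest.approx(5.0 - 1.1)
        assert de_counts(res) == {
            "up_lncRNA": 0, "down_lncRNA": 1, "up_mRNA": 1, "down_mRNA": 0,
        }

    def test_label_swap_antisymmetry(self, rng):
        case = rng.normal(size=(20, 4))
        control = rng.normal(size=(20, 3))
        m = _two_group_matrix(case, control, [f"P{i}" for i in range(20)])
        ann = make_annotation(
            {f"P{i}": (f"G{i}", "mRNA", "chr1", i * 100, i * 100 + 10, "+") for i in range(20)}
        )
        fwd = differential_expression(m, ann, "tibetan", "han")
        rev = differential_expression(m, ann, "han", "tibetan")
        for a, b in zip(fwd, rev):
            assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-12)
            assert a.t_stat == pytest.approx(-b.t_stat, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_missing_label_rejected(self, tiny_matrix):
        from coexnet.preprocess import log2_transform

        m = log2_transform(tiny_matrix)
        ann = make_annotation(
            {p: (p, "mRNA", None, None, None, None) for p in m.probe_ids}
        )
        with pytest.raises(ValidationError, match="absent"):
            differential_expression(m, ann, "nope", "han")

    def test_raw_scale_rejected(self, tiny_matrix):
        ann = make_annotation(
            {p: (p, "mRNA", None, None, None, None) for p in tiny_matrix.probe_ids}
        )
        with pytest.raises(StateError):
            differential_expression(tiny_matrix, ann, "tibetan", "han")

    def test_table_round_trip(self, tmp_path, rng):
        case = rng.normal(size=(5, 4))
        control = rng.normal(size=(5, 3))
        m = _two_group_matrix(case, control, [f"P{i}" for i in range(5)])
        ann = make_annotation(
            {f"P{i}": (f"G{i}", "mRNA", None, None, None, None) for i in range(5)}
        )
        res = differential_expression(m, ann, "tibetan", "han")
        write_de_table(res, tmp_path / "de.tsv")
        back = read_de_table(tmp_path / "de.tsv")
        assert back == res


class TestVolcanoTable:
    @staticmethod
    def _result(p):
        return DEResult("P", "G", "mRNA", 1.0, 0.0, 1.0, 2.0, p, p, "ns", False)

    @pytest.mark.parametrize("p,expected", [(0.01, 2.0), (1.0, 0.0), (0.0, 350.0)])
    def test_neg_log10_with_zero_cap(self, p, expected):
        table = volcano_table([self._result(p)])
        assert table["neg_log10_p"].iloc[0] == pytest.approx(expected)


class TestPooledTTestDEEstimator:
    def test_fit_attributes_and_selection(self, rng):
        n_up, n_null = 3, 17
        X_case = rng.normal(size=(5, n_up + n_null))
        X_case[:, :n_up] += 4.0
        X_control = rng.normal(size=(3, n_up + n_null))
        X = np.vstack([X_case, X_control])
        y = np.array(["t"] * 5 + ["h"] * 3)
        est = PooledTTestDE(case_label="t", control_label="h").fit(X, y)
        assert est.get_support()[:n_up].all()
        assert est.transform(X).shape[1] == est.get_support().sum()
        # estimator agrees with the scalar operation feature by feature
        t0, p0, _ = t_test_two_group(X_case[:, 0], X_control[:, 0])
        assert est.t_stat_[0] == pytest.approx(t0) and est.p_value_[0] == pytest.approx(p0)

    def test_get_params_round_trip(self):
        est = PooledTTestDE(case_label="t", control_label="h", alpha=0.01)
        params = est.get_params()
        assert params["alpha"] == 0.01
        est.set_params(alpha=0.1)
        assert est.alpha == 0.1
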