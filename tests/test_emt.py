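import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from emtstrat import EMTSignature, ExpressionMatrix, ecdf_eval, emt_score_cohort, emt_score_sample, signed_ks
from helpers_oracle import ks_oracle

finite_floats = st.floats(min_value=-50, max_value=50, allow_nan=False)
value_lists = st.lists(finite_floats, min_size=1, max_size=30)


class TestECDF:
    @pytest.mark.parametrize(
        "values,grid,expected",
        [
            ([1, 2, 3], [1, 2, 3], [1 / 3, 2 / 3, 1.0]),
            ([1, 1, 2], [1], [2 / 3]),
            ([5, 6], [0], [0.0]),
            ([1, 2, 3], [2.5], [2 / 3]),
        ],
    )
    def test_definition(self, values, grid, expected):
        np.testing.assert_allclose(ecdf_eval(values, grid), expected)

    def test_empty_values_error(self):
        with pytest.raises(ValueError):
            ecdf_eval([], [1.0])

    @given(value_lists)
    def test_monotone_and_bounded(self, values):
        grid = np.sort(np.unique(values))
        f = ecdf_eval(values, grid)
        assert np.all(np.diff(f) >= 0)
        assert np.all((f >= 0) & (f <= 1))
        assert f[-1] == 1.0


class TestSignedKS:
    @pytest.mark.parametrize(
        "epi,mes,expected",
        [
            ([1, 2, 3], [4, 5, 6], 1.0),          # complete separation, mesenchymal higher
            ([4, 5, 6], [1, 2, 3], -1.0),         # mirror
            ([1, 3, 5, 7], [2, 4, 6, 8], 0.25),   # interleaved, enumerated by hand
            ([1, 2, 3], [1, 2, 3], 0.0),          # identical ECDFs
        ],
    )
    def test_examples(self, epi, mes, expected):
        score, d_plus, d_minus = signed_ks(epi, mes)
        assert score == pytest.approx(expected)
        assert d_plus >= 0 and d_minus >= 0
        assert score in (d_plus, -d_minus, 0.0)

    def test_derived_interleaved_components(self):
        score, d_plus, d_minus = signed_ks([1, 3, 5, 7], [2, 4, 6, 8])
        assert (d_plus, d_minus) == (0.25, 0.0)
        assert score == 0.25

    def test_empty_or_nonfinite_errors(self):
        with pytest.raises(ValueError):
            signed_ks([], [1.0])
        with pytest.raises(ValueError):
            signed_ks([1.0, np.nan], [2.0])

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            n_e, n_m = rng.integers(1, 51, size=2)
            # mixed continuous and tied (integer) draws
            epi = np.round(rng.normal(0, 2, n_e), rng.integers(0, 2))
            mes = np.round(rng.normal(0.5, 2, n_m), rng.integers(0, 2))
            assert signed_ks(epi, mes) == ks_oracle(epi, mes)

    @given(value_lists, value_lists)
    def test_bounds_and_antisymmetry(self, a, b):
        score, d_plus, d_minus = signed_ks(a, b)
        assert -1.0 <= score <= 1.0
        if d_plus != d_minus:
            back, bp, bm = signed_ks(b, a)
            assert back == -score
            assert (bp, bm) == (d_minus, d_plus)

    @given(value_lists, value_lists)
    def test_unit_score_iff_complete_separation(self, a, b):
        score, _, _ = signed_ks(a, b)
        separated = max(a) < min(b) or max(b) < min(a)
        assert (abs(score) == 1.0) == separated

    def test_shift_never_decreases_score(self, rng):
        for _ in range(100):
            epi = rng.normal(size=12)
            mes = rng.normal(size=15)
            base = signed_ks(epi, mes)[0]
            shifted = signed_ks(epi, mes + rng.uniform(0.01, 3.0))[0]
            assert shifted >= base


@pytest.fixture
def sig():
    return EMTSignature("toy", tuple(f"E{i}" for i in range(12)), tuple(f"M{i}" for i in range(12)))


def _matrix_for(sig, values_by_sample):
    genes = list(sig.epithelial) + list(sig.mesenchymal)
    return ExpressionMatrix(pd.DataFrame(values_by_sample, index=genes))


class TestSampleAndCohortScoring:
    def test_complete_separation_positive(self, sig):
        epi_vals = np.arange(12, dtype=float)
        mes_vals = np.arange(100, 112, dtype=float)
        m = _matrix_for(sig, {"s1": np.r_[epi_vals, mes_vals], "s2": np.r_[mes_vals, epi_vals]})
        assert emt_score_sample(m, "s1", sig).score == 1.0
        assert emt_score_sample(m, "s2", sig).score == -1.0

    def test_min_genes_marks_invalid(self, sig):
        m = _matrix_for(sig, {"s1": np.arange(24.0), "s2": np.arange(24.0)})
        res = emt_score_sample(m, "s1", sig, min_genes=20)
        assert not res.valid and np.isnan(res.score)
        assert (res.n_epi_used, res.n_mes_used) == (12, 12)

    def test_constant_expression_scores_zero(self, sig):
        m = _matrix_for(sig, {"s1": np.full(24, 5.0), "s2": np.full(24, 5.0)})
        assert emt_score_sample(m, "s1", sig).score == 0.0

    def test_unknown_sample_errors(self, sig):
        m = _matrix_for(sig, {"s1": np.arange(24.0), "s2": np.arange(24.0)})
        with pytest.raises(KeyError):
            emt_score_sample(m, "nope", sig)

    def test_rank_invariance_under_monotone_transform(self, sig, rng):
        vals = rng.normal(5, 1, size=24)
        m = _matrix_for(sig, {"s1": vals, "s2": np.exp(vals / 2), "s3": vals**3})
        scores = emt_score_cohort(m, sig)["score"]
        assert scores.nunique() == 1

    def test_cohort_order_invariance(self, sig, rng):
        vals = {f"s{i}": rng.normal(5, 1, size=24) for i in range(6)}
        m = _matrix_for(sig, vals)
        perm = ExpressionMatrix(m.data[["s3", "s0", "s5", "s1", "s4", "s2"]])
        a = emt_score_cohort(m, sig).set_index("sample_id").sort_index()
        b = emt_score_cohort(perm, sig).set_index("sample_id").sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_cohort_matches_oracle_on_random_matrix(self, rng):
        genes = [f"E{i}" for i in range(40)] + [f"M{i}" for i in range(60)] + [f"B{i}" for i in range(100)]
        big = EMTSignature("big", tuple(genes[:40]), tuple(genes[40:100]))
        m = ExpressionMatrix(pd.DataFrame(
            np.round(rng.normal(5, 1, size=(200, 50)), 1), index=genes,
            columns=[f"s{i}" for i in range(50)]))
        table = emt_score_cohort(m, big).set_index("sample_id")
        for s in m.sample_ids:
            col = m.sample_values(s)
            expected = ks_oracle(col.loc[list(big.epithelial)], col.loc[list(big.mesenchymal)])
            assert table.loc[s, "score"] == expected[0]
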