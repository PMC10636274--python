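"""Natural-abundance distributions, correction matrices and MID inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dual_matrix_enum, natural_distribution_enum
from midquant.correction import (
    CorrectionError,
    IllConditionedError,
    build_correction_matrix,
    build_dual_matrix,
    build_tandem_matrix,
    correct_mid,
    natural_distribution,
)
from midquant.method import TracerSpec, parse_formula

# a "no heavy isotopes" table: correction must collapse to the identity
CLEAN_TABLE = {
    "C": [(12, 12.0, 1.0), (13, 13.00335, 0.0)],
    "H": [(1, 1.00783, 1.0), (2, 2.01410, 0.0)],
    "N": [(14, 14.00307, 1.0), (15, 15.00011, 0.0)],
    "O": [(16, 15.99491, 1.0), (17, 16.99913, 0.0), (18, 17.99916, 0.0)],
    "S": [(32, 31.97207, 1.0), (33, 32.97146, 0.0), (34, 33.96787, 0.0),
          (36, 35.96708, 0.0)],
}


class TestNaturalDistribution:
    def test_single_carbon_matches_isotope_table(self):
        np.testing.assert_allclose(natural_distribution({"C": 1}),
                                   [0.9893, 0.0107], atol=1e-15)

    def test_empty_formula_is_identity(self):
        np.testing.assert_allclose(natural_distribution({}), [1.0])
        np.testing.assert_allclose(natural_distribution({"C": 0}), [1.0])

    @pytest.mark.parametrize("formula_text", [
        "C6H12O6", "C5H11N2O3", "C3H7NO2S", "H2O", "CH4", "C2H5NO2",
    ])
    def test_matches_enumeration_oracle(self, formula_text):
        formula = parse_formula(formula_text)
        dist = natural_distribution(formula)
        oracle = natural_distribution_enum(formula)
        for shift, prob in oracle.items():
            assert dist[shift] == pytest.approx(prob, abs=1e-12)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_truncation_reports_tail_mass(self):
        full = natural_distribution({"C": 10})
        trunc, tail = natural_distribution({"C": 10}, max_shift=2,
                                           return_tail=True)
        assert trunc.size == 3
        assert tail == pytest.approx(float(full[3:].sum()), abs=1e-15)
        assert trunc.sum() + tail == pytest.approx(1.0, abs=1e-12)

    def test_unknown_element_rejected(self):
        with pytest.raises(CorrectionError):
            natural_distribution({"Xx": 1})


class TestSingleTracerMatrix:
    def test_two_carbon_binomial_by_hand(self):
        m = build_correction_matrix({"C": 2}, TracerSpec("C", 13, 2),
                                    "high_res_ms1")
        p, q = 0.9893, 0.0107
        expected = np.array([
            [p**2, 0, 0],
            [2 * p * q, p, 0],
            [q**2, q, 1],
        ])
        np.testing.assert_allclose(m.matrix, expected, atol=1e-12)

    def test_no_heavy_isotopes_gives_identity(self):
        for mode in ("low_res_ms1", "high_res_ms1"):
            m = build_correction_matrix(
                parse_formula("C5H11N2O3"), TracerSpec("C", 13, 5), mode,
                isotope_table=CLEAN_TABLE)
            np.testing.assert_allclose(m.matrix, np.eye(6), atol=1e-15)

    def test_low_res_includes_non_tracer_elements(self):
        formula = parse_formula("C5H11N2O3")
        tracer = TracerSpec("C", 13, 5)
        low = build_correction_matrix(formula, tracer, "low_res_ms1")
        high = build_correction_matrix(formula, tracer, "high_res_ms1")
        # M+1 from an unlabeled molecule is larger at unit resolution:
        # 15N, 2H and 17O all land on the same nominal channel
        assert low.matrix[1, 0] > high.matrix[1, 0]
        expected_low = natural_distribution_enum(formula)
        assert low.matrix[1, 0] == pytest.approx(expected_low[1], abs=1e-12)

    def test_lower_triangular(self):
        m = build_correction_matrix(parse_formula("C6H12O6"),
                                    TracerSpec("C", 13, 6), "high_res_ms1")
        upper = np.triu(m.matrix, k=1)
        assert np.all(upper == 0)

    def test_columns_sum_at_most_one(self):
        m = build_correction_matrix(parse_formula("C6H12O6"),
                                    TracerSpec("C", 13, 6), "low_res_ms1",
                                    n_channels=4)
        sums = m.matrix.sum(axis=0)
        assert np.all(sums <= 1 + 1e-12)
        assert sums[0] < 1  # truncation dropped real mass

    def test_more_positions_than_atoms_rejected(self):
        with pytest.raises(CorrectionError):
            build_correction_matrix({"C": 2}, TracerSpec("C", 13, 5),
                                    "high_res_ms1")


class TestDualMatrix:
    def test_degenerate_second_tracer_reduces_to_single(self):
        formula = parse_formula("C5H11N2O3")
        dual = build_dual_matrix(formula, TracerSpec("C", 13, 5),
                                 TracerSpec("N", 15, 0), "high_res_ms1")
        single = build_correction_matrix(formula, TracerSpec("C", 13, 5),
                                         "high_res_ms1")
        np.testing.assert_allclose(dual.matrix, single.matrix, atol=1e-14)

    def test_high_res_matches_enumeration_oracle(self):
        formula = {"C": 2, "N": 1}
        m = build_dual_matrix(formula, TracerSpec("C", 13, 2),
                              TracerSpec("N", 15, 1), "high_res_ms1")
        oracle = dual_matrix_enum(formula, "C", 2, "N", 1)
        assert m.matrix.shape == (6, 6)
        np.testing.assert_allclose(m.matrix, oracle, atol=1e-12)

    def test_no_heavy_isotopes_gives_identity(self):
        m = build_dual_matrix(parse_formula("C5H11N2O3"),
                              TracerSpec("C", 13, 5), TracerSpec("N", 15, 2),
                              "high_res_ms1", isotope_table=CLEAN_TABLE)
        np.testing.assert_allclose(m.matrix, np.eye(18), atol=1e-15)

    def test_same_element_rejected(self):
        with pytest.raises(CorrectionError):
            build_dual_matrix({"C": 4}, TracerSpec("C", 13, 2),
                              TracerSpec("C", 13, 2), "high_res_ms1")

    def test_low_res_isobaric_pairs_rejected(self):
        # (1,0) and (0,1) both shift +1 nominal at unit resolution
        with pytest.raises(CorrectionError, match="isobaric"):
            build_dual_matrix(parse_formula("C5H11N2O3"),
                              TracerSpec("C", 13, 5), TracerSpec("N", 15, 2),
                              "low_res_ms1")


class TestTandemMatrix:
    def test_full_product_equals_ms1_matrix(self):
        formula = parse_formula("C5H11N2O3")
        tracer = TracerSpec("C", 13, 5)
        tandem = build_tandem_matrix(formula, formula, tracer, 5,
                                     mode="high_res_ms1")
        ms1 = build_correction_matrix(formula, tracer, "high_res_ms1")
        np.testing.assert_allclose(tandem.matrix, ms1.matrix, atol=1e-15)

    def test_product_without_tracer_atoms_is_scalar(self):
        tandem = build_tandem_matrix({"C": 5, "H": 10}, {"H": 4},
                                     TracerSpec("C", 13, 5), 0,
                                     mode="high_res_ms1")
        assert tandem.matrix.shape == (1, 1)
        # no tracer atoms left: the only channel holds everything
        assert tandem.matrix[0, 0] == pytest.approx(1.0)

    def test_product_subformula_matrix(self):
        tandem = build_tandem_matrix({"C": 5, "H": 10, "N": 2}, {"C": 2},
                                     TracerSpec("C", 13, 5), 2,
                                     mode="high_res_ms1")
        direct = build_correction_matrix({"C": 2}, TracerSpec("C", 13, 2),
                                         "high_res_ms1")
        np.testing.assert_allclose(tandem.matrix, direct.matrix, atol=1e-15)

    def test_non_subformula_rejected(self):
        with pytest.raises(CorrectionError):
            build_tandem_matrix({"C": 2}, {"C": 3}, TracerSpec("C", 13, 2), 2)


class TestCorrectMid:
    def gln_matrix(self):
        return build_correction_matrix(parse_formula("C5H11N2O3"),
                                       TracerSpec("C", 13, 5), "high_res_ms1")

    def test_matrix_column_recovers_unit_vector(self):
        m = self.gln_matrix()
        result = correct_mid(m.matrix[:, 2].copy(), m)
        expected = np.zeros(6)
        expected[2] = 1.0
        np.testing.assert_allclose(result.fractions, expected, atol=1e-9)
        assert result.residual_norm == pytest.approx(0.0, abs=1e-12)

    def test_identity_matrix_is_passthrough(self):
        from midquant.correction import CorrectionMatrix

        raw = np.array([0.5, 0.3, 0.2])
        m = CorrectionMatrix(matrix=np.eye(3), mode="high_res_ms1",
                             formula={"C": 2}, tracers=())
        np.testing.assert_allclose(correct_mid(raw, m).fractions, raw)

    def test_mixture_forward_then_invert(self):
        """30% U-13C5 + 70% unlabeled glutamine, convolved with natural
        background and inverted, returns the exact mixture."""
        m = self.gln_matrix()
        x = np.array([0.7, 0, 0, 0, 0, 0.3])
        raw = m.matrix @ x
        raw = raw / raw.sum()
        np.testing.assert_allclose(correct_mid(raw, m).fractions, x, atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6).filter(
        lambda v: sum(v) > 0.1))
    def test_round_trip_any_simplex_vector(self, weights):
        m = self.gln_matrix()
        x = np.array(weights) / np.sum(weights)
        raw = m.matrix @ x
        raw = raw / raw.sum()
        np.testing.assert_allclose(correct_mid(raw, m).fractions, x, atol=1e-8)

    def test_scale_invariance_before_normalization(self):
        m = self.gln_matrix()
        x = np.array([0.2, 0.2, 0.2, 0.2, 0.1, 0.1])
        raw = m.matrix @ x
        a = correct_mid(raw / raw.sum(), m).fractions
        b = correct_mid((raw * 1e7) / (raw * 1e7).sum(), m).fractions
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_ill_conditioned_matrix_flagged(self):
        from midquant.correction import CorrectionMatrix

        bad = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-15]])
        m = CorrectionMatrix(matrix=bad, mode="high_res_ms1",
                             formula={"C": 1}, tracers=())
        with pytest.raises(IllConditionedError):
            correct_mid(np.array([0.5, 0.5]), m)

    def test_approximately_unbiased_under_multiplicative_noise(self):
        """Mean corrected MID over replicates stays within 3 standard errors
        of the truth for small multiplicative noise."""
        m = self.gln_matrix()
        x = np.array([0.55, 0.1, 0.05, 0.05, 0.05, 0.2])
        clean = m.matrix @ x
        rng = np.random.default_rng(11)
        n_rep = 500
        results = np.empty((n_rep, 6))
        for r in range(n_rep):
            noisy = clean * (1 + rng.normal(0, 0.02, clean.size))
            noisy = np.clip(noisy, 0, None)
            results[r] = correct_mid(noisy / noisy.sum(), m).fractions
        mean = results.mean(axis=0)
        sem = results.std(axis=0, ddof=1) / np.sqrt(n_rep)
        np.testing.assert_array_less(np.abs(mean - x), 3 * sem + 1e-4)
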