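"""Closed-form single- and multi-locus variance formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famvar.model import (
    allele_variances,
    am_multilocus_covariance,
    mean_rm,
    var_am,
    var_rm,
    var_sibdiff_am,
    var_sibdiff_rm,
    var_total,
)
from famvar.params import AssortmentParams, LocusParams, MultiLocusModel
from famvar.tables import build_trio_table, enumerate_moments

# strategies for random loci / assortment
_beta = st.floats(-1, 1, allow_nan=False)
_locus = st.builds(
    LocusParams,
    q2=st.floats(0.05, 0.95),
    beta_c=_beta,
    beta_m=_beta,
    beta_f=_beta,
    beta_i=_beta,
    beta_s=_beta,
)
_rho = st.floats(0, 1)


@pytest.mark.parametrize(
    "locus, expected",
    [
        (LocusParams(0.5, 1, 1, 1, 7, 0), 3.0),  # imprinting never shifts the mean
        (LocusParams(0.3, beta_i=0.9, beta_s=0.4), 0.0),
        (LocusParams(0.3, 1, 0.5, -0.5), 0.6),
    ],
)
def test_mean_rm(locus, expected):
    assert mean_rm(locus) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "locus, expected",
    [
        (LocusParams(0.5, beta_c=1), 0.5),  # textbook 2 q1 q2 bc^2
        (LocusParams(0.5, beta_i=1), 0.5),  # imprinting-only variance
        (LocusParams(0.3, 1, 0.5, -0.5, 0.2), 0.7308),
    ],
)
def test_var_rm(locus, expected):
    assert var_rm(locus) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "locus, expected",
    [
        (LocusParams(0.5, beta_c=1, beta_s=1), 0.0),  # bc = bs cancels exactly
        (LocusParams(0.5, beta_c=1, beta_s=0.5), 0.125),
        (LocusParams(0.5, beta_m=5, beta_f=-3), 0.0),  # parental effects cancel
    ],
)
def test_var_sibdiff_rm(locus, expected):
    assert var_sibdiff_rm(locus) == pytest.approx(expected, abs=1e-12)


def test_var_am_examples(mixed_locus):
    locus = LocusParams(0.5, beta_c=1)
    assert var_am(locus, AssortmentParams(rho=1.0)) == pytest.approx(1.0)
    # frozen value, cross-checked against table enumeration below
    trio = LocusParams(0.3, 1, 0.5, -0.5, 0.2)
    assert var_am(trio, AssortmentParams(rho=0.2)) == pytest.approx(0.767424, rel=1e-12)
    _, v_enum = enumerate_moments(build_trio_table(trio), trio, "z_am", rho=0.2)
    assert var_am(trio, AssortmentParams(rho=0.2)) == pytest.approx(v_enum, rel=1e-10)


def test_var_sibdiff_am_examples():
    locus = LocusParams(0.5, beta_c=1, beta_s=0.5)
    assert var_sibdiff_am(locus, AssortmentParams(rho=0.2)) == pytest.approx(0.1)
    assert var_sibdiff_am(locus, AssortmentParams(rho=1.0)) == pytest.approx(0.0)


def test_rho_out_of_range_rejected():
    with pytest.raises(ValueError):
        AssortmentParams(rho=-0.1)
    with pytest.raises(ValueError):
        AssortmentParams(rho=1.5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(locus=_locus)
def test_var_am_reduces_to_rm_at_zero_rho(locus):
    assert var_am(locus, AssortmentParams(rho=0.0)) == var_rm(locus)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(locus=_locus, rho=_rho)
def test_sibdiff_am_ratio_is_one_minus_rho(locus, rho):
    v_rm = var_sibdiff_rm(locus)
    v_am = var_sibdiff_am(locus, AssortmentParams(rho=rho))
    if v_rm > 1e-12:
        assert v_am / v_rm == pytest.approx(1.0 - rho, abs=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(locus=_locus, rho=_rho)
def test_allele_relabelling_invariance(locus, rho):
    """Swapping A1 and A2 (q2 -> q1, all betas negated) leaves every
    variance unchanged."""
    other = locus.relabelled()
    assort = AssortmentParams(rho=rho)
    assert var_rm(other) == pytest.approx(var_rm(locus), rel=1e-10, abs=1e-12)
    assert var_sibdiff_rm(other) == pytest.approx(var_sibdiff_rm(locus), rel=1e-10, abs=1e-12)
    assert var_am(other, assort) == pytest.approx(var_am(locus, assort), rel=1e-10, abs=1e-12)
    assert var_sibdiff_am(other, assort) == pytest.approx(
        var_sibdiff_am(locus, assort), rel=1e-10, abs=1e-12
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(q2=st.floats(0.05, 0.95), bc=_beta)
def test_var_rm_direct_only_is_textbook(q2, bc):
    locus = LocusParams(q2, beta_c=bc)
    assert var_rm(locus) == pytest.approx(2 * q2 * (1 - q2) * bc**2, rel=1e-12, abs=1e-15)


class TestVarTotal:
    def test_independent_loci_sum(self, mixed_locus):
        model = MultiLocusModel(loci=[mixed_locus, mixed_locus])
        assert var_total(model, "RM") == pytest.approx(2 * var_rm(mixed_locus))

    def test_perfectly_correlated_pair(self, mixed_locus):
        k = np.array([[0.0, 1.0], [1.0, 0.0]])
        model = MultiLocusModel(loci=[mixed_locus, mixed_locus], k_matrix=k)
        assert var_total(model, "RM") == pytest.approx(4 * var_rm(mixed_locus))

    def test_matches_monte_carlo_on_correlated_values(self, rng):
        """Sum of per-locus genotypic values with correlation k_ij has the
        variance sum V + sum k_ij sqrt(V_i V_j); checked by simulating
        jointly normal per-locus values at 3 loci."""
        loci = [
            LocusParams(0.3, beta_c=1.0),
            LocusParams(0.5, beta_c=-0.6, beta_m=0.4),
            LocusParams(0.7, beta_c=0.8, beta_i=0.3),
        ]
        k = np.array([[0, 0.3, -0.1], [0.3, 0, 0.2], [-0.1, 0.2, 0]])
        model = MultiLocusModel(loci=loci, k_matrix=k)
        v = np.array([var_rm(l) for l in loci])
        cov = np.sqrt(np.outer(v, v)) * (k + np.eye(3))
        draws = rng.multivariate_normal(np.zeros(3), cov, size=400_000)
        mc = draws.sum(axis=1).var()
        assert var_total(model, "RM") == pytest.approx(mc, rel=0.02)

    def test_regime_dispatch(self, mixed_locus):
        model = MultiLocusModel(loci=[mixed_locus])
        assort = AssortmentParams(rho=0.4)
        assert var_total(model, "AM", assort) == pytest.approx(var_am(mixed_locus, assort))
        assert var_total(model, "sibdiff-AM", assort) == pytest.approx(
            var_sibdiff_am(mixed_locus, assort)
        )
        with pytest.raises(ValueError):
            var_total(model, "bogus")


class TestAlleleVariances:
    def test_examples(self):
        assert allele_variances(LocusParams(0.5, 1, 1, 0)) == pytest.approx((1.0, 0.25))
        v_m, _ = allele_variances(LocusParams(0.4, beta_c=0.7, beta_m=-0.7))
        assert v_m == pytest.approx(0.0)
        v_m, _ = allele_variances(LocusParams(0.3, beta_c=1, beta_m=0.5))
        assert v_m == pytest.approx(0.4725)

    def test_against_two_point_enumeration(self, rng):
        """The maternal-allele variance is that of a two-point variable
        taking (bc+bm) with frequency q1 and 0 with frequency q2."""
        for _ in range(50):
            q2 = rng.uniform(0.05, 0.95)
            bc, bm = rng.uniform(-1, 1, 2)
            locus = LocusParams(q2, beta_c=bc, beta_m=bm)
            q1 = 1 - q2
            eff = bc + bm
            mean = q1 * eff
            enum = q1 * (eff - mean) ** 2 + q2 * mean**2
            assert allele_variances(locus)[0] == pytest.approx(enum, abs=1e-12)


class TestMultilocusCovariance:
    def test_no_correlation(self):
        locus = LocusParams(0.3, beta_c=1.0, beta_m=0.4, beta_f=-0.2)
        out = am_multilocus_covariance(locus, AssortmentParams(), n_loci=7)
        assert out["total_cov"] == 0.0
        q1q2 = 0.3 * 0.7
        bc, bm, bf = 1.0, 0.4, -0.2
        expected = 2 * 7 * q1q2 * (bc**2 + bm**2 / 2 + bf**2 / 2 + bc * bm + bc * bf)
        assert out["v_x"] == pytest.approx(expected)

    def test_single_locus_has_no_cross_terms(self):
        locus = LocusParams(0.5, beta_c=1.0)
        out = am_multilocus_covariance(
            locus, AssortmentParams(f=0.3, k=0.5, s=0.5), n_loci=1
        )
        assert out["k_term"] == 0.0
        assert out["s_term"] == 0.0
        assert out["f_term"] != 0.0

    def test_two_locus_example(self):
        locus = LocusParams(0.5, beta_c=1.0)
        out = am_multilocus_covariance(
            locus, AssortmentParams(f=0.2, k=0.1, s=0.05), n_loci=2
        )
        assert out["f_term"] == pytest.approx(0.1)
        assert out["k_term"] == pytest.approx(0.05)
        assert out["s_term"] == pytest.approx(0.025)

    def test_against_correlated_allele_simulation(self, rng):
        """Monte-Carlo oracle: jointly normal allele values with the f/k/s
        correlation pattern reproduce V(X) + covariance terms."""
        q2, bc, bm, bf = 0.4, 0.8, 0.3, -0.2
        f, k, s = 0.25, 0.1, 0.05
        n_loci = 3
        locus = LocusParams(q2, beta_c=bc, beta_m=bm, beta_f=bf)
        out = am_multilocus_covariance(locus, AssortmentParams(f=f, k=k, s=s), n_loci)
        q1q2 = q2 * (1 - q2)
        sd_m = np.sqrt(q1q2) * (bc + bm)
        sd_f = np.sqrt(q1q2) * (bc + bf)
        # order: maternal alleles (l), then paternal alleles (l)
        sd = np.array([sd_m] * n_loci + [sd_f] * n_loci)
        corr = np.full((2 * n_loci, 2 * n_loci), 0.0)
        for i in range(n_loci):
            for j in range(n_loci):
                if i != j:
                    corr[i, j] = corr[n_loci + i, n_loci + j] = k  # within gamete
                    corr[i, n_loci + j] = corr[n_loci + j, i] = s  # across gametes
            corr[i, n_loci + i] = corr[n_loci + i, i] = f  # same locus
        np.fill_diagonal(corr, 1.0)
        cov = corr * np.outer(sd, sd)
        draws = rng.multivariate_normal(np.zeros(2 * n_loci), cov, size=400_000)
        mc = draws.sum(axis=1).var()
        assert out["v_x_with_cov"] == pytest.approx(mc, rel=0.02)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            am_multilocus_covariance(LocusParams(0.5), AssortmentParams(), n_loci=0)
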