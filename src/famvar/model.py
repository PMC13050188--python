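"""Closed-form means and variances of the family-effects model.

Single-locus results (random mating, sibling differences, assortative
mating) and their multilocus combination.  Every formula here is checked
against exact enumeration of the mating tables in
:mod:`famvar.tables`, which serves as the brute-force oracle.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .params import AssortmentParams, LocusParams, MultiLocusModel

__all__ = [
    "mean_rm",
    "var_rm",
    "var_sibdiff_rm",
    "var_am",
    "var_sibdiff_am",
    "var_total",
    "allele_variances",
    "am_multilocus_covariance",
]

Regime = Literal["RM", "AM", "sibdiff-RM", "sibdiff-AM"]


def mean_rm(locus: LocusParams) -> float:
    """Population mean of the child phenotype under random mating.

    mu = 2 q2 (beta_c + beta_m + beta_f).  Parent-of-origin effects are
    zero on average and sibling effects enter only the (unmodelled here)
    full phenotype, so neither shifts the mean.
    """
    return 2.0 * locus.q2 * (locus.beta_c + locus.beta_m + locus.beta_f)


def var_rm(locus: LocusParams) -> float:
    """Single-locus genetic variance of the child phenotype under random mating.

    V = 2 q1 q2 (bc^2 + bm^2 + bf^2 + bi^2 + bc*bm + bc*bf + bm*bi - bf*bi)

    Direct, parental and imprinting genotypic values are mutually
    confounded, producing the cross terms; note the sign asymmetry of the
    paternal-imprinting term, a consequence of the +maternal/-paternal
    phase coding.
    """
    # evaluated through the assortative-mating polynomial at rho = 0 so
    # the two agree bit-for-bit, not merely to rounding
    return _var_am_poly(locus, 0.0)


def var_sibdiff_rm(locus: LocusParams) -> float:
    """Single-locus variance of the sibling phenotype difference, random mating.

    Vs = 2 q1 q2 (bc^2 + bi^2 + bs^2 - 2 bc*bs).  Indirect parental
    contributions are shared by both siblings and cancel exactly; direct
    and sibling effects oppose each other in the difference.
    """
    bc, bi, bs = locus.beta_c, locus.beta_i, locus.beta_s
    return 2.0 * locus.q1 * locus.q2 * (bc**2 + bi**2 + bs**2 - 2.0 * bc * bs)


def _var_am_poly(locus: LocusParams, rho: float) -> float:
    """Assortative-mating variance polynomial, without range-checking rho.

    Used internally where ``rho`` is a measured (noisy) correlation that
    may fall slightly outside [0, 1].
    """
    bc, bm, bf, bi = locus.beta_c, locus.beta_m, locus.beta_f, locus.beta_i
    q1q2 = locus.q1 * locus.q2
    t0 = 2.0 * (bc**2 + bi**2 + bm**2 + bf**2 + bc * bm + bc * bf + bm * bi - bf * bi)
    t1 = bc**2 + 2.0 * bm**2 + 2.0 * bf**2 - bi**2 + 4.0 * bc * bm + 4.0 * bc * bf + 4.0 * bm * bf
    t2 = (
        bc**2
        - bi**2
        + 2.0 * bc * bm
        + 2.0 * bc * bf
        - 2.0 * bm * bi
        + 2.0 * bf * bi
        + 4.0 * bm * bf
    )
    return q1q2 * (t0 + rho * t1 + rho**2 * t2)


def var_am(locus: LocusParams, assort: AssortmentParams) -> float:
    """Single-locus genetic variance under assortative mating.

    A quadratic polynomial in the mate allele correlation ``rho`` that
    reduces to :func:`var_rm` at rho = 0.  The population mean is
    unchanged by assortment; only the variance inflates.
    """
    return _var_am_poly(locus, assort.rho)


def var_sibdiff_am(locus: LocusParams, assort: AssortmentParams) -> float:
    """Sibling-difference variance under assortative mating.

    Vs_AM = (1 - rho) * Vs_RM: assortment shrinks segregation variance
    within families through the increased homozygosity of parents.
    """
    return (1.0 - assort.rho) * var_sibdiff_rm(locus)


_REGIME_FUNCS = {
    "RM": lambda locus, assort: var_rm(locus),
    "AM": lambda locus, assort: var_am(locus, assort),
    "sibdiff-RM": lambda locus, assort: var_sibdiff_rm(locus),
    "sibdiff-AM": lambda locus, assort: var_sibdiff_am(locus, assort),
}


def var_total(
    model: MultiLocusModel,
    regime: Regime = "RM",
    assort: AssortmentParams | None = None,
) -> float:
    """Total genetic variance over correlated loci.

    V_tot = sum_j V_j + sum_{i != j} k_ij sqrt(V_i V_j)

    with per-locus variances V_j dispatched by ``regime``.  The
    off-diagonal sum runs over ordered pairs, i.e. twice the sum over
    unordered pairs.  Loci with negative per-locus variance (possible
    only for non-physical parameter combinations) are rejected because
    the square root is undefined.
    """
    if regime not in _REGIME_FUNCS:
        raise ValueError(f"unknown regime {regime!r}")
    if assort is None:
        assort = AssortmentParams()
    v = np.array([_REGIME_FUNCS[regime](locus, assort) for locus in model.loci])
    if np.any(v < 0):
        raise ValueError("negative per-locus variance under this regime")
    sd = np.sqrt(v)
    cross = sd[:, None] * sd[None, :] * model.k_matrix
    return float(v.sum() + cross.sum())


def allele_variances(locus: LocusParams) -> tuple[float, float]:
    """Variance contributed by a single maternal / paternal allele.

    With parent-of-origin effects set aside, a maternally inherited
    allele takes one of two values, (beta_c + beta_m) or 0, so its
    variance is the two-point-distribution value q1 q2 (beta_c + beta_m)^2;
    analogously q1 q2 (beta_c + beta_f)^2 for a paternal allele.
    """
    q1q2 = locus.q1 * locus.q2
    return (
        q1q2 * (locus.beta_c + locus.beta_m) ** 2,
        q1q2 * (locus.beta_c + locus.beta_f) ** 2,
    )


def am_multilocus_covariance(
    model_locus: LocusParams,
    assort: AssortmentParams,
    n_loci: int,
) -> dict[str, float]:
    """Allele-level variance and covariance decomposition for ``n_loci``
    exchangeable loci (equal frequencies and effects) under assortment.

    Returns the no-correlation variance V(X) plus the three covariance
    terms induced by the allele correlations ``f`` (same locus, across
    gametes), ``k`` (different loci, within a gamete; evaluated
    separately for the maternal and paternal gamete) and ``s``
    (different loci, across gametes), and their total:

    * f-term:  l * f * q1 q2 (bc + bm)(bc + bf)
    * k-term:  l(l-1)/2 * k * q1 q2 [(bc + bm)^2 + (bc + bf)^2]
    * s-term:  l(l-1) * s * q1 q2 (bc + bm)(bc + bf)

    Each term sums the covariance once per unordered allele pair; in the
    variance of the summed allelic values every pair enters twice, so
    ``v_x_with_cov`` = v_x + 2 * total_cov (verified against a
    correlated-allele simulation oracle in the tests).  Imprinting is
    excluded at this allele level.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    q1q2 = model_locus.q1 * model_locus.q2
    bc, bm, bf = model_locus.beta_c, model_locus.beta_m, model_locus.beta_f
    am = bc + bm
    af = bc + bf
    l = n_loci
    v_x = l * q1q2 * (am**2 + af**2)
    f_term = l * assort.f * q1q2 * am * af
    k_term = 0.5 * l * (l - 1) * assort.k * q1q2 * (am**2 + af**2)
    s_term = l * (l - 1) * assort.s * q1q2 * am * af
    total_cov = f_term + k_term + s_term
    return {
        "v_x": v_x,
        "f_term": f_term,
        "k_term": k_term,
        "s_term": s_term,
        "total_cov": total_cov,
        "v_x_with_cov": v_x + 2.0 * total_cov,
    }
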