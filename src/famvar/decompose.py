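"""Variance decomposition of simulated populations vs closed-form theory.

The decomposition is simulation-internal: it uses the true simulated
effect sizes to split the realized genetic variance into per-class
components (direct, maternal, paternal, imprinting, sibling) and their
pairwise covariances, for either the trio design (child phenotypes) or
the sibling-difference design.  The closed-form expectation combines
the per-locus variance formulas, evaluated at realized allele
frequencies and the realized mate genotype correlation, with measured
inter-locus correlations of the per-locus genotypic values.

A joint least-squares estimator of the four trio-design effects is
included as a secondary diagnostic; marginal single-class estimates are
confounded by construction and are not offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import _var_am_poly, var_sibdiff_rm
from .params import LocusParams
from .scenarios import CLASSES, EffectTable
from .simulate import PhasedPopulation

__all__ = [
    "VarianceDecomposition",
    "component_decomposition",
    "per_locus_values",
    "expected_total",
    "realized_rho_per_locus",
    "k_matrix_estimate",
    "trio_regression",
]

_COMPONENT_NAMES = {
    "c": "direct",
    "m": "maternal",
    "f": "paternal",
    "i": "imprinting",
    "s": "sibling",
}


@dataclass
class VarianceDecomposition:
    """Per-class variances, pairwise covariances and totals.

    ``components[k]`` is Var of the class-k genotypic value vector;
    ``covariances[(j, k)]`` (j < k in CLASSES order) the covariance
    between classes j and k.  ``total_estimated`` equals
    sum(components) + 2 * sum(covariances) up to floating point.
    """

    design: str
    components: dict[str, float]
    covariances: dict[tuple[str, str], float]
    total_estimated: float
    total_expected: float | None = None

    def component_sum(self) -> float:
        return sum(self.components.values()) + 2.0 * sum(self.covariances.values())


def _class_vectors(
    pop: PhasedPopulation,
    parents: PhasedPopulation | None,
    effects: EffectTable,
    design: str,
) -> dict[str, np.ndarray]:
    """Genotypic-value vector of each effect class (zeros where inactive)."""
    causal = effects.causal
    b = effects.causal_betas
    bc, bm, bf, bi, bs = (b[:, k] for k in range(5))
    xc = pop.dosage[:, causal].astype(float)
    xi = pop.imprint[:, causal].astype(float)

    if design == "trio":
        vec = {"c": xc @ bc, "i": xi @ bi}
        if parents is None:
            if np.any(bm) or np.any(bf):
                raise ValueError("trio decomposition needs parental genotypes")
            n = pop.n
            vec["m"] = np.zeros(n)
            vec["f"] = np.zeros(n)
        else:
            pdos = parents.dosage[:, causal].astype(float)
            vec["m"] = pdos[pop.mother_id] @ bm
            vec["f"] = pdos[pop.father_id] @ bf
        if np.any(bs):
            if np.any(pop.sibling_id < 0):
                raise ValueError("sibling effects active but sibling links missing")
            vec["s"] = xc[pop.sibling_id] @ bs
        else:
            vec["s"] = np.zeros(pop.n)
        return vec

    if design == "sibdiff":
        if np.any(pop.sibling_id < 0):
            raise ValueError("sibling-difference design needs sibling links")
        first = np.flatnonzero(np.arange(pop.n) < pop.sibling_id)  # each pair once
        sib = pop.sibling_id[first]
        dxc = xc[first] - xc[sib]
        dxi = xi[first] - xi[sib]
        zeros = np.zeros(len(first))
        return {
            "c": dxc @ bc,
            "m": zeros,
            "f": zeros.copy(),
            "i": dxi @ bi,
            "s": -dxc @ bs,  # sibling term of the difference: (Xs-Xc) bs
        }

    raise ValueError(f"unknown design {design!r}")


def component_decomposition(
    pop: PhasedPopulation,
    parents: PhasedPopulation | None,
    effects: EffectTable,
    design: str = "trio",
) -> VarianceDecomposition:
    """Split the realized genetic variance into class components.

    The component variances and covariances sum to the variance of the
    summed genetic value exactly (one observation per child for the trio
    design, one per sibling pair for the difference design).
    """
    vec = _class_vectors(pop, parents, effects, design)
    stack = np.vstack([vec[k] for k in CLASSES])
    cov = np.cov(stack, ddof=0)
    components = {k: float(cov[i, i]) for i, k in enumerate(CLASSES)}
    covariances = {
        (CLASSES[i], CLASSES[j]): float(cov[i, j])
        for i in range(5)
        for j in range(i + 1, 5)
    }
    total = float(np.var(stack.sum(axis=0)))
    return VarianceDecomposition(
        design=design,
        components=components,
        covariances=covariances,
        total_estimated=total,
    )


def per_locus_values(
    pop: PhasedPopulation,
    parents: PhasedPopulation | None,
    effects: EffectTable,
    design: str = "trio",
) -> np.ndarray:
    """Matrix of per-locus genotypic values (rows: children or sib pairs).

    Column j sums all active class contributions of causal locus j; the
    row sums reproduce the total genetic values used in
    :func:`component_decomposition`.
    """
    causal = effects.causal
    b = effects.causal_betas
    bc, bm, bf, bi, bs = (b[:, k] for k in range(5))
    xc = pop.dosage[:, causal].astype(float)
    xi = pop.imprint[:, causal].astype(float)
    if design == "trio":
        u = xc * bc + xi * bi
        if parents is not None and (np.any(bm) or np.any(bf)):
            pdos = parents.dosage[:, causal].astype(float)
            u += pdos[pop.mother_id] * bm + pdos[pop.father_id] * bf
        if np.any(bs):
            u += xc[pop.sibling_id] * bs
        return u
    if design == "sibdiff":
        first = np.flatnonzero(np.arange(pop.n) < pop.sibling_id)
        sib = pop.sibling_id[first]
        dxc = xc[first] - xc[sib]
        dxi = xi[first] - xi[sib]
        return dxc * bc + dxi * bi - dxc * bs
    raise ValueError(f"unknown design {design!r}")


def realized_rho_per_locus(
    parents: PhasedPopulation,
    pop: PhasedPopulation,
    causal: np.ndarray,
) -> np.ndarray:
    """Per-causal-locus mate genotype correlation of the realized pairings.

    This is the quantity the assortative-mating variance formulas take
    as rho (measured, possibly slightly negative through noise).
    """
    dm = parents.dosage[pop.mother_id][:, causal].astype(float)
    df = parents.dosage[pop.father_id][:, causal].astype(float)
    dm = dm[::2]  # one entry per pair (both sibs share parents)
    df = df[::2]
    dm -= dm.mean(axis=0)
    df -= df.mean(axis=0)
    den = dm.std(axis=0) * df.std(axis=0)
    num = (dm * df).mean(axis=0)
    out = np.zeros(len(causal))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def k_matrix_estimate(values: np.ndarray) -> np.ndarray:
    """Inter-locus correlation of per-locus genotypic values, zero diagonal.

    Loci whose value column is constant (no realized variance) get zero
    correlation with everything.
    """
    sd = values.std(axis=0)
    ok = sd > 0
    k = np.zeros((values.shape[1], values.shape[1]))
    if ok.sum() >= 2:
        sub = np.corrcoef(values[:, ok], rowvar=False)
        k[np.ix_(ok, ok)] = sub
    np.fill_diagonal(k, 0.0)
    return k


def expected_total(
    effects: EffectTable,
    realized_freqs: np.ndarray,
    realized_rho: np.ndarray | float,
    k_matrix: np.ndarray,
    design: str = "trio",
) -> float:
    """Closed-form total variance at realized frequencies and correlations.

    Per-locus variances come from the assortative-mating polynomial (or
    its sibling-difference counterpart) evaluated at the measured mate
    genotype correlation; cross-locus terms are k_ij sqrt(V_i V_j) over
    ordered pairs.  Negative per-locus values (impossible for physical
    parameters, approximated only by measurement noise in rho) are
    floored at zero before the square root.
    """
    causal = effects.causal
    b = effects.causal_betas
    q = np.asarray(realized_freqs, dtype=float)[causal]
    rho = np.broadcast_to(np.asarray(realized_rho, dtype=float), (len(causal),))
    v = np.empty(len(causal))
    for j in range(len(causal)):
        locus = LocusParams(
            q2=float(np.clip(q[j], 1e-9, 1 - 1e-9)),
            beta_c=b[j, 0],
            beta_m=b[j, 1],
            beta_f=b[j, 2],
            beta_i=b[j, 3],
            beta_s=b[j, 4],
        )
        if design == "trio":
            v[j] = _var_am_poly(locus, float(rho[j]))
        elif design == "sibdiff":
            v[j] = (1.0 - float(rho[j])) * var_sibdiff_rm(locus)
        else:
            raise ValueError(f"unknown design {design!r}")
    sd = np.sqrt(np.clip(v, 0.0, None))
    return float(v.sum() + (sd[:, None] * sd[None, :] * k_matrix).sum())


def trio_regression(
    pop: PhasedPopulation,
    parents: PhasedPopulation,
    causal: np.ndarray,
) -> np.ndarray:
    """Joint least-squares estimates of (bc, bm, bf, bi) per causal locus.

    Regresses the child phenotype on the stacked child-dose, mother-dose,
    father-dose and phase covariates of all causal loci simultaneously.
    Secondary diagnostic only: estimates are unbiased under the model but
    noisy, and marginal (single-locus) versions would be confounded.
    """
    xc = pop.dosage[:, causal].astype(float)
    xi = pop.imprint[:, causal].astype(float)
    pdos = parents.dosage[:, causal].astype(float)
    design = np.hstack([xc, pdos[pop.mother_id], pdos[pop.father_id], xi])
    design = np.hstack([np.ones((pop.n, 1)), design])
    coef, *_ = np.linalg.lstsq(design, pop.phenotype, rcond=None)
    return coef[1:].reshape(4, len(causal)).T  # columns: bc, bm, bf, bi
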