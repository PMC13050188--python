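"""Equilibrium family generation from the single-locus mating model.

Generates independent nuclear families (mother, father, two phased
children) directly from the assortative-mating equilibrium law, locus by
locus: at each locus the four parental alleles are exchangeably
correlated at level ``rho`` (the mate allele correlation, equal to the
inbreeding coefficient F at equilibrium), realized through a de Finetti
/ beta-mixture construction — a latent per-family, per-locus frequency
p ~ Beta(q (1-rho)/rho, (1-q)(1-rho)/rho) with alleles i.i.d.
Bernoulli(p) given p.  This reproduces, exactly and self-consistently:

* parental genotype frequencies of inbreeding form
  (q1^2 + rho q1 q2, 2 q1 q2 (1 - rho), q2^2 + rho q1 q2),
* child allele correlation f = rho (children sit at the same
  equilibrium as their parents),
* invariant allele frequencies.

Children are produced by fair Mendelian transmission, independently per
locus (loci unlinked here) and per child.  ``rho = 0`` reduces to random
mating under Hardy-Weinberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenarios import EffectTable

__all__ = ["FamilyCohort", "generate_families"]


@dataclass
class FamilyCohort:
    """``n_families`` independent families over L unlinked loci.

    Child haplotype arrays have shape (n_families, L, 2): the last axis
    indexes the two siblings.  Phenotypes: ``y_children`` is
    (n_families, 2); parents' phenotypes are per family.
    """

    mother_dosage: np.ndarray  # (n_fam, L)
    father_dosage: np.ndarray
    child_maternal: np.ndarray  # (n_fam, L, 2)
    child_paternal: np.ndarray
    y_mother: np.ndarray
    y_father: np.ndarray
    y_children: np.ndarray  # (n_fam, 2)
    allele_freqs: np.ndarray
    rho: float
    assorted: np.ndarray  # boolean mask of loci subject to mate assortment

    @property
    def n_families(self) -> int:
        return self.mother_dosage.shape[0]

    @property
    def child_dosage(self) -> np.ndarray:
        """(n_fam, L, 2) genotype dosages of the children."""
        return self.child_maternal + self.child_paternal

    @property
    def child_imprint(self) -> np.ndarray:
        return self.child_maternal.astype(np.int8) - self.child_paternal.astype(np.int8)

    def all_dosages(self) -> np.ndarray:
        """Stack (children of all families, then mothers, then fathers).

        Order: child 0 of each family, child 1 of each family, mothers,
        fathers — matching :meth:`all_phenotypes`.
        """
        c = self.child_dosage
        return np.concatenate(
            [c[:, :, 0], c[:, :, 1], self.mother_dosage, self.father_dosage], axis=0
        )

    def all_phenotypes(self) -> np.ndarray:
        return np.concatenate(
            [self.y_children[:, 0], self.y_children[:, 1], self.y_mother, self.y_father]
        )

    def sibling_pairs(self) -> np.ndarray:
        """(n_fam, 2) row indices into ``all_dosages`` of each sib pair."""
        n = self.n_families
        return np.column_stack([np.arange(n), np.arange(n) + n])

    def realized_mate_genotype_correlation(self) -> float:
        """Mean correlation of mother vs father dosage at assorted loci
        (all loci under random mating)."""
        sel = self.assorted if self.assorted.any() else np.ones_like(self.assorted)
        dm = self.mother_dosage[:, sel] - self.mother_dosage[:, sel].mean(axis=0)
        df = self.father_dosage[:, sel] - self.father_dosage[:, sel].mean(axis=0)
        num = (dm * df).mean(axis=0)
        den = dm.std(axis=0) * df.std(axis=0)
        ok = den > 0
        return float((num[ok] / den[ok]).mean())

    def realized_child_allele_correlation(self) -> float:
        """Mean per-locus correlation between the two alleles of a child."""
        sel = self.assorted if self.assorted.any() else np.ones_like(self.assorted)
        am = np.concatenate(
            [self.child_maternal[:, sel, k] for k in (0, 1)], axis=0
        ).astype(float)
        af = np.concatenate(
            [self.child_paternal[:, sel, k] for k in (0, 1)], axis=0
        ).astype(float)
        am -= am.mean(axis=0)
        af -= af.mean(axis=0)
        num = (am * af).mean(axis=0)
        den = am.std(axis=0) * af.std(axis=0)
        ok = den > 0
        return float((num[ok] / den[ok]).mean())


def _sample_exchangeable_alleles(
    q: np.ndarray,
    rho: float,
    n_families: int,
    assorted: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, ...]:
    """Four allele matrices (n_fam, L): mother x2, father x2.

    Loci flagged in the boolean mask ``assorted`` get pairwise allele
    correlation ``rho`` among all four alleles; the rest are i.i.d.
    Bernoulli(q) (mate assortment only correlates trait-associated
    loci; neutral loci stay at Hardy-Weinberg).
    """
    n_loci = q.shape[0]
    p = np.broadcast_to(q, (n_families, n_loci)).copy()
    if rho > 0.0 and assorted.any():
        qa = q[assorted]
        a = qa * (1.0 - rho) / rho
        b = (1.0 - qa) * (1.0 - rho) / rho
        p[:, assorted] = rng.beta(a, b, size=(n_families, int(assorted.sum())))
    draws = [
        (rng.random((n_families, n_loci)) < p).astype(np.uint8) for _ in range(4)
    ]
    return tuple(draws)


def generate_families(
    n_families: int,
    allele_freqs: np.ndarray,
    rho: float,
    effects: EffectTable,
    env_var: float,
    rng: np.random.Generator | int | None = None,
) -> FamilyCohort:
    """Sample families at assortative-mating equilibrium.

    Children's phenotypes follow the full model
    Y = Xc bc + Xm bm + Xf bf + Xi bi + Xsib bs + eps.  Parents'
    phenotypes include their own direct and imprinting-free terms plus
    environmental noise inflated by the maternal and paternal target
    contributions (their parents are not modelled); parental phenotypes
    only matter as members of relatedness pairs, not for mating, which
    is already at equilibrium by construction.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    rng = np.random.default_rng(rng)
    q = np.asarray(allele_freqs, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("allele frequencies must be in (0, 1)")

    assorted = np.any(effects.betas != 0.0, axis=1)
    m1, m2, f1, f2 = _sample_exchangeable_alleles(q, rho, n_families, assorted, rng)
    mother = (m1 + m2).astype(np.int8)
    father = (f1 + f2).astype(np.int8)

    n_loci = q.shape[0]
    child_mat = np.empty((n_families, n_loci, 2), dtype=np.uint8)
    child_pat = np.empty((n_families, n_loci, 2), dtype=np.uint8)
    for k in range(2):
        pick_m = rng.integers(0, 2, size=(n_families, n_loci), dtype=np.uint8)
        pick_f = rng.integers(0, 2, size=(n_families, n_loci), dtype=np.uint8)
        child_mat[:, :, k] = np.where(pick_m == 0, m1, m2)
        child_pat[:, :, k] = np.where(pick_f == 0, f1, f2)

    b = effects.betas
    bc, bm, bf, bi, bs = (b[:, j] for j in range(5))
    dos = child_mat + child_pat
    imp = child_mat.astype(np.int8) - child_pat.astype(np.int8)

    y_children = np.empty((n_families, 2))
    for k in range(2):
        sib = 1 - k
        y_children[:, k] = (
            dos[:, :, k] @ bc
            + mother @ bm
            + father @ bf
            + imp[:, :, k] @ bi
            + dos[:, :, sib] @ bs
        )
    y_children += rng.normal(0.0, np.sqrt(env_var), size=(n_families, 2))

    # parents: direct term + noise standing in for their own (unmodelled)
    # parental contributions, keeping Var(Y) comparable across roles
    extra = float(
        np.sum(2.0 * q * (1.0 - q) * bm**2) + np.sum(2.0 * q * (1.0 - q) * bf**2)
    )
    parent_sd = np.sqrt(env_var + extra)
    y_mother = mother @ bc + rng.normal(0.0, parent_sd, size=n_families)
    y_father = father @ bc + rng.normal(0.0, parent_sd, size=n_families)

    return FamilyCohort(
        mother_dosage=mother.astype(np.uint8),
        father_dosage=father.astype(np.uint8),
        child_maternal=child_mat,
        child_paternal=child_pat,
        y_mother=y_mother,
        y_father=y_father,
        y_children=y_children,
        allele_freqs=q,
        rho=rho,
        assorted=assorted if rho > 0.0 else np.zeros_like(assorted),
    )
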