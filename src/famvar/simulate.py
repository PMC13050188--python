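"""Forward-in-time family simulation with phased transmission.

Each generation, prospective mothers and fathers are paired (randomly or
by phenotype-ordered assortment at a target mate correlation ``rho_y``),
every pair produces two offspring by independent meioses, and offspring
phenotypes accumulate direct, indirect maternal/paternal, parent-of-
origin and indirect sibling contributions plus Gaussian environmental
noise.  Phase is tracked throughout: the dosage is maternal + paternal
haplotype and the imprinting covariate is maternal - paternal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import HaplotypePanel
from .scenarios import EffectScenario, EffectTable, sample_effects

__all__ = [
    "PhasedPopulation",
    "SimulationConfig",
    "SimulationResult",
    "meiosis",
    "assort_mates",
    "compute_phenotypes",
    "run_generations",
]


@dataclass
class PhasedPopulation:
    """One generation of phased individuals with pedigree links.

    ``maternal`` / ``paternal`` are (n, L) haplotype matrices in {0, 1}.
    ``mother_id`` / ``father_id`` index into the previous generation (-1
    for founders); ``sibling_id`` indexes within this generation (-1 if
    none).  ``sex`` is 0 for female, 1 for male.
    """

    maternal: np.ndarray
    paternal: np.ndarray
    mother_id: np.ndarray
    father_id: np.ndarray
    sibling_id: np.ndarray
    sex: np.ndarray
    phenotype: np.ndarray
    generation: int

    @property
    def n(self) -> int:
        return self.maternal.shape[0]

    @property
    def dosage(self) -> np.ndarray:
        """Genotype dosage X = Am + Af in {0, 1, 2}."""
        return self.maternal + self.paternal

    @property
    def imprint(self) -> np.ndarray:
        """Phase code Xi = Am - Af in {-1, 0, +1} (nonzero only at hets)."""
        return self.maternal.astype(np.int8) - self.paternal.astype(np.int8)


@dataclass
class SimulationConfig:
    n_individuals: int = 4000
    n_generations: int = 10
    rho_y: float = 0.0
    offspring_per_pair: int = 2
    recomb_rate: float = 0.01  # crossover probability per adjacent-locus interval
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 4 or self.n_individuals % 2:
            raise ValueError("n_individuals must be even and >= 4")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (0.0 <= self.rho_y <= 1.0):
            raise ValueError("rho_y must be in [0, 1]")
        if self.offspring_per_pair != 2:
            raise ValueError("exactly two offspring per pair are supported")
        if not (0.0 <= self.recomb_rate <= 1.0):
            raise ValueError("recomb_rate must be in [0, 1]")


@dataclass
class SimulationResult:
    history: list[PhasedPopulation]
    effects: EffectTable
    diagnostics: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def final(self) -> PhasedPopulation:
        return self.history[-1]


def meiosis(
    maternal: np.ndarray,
    paternal: np.ndarray,
    parent_idx: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per row of ``parent_idx`` from the phased parents.

    The transmitted strand starts on either parental haplotype with
    probability 1/2 and switches between strands independently with
    probability ``recomb_rate`` at each adjacent-locus interval (a
    geometric/Markov crossover process).  ``recomb_rate = 0`` transmits
    one haplotype intact; ``recomb_rate = 0.5`` is free recombination.
    """
    h1 = maternal[parent_idx]
    h2 = paternal[parent_idx]
    n, n_loci = h1.shape
    start = rng.integers(0, 2, size=(n, 1), dtype=np.uint8)
    if n_loci > 1 and recomb_rate > 0.0:
        switches = rng.random((n, n_loci - 1)) < recomb_rate
        crossings = np.bitwise_and(np.cumsum(switches, axis=1), 1).astype(np.uint8)
        strand = np.concatenate([start, start ^ crossings], axis=1)
    else:
        strand = np.broadcast_to(start, (n, n_loci))
    return np.where(strand == 0, h1, h2)


def assort_mates(
    y_female: np.ndarray,
    y_male: np.ndarray,
    rho_y: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair females with males at a target phenotypic correlation.

    Rank-matching against a bivariate Gaussian template: the template's
    first column is rank-aligned with the female phenotypes and the
    second with the male phenotypes, so each template row defines one
    pair.  ``rho_y = 0`` reduces to random pairing, ``rho_y = 1`` to
    co-sorting.  Returns (female_indices, male_indices) of the pairs.
    """
    if len(y_female) != len(y_male):
        raise ValueError("need equal numbers of prospective mothers and fathers")
    n = len(y_female)
    t1 = rng.standard_normal(n)
    t2 = rho_y * t1 + np.sqrt(1.0 - rho_y**2) * rng.standard_normal(n)
    # female with phenotype rank r is placed where t1 has rank r
    f_sorted = np.argsort(y_female, kind="stable")
    m_sorted = np.argsort(y_male, kind="stable")
    f_idx = np.empty(n, dtype=np.int64)
    m_idx = np.empty(n, dtype=np.int64)
    f_idx[np.argsort(t1, kind="stable")] = f_sorted
    m_idx[np.argsort(t2, kind="stable")] = m_sorted
    return f_idx, m_idx


def compute_phenotypes(
    pop: PhasedPopulation,
    parents: PhasedPopulation | None,
    effects: EffectTable,
    env_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotypes Y = Xc*bc + Xm*bm + Xf*bf + Xi*bi + Xs*bs + eps.

    ``parents`` supplies maternal/paternal genotypes; for founders
    (parents is None) only the direct and imprinting terms apply, which
    seeds the first round of mate assortment.  A missing sibling link
    with active sibling effects is an error.
    """
    causal = effects.causal
    b = effects.betas[causal]
    bc, bm, bf, bi, bs = (b[:, k] for k in range(5))
    xc = pop.dosage[:, causal]
    y = xc @ bc + pop.imprint[:, causal] @ bi
    if parents is not None:
        if np.any(bm) or np.any(bf):
            pdos = parents.dosage[:, causal]
            y = y + pdos[pop.mother_id] @ bm + pdos[pop.father_id] @ bf
    elif np.any(bm) or np.any(bf):
        # founders: indirect parental contributions are unobservable
        pass
    if np.any(bs):
        if np.any(pop.sibling_id < 0):
            raise ValueError("sibling effects active but sibling links missing")
        y = y + xc[pop.sibling_id] @ bs
    return y + rng.normal(0.0, np.sqrt(env_var), size=pop.n)


def _founder_population(panel: HaplotypePanel, n: int) -> PhasedPopulation:
    if 2 * n > panel.n_haplotypes:
        raise ValueError("panel too small for requested population size")
    mat = panel.haplotypes[0 : 2 * n : 2].copy()
    pat = panel.haplotypes[1 : 2 * n : 2].copy()
    none = np.full(n, -1, dtype=np.int64)
    sex = (np.arange(n) % 2).astype(np.uint8)
    return PhasedPopulation(
        maternal=mat,
        paternal=pat,
        mother_id=none,
        father_id=none.copy(),
        sibling_id=none.copy(),
        sex=sex,
        phenotype=np.zeros(n),
        generation=0,
    )


def _mate_stats(
    parents: PhasedPopulation,
    mothers: np.ndarray,
    fathers: np.ndarray,
    causal: np.ndarray,
) -> tuple[float, float]:
    """(mate phenotypic correlation, mean per-locus mate genotype correlation)."""
    ym = parents.phenotype[mothers]
    yf = parents.phenotype[fathers]
    r_y = float(np.corrcoef(ym, yf)[0, 1])
    dm = parents.dosage[mothers][:, causal].astype(float)
    df = parents.dosage[fathers][:, causal].astype(float)
    dm -= dm.mean(axis=0)
    df -= df.mean(axis=0)
    num = (dm * df).mean(axis=0)
    den = dm.std(axis=0) * df.std(axis=0)
    ok = den > 0
    rho_bar = float((num[ok] / den[ok]).mean()) if ok.any() else float("nan")
    return r_y, rho_bar


def run_generations(
    config: SimulationConfig,
    scenario: EffectScenario,
    panel: HaplotypePanel,
    effects: EffectTable | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulationResult:
    """Iterate pairing -> meiosis -> phenotypes for ``n_generations``.

    Returns the full generation history with pedigree links plus a
    per-generation diagnostics frame (realized mate phenotypic
    correlation, mean causal-locus mate genotype correlation, genetic
    and phenotypic variance).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = np.random.default_rng(rng)
    n = config.n_individuals
    if effects is None:
        effects = sample_effects(scenario, panel.allele_freqs, rng)
    causal = effects.causal
    b = effects.betas[causal]

    pop = _founder_population(panel, n)
    pop.phenotype = compute_phenotypes(pop, None, effects, scenario.env_var, rng)
    history = [pop]
    diag_rows = []

    for gen in range(1, config.n_generations + 1):
        prev = history[-1]
        females = np.flatnonzero(prev.sex == 0)
        males = np.flatnonzero(prev.sex == 1)
        fi, mi = assort_mates(
            prev.phenotype[females], prev.phenotype[males], config.rho_y, rng
        )
        mothers = females[fi]
        fathers = males[mi]
        r_y, rho_bar = _mate_stats(prev, mothers, fathers, causal)

        n_pairs = len(mothers)
        mother_of = np.repeat(mothers, 2)
        father_of = np.repeat(fathers, 2)
        mat_gam = meiosis(prev.maternal, prev.paternal, mother_of, config.recomb_rate, rng)
        pat_gam = meiosis(prev.maternal, prev.paternal, father_of, config.recomb_rate, rng)

        idx = np.arange(2 * n_pairs)
        sibling = idx ^ 1  # 2k <-> 2k+1
        sex = (idx % 2).astype(np.uint8)  # one daughter, one son per pair
        child = PhasedPopulation(
            maternal=mat_gam,
            paternal=pat_gam,
            mother_id=mother_of,
            father_id=father_of,
            sibling_id=sibling,
            sex=sex,
            phenotype=np.zeros(2 * n_pairs),
            generation=gen,
        )
        child.phenotype = compute_phenotypes(child, prev, effects, scenario.env_var, rng)

        g = child.dosage[:, causal] @ b[:, 0]  # direct genetic values
        diag_rows.append(
            {
                "generation": gen,
                "mate_r_y": r_y,
                "mate_rho_bar": rho_bar,
                "var_direct": float(np.var(g)),
                "var_phenotype": float(np.var(child.phenotype)),
            }
        )
        history.append(child)

    return SimulationResult(
        history=history, effects=effects, diagnostics=pd.DataFrame(diag_rows)
    )
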