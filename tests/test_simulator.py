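"""Forward-in-time simulator: transmission, assortment, phenotypes."""

import numpy as np
import pytest

from famvar.founders import generate_founders
from famvar.scenarios import EffectScenario, EffectTable, sample_effects
from famvar.simulate import (
    PhasedPopulation,
    SimulationConfig,
    assort_mates,
    compute_phenotypes,
    meiosis,
    run_generations,
)


def _single_locus_effects(n_loci, **betas):
    b = np.zeros((n_loci, 5))
    for name, val in betas.items():
        b[0, {"bc": 0, "bm": 1, "bf": 2, "bi": 3, "bs": 4}[name]] = val
    return EffectTable(betas=b, causal=np.array([0]))


class TestMeiosis:
    def test_no_recombination_transmits_one_haplotype(self, rng):
        mat = rng.integers(0, 2, (10, 40)).astype(np.uint8)
        pat = rng.integers(0, 2, (10, 40)).astype(np.uint8)
        idx = np.arange(10)
        g = meiosis(mat, pat, idx, recomb_rate=0.0, rng=rng)
        for i in range(10):
            assert np.array_equal(g[i], mat[i]) or np.array_equal(g[i], pat[i])

    def test_transmitted_frequency_matches_parental(self, rng):
        mat = rng.integers(0, 2, (200, 30)).astype(np.uint8)
        pat = rng.integers(0, 2, (200, 30)).astype(np.uint8)
        idx = np.repeat(np.arange(200), 20)
        g = meiosis(mat, pat, idx, recomb_rate=0.1, rng=rng)
        parental = (mat + pat).mean() / 2
        assert g.mean() == pytest.approx(parental, abs=3 / np.sqrt(g.size))

    def test_free_recombination_decouples_adjacent_loci(self, rng):
        # heterozygous parent with perfectly coupled haplotypes
        mat = np.ones((1, 200), dtype=np.uint8)
        pat = np.zeros((1, 200), dtype=np.uint8)
        idx = np.zeros(4000, dtype=int)
        g = meiosis(mat, pat, idx, recomb_rate=0.5, rng=rng).astype(float)
        r = np.corrcoef(g[:, :-1].ravel(), g[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.05


class TestAssortMates:
    def test_random_pairing_at_zero(self, rng):
        ym, yf = rng.normal(size=3000), rng.normal(size=3000)
        fi, mi = assort_mates(ym, yf, 0.0, rng)
        r = np.corrcoef(ym[fi], yf[mi])[0, 1]
        assert abs(r) < 3 / np.sqrt(3000)

    def test_perfect_assortment_co_sorts(self, rng):
        ym, yf = rng.normal(size=500), rng.normal(size=500)
        fi, mi = assort_mates(ym, yf, 1.0, rng)
        assert np.corrcoef(ym[fi], yf[mi])[0, 1] > 0.99
        assert np.array_equal(np.argsort(ym[fi]), np.argsort(yf[mi]))

    def test_intermediate_target_hit(self, rng):
        ym, yf = rng.normal(size=4000), rng.normal(size=4000)
        fi, mi = assort_mates(ym, yf, 0.2, rng)
        assert np.corrcoef(ym[fi], yf[mi])[0, 1] == pytest.approx(0.2, abs=0.02)

    def test_unequal_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            assort_mates(np.zeros(3), np.zeros(4), 0.0, rng)


def test_phase_and_dosage_consistency():
    panel = generate_founders(300, 60, rng=0)
    scen = EffectScenario.preset("V4", n_causal=30)
    res = run_generations(
        SimulationConfig(n_individuals=300, n_generations=3), scen, panel, rng=1
    )
    for pop in res.history:
        dos = pop.dosage
        imp = pop.imprint
        assert np.array_equal(dos, pop.maternal + pop.paternal)
        assert np.all(np.isin(dos, (0, 1, 2)))
        assert np.all(imp[dos != 1] == 0)
        assert np.all(np.isin(imp[dos == 1], (-1, 1)))
        if pop.generation > 0:
            assert pop.mother_id.min() >= 0
            assert pop.father_id.max() < res.history[pop.generation - 1].n
            # both sibs share both parents
            assert np.array_equal(pop.mother_id, pop.mother_id[pop.sibling_id])


def test_determinism_matched_seed():
    panel = generate_founders(200, 40, rng=5)
    scen = EffectScenario.preset("V1", n_causal=20)
    cfg = SimulationConfig(n_individuals=200, n_generations=3, rho_y=0.3)
    a = run_generations(cfg, scen, panel, rng=9)
    b = run_generations(cfg, scen, panel, rng=9)
    assert np.array_equal(a.final.maternal, b.final.maternal)
    assert np.array_equal(a.final.phenotype, b.final.phenotype)


def test_allele_frequencies_conserved_in_expectation():
    panel = generate_founders(2000, 100, rng=2)
    scen = EffectScenario.preset("V1", n_causal=50)
    res = run_generations(
        SimulationConfig(n_individuals=2000, n_generations=5, rho_y=0.3), scen, panel, rng=3
    )
    f0 = res.history[0].dosage.mean(axis=0) / 2
    f5 = res.final.dosage.mean(axis=0) / 2
    drift_sd = np.sqrt(5 * f0 * (1 - f0) / (2 * 2000))
    assert np.mean(np.abs(f5 - f0) < 4 * drift_sd) > 0.95
    assert np.abs(f5.mean() - f0.mean()) < 0.005


def test_phenotype_trio_row():
    """A1A1 mother, A1A2 father, child with paternal A2: genetic value
    bc + bf - bi at a single locus."""
    parents = PhasedPopulation(
        maternal=np.array([[0], [0]], dtype=np.uint8),
        paternal=np.array([[0], [1]], dtype=np.uint8),  # father is heterozygous
        mother_id=np.full(2, -1),
        father_id=np.full(2, -1),
        sibling_id=np.full(2, -1),
        sex=np.array([0, 1], dtype=np.uint8),
        phenotype=np.zeros(2),
        generation=0,
    )
    child = PhasedPopulation(
        maternal=np.array([[0]], dtype=np.uint8),
        paternal=np.array([[1]], dtype=np.uint8),  # A1A2: maternal A1, paternal A2
        mother_id=np.array([0]),
        father_id=np.array([1]),
        sibling_id=np.array([-1]),
        sex=np.array([0], dtype=np.uint8),
        phenotype=np.zeros(1),
        generation=1,
    )
    eff = _single_locus_effects(1, bc=1.0, bm=0.3, bf=0.7, bi=0.2)
    y = compute_phenotypes(child, parents, eff, env_var=0.0, rng=np.random.default_rng(0))
    assert y[0] == pytest.approx(1.0 + 0.7 - 0.2)


def test_phenotype_pure_noise_when_no_effects(rng):
    pop = PhasedPopulation(
        maternal=np.zeros((4000, 3), dtype=np.uint8),
        paternal=np.zeros((4000, 3), dtype=np.uint8),
        mother_id=np.full(4000, -1),
        father_id=np.full(4000, -1),
        sibling_id=np.full(4000, -1),
        sex=np.zeros(4000, dtype=np.uint8),
        phenotype=np.zeros(4000),
        generation=0,
    )
    eff = _single_locus_effects(3)
    y = compute_phenotypes(pop, None, eff, env_var=0.7, rng=rng)
    assert y.mean() == pytest.approx(0.0, abs=0.06)
    assert y.var() == pytest.approx(0.7, rel=0.1)


def test_missing_sibling_link_with_sibling_effects(rng):
    pop = PhasedPopulation(
        maternal=np.zeros((10, 2), dtype=np.uint8),
        paternal=np.zeros((10, 2), dtype=np.uint8),
        mother_id=np.full(10, -1),
        father_id=np.full(10, -1),
        sibling_id=np.full(10, -1),
        sex=np.zeros(10, dtype=np.uint8),
        phenotype=np.zeros(10),
        generation=0,
    )
    eff = _single_locus_effects(2, bs=0.5)
    with pytest.raises(ValueError, match="sibling"):
        compute_phenotypes(pop, None, eff, 0.5, rng)


def test_assortative_mating_inflates_genetic_variance():
    """Ten generations of strong phenotype-ordered assortment build up
    positive inter-locus correlations and inflate the direct genetic
    variance relative to the founders; random mating does not."""
    panel = generate_founders(2000, 200, rng=21)
    scen = EffectScenario.preset("V1", n_causal=100)
    eff = sample_effects(scen, panel.allele_freqs, np.random.default_rng(22))
    cfg_am = SimulationConfig(n_individuals=2000, n_generations=10, rho_y=0.5)
    cfg_rm = SimulationConfig(n_individuals=2000, n_generations=10, rho_y=0.0)
    am = run_generations(cfg_am, scen, panel, effects=eff, rng=23)
    rm = run_generations(cfg_rm, scen, panel, effects=eff, rng=23)
    v0 = am.diagnostics["var_direct"].iloc[0]
    v_am = am.diagnostics["var_direct"].iloc[-1]
    v_rm = rm.diagnostics["var_direct"].iloc[-1]
    assert v_am > 1.1 * v0
    assert v_am > v_rm
    assert abs(v_rm - v0) < 0.15 * v0


def test_assortment_induces_positive_mate_genotype_correlation():
    """Realized per-locus mate genotype correlation is positive under
    assortment but far below the phenotypic target: the correlation is
    spread over many loci."""
    panel = generate_founders(2000, 100, rng=31)
    scen = EffectScenario.preset("V1", n_causal=50)
    res = run_generations(
        SimulationConfig(n_individuals=2000, n_generations=8, rho_y=0.8),
        scen, panel, rng=32,
    )
    rho_bar = res.diagnostics["mate_rho_bar"].iloc[-1]
    assert 0.0 < rho_bar < 0.2
    assert res.diagnostics["mate_r_y"].iloc[-1] == pytest.approx(0.8, abs=0.05)


def test_homozygosity_rises_under_assortment_matched_seeds():
    panel = generate_founders(2000, 100, rng=41)
    scen = EffectScenario.preset("V1", n_causal=50)
    eff = sample_effects(scen, panel.allele_freqs, np.random.default_rng(42))
    am = run_generations(
        SimulationConfig(n_individuals=2000, n_generations=10, rho_y=0.8),
        scen, panel, effects=eff, rng=43,
    )
    rm = run_generations(
        SimulationConfig(n_individuals=2000, n_generations=10, rho_y=0.0),
        scen, panel, effects=eff, rng=43,
    )
    causal = eff.causal
    het_am = np.mean([(p.dosage[:, causal] == 1).mean() for p in am.history[-3:]])
    het_rm = np.mean([(p.dosage[:, causal] == 1).mean() for p in rm.history[-3:]])
    assert het_am < het_rm


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_individuals=101)
    with pytest.raises(ValueError):
        SimulationConfig(rho_y=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_generations=0)
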