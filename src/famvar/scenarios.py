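"""Effect-size scenarios and sampling.

A scenario names the active effect classes (direct c, maternal m,
paternal f, imprinting i, sibling s), the target population-level
variance contributed by each class, the correlation of effect sizes
across loci between classes, and the environmental variance.

The preset scenarios are:

========  ==========================================================
V1        direct effects only
V2        direct + imprinting (uncorrelated)
V3        direct + maternal + paternal (uncorrelated)
V4        direct + maternal + paternal + imprinting (uncorrelated)
V5        V4 classes with cross-effect correlations
V6        direct correlated with maternal and paternal
========  ==========================================================

Default component variances put the direct variance at 0.5 (the SNP
heritability when no other class is active) with environmental variance
0.5, and indirect/imprinting classes at 0.1 each (0.125 for V6's
parental classes); cross-effect correlations of 0.5 between direct and
parental effects, 0.5 between the two parental classes, and +/-0.25
between parental and imprinting effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EffectScenario", "EffectTable", "sample_effects", "CLASSES"]

CLASSES = ("c", "m", "f", "i", "s")

_V5_CORR = np.array(
    [
        #  c     m     f     i     s
        [1.00, 0.50, 0.50, 0.00, 0.0],
        [0.50, 1.00, 0.50, 0.25, 0.0],
        [0.50, 0.50, 1.00, -0.25, 0.0],
        [0.00, 0.25, -0.25, 1.00, 0.0],
        [0.00, 0.00, 0.00, 0.00, 1.0],
    ]
)

_V6_CORR = np.array(
    [
        [1.00, 0.50, 0.50, 0.0, 0.0],
        [0.50, 1.00, 0.25, 0.0, 0.0],
        [0.50, 0.25, 1.00, 0.0, 0.0],
        [0.00, 0.00, 0.00, 1.0, 0.0],
        [0.00, 0.00, 0.00, 0.0, 1.0],
    ]
)


@dataclass
class EffectScenario:
    """Active effect classes, their target variances and correlations."""

    scenario_id: str
    variances: dict[str, float]  # class -> target population variance
    corr: np.ndarray = field(default=None)  # type: ignore[assignment]  # 5x5 over CLASSES
    n_causal: int = 200
    env_var: float = 0.5

    def __post_init__(self) -> None:
        if self.corr is None:
            self.corr = np.eye(len(CLASSES))
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (5, 5):
            raise ValueError("corr must be 5x5 over (c, m, f, i, s)")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("corr must be symmetric")
        if np.linalg.eigvalsh(self.corr).min() < -1e-9:
            raise ValueError("corr must be positive semidefinite")
        for k, v in self.variances.items():
            if k not in CLASSES:
                raise ValueError(f"unknown effect class {k!r}")
            if v < 0:
                raise ValueError("target variances must be >= 0")
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")
        if self.env_var < 0:
            raise ValueError("env_var must be >= 0")

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(k for k in CLASSES if self.variances.get(k, 0.0) > 0.0)

    def with_sibling(self, variance: float = 0.1, corr_cs: float = 0.3) -> "EffectScenario":
        """Variant of this scenario with indirect sibling effects added.

        ``corr_cs`` is the correlation between direct and sibling effect
        sizes across loci; positive values shrink the sibling-difference
        variance through the -2*beta_c*beta_s term.
        """
        corr = self.corr.copy()
        corr[0, 4] = corr[4, 0] = corr_cs
        variances = dict(self.variances)
        variances["s"] = variance
        return EffectScenario(
            scenario_id=self.scenario_id + "+s",
            variances=variances,
            corr=corr,
            n_causal=self.n_causal,
            env_var=self.env_var,
        )

    @classmethod
    def preset(
        cls, scenario_id: str, n_causal: int = 200, env_var: float = 0.5
    ) -> "EffectScenario":
        presets: dict[str, tuple[dict[str, float], np.ndarray | None]] = {
            "V1": ({"c": 0.5}, None),
            "V2": ({"c": 0.5, "i": 0.1}, None),
            "V3": ({"c": 0.5, "m": 0.1, "f": 0.1}, None),
            "V4": ({"c": 0.5, "m": 0.1, "f": 0.1, "i": 0.1}, None),
            "V5": ({"c": 0.5, "m": 0.1, "f": 0.1, "i": 0.1}, _V5_CORR),
            "V6": ({"c": 0.5, "m": 0.125, "f": 0.125}, _V6_CORR),
        }
        if scenario_id not in presets:
            raise ValueError(f"unknown scenario {scenario_id!r}")
        variances, corr = presets[scenario_id]
        return cls(
            scenario_id=scenario_id,
            variances=variances,
            corr=corr,
            n_causal=n_causal,
            env_var=env_var,
        )


@dataclass
class EffectTable:
    """Sampled per-locus effects: (L, 5) array over CLASSES, zero at
    non-causal loci; ``causal`` holds the causal locus indices."""

    betas: np.ndarray
    causal: np.ndarray

    def column(self, cls_name: str) -> np.ndarray:
        return self.betas[:, CLASSES.index(cls_name)]

    @property
    def causal_betas(self) -> np.ndarray:
        return self.betas[self.causal]


def sample_effects(
    scenario: EffectScenario,
    allele_freqs: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> EffectTable:
    """Draw per-locus effect sizes matching the scenario's targets.

    ``n_causal`` loci are chosen uniformly; the five effect classes are
    drawn jointly normal with the scenario's correlation matrix, scaled
    per locus by 1/sqrt(2 q (1-q)) and then per class so that the
    expected population-level contribution of class k,
    sum_j 2 q_j (1-q_j) beta_kj^2, equals the target variance exactly on
    the supplied (realized) allele frequencies.  Inactive classes are
    exactly zero.
    """
    rng = np.random.default_rng(rng)
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    n_loci = allele_freqs.shape[0]
    if scenario.n_causal > n_loci:
        raise ValueError("n_causal exceeds number of loci")
    causal = np.sort(rng.choice(n_loci, size=scenario.n_causal, replace=False))
    q = allele_freqs[causal]
    het = 2.0 * q * (1.0 - q)

    chol = np.linalg.cholesky(scenario.corr + 1e-12 * np.eye(5))
    raw = rng.standard_normal((scenario.n_causal, 5)) @ chol.T
    raw /= np.sqrt(het)[:, None]

    betas = np.zeros((n_loci, 5))
    for k, name in enumerate(CLASSES):
        target = scenario.variances.get(name, 0.0)
        if target <= 0.0:
            continue
        realized = float(het @ raw[:, k] ** 2)
        betas[causal, k] = raw[:, k] * np.sqrt(target / realized)
    return EffectTable(betas=betas, causal=causal)
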