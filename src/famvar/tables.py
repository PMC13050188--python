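"""Exact enumeration of single-locus mating tables.

The trio table lists every (mother genotype, father genotype, phased
child genotype) combination with the child's phenotype terms and its
probability under random mating (``z``) and under assortative-mating
equilibrium (``z_am``).  The sibling table extends each trio row with a
second, independently transmitted offspring.  Weighted moments over
these tables are the brute-force oracle for every closed-form variance
in :mod:`famvar.model`.

Genotype codes: 0/1/2 copies of allele A2.  A phased child genotype is
the ordered allele pair (maternal, paternal), each 0 or 1 copies of A2.
Parental heterozygotes are unordered and treated interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import LocusParams

__all__ = [
    "MatingTableRow",
    "SiblingTableRow",
    "build_trio_table",
    "build_sibling_table",
    "am_frequency",
    "enumerate_moments",
    "ZAM_PARSES",
    "SELECTED_ZAM_PARSE",
]

# transmissible alleles (copies of A2) per parental genotype
_TRANSMIT = {0: (0,), 1: (0, 1), 2: (1,)}


def _hwe(genotype: int, q2: float) -> float:
    q1 = 1.0 - q2
    return {0: q1 * q1, 1: 2.0 * q1 * q2, 2: q2 * q2}[genotype]


# ---------------------------------------------------------------------------
# assortative-mating row frequencies
#
# Each row's frequency is a product of two bracketed factors.  The first
# bracket is an explicit polynomial in (q1, q2, rho), keyed by the
# unordered parental genotype pair.  The second bracket couples the pair
# frequency to the scale factor S = 2 q1 q2 (1 + rho); its printed form
# is ambiguous between "1 + rho * S * W" and "1 + rho * W / S" (W the
# pair-specific tail).  Both candidate parses are implemented below;
# the one satisfying conservation (sum over rows = 1), reduction to the
# random-mating frequency at rho = 0, allele-frequency invariance in the
# children, and agreement of the enumerated variance with the
# closed-form assortative-mating variance is selected, and that
# selection is asserted by the test-suite.
# ---------------------------------------------------------------------------


def _first_bracket(pair: tuple[int, int], q2: float, rho: float) -> float:
    q1 = 1.0 - q2
    r2 = rho * rho * q1 * q1 * q2 * q2
    if pair == (0, 0):
        return q1**4 + 2 * rho * q1**3 * q2 + r2
    if pair == (0, 1):
        return q1**3 * q2 + rho * q1**2 * q2 * (q2 - q1) - r2
    if pair == (0, 2):
        return q1**2 * q2**2 + rho * q1 * q2 * (q1**2 + q2**2) + r2
    if pair == (1, 1):
        return q1**2 * q2**2 - 2 * rho * q1**2 * q2**2 + r2
    if pair == (1, 2):
        return q1 * q2**3 + rho * q1 * q2**2 * (q1 - q2) - r2
    if pair == (2, 2):
        return q2**4 + 2 * rho * q1 * q2**3 + r2
    raise KeyError(pair)


def _tail(pair: tuple[int, int], q2: float) -> float:
    q1 = 1.0 - q2
    return {
        (0, 0): 4 * q2**2,
        (0, 1): 2 * q2 * (q2 - q1),
        (0, 2): -4 * q1 * q2,
        (1, 1): (q1 - q2) ** 2,
        (1, 2): 2 * q1 * (q1 - q2),
        (2, 2): 4 * q1**2,
    }[pair]


def _second_bracket_product(pair: tuple[int, int], q2: float, rho: float) -> float:
    s = 2.0 * (1.0 - q2) * q2 * (1.0 + rho)
    return 1.0 + rho * s * _tail(pair, q2)


def _second_bracket_ratio(pair: tuple[int, int], q2: float, rho: float) -> float:
    s = 2.0 * (1.0 - q2) * q2 * (1.0 + rho)
    return 1.0 + rho * _tail(pair, q2) / s


ZAM_PARSES = {
    "product": _second_bracket_product,
    "ratio": _second_bracket_ratio,
}

#: The parse satisfying all testable constraints (see module docstring).
SELECTED_ZAM_PARSE = "ratio"


@dataclass(frozen=True)
class MatingTableRow:
    """One trio row: parental genotypes, phased child, phenotype terms, z."""

    x_m: int  # mother genotype, copies of A2
    x_f: int  # father genotype
    a_m: int  # child's maternal allele (0/1 copies of A2)
    a_f: int  # child's paternal allele
    c_c: int  # multiplier of beta_c in Yc  (child dose)
    c_m: int  # multiplier of beta_m        (mother dose)
    c_f: int  # multiplier of beta_f        (father dose)
    c_i: int  # multiplier of beta_i        (+1/-1/0 phase code)
    z: float  # row probability under random mating
    q2: float

    @property
    def x_c(self) -> int:
        return self.a_m + self.a_f

    def y_c(self, locus: LocusParams) -> float:
        return (
            self.c_c * locus.beta_c
            + self.c_m * locus.beta_m
            + self.c_f * locus.beta_f
            + self.c_i * locus.beta_i
        )

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.x_m, self.x_f)))  # type: ignore[return-value]


@dataclass(frozen=True)
class SiblingTableRow:
    """One sibling row: a trio row extended with a second offspring.

    ``fz`` is the Mendelian probability of the sibling's phased genotype
    given the parents; row weight is z * fz (or z_am * fz).
    """

    x_m: int
    x_f: int
    a_m: int
    a_f: int
    s_m: int  # sibling's maternal allele
    s_f: int  # sibling's paternal allele
    z: float
    fz: float
    q2: float

    @property
    def x_c(self) -> int:
        return self.a_m + self.a_f

    @property
    def x_s(self) -> int:
        return self.s_m + self.s_f

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.x_m, self.x_f)))  # type: ignore[return-value]

    def y_c(self, locus: LocusParams) -> float:
        return (
            self.x_c * locus.beta_c
            + self.x_m * locus.beta_m
            + self.x_f * locus.beta_f
            + (self.a_m - self.a_f) * locus.beta_i
            + self.x_s * locus.beta_s
        )

    def y_s(self, locus: LocusParams) -> float:
        return (
            self.x_s * locus.beta_c
            + self.x_m * locus.beta_m
            + self.x_f * locus.beta_f
            + (self.s_m - self.s_f) * locus.beta_i
            + self.x_c * locus.beta_s
        )

    def y_diff(self, locus: LocusParams) -> float:
        return self.y_c(locus) - self.y_s(locus)


def build_trio_table(locus: LocusParams) -> list[MatingTableRow]:
    """Enumerate all 16 (mother, father, phased child) combinations.

    Row probabilities assume Hardy-Weinberg parental frequencies and fair
    Mendelian transmission.
    """
    rows = []
    for x_m in (0, 1, 2):
        for x_f in (0, 1, 2):
            pz = _hwe(x_m, locus.q2) * _hwe(x_f, locus.q2)
            t_m, t_f = _TRANSMIT[x_m], _TRANSMIT[x_f]
            for a_m in t_m:
                for a_f in t_f:
                    rows.append(
                        MatingTableRow(
                            x_m=x_m,
                            x_f=x_f,
                            a_m=a_m,
                            a_f=a_f,
                            c_c=a_m + a_f,
                            c_m=x_m,
                            c_f=x_f,
                            c_i=a_m - a_f,
                            z=pz / (len(t_m) * len(t_f)),
                            q2=locus.q2,
                        )
                    )
    return rows


def build_sibling_table(locus: LocusParams) -> list[SiblingTableRow]:
    """Enumerate all 36 (mother, father, phased child, phased sibling) rows."""
    rows = []
    for trio in build_trio_table(locus):
        t_m, t_f = _TRANSMIT[trio.x_m], _TRANSMIT[trio.x_f]
        for s_m in t_m:
            for s_f in t_f:
                rows.append(
                    SiblingTableRow(
                        x_m=trio.x_m,
                        x_f=trio.x_f,
                        a_m=trio.a_m,
                        a_f=trio.a_f,
                        s_m=s_m,
                        s_f=s_f,
                        z=trio.z,
                        fz=1.0 / (len(t_m) * len(t_f)),
                        q2=locus.q2,
                    )
                )
    return rows


def am_frequency(
    row: MatingTableRow | SiblingTableRow,
    rho: float,
    parse: str = SELECTED_ZAM_PARSE,
) -> float:
    """Row probability under assortative-mating equilibrium.

    Reduces exactly to ``row.z`` at rho = 0.  For a sibling row this is
    the trio-row probability; multiply by ``fz`` for the pair weight.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    bracket2 = ZAM_PARSES[parse](row.pair, row.q2, rho)
    return _first_bracket(row.pair, row.q2, rho) * bracket2


def enumerate_moments(
    table: list[MatingTableRow] | list[SiblingTableRow],
    locus: LocusParams,
    weights: str = "z",
    rho: float = 0.0,
    parse: str = SELECTED_ZAM_PARSE,
) -> tuple[float, float]:
    """Weighted first and second central moments over a mating table.

    For a trio table the moments are of the child phenotype Yc; for a
    sibling table, of the sibling difference Yc - Ys.  ``weights`` is
    ``"z"`` (random mating) or ``"z_am"`` (assortative mating at the
    given ``rho``).  Raises if the chosen weights do not sum to one.
    """
    if weights not in ("z", "z_am"):
        raise ValueError("weights must be 'z' or 'z_am'")
    ws, ys = [], []
    for row in table:
        w = row.z if weights == "z" else am_frequency(row, rho, parse)
        if isinstance(row, SiblingTableRow):
            w *= row.fz
            y = row.y_diff(locus)
        else:
            y = row.y_c(locus)
        ws.append(w)
        ys.append(y)
    total = sum(ws)
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"weights are not normalized (sum = {total!r})")
    mean = sum(w * y for w, y in zip(ws, ys))
    second = sum(w * y * y for w, y in zip(ws, ys))
    return mean, second - mean * mean


def child_allele_frequency(
    table: list[MatingTableRow],
    rho: float = 0.0,
    parse: str = SELECTED_ZAM_PARSE,
) -> float:
    """Marginal A2 frequency among children implied by the row weights.

    Equals q2 for every rho: assortment reshapes genotype frequencies
    but never allele frequencies.
    """
    freq = 0.0
    for row in table:
        w = row.z if rho == 0.0 else am_frequency(row, rho, parse)
        freq += w * row.x_c / 2.0
    return freq
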