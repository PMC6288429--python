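"""Heart-failure microdomain remodeling algebra.

Three fractions describe the remodeling state of a myocyte:

* ``f_TT`` — T-tubule integrity (1.0 intact, 0.0 fully de-tubulated).
  LTCCs, NCX and RyR-LTCC coupling are redistributed in proportion to
  T-tubule loss.
* ``f_B2AR`` — fraction of LTCCs associated with a beta2-adrenergic
  receptor.
* ``f_PDE`` — fraction of LTCCs experiencing phosphodiesterase activity.

Treating the three associations as independent, the product of the state
fractions gives the probability of each LTCC subgroup (A–F).  Channels in
the T-tubular membrane lacking both beta2AR and PDE are physiologically
indistinguishable from subgroup C (never phosphorylated) and are absorbed
into it; likewise F absorbs the surface no-beta2AR/no-PDE channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SUBGROUPS = ("A", "B", "C", "D", "E", "F")

#: Subgroup -> (location, signaling class)
SUBGROUP_INFO = {
    "A": ("t-tubular", "with_PDE"),
    "B": ("t-tubular", "without_PDE"),
    "C": ("t-tubular", "without_B2AR"),
    "D": ("surface", "with_PDE"),
    "E": ("surface", "without_PDE"),
    "F": ("surface", "without_B2AR"),
}


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} = {value} outside [0, 1]")
    return value


@dataclass(frozen=True)
class RemodelingParams:
    """Remodeling state of one myocyte model."""

    f_TT: float = 1.0
    f_B2AR: float = 1.0
    f_PDE: float = 1.0
    stimulated: bool = False

    def __post_init__(self):
        _check_fraction("f_TT", self.f_TT)
        _check_fraction("f_B2AR", self.f_B2AR)
        _check_fraction("f_PDE", self.f_PDE)


@dataclass(frozen=True)
class SubgroupFractions:
    """Weights of the six LTCC subpopulations; always a distribution."""

    wA: float
    wB: float
    wC: float
    wD: float
    wE: float
    wF: float

    def __post_init__(self):
        w = self.as_array()
        if np.any(w < -1e-12):
            raise ValueError("subgroup weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"subgroup weights sum to {w.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.wA, self.wB, self.wC, self.wD, self.wE,
                         self.wF])

    @property
    def t_tubular(self) -> float:
        return self.wA + self.wB + self.wC

    @property
    def surface(self) -> float:
        return self.wD + self.wE + self.wF


def compute_subgroup_fractions(params: RemodelingParams) -> SubgroupFractions:
    """Product-form subgroup probabilities.

    C and F absorb both PDE states of the no-beta2AR channels, so the six
    weights sum to 1 exactly.
    """
    ft, fb, fp = params.f_TT, params.f_B2AR, params.f_PDE
    return SubgroupFractions(
        wA=ft * fb * fp,
        wB=ft * fb * (1.0 - fp),
        wC=ft * (1.0 - fb),
        wD=(1.0 - ft) * fb * fp,
        wE=(1.0 - ft) * fb * (1.0 - fp),
        wF=(1.0 - ft) * (1.0 - fb),
    )


def ncx_distribution(f_TT: float) -> tuple[float, float]:
    """(T-tubular, surface) NCX fractions.

    In the intact cell a fifth of the exchangers face the surface membrane;
    de-tubulation moves a proportional share of the T-tubular exchangers to
    the surface, where they sense the sub-sarcolemmal Ca pool.
    """
    f_TT = _check_fraction("f_TT", f_TT)
    t_tub = 0.8 * f_TT
    surface = 0.2 + 0.8 * (1.0 - f_TT)
    return t_tub, surface


def ryr_coupling(f_TT: float) -> tuple[float, float]:
    """(coupled, orphaned) RyR fractions.

    Coupled RyRs keep their dyadic LTCC partners and are triggered by the
    dyadic Ca current; orphaned RyRs are gated by the bulk cytosolic Ca
    signal and release into the myoplasm.
    """
    f_TT = _check_fraction("f_TT", f_TT)
    return f_TT, 1.0 - f_TT


# ------------------------------------------------------------------
# case presets (Fig.-2-style subgroup weightings)
# ------------------------------------------------------------------

_R3 = 0.8 ** (1.0 / 3.0)          # 0.92832: per-axis fraction, triple product
_R2 = 0.8 ** 0.5                  # 0.89443: per-axis fraction, double product

#: Nominal (f_TT, f_B2AR, f_PDE) of each case, solved so the product-form
#: weight of the dominant subgroup is exactly 0.8.  Parameters that do not
#: enter the dominant weight are neutral (0.5).
CASE_PARAMS = {
    1: (_R3, _R3, _R3),                       # dominant A
    2: (_R3, _R3, 1.0 - _R3),                 # dominant B
    3: (_R2, 1.0 - _R2, 0.5),                 # dominant C
    4: (1.0 - _R3, _R3, _R3),                 # dominant D
    5: (1.0 - _R3, _R3, 1.0 - _R3),           # dominant E
    6: (1.0 - _R2, 1.0 - _R2, 0.5),           # dominant F
}

DOMINANT_SUBGROUP = {1: "A", 2: "B", 3: "C", 4: "D", 5: "E", 6: "F"}


@dataclass(frozen=True)
class CaseDefinition:
    """One of the six canonical subgroup weightings.

    80% of the LTCCs sit in the case's dominant subgroup; the remaining 20%
    are spread over the other five according to their association
    probabilities at the case's nominal remodeling parameters.
    """

    case_id: int
    params: RemodelingParams
    fractions: SubgroupFractions

    def __post_init__(self):
        dom = DOMINANT_SUBGROUP[self.case_id]
        w = getattr(self.fractions, "w" + dom)
        if abs(w - 0.8) > 1e-9:
            raise ValueError(
                f"case {self.case_id}: dominant subgroup {dom} weight is "
                f"{w}, expected 0.8")


def case_definition(case_id: int, stimulated: bool = False) -> CaseDefinition:
    if case_id not in CASE_PARAMS:
        raise ValueError(f"case_id must be 1..6, got {case_id}")
    ft, fb, fp = CASE_PARAMS[case_id]
    params = RemodelingParams(f_TT=ft, f_B2AR=fb, f_PDE=fp,
                              stimulated=stimulated)
    return CaseDefinition(case_id=case_id, params=params,
                          fractions=compute_subgroup_fractions(params))
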