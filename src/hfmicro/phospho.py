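"""Binary-phosphorylation population algebra.

PKA phosphorylation is modeled as a binary, quasi-static property: each
target (the LTCC subgroups and seven further substrates) is split into
phosphorylated / unphosphorylated populations and the whole-cell current is
the weighted sum of the populations' currents.  CaMKII phosphorylation is an
independent binary axis, giving up to four populations per target.

Which fraction of a LTCC subgroup is phosphorylated depends on its signaling
environment:

* channels associated with a beta2-adrenergic receptor and a
  phosphodiesterase (``with_PDE``; subgroups A, D) carry the basal fraction
  (default 25%) at rest and the stimulated fraction (default 75%) under
  sympathetic stimulation;
* channels with a beta2AR but no PDE (``without_PDE``; subgroups B, E) lose
  the cAMP-hydrolyzing brake.  Since PDE activity is itself PKA-driven, its
  absence matters only when PKA is active: these channels carry the basal
  fraction at rest and are fully (100%) phosphorylated under stimulation;
* channels without a beta2AR (``without_B2AR``; subgroups C, F) are never
  phosphorylated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

SUBGROUP_CLASSES = ("with_PDE", "without_PDE", "without_B2AR")

#: Supported phosphorylation targets.
TARGET_IDS = ("LTCC", "RyR", "PLB", "IKs", "INa", "INaK", "IKur", "TnI",
              "INaL")


@dataclass(frozen=True)
class PhosphoConfig:
    """Quasi-static phosphorylation settings."""

    basal_pka_fraction: float = 0.25
    stim_pka_fraction: float = 0.75
    ltcc_amp_factor: float = 2.5
    pka_activation_shift_mv: float = 8.0
    camk_fraction: float = 0.1
    stimulated: bool = False

    def __post_init__(self):
        for name in ("basal_pka_fraction", "stim_pka_fraction",
                     "camk_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} = {val} outside [0, 1]")
        if self.ltcc_amp_factor < 1.0:
            raise ValueError("ltcc_amp_factor must be >= 1")
        if not 0.0 <= self.pka_activation_shift_mv <= 30.0:
            raise ValueError("pka_activation_shift_mv outside [0, 30] mV")

    @property
    def target_fraction(self) -> float:
        """PKA-phosphorylated fraction of the seven non-LTCC targets."""
        return self.stim_pka_fraction if self.stimulated \
            else self.basal_pka_fraction


def pka_fraction(config: PhosphoConfig, subgroup_class: str) -> float:
    """PKA-phosphorylated fraction of an LTCC subgroup class."""
    if subgroup_class == "without_B2AR":
        return 0.0
    if subgroup_class == "without_PDE":
        return 1.0 if config.stimulated else config.basal_pka_fraction
    if subgroup_class == "with_PDE":
        return config.stim_pka_fraction if config.stimulated \
            else config.basal_pka_fraction
    raise ValueError(f"unknown subgroup class: {subgroup_class!r}; "
                     f"expected one of {SUBGROUP_CLASSES}")


@dataclass(frozen=True)
class TargetSplit:
    """Population weights of one target over the PKA x CaMKII axes.

    Weights order: (PKA-/CaMKII-, PKA+/CaMKII-, PKA-/CaMKII+, PKA+/CaMKII+).
    """

    target: str
    weights: tuple

    def __post_init__(self):
        if self.target not in TARGET_IDS:
            raise ValueError(f"unsupported target: {self.target!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) > 4 or len(w) < 1:
            raise ValueError("between 1 and 4 population weights required")
        if np.any(w < 0):
            raise ValueError("population weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"population weights sum to {w.sum()}, not 1")

    @classmethod
    def from_fractions(cls, target: str, pka: float,
                       camk: float = 0.0) -> "TargetSplit":
        """Independent PKA/CaMKII axes -> product weights."""
        return cls(target, ((1 - pka) * (1 - camk), pka * (1 - camk),
                            (1 - pka) * camk, pka * camk))


def population_current(base_current: float, split: TargetSplit,
                       pka_effect: float = 1.0,
                       camk_effect: float = 1.0) -> float:
    """Weighted-sum current over the phosphorylation populations.

    ``pka_effect`` / ``camk_effect`` are the multiplicative effects carried
    by the respective phosphorylated populations; doubly phosphorylated
    channels carry the product (independent processes).
    """
    w = np.asarray(split.weights, dtype=float)
    mults = np.array([1.0, pka_effect, camk_effect,
                      pka_effect * camk_effect])[: len(w)]
    return float(base_current * np.dot(w, mults))


# ------------------------------------------------------------------
# per-target PKA effects (loaded from the constants file)
# ------------------------------------------------------------------

def load_target_effects() -> dict:
    """Per-target PKA effect constants with provenance strings.

    Returns the parsed mapping from ``data/pka_targets.yaml``; each entry
    documents the modified parameter, the multiplier applied to the
    phosphorylated population, and a source citation.
    """
    text = resources.files("hfmicro").joinpath("data/pka_targets.yaml") \
        .read_text()
    return yaml.safe_load(text)


def target_effects(target: str, phosphorylated: bool,
                   table: dict | None = None) -> dict:
    """Parameter modifications for one target.

    Returns a mapping ``{parameter_name: multiplier}``; the identity mapping
    when ``phosphorylated`` is false.
    """
    if table is None:
        table = load_target_effects()
    if target not in TARGET_IDS:
        raise ValueError(f"unsupported target: {target!r}; "
                         f"expected one of {TARGET_IDS}")
    entry = table["targets"].get(target)
    if entry is None:
        raise ValueError(f"no effect entry for target {target!r}")
    effects = entry.get("effects", {})
    if not phosphorylated:
        return {k: 1.0 for k in effects}
    return {k: float(v) for k, v in effects.items()}
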