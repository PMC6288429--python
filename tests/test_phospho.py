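"""Binary-phosphorylation population algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfmicro.phospho import (
    PhosphoConfig, TargetSplit, load_target_effects, pka_fraction,
    population_current, target_effects,
)

BASAL = PhosphoConfig(stimulated=False)
STIM = PhosphoConfig(stimulated=True)


class TestPkaFraction:
    def test_without_b2ar_never_phosphorylated(self):
        assert pka_fraction(BASAL, "without_B2AR") == 0.0
        assert pka_fraction(STIM, "without_B2AR") == 0.0

    def test_without_pde_fully_phosphorylated_under_stimulation(self):
        assert pka_fraction(STIM, "without_PDE") == 1.0

    def test_without_pde_is_basal_at_rest(self):
        # PDE activity is PKA-driven, so its absence is silent at rest
        assert pka_fraction(BASAL, "without_PDE") == BASAL.basal_pka_fraction

    def test_with_pde_tracks_stimulation(self):
        assert pka_fraction(BASAL, "with_PDE") == 0.25
        assert pka_fraction(STIM, "with_PDE") == 0.75

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown subgroup class"):
            pka_fraction(BASAL, "mystery")


class TestPopulationCurrent:
    def test_unphosphorylated_identity(self):
        split = TargetSplit.from_fractions("LTCC", pka=0.0)
        assert population_current(-3.0, split, pka_effect=2.5) == -3.0

    def test_fully_phosphorylated_ltcc_is_2p5x(self):
        split = TargetSplit.from_fractions("LTCC", pka=1.0)
        assert population_current(-3.0, split, pka_effect=2.5) \
            == pytest.approx(-7.5)

    def test_half_split_gives_1p75x(self):
        split = TargetSplit.from_fractions("LTCC", pka=0.5)
        assert population_current(1.0, split, pka_effect=2.5) \
            == pytest.approx(1.75)

    def test_independent_camk_axis_multiplies(self):
        split = TargetSplit.from_fractions("LTCC", pka=1.0, camk=1.0)
        assert population_current(1.0, split, pka_effect=2.5,
                                  camk_effect=1.1) == pytest.approx(2.75)

    @settings(deadline=None, max_examples=50)
    @given(p1=st.floats(0, 1), p2=st.floats(0, 1), lam=st.floats(0, 1),
           base=st.floats(-10, 10))
    def test_current_linear_in_population_weights(self, p1, p2, lam, base):
        """Convex combination of two valid splits gives the convex
        combination of the currents (fixed state)."""
        s1 = TargetSplit.from_fractions("LTCC", pka=p1)
        s2 = TargetSplit.from_fractions("LTCC", pka=p2)
        mix = TargetSplit("LTCC", tuple(
            lam * np.array(s1.weights) + (1 - lam) * np.array(s2.weights)))
        i1 = population_current(base, s1, 2.5)
        i2 = population_current(base, s2, 2.5)
        imix = population_current(base, mix, 2.5)
        assert imix == pytest.approx(lam * i1 + (1 - lam) * i2, abs=1e-9)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            TargetSplit("LTCC", (-0.1, 1.1))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            TargetSplit("LTCC", (0.5, 0.4))


class TestTargetEffects:
    def test_unphosphorylated_identity(self):
        for target in ("LTCC", "PLB", "IKs"):
            assert all(v == 1.0
                       for v in target_effects(target, False).values())

    def test_ltcc_amplitude_factor(self):
        assert target_effects("LTCC", True)["amplitude"] == 2.5

    def test_plb_modifies_serca_affinity(self):
        eff = target_effects("PLB", True)
        assert 0 < eff["serca_km"] < 1

    def test_unsupported_target_rejected(self):
        with pytest.raises(ValueError, match="unsupported target"):
            target_effects("IKr", True)

    def test_constants_file_carries_citations(self):
        table = load_target_effects()
        for name, entry in table["targets"].items():
            assert entry.get("source"), f"{name} lacks a source citation"


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="basal_pka_fraction"):
            PhosphoConfig(basal_pka_fraction=1.2)

    def test_amp_factor_lower_bound(self):
        with pytest.raises(ValueError, match="ltcc_amp_factor"):
            PhosphoConfig(ltcc_amp_factor=0.5)
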