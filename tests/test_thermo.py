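"""Two-state unfolding model, ligand shifts, and scan simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfdp import (
    Emission,
    LigandModifier,
    MixtureSpec,
    ProteinSpecies,
    apply_ligands,
    fraction_unfolded,
    ligand_library,
    mixture_preset,
    simulate_scan,
    single_species_mixture,
    six_curves,
    species_library,
)
from tfdp.errors import ConfigurationError, InvalidInputError
from tfdp.features import detect_peaks
from tests.conftest import TM_BY_SPECIES, detected_tm

HSA600 = ProteinSpecies("HSA", 75.1, dh_vanthoff=600.0)

# Independent arbitrary-precision evaluation (sympy, 20 digits) of
# 1/(1+exp(dG/(R T))) at T = Tm - 2 degC, dH = 600 kJ/mol, Tm = 75.1 degC.
F_U_TM_MINUS_2 = 0.23202307869421037230


class TestFractionUnfolded:
    def test_midpoint_is_half(self):
        for sp in species_library().values():
            assert fraction_unfolded(sp.tm_celsius, sp) == pytest.approx(0.5, abs=1e-12)

    def test_saturation_far_above_tm(self):
        assert fraction_unfolded(HSA600.tm_celsius + 60.0, HSA600) >= 0.999

    def test_closed_form_against_high_precision_oracle(self):
        assert fraction_unfolded(73.1, HSA600) == pytest.approx(F_U_TM_MINUS_2, abs=1e-12)

    def test_non_finite_temperature_rejected(self):
        with pytest.raises(InvalidInputError):
            fraction_unfolded(float("nan"), HSA600)

    @given(st.floats(min_value=20.0, max_value=110.0), st.floats(min_value=20.0, max_value=110.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_temperature(self, t_a, t_b):
        lo, hi = sorted((t_a, t_b))
        assert fraction_unfolded(lo, HSA600) <= fraction_unfolded(hi, HSA600) + 1e-15


class TestLigands:
    def test_myristate_shifts_hsa_and_lyz_only(self):
        mix = apply_ligands(mixture_preset("CONTROL", ligands=["MYRISTATE"]))
        tms = {sp.name: sp.tm_celsius for sp, _ in mix.components}
        assert tms["HSA"] == 80.3 and tms["LYZ"] == 55.6
        for other in ("LCN1", "IGA", "LTF"):
            assert tms[other] == TM_BY_SPECIES[other]

    def test_latanoprost_is_identity(self):
        base = mixture_preset("CONTROL")
        treated = apply_ligands(mixture_preset("CONTROL", ligands=["LATANOPROST"]))
        assert [(sp.tm_celsius, c) for sp, c in treated.components] == [
            (sp.tm_celsius, c) for sp, c in base.components
        ]

    def test_ferric_iron_shifts_ltf_only(self):
        mix = apply_ligands(mixture_preset("CONTROL", ligands=["FE3"]))
        tms = {sp.name: sp.tm_celsius for sp, _ in mix.components}
        assert tms["LTF"] == 95.0
        assert all(tms[n] == TM_BY_SPECIES[n] for n in ("HSA", "LYZ", "LCN1", "IGA"))

    def test_absolute_replacement_is_idempotent(self):
        once = apply_ligands(mixture_preset("CONTROL", ligands=["MYRISTATE"]))
        twice = apply_ligands(
            MixtureSpec(once.components, (ligand_library()["MYRISTATE"],), name="again")
        )
        assert [sp.tm_celsius for sp, _ in twice.components] == [
            sp.tm_celsius for sp, _ in once.components
        ]

    def test_unknown_species_in_shift_table_rejected(self):
        bad = LigandModifier("X", set_tm={"NOT_A_PROTEIN": 80.0})
        mix = MixtureSpec(mixture_preset("CONTROL").components, (bad,))
        with pytest.raises(ConfigurationError):
            apply_ligands(mix)


class TestSimulateScan:
    def test_seeded_determinism_bit_identical(self):
        mix = mixture_preset("CONTROL")
        a = simulate_scan(mix, noise_sigma_rel=0.002, seed=123)
        b = simulate_scan(mix, noise_sigma_rel=0.002, seed=123)
        assert np.array_equal(a.f330, b.f330) and np.array_equal(a.f350, b.f350)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_scan(mixture_preset("CONTROL"), noise_sigma_rel=-0.1)

    def test_empty_mixture_rejected(self):
        with pytest.raises(InvalidInputError):
            MixtureSpec(components=())
        sp = species_library()["HSA"]
        with pytest.raises(InvalidInputError):
            MixtureSpec(components=((sp, 0.0),))

    def test_mixture_superposition_exact(self):
        """Channel signals of a mixture equal the sum of the single-species signals."""
        mix = mixture_preset("CONTROL")
        whole = simulate_scan(mix, noise_sigma_rel=0.0)
        f330 = np.zeros_like(whole.f330)
        f350 = np.zeros_like(whole.f350)
        for sp, conc in mix.components:
            part = simulate_scan(
                MixtureSpec(((sp, conc),), name=sp.name), noise_sigma_rel=0.0
            )
            f330 += part.f330
            f350 += part.f350
        np.testing.assert_allclose(whole.f330, f330, rtol=1e-12)
        np.testing.assert_allclose(whole.f350, f350, rtol=1e-12)

    def test_ratio_concentration_invariance(self):
        """F350/F330 of a single species is independent of its concentration."""
        lo = simulate_scan(single_species_mixture("LYZ", 10.0), noise_sigma_rel=0.0)
        hi = simulate_scan(single_species_mixture("LYZ", 500.0), noise_sigma_rel=0.0)
        np.testing.assert_allclose(lo.ratio, hi.ratio, rtol=1e-13)

    def test_single_species_ratio_monotone(self):
        run = simulate_scan(single_species_mixture("HSA"), noise_sigma_rel=0.0)
        assert np.all(np.diff(run.ratio) >= -1e-14)

    def test_contrast_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            Emission(d330=-0.2, d350=0.2)  # above the 5% cap
        with pytest.raises(InvalidInputError):
            Emission(d330=0.01, d350=0.01)  # wrong sign: no red shift


class TestRoundTripFidelity:
    """Derivative apex of the simulated ratio recovers the model Tm to 0.1 degC."""

    @pytest.mark.parametrize("name", sorted(TM_BY_SPECIES))
    def test_single_species(self, name):
        got, pk = detected_tm(name)
        assert got == pytest.approx(TM_BY_SPECIES[name], abs=0.1)
        assert pk.n_raw_peaks == 1

    @pytest.mark.parametrize(
        "name, ligand, expected",
        [("HSA", "MYRISTATE", 80.3), ("LYZ", "MYRISTATE", 55.6)],
    )
    def test_ligand_shifted_species(self, name, ligand, expected):
        got, _ = detected_tm(name, ligands=[ligand])
        assert got == pytest.approx(expected, abs=0.1)

    def test_fe3_ltf_boundary_censored_at_scan_limit(self):
        got, pk = detected_tm("LTF", ligands=["FE3"])
        assert got == 95.0 and pk.censored2

    def test_control_preset_two_peaks(self, control_two_peak):
        pk = control_two_peak
        assert pk.complete and pk.n_raw_peaks == 2
        assert not (pk.censored1 or pk.censored2)
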