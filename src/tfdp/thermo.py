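"""Mechanistic forward simulator of nanoDSF melting scans.

Each protein is a reversible two-state unfolder with a van't Hoff free energy
``dG(T) = dH_vH * (1 - T/Tm)`` (temperatures in kelvin), so the unfolded
fraction is a logistic function of temperature with midpoint Tm and sharpness
set by dH_vH.  Unfolding red-shifts intrinsic tryptophan emission: the 350 nm
channel gains intensity and the 330 nm channel loses it, so the ratio
F350/F330 rises through a transition and its temperature derivative peaks at
(very nearly) Tm.

A mixture's channel signal is the concentration-weighted superposition of its
components' signals; this linear model deliberately has no protein-protein
interaction terms, so mixture peaks always lie within the span of component
Tms.  Ligand binding (myristic acid on HSA and LYZ, Fe3+ on lactotransferrin)
is modelled as saturating: the bound species simply carries a replaced or
shifted Tm.

The per-species contrast is kept small (|d_lambda|/a_lambda = 1% by default).
The ratio of two affine functions of the unfolded fraction is a Moebius
transform, whose derivative apex sits ~2*|d|/ (dH_vH / (R*Tm^2)) above Tm;
at 1% contrast and dH_vH = 800 kJ/mol this bias is ~0.025 degC, comfortably
below the 0.1 degC reporting resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, InvalidInputError
from .io import DEFAULT_GRID, NanoDSFRun, TemperatureGrid

__all__ = [
    "GAS_CONSTANT_KJ",
    "CELSIUS_OFFSET",
    "Emission",
    "ProteinSpecies",
    "LigandModifier",
    "MixtureSpec",
    "fraction_unfolded",
    "apply_ligands",
    "simulate_scan",
    "species_library",
    "ligand_library",
    "mixture_preset",
]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ / (mol K)
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class Emission:
    """Per-wavelength emission model of one species.

    ``a330``/``a350`` are mean signals per unit concentration (RFU per ug/mL);
    ``d330``/``d350`` the folded-to-unfolded contrast on the same scale (the
    signal moves from ``a - d`` to ``a + d`` through the transition); the
    baseline slopes are linear temperature drifts (fraction per degC,
    referenced to 35 degC).
    """

    a330: float = 1.0
    a350: float = 1.0
    d330: float = -0.01
    d350: float = 0.01
    baseline_slope_330: float = 0.0
    baseline_slope_350: float = 0.0

    def __post_init__(self) -> None:
        if self.a330 <= 0 or self.a350 <= 0:
            raise InvalidInputError("mean emission coefficients must be positive")
        if abs(self.d330) / self.a330 > 0.05 or abs(self.d350) / self.a350 > 0.05:
            raise InvalidInputError("contrast |d|/a must not exceed 5% (low-contrast regime)")
        if not (self.d350 > 0 > self.d330):
            raise InvalidInputError("unfolding must red-shift emission: d350 > 0 > d330")


@dataclass(frozen=True)
class ProteinSpecies:
    """Thermodynamic and emission parameters of one two-state unfolder."""

    name: str
    tm_celsius: float
    dh_vanthoff: float = 800.0  # kJ/mol
    emission: Emission = field(default_factory=Emission)

    def __post_init__(self) -> None:
        if not np.isfinite(self.tm_celsius) or not (20.0 <= self.tm_celsius <= 110.0):
            raise InvalidInputError(f"{self.name}: Tm {self.tm_celsius} degC outside [20, 110]")
        if not np.isfinite(self.dh_vanthoff) or self.dh_vanthoff <= 0:
            raise InvalidInputError(f"{self.name}: van't Hoff enthalpy must be positive")


@dataclass(frozen=True)
class LigandModifier:
    """A bound ligand's effect on species melting temperatures.

    ``set_tm`` maps species name -> absolute replacement Tm (degC);
    ``delta_tm`` maps species name -> additive shift (degC).  Species absent
    from both maps are unaffected.
    """

    ligand: str
    set_tm: Mapping[str, float] = field(default_factory=dict)
    delta_tm: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MixtureSpec:
    """A named set of (species, concentration ug/mL) pairs plus ligand state."""

    components: tuple[tuple[ProteinSpecies, float], ...]
    ligands: tuple[LigandModifier, ...] = ()
    name: str = "mixture"

    def __post_init__(self) -> None:
        if not self.components:
            raise InvalidInputError("mixture needs at least one component")
        for sp, conc in self.components:
            if not np.isfinite(conc) or conc < 0:
                raise InvalidInputError(f"{sp.name}: concentration must be finite and >= 0")
        if not any(conc > 0 for _, conc in self.components):
            raise InvalidInputError("mixture needs at least one component with concentration > 0")

    def species_names(self) -> list[str]:
        return [sp.name for sp, _ in self.components]


# ---------------------------------------------------------------------------
# The two-state model
# ---------------------------------------------------------------------------

def fraction_unfolded(t: float | np.ndarray, species: ProteinSpecies) -> float | np.ndarray:
    """Equilibrium unfolded fraction of ``species`` at temperature ``t`` (degC).

    f_U(T) = 1 / (1 + exp(dG(T) / (R T_K))) with dG(T) = dH_vH (1 - T_K/Tm_K);
    monotonically non-decreasing in T, and exactly 1/2 at T = Tm.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise InvalidInputError("temperature must be finite")
    t_k = t_arr + CELSIUS_OFFSET
    tm_k = species.tm_celsius + CELSIUS_OFFSET
    dg = species.dh_vanthoff * (1.0 - t_k / tm_k)
    out = expit(-dg / (GAS_CONSTANT_KJ * t_k))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def apply_ligands(mixture: MixtureSpec) -> MixtureSpec:
    """Return the mixture with all ligand-induced Tm changes applied.

    Absolute replacements are idempotent; concentrations are untouched.
    A shift table naming a species not present in the mixture is a
    :class:`ConfigurationError`.
    """
    known = set(mixture.species_names())
    species_by_name = {sp.name: sp for sp, _ in mixture.components}
    for lig in mixture.ligands:
        for target in list(lig.set_tm) + list(lig.delta_tm):
            if target not in known:
                raise ConfigurationError(
                    f"ligand {lig.ligand!r} references unknown species {target!r}"
                )
        for target, tm in lig.set_tm.items():
            species_by_name[target] = replace(species_by_name[target], tm_celsius=float(tm))
        for target, dtm in lig.delta_tm.items():
            sp = species_by_name[target]
            species_by_name[target] = replace(sp, tm_celsius=sp.tm_celsius + float(dtm))
    new_components = tuple(
        (species_by_name[sp.name], conc) for sp, conc in mixture.components
    )
    return replace(mixture, components=new_components, ligands=())


def _channel_signal(mixture: MixtureSpec, t: np.ndarray, wavelength: int) -> np.ndarray:
    total = np.zeros_like(t)
    for sp, conc in mixture.components:
        if conc == 0:
            continue
        em = sp.emission
        if wavelength == 330:
            a, d, slope = em.a330, em.d330, em.baseline_slope_330
        else:
            a, d, slope = em.a350, em.d350, em.baseline_slope_350
        x = 2.0 * fraction_unfolded(t, sp) - 1.0
        total += conc * (1.0 + slope * (t - 35.0)) * (a + d * x)
    return total


def simulate_scan(
    mixture: MixtureSpec,
    grid: TemperatureGrid = DEFAULT_GRID,
    noise_sigma_rel: float = 0.002,
    seed: int | np.random.Generator | None = None,
) -> NanoDSFRun:
    """Simulate one nanoDSF scan of ``mixture`` on ``grid``.

    Ligands are applied first.  Each channel is the linear superposition of
    component signals; multiplicative Gaussian noise ``(1 + sigma_rel * eps)``
    is then applied independently per point and per channel.  With
    ``noise_sigma_rel = 0`` the output is deterministic.
    """
    if not np.isfinite(noise_sigma_rel) or noise_sigma_rel < 0:
        raise InvalidInputError("noise_sigma_rel must be >= 0")
    resolved = apply_ligands(mixture)
    t = grid.values
    f330 = _channel_signal(resolved, t, 330)
    f350 = _channel_signal(resolved, t, 350)
    if noise_sigma_rel > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        f330 = f330 * (1.0 + noise_sigma_rel * rng.standard_normal(t.shape))
        f350 = f350 * (1.0 + noise_sigma_rel * rng.standard_normal(t.shape))
    if np.any(f330 <= 0) or np.any(f350 <= 0):
        raise InvalidInputError("simulated channel signal became non-positive; lower the noise")
    return NanoDSFRun(
        sample_id=resolved.name,
        temperatures=t.copy(),
        f330=f330,
        f350=f350,
        meta={"simulated": True, "noise_sigma_rel": noise_sigma_rel},
    )


# ---------------------------------------------------------------------------
# Shipped species / ligand / mixture library
# ---------------------------------------------------------------------------

def _load_library() -> dict:
    with resources.files("tfdp.data").joinpath("species.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)


def species_library() -> dict[str, ProteinSpecies]:
    """The five core tear proteins with their measured Tms and default model parameters."""
    lib = _load_library()
    em = Emission(**lib["emission_defaults"])
    dh = float(lib["dh_vanthoff_default"])
    return {
        name: ProteinSpecies(name=name, tm_celsius=float(entry["tm_celsius"]), dh_vanthoff=dh, emission=em)
        for name, entry in lib["species"].items()
    }


def ligand_library() -> dict[str, LigandModifier]:
    """Ligand modifiers at saturating concentration (myristate, Fe3+, latanoprost)."""
    lib = _load_library()
    return {
        name: LigandModifier(ligand=name, set_tm=entry.get("set", {}), delta_tm=entry.get("delta", {}))
        for name, entry in lib["ligands"].items()
    }


def mixture_preset(name: str, ligands: Sequence[str | LigandModifier] = ()) -> MixtureSpec:
    """A named tear-protein mixture preset (``"CONTROL"`` or ``"POAG"``).

    CONTROL mimics healthy tear composition (140 ug/mL HSA, 110 LTF, 50 LYZ,
    30 IgA, 100 LCN1); POAG the glaucomatous one (110/150/30/30/60).
    Optional ligands are attached by name or as modifier objects.
    """
    lib = _load_library()
    if name not in lib["mixtures"]:
        raise ConfigurationError(f"unknown mixture preset {name!r}; options: {sorted(lib['mixtures'])}")
    species = species_library()
    lig_lib = ligand_library()
    resolved_ligands = []
    for lig in ligands:
        if isinstance(lig, LigandModifier):
            resolved_ligands.append(lig)
        elif lig in lig_lib:
            resolved_ligands.append(lig_lib[lig])
        else:
            raise ConfigurationError(f"unknown ligand {lig!r}; options: {sorted(lig_lib)}")
    components = tuple(
        (species[sp_name], float(conc)) for sp_name, conc in lib["mixtures"][name].items()
    )
    return MixtureSpec(components=components, ligands=tuple(resolved_ligands), name=name)


def single_species_mixture(
    name: str, concentration: float = 100.0, ligands: Sequence[str | LigandModifier] = ()
) -> MixtureSpec:
    """Convenience: a one-component mixture of a library species."""
    species = species_library()
    if name not in species:
        raise ConfigurationError(f"unknown species {name!r}; options: {sorted(species)}")
    lig_lib = ligand_library()
    resolved = tuple(
        lig if isinstance(lig, LigandModifier) else lig_lib[lig] for lig in ligands
    )
    # drop shift entries for species absent from this single-protein sample
    pruned = tuple(
        LigandModifier(
            ligand=l.ligand,
            set_tm={k: v for k, v in l.set_tm.items() if k == name},
            delta_tm={k: v for k, v in l.delta_tm.items() if k == name},
        )
        for l in resolved
    )
    return MixtureSpec(components=((species[name], float(concentration)),), ligands=pruned, name=name)
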