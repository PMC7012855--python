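"""Media as elemental compositions and their derived composite quantities.

A :class:`Material` is a named elemental mixture (atomic fractions) with a
bulk density.  From it the module derives mass fractions, electron fractions,
the Mayneord power-law effective atomic number Z_eff, the Bragg-additivity
mean excitation energy I, and the electron density — the inputs the
stopping-power formulas need.

Elemental constants (Z, standard atomic weight, in-compound mean excitation
energy) ship as a versioned text fixture; a registry of the study materials
(film active layers and whole films, water, aluminium, PMMA) ships alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ElementFraction",
    "Material",
    "ELEMENTS",
    "atomic_to_mass_fractions",
    "electron_fractions",
    "effective_atomic_number",
    "mean_excitation_energy",
    "electron_density",
    "get_material",
    "available_materials",
    "FIXTURE_VERSIONS",
]

_AVOGADRO = 6.02214076e23  # 1/mol


def _load_elements() -> dict:
    table = {}
    text = resources.files("letfilm.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, z, a, i_ev = line.split("\t")
        table[sym] = {"Z": int(z), "A": float(a), "I_eV": float(i_ev)}
    return table


#: Elemental constants keyed by chemical symbol: Z, A (g/mol), I (eV).
ELEMENTS: dict = _load_elements()

FIXTURE_VERSIONS = {
    "elements": "1",
    "materials": "1",
}


def _element(symbol: str) -> dict:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise ConfigurationError(
            f"unknown element symbol {symbol!r}; known: {sorted(ELEMENTS)}"
        ) from None


@dataclass(frozen=True)
class ElementFraction:
    """One constituent of a composition: chemical symbol + atomic fraction."""

    element: str
    atomic_fraction: float

    def __post_init__(self):
        _element(self.element)
        if self.atomic_fraction < 0:
            raise ConfigurationError(
                f"atomic fraction of {self.element} is negative"
            )


def _normalize(composition: list[ElementFraction]) -> list[ElementFraction]:
    """Merge duplicate elements and rescale fractions to sum to 1."""
    if not composition:
        raise ConfigurationError("composition is empty")
    merged: dict[str, float] = {}
    for ef in composition:
        merged[ef.element] = merged.get(ef.element, 0.0) + ef.atomic_fraction
    total = sum(merged.values())
    if total <= 0:
        raise ConfigurationError("composition has zero total fraction")
    return [
        ElementFraction(sym, frac / total)
        for sym, frac in merged.items()
        if frac > 0
    ]


@dataclass(frozen=True)
class Material:
    """A named medium: elemental composition, bulk density, optional I."""

    name: str
    composition: list[ElementFraction]
    density: float  # g/cm^3
    I_override: float | None = None  # eV

    def __post_init__(self):
        if not np.isfinite(self.density) or self.density <= 0:
            raise ConfigurationError(
                f"material {self.name!r}: density must be finite and > 0"
            )
        object.__setattr__(self, "composition", _normalize(self.composition))

    @property
    def mass_fractions(self) -> dict[str, float]:
        return atomic_to_mass_fractions(self.composition)

    @property
    def z_eff(self) -> float:
        return effective_atomic_number(self.composition)

    @property
    def I_eV(self) -> float:
        return mean_excitation_energy(self)

    @property
    def electrons_per_gram(self) -> float:
        return electron_density(self)


def atomic_to_mass_fractions(
    composition: list[ElementFraction],
) -> dict[str, float]:
    """Convert atomic fractions to mass fractions, w_i = f_i A_i / sum f_j A_j."""
    comp = _normalize(composition)
    weights = {ef.element: ef.atomic_fraction * _element(ef.element)["A"] for ef in comp}
    total = sum(weights.values())
    return {sym: w / total for sym, w in weights.items()}


def electron_fractions(composition: list[ElementFraction]) -> dict[str, float]:
    """Fraction of the electrons contributed by each element, f_i Z_i / sum f_j Z_j."""
    comp = _normalize(composition)
    weights = {ef.element: ef.atomic_fraction * _element(ef.element)["Z"] for ef in comp}
    total = sum(weights.values())
    return {sym: w / total for sym, w in weights.items()}


def effective_atomic_number(
    composition: list[ElementFraction], exponent: float = 2.94
) -> float:
    """Mayneord power-law effective atomic number.

    Z_eff = (sum_i alpha_i Z_i^m)^(1/m) with alpha_i the electron fraction of
    element i and m the photoelectric-regime exponent (default 2.94).
    """
    alphas = electron_fractions(composition)
    s = sum(alpha * _element(sym)["Z"] ** exponent for sym, alpha in alphas.items())
    return float(s ** (1.0 / exponent))


def mean_excitation_energy(material: Material) -> float:
    """Mean excitation energy I (eV) by Bragg additivity.

    ln I = sum_i w_i (Z_i/A_i) ln I_i / sum_i w_i (Z_i/A_i).  An I_override on
    the material short-circuits the mixture rule (used for compounds with a
    standard recommended value such as water).
    """
    if material.I_override is not None:
        if material.I_override <= 0:
            raise ConfigurationError("I_override must be positive")
        return float(material.I_override)
    num = 0.0
    den = 0.0
    for sym, w in material.mass_fractions.items():
        el = _element(sym)
        zi_ai = w * el["Z"] / el["A"]
        num += zi_ai * np.log(el["I_eV"])
        den += zi_ai
    return float(np.exp(num / den))


def electron_density(material: Material) -> float:
    """Electrons per gram, N_A sum_i w_i Z_i / A_i."""
    return _AVOGADRO * sum(
        w * _element(sym)["Z"] / _element(sym)["A"]
        for sym, w in material.mass_fractions.items()
    )


# ---------------------------------------------------------------------------
# bundled registry

def _load_registry() -> dict:
    text = resources.files("letfilm.data").joinpath("materials.json").read_text()
    raw = json.loads(text)["materials"]
    registry = {}
    for name, rec in raw.items():
        comp = [ElementFraction(sym, f) for sym, f in rec["composition"].items() if f > 0]
        registry[name] = Material(
            name=name,
            composition=comp,
            density=rec["density"],
            I_override=rec.get("I_override"),
        )
    return registry


_REGISTRY: dict[str, Material] | None = None


def _registry() -> dict[str, Material]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return _REGISTRY


def available_materials() -> list[str]:
    return sorted(_registry())


def get_material(name: str, density: float | None = None) -> Material:
    """Fetch a bundled material by name, optionally overriding its density."""
    try:
        mat = _registry()[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown material {name!r}; known: {available_materials()}"
        ) from None
    if density is not None:
        mat = Material(mat.name, list(mat.composition), density, mat.I_override)
    return mat
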