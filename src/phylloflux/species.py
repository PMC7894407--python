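"""Shared species registry.

Per-compound physical constants used across the package: molar mass,
effective Henry's law constant H* (M atm^-1, including hydration
equilibria), the Wesely surface-reactivity factor f0, the number of
carbon atoms (used by the leaf box model's atom-conserving bookkeeping),
and the in-leaf conversion map (product species with molar yields).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SpeciesProperties:
    """Physical and chemical constants for one trace gas.

    Parameters
    ----------
    name : canonical identifier (lowercase, underscore-separated).
    molar_mass : g mol^-1.
    henry_eff : effective Henry constant H*, M atm^-1.
    f0 : Wesely reactivity factor in [0, 1] (ozone-like surface
        reactivity; scales the non-stomatal surface resistances).
    n_carbon : carbon atoms per molecule.
    conversion_products : ((product name, molar yield), ...) describing
        the in-leaf conversion of a deposited molecule.
    """

    name: str
    molar_mass: float
    henry_eff: float
    f0: float = 0.0
    n_carbon: int = 0
    conversion_products: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if self.henry_eff <= 0:
            raise ValueError(f"{self.name}: henry_eff must be > 0")
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError(f"{self.name}: f0 must lie in [0, 1]")
        for product, y in self.conversion_products:
            if not 0.0 <= y <= 1.0:
                raise ValueError(f"{self.name} -> {product}: yield {y} outside [0, 1]")
        total = sum(y for _, y in self.conversion_products)
        if total > 1.0 + 1e-12:
            raise ValueError(f"{self.name}: conversion yields sum to {total} > 1")


# Defaults. H* for 1,2-ISOPOOH / MVK / MEK are the effective-solubility
# values used by the deposition scheme; isoprene and MACR carry literature
# Henry constants and play no role in the liquid-phase model.
_DEFAULTS = (
    SpeciesProperties("isopooh_12", 118.13, 1.7e6, f0=1.0, n_carbon=5,
                      conversion_products=(("mvk", 0.5), ("mek", 0.5))),
    SpeciesProperties("isopooh_43", 118.13, 1.7e6, f0=1.0, n_carbon=5,
                      conversion_products=(("macr", 1.0),)),
    SpeciesProperties("mvk", 70.09, 44.0, f0=1.0, n_carbon=4,
                      conversion_products=(("mek", 1.0),)),
    SpeciesProperties("mek", 72.11, 21.0, f0=0.0, n_carbon=4),
    SpeciesProperties("macr", 70.09, 6.5, f0=0.0, n_carbon=4),
    SpeciesProperties("isoprene", 68.12, 1.3e-2, f0=0.0, n_carbon=5),
    SpeciesProperties("hcho", 30.03, 3.2e3, f0=0.0, n_carbon=1),
)

_ALIASES = {
    "1,2-isopooh": "isopooh_12",
    "4,3-isopooh": "isopooh_43",
    "isopooh": "isopooh_12",
    "formaldehyde": "hcho",
}


class SpeciesRegistry:
    """Lookup table of :class:`SpeciesProperties`, with aliases."""

    def __init__(self, species: tuple[SpeciesProperties, ...] = _DEFAULTS):
        self._table = {s.name: s for s in species}

    def __contains__(self, name: str) -> bool:
        key = name.lower()
        return key in self._table or key in _ALIASES

    def __getitem__(self, name: str) -> SpeciesProperties:
        key = name.lower()
        key = _ALIASES.get(key, key)
        try:
            return self._table[key]
        except KeyError:
            raise KeyError(f"unknown species {name!r}; known: {sorted(self._table)}") from None

    def names(self) -> list[str]:
        return sorted(self._table)

    def add(self, props: SpeciesProperties) -> None:
        self._table[props.name] = props


#: Module-level default registry.
REGISTRY = SpeciesRegistry()
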