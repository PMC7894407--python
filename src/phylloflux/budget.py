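"""Global MEK budget closure.

Deposited MVK and 1,2-ISOPOOH are converted in leaves and re-emitted as
MEK.  The accounting is molar: a deposited mass D_p (Tg yr^-1) of parent
p contributes

    mek_from_p = D_p / M_p * yield_p * M_MEK      [Tg yr^-1]

and the total source is expressed as a fraction of the isoprene
emission, on both a molar basis

    f_molar = (mek_source / M_MEK) / (E_isoprene / M_isoprene) * 100

and a mass basis (mek_source / E_isoprene * 100).  Both are reported so
the basis of any quoted recycling percentage is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .species import REGISTRY, SpeciesRegistry


@dataclass(frozen=True)
class BudgetInputs:
    """Annual deposition totals, conversion yields and the isoprene
    emission against which the MEK source is expressed."""

    dep_mvk: float                    # Tg yr^-1
    dep_isopooh: float                # Tg yr^-1
    yield_mvk_to_mek: float = 1.0     # molar fraction
    yield_isopooh_to_mek: float = 0.5
    isoprene_emission: float = 416.0  # Tg yr^-1

    def __post_init__(self) -> None:
        if self.dep_mvk < 0 or self.dep_isopooh < 0:
            raise ValueError("deposition masses must be >= 0")
        for y in (self.yield_mvk_to_mek, self.yield_isopooh_to_mek):
            if not 0.0 <= y <= 1.0:
                raise ValueError("yields must lie in [0, 1]")
        if self.isoprene_emission < 0:
            raise ValueError("isoprene emission must be >= 0")


@dataclass(frozen=True)
class BudgetResult:
    mek_source: float                 # Tg yr^-1
    mek_from_mvk: float
    mek_from_isopooh: float
    isoprene_fraction_molar: float    # percent
    isoprene_fraction_mass: float     # percent
    fractions_defined: bool = True
    label: str = "central"


def mek_source(inputs: BudgetInputs, registry: SpeciesRegistry = REGISTRY,
               label: str = "central") -> BudgetResult:
    """Close the MEK budget for one set of deposition totals."""
    m_mek = registry["mek"].molar_mass
    from_mvk = inputs.dep_mvk / registry["mvk"].molar_mass * inputs.yield_mvk_to_mek * m_mek
    from_iso = (inputs.dep_isopooh / registry["isopooh_12"].molar_mass
                * inputs.yield_isopooh_to_mek * m_mek)
    total = from_mvk + from_iso
    if inputs.isoprene_emission > 0:
        molar = (total / m_mek) / (inputs.isoprene_emission
                                   / registry["isoprene"].molar_mass) * 100.0
        mass = total / inputs.isoprene_emission * 100.0
        defined = True
    else:
        molar = mass = float("nan")
        defined = False
    return BudgetResult(total, from_mvk, from_iso, molar, mass, defined, label)


def scenario_bounds(inputs: BudgetInputs,
                    scenarios: dict[str, tuple[float, float]],
                    registry: SpeciesRegistry = REGISTRY) -> list[BudgetResult]:
    """Budget under alternative deposition totals.

    ``scenarios`` maps a label (e.g. ``lower``/``central``/``upper``) to
    (dep_mvk, dep_isopooh) totals; yields and the isoprene emission are
    shared from ``inputs``.
    """
    results = []
    for label, (dep_mvk, dep_iso) in scenarios.items():
        alt = replace(inputs, dep_mvk=dep_mvk, dep_isopooh=dep_iso)
        results.append(mek_source(alt, registry, label=label))
    return results


def grid_budget(fields: pd.DataFrame, inputs: BudgetInputs,
                registry: SpeciesRegistry = REGISTRY,
                ) -> tuple[BudgetResult, pd.DataFrame]:
    """Cell-wise budget on gridded deposition fields.

    ``fields`` needs columns ``lat, lon, dep_mvk, dep_isopooh`` (Tg yr^-1
    per cell).  Returns the global result on the field totals and the
    per-cell MEK source field; by linearity the global sum of the cell
    field equals the scalar budget on the totals.
    """
    for col in ("dep_mvk", "dep_isopooh"):
        if col not in fields.columns:
            raise KeyError(f"gridded fields lack column {col!r}")
        if np.any(fields[col].to_numpy() < 0):
            raise ValueError(f"{col} contains negative cells")
    m_mek = registry["mek"].molar_mass
    cell_mvk = (fields["dep_mvk"].to_numpy() / registry["mvk"].molar_mass
                * inputs.yield_mvk_to_mek * m_mek)
    cell_iso = (fields["dep_isopooh"].to_numpy() / registry["isopooh_12"].molar_mass
                * inputs.yield_isopooh_to_mek * m_mek)
    per_cell = fields[["lat", "lon"]].copy()
    per_cell["mek_source"] = cell_mvk + cell_iso
    totals = replace(inputs,
                     dep_mvk=float(fields["dep_mvk"].sum()),
                     dep_isopooh=float(fields["dep_isopooh"].sum()))
    return mek_source(totals, registry, label="gridded"), per_cell
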