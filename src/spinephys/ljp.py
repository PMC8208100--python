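"""Henderson liquid-junction-potential calculator for patch-clamp solutions.

The junction potential between the pipette internal solution and the bath
arises from unequal ionic mobilities across the interface.  It is
estimated with the generalised Henderson equation using limiting
equivalent conductivities from a bundled published table (overridable by
the caller).  Recipes are entered as salt concentrations (mM) and
dissociated through a small dictionary of strong electrolytes; weak or
large species (HEPES, EGTA, nucleotides) are included with their
literature charge states at pH 7.3 and contribute little.  A ``KOH``
entry in a recipe marks pH titration: enough K+ is added to restore
electroneutrality.

Sign convention: the returned value is the potential of the bath relative
to the pipette solution, which is the correction electrophysiologists
quote (positive for potassium-gluconate internals).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "IonSpecies",
    "IonSolution",
    "load_mobility_table",
    "dissociate_recipe",
    "henderson_ljp",
    "SALT_DICTIONARY",
]

FARADAY = 96485.33212  # C/mol
GAS_R = 8.31446        # J/(mol K)

#: fraction of HEPES in the anionic form at pH 7.3 (pKa 7.5)
HEPES_ANION_FRACTION = 1.0 / (1.0 + 10.0 ** (7.5 - 7.3))


@dataclass(frozen=True)
class IonSpecies:
    """An ionic species with signed valence and limiting equivalent
    conductivity (S cm^2 / equiv, 25 C) as its mobility proxy."""

    name: str
    valence: int
    conductivity: float

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError("ion valence must be non-zero")
        if self.conductivity <= 0:
            raise ValueError("ion mobility must be positive")


def load_mobility_table() -> dict[str, IonSpecies]:
    """Bundled limiting-conductivity table (see the CSV for sources)."""
    table: dict[str, IonSpecies] = {}
    path = resources.files("spinephys").joinpath("data/ion_mobilities.csv")
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["species"]] = IonSpecies(
                row["species"], int(row["valence"]), float(row["conductivity"])
            )
    return table


@dataclass
class IonSolution:
    """Fully dissociated ionic composition: species name -> concentration mM."""

    concentrations_mm: dict[str, float]
    temperature_k: float = 295.15
    species: dict[str, IonSpecies] = field(default_factory=load_mobility_table)

    def __post_init__(self) -> None:
        for name, c in self.concentrations_mm.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")
            if name not in self.species:
                raise KeyError(f"no mobility entry for ion {name!r}")
        self.check_electroneutrality()

    def net_charge(self) -> float:
        return sum(self.species[i].valence * c for i, c in self.concentrations_mm.items())

    def check_electroneutrality(self, tolerance: float = 0.05) -> None:
        """Net charge within 5 % of total ionic charge (slack for
        unmodelled titrants and the CO2/bicarbonate buffer)."""
        total = sum(abs(self.species[i].valence) * c
                    for i, c in self.concentrations_mm.items())
        if total > 0 and abs(self.net_charge()) > tolerance * total:
            raise ValueError(
                f"solution not electroneutral: net {self.net_charge():.2f} "
                f"of total {total:.1f} charge-mM"
            )


#: stoichiometric dissociation of supported recipe components
SALT_DICTIONARY: dict[str, dict[str, float]] = {
    "K-gluconate": {"K": 1, "gluconate": 1},
    "NaCl": {"Na": 1, "Cl": 1},
    "KCl": {"K": 1, "Cl": 1},
    "MgCl2": {"Mg": 1, "Cl": 2},
    "CaCl2": {"Ca": 1, "Cl": 2},
    "NaHCO3": {"Na": 1, "HCO3": 1},
    "NaH2PO4": {"Na": 1, "H2PO4": 1},
    "HEPES": {"HEPES": HEPES_ANION_FRACTION},
    "EGTA": {"EGTA": 1},
    "Mg-ATP": {"Mg": 1, "ATP": 1},
    "Na-GTP": {"Na": 3, "GTP": 1},
    "glucose": {},
    "sucrose": {},
    "KOH": {},   # pH titrant: contributes the K+ needed for electroneutrality
}

_ALIASES = {"Mg2ATP": "Mg-ATP", "MgATP": "Mg-ATP", "Na3GTP": "Na-GTP",
            "Na2GTP": "Na-GTP", "K-gluc": "K-gluconate"}


def dissociate_recipe(
    recipe_mm: dict[str, float],
    temperature_k: float = 295.15,
    species: dict[str, IonSpecies] | None = None,
) -> IonSolution:
    """Dissociate a salt recipe (mM) into an :class:`IonSolution`.

    Unknown salts raise a KeyError listing the supported dictionary.  When
    the recipe contains ``KOH`` (pH adjustment, amount unspecified), K+ is
    added to neutralise the residual anionic charge of the weak acids.
    """
    conc: dict[str, float] = {}
    titrate = False
    for salt, mm in recipe_mm.items():
        name = _ALIASES.get(salt, salt)
        if name not in SALT_DICTIONARY:
            raise KeyError(
                f"unknown salt {salt!r}; supported: {sorted(SALT_DICTIONARY)}"
            )
        if name == "KOH":
            titrate = True
        for ion, stoich in SALT_DICTIONARY[name].items():
            conc[ion] = conc.get(ion, 0.0) + stoich * mm
    kwargs = {} if species is None else {"species": species}
    if titrate:
        sp = species or load_mobility_table()
        net = sum(sp[i].valence * c for i, c in conc.items())
        if net < 0:
            conc["K"] = conc.get("K", 0.0) - net
    return IonSolution(conc, temperature_k=temperature_k, **kwargs)


def henderson_ljp(
    pipette: IonSolution,
    bath: IonSolution,
    temperature_k: float | None = None,
) -> float:
    """Junction potential of the bath relative to the pipette, in mV.

    Generalised Henderson equation: with lambda_i the limiting equivalent
    conductivity, z_i the signed valence and dc_i = c_i(bath) - c_i(pipette),

        V = (RT/F) * [sum sign(z_i) lambda_i dc_i / sum |z_i| lambda_i dc_i]
                   * ln[sum |z_i| lambda_i c_i(pip) / sum |z_i| lambda_i c_i(bath)]

    which reduces to the classical binary-electrolyte closed form
    (RT/F) * ((l+ - l-)/(l+ + l-)) * ln(c_pip/c_bath) for a single salt.
    """
    if temperature_k is None:
        temperature_k = bath.temperature_k
    species = {**pipette.species, **bath.species}
    names = set(pipette.concentrations_mm) | set(bath.concentrations_mm)
    num = den = cond_p = cond_b = 0.0
    for name in names:
        sp = species[name]
        cp = pipette.concentrations_mm.get(name, 0.0)
        cb = bath.concentrations_mm.get(name, 0.0)
        dc = cb - cp
        sign = 1.0 if sp.valence > 0 else -1.0
        num += sign * sp.conductivity * dc
        den += abs(sp.valence) * sp.conductivity * dc
        cond_p += abs(sp.valence) * sp.conductivity * cp
        cond_b += abs(sp.valence) * sp.conductivity * cb
    if cond_p == 0.0 or cond_b == 0.0:
        raise ValueError("junction potential undefined for a zero-ionic-strength solution")
    rt_f_mv = GAS_R * temperature_k / FARADAY * 1e3
    if cond_p == cond_b or den == 0.0:
        # identical total conductance: the prefactor limit still applies
        if den == 0.0:
            return 0.0
        return 0.0 if cond_p == cond_b else rt_f_mv * num / den * math.log(cond_p / cond_b)
    return rt_f_mv * (num / den) * math.log(cond_p / cond_b)


# the published pipette/bath compositions this package was written around
INTERNAL_RECIPE_MM = {
    "K-gluconate": 135.0, "NaCl": 8.0, "HEPES": 10.0, "EGTA": 0.1,
    "Mg-ATP": 2.0, "Na-GTP": 0.3, "KOH": 0.0,
}
RECORDING_ACSF_MM = {
    "NaCl": 118.0, "NaHCO3": 25.0, "glucose": 10.0, "KCl": 2.5,
    "NaH2PO4": 1.0, "MgCl2": 1.0, "CaCl2": 2.5,
}


def reference_junction_potential(temperature_k: float = 295.15) -> float:
    """Junction potential of the potassium-gluconate internal against the
    recording artificial cerebrospinal fluid at the given temperature."""
    pip = dissociate_recipe(INTERNAL_RECIPE_MM, temperature_k)
    bath = dissociate_recipe(RECORDING_ACSF_MM, temperature_k)
    return henderson_ljp(pip, bath, temperature_k)
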