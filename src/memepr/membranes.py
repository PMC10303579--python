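"""Lipid compositions of model photoreceptor membranes.

Three liposome models are represented: the photoreceptor plasma membrane
(PM), young disc membrane (YDM) and old disc membrane (ODM).  They differ
in their PC:PE molar ratio, their content of docosahexaenoic-acid (22:6,
DHA) esterified chains and their cholesterol fraction.  Each preset stores
the species concentrations in mM; derived quantities (mole percentages,
PC:PE ratio) are computed relative to the structural lipid pool
(PC + PE + sterol), excluding the trace spin label and any retinoid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional

__all__ = [
    "LipidSpecies",
    "MembraneComposition",
    "CompositionError",
    "preset",
    "mole_percent",
    "pc_pe_ratio",
    "retinoid_mole_percent",
    "composition_report",
    "MEMBRANE_CLASSES",
    "RETINOIDS",
]

MEMBRANE_CLASSES = ("PM", "YDM", "ODM")

#: Retinoids studied: all-trans retinal, 11-cis retinal, all-trans retinol,
#: and the all-trans retinal condensation dimer.
RETINOIDS = ("atral", "11cral", "atrol", "atral_dimer")

HEADGROUP_CLASSES = ("PC", "PE", "sterol", "spin_label", "retinoid")

#: Headgroup classes counted in the structural-lipid denominator.
LIPID_CLASSES = ("PC", "PE", "sterol")


class CompositionError(ValueError):
    """Raised for invalid membrane compositions or undefined derived values."""


@dataclass(frozen=True)
class LipidSpecies:
    """One molecular species in a membrane composition.

    Chains are described as (carbons, double_bonds) tuples; sterols,
    retinoids and the spin label may omit them.  ``contains_dha`` flags
    species with at least one 22:6 chain.
    """

    name: str
    headgroup_class: str
    sn1_chain: Optional[tuple[int, int]] = None
    sn2_chain: Optional[tuple[int, int]] = None
    contains_dha: bool = False

    def __post_init__(self) -> None:
        if self.headgroup_class not in HEADGROUP_CLASSES:
            raise CompositionError(
                f"unknown headgroup class {self.headgroup_class!r}; "
                f"expected one of {HEADGROUP_CLASSES}"
            )
        for chain in (self.sn1_chain, self.sn2_chain):
            if chain is not None:
                carbons, dbonds = chain
                if carbons <= 0 or dbonds < 0:
                    raise CompositionError(f"invalid chain descriptor {chain}")
        chains = [c for c in (self.sn1_chain, self.sn2_chain) if c is not None]
        if chains:
            has_dha = any(c == (22, 6) for c in chains)
            if has_dha != self.contains_dha:
                raise CompositionError(
                    f"{self.name}: contains_dha={self.contains_dha} is inconsistent "
                    f"with chains {chains}"
                )

    @property
    def is_lipid(self) -> bool:
        return self.headgroup_class in LIPID_CLASSES


def _chain(spec: str) -> tuple[int, int]:
    carbons, dbonds = spec.split(":")
    return int(carbons), int(dbonds)


# Species used by the presets.  PDHAPC/PDHAPE carry a 22:6 sn2 chain.
SPECIES = {
    "DMPC": LipidSpecies("DMPC", "PC", _chain("14:0"), _chain("14:0")),
    "POPC": LipidSpecies("POPC", "PC", _chain("16:0"), _chain("18:1")),
    "PDHAPC": LipidSpecies("PDHAPC", "PC", _chain("16:0"), _chain("22:6"), True),
    "PDHAPE": LipidSpecies("PDHAPE", "PE", _chain("16:0"), _chain("22:6"), True),
    "POPE": LipidSpecies("POPE", "PE", _chain("16:0"), _chain("18:1")),
    "cholesterol": LipidSpecies("cholesterol", "sterol"),
    "n-PC": LipidSpecies("n-PC", "spin_label", _chain("18:0"), _chain("16:0")),
}

for _name in RETINOIDS:
    SPECIES[_name] = LipidSpecies(_name, "retinoid")


@dataclass(frozen=True)
class MembraneComposition:
    """A membrane model: species -> concentration (mM), plus an optional retinoid."""

    membrane_class: str
    entries: Mapping[LipidSpecies, float]
    retinoid_entry: Optional[tuple[LipidSpecies, float]] = None

    def __post_init__(self) -> None:
        if self.membrane_class not in MEMBRANE_CLASSES + ("custom",):
            raise CompositionError(
                f"unknown membrane class {self.membrane_class!r}; "
                f"expected one of {MEMBRANE_CLASSES + ('custom',)}"
            )
        object.__setattr__(self, "entries", dict(self.entries))
        for species, conc in self.entries.items():
            if conc < 0:
                raise CompositionError(f"{species.name}: negative concentration {conc}")
        if self.retinoid_entry is not None and self.retinoid_entry[1] < 0:
            raise CompositionError("negative retinoid concentration")
        if self.lipid_total <= 0:
            raise CompositionError("total structural lipid concentration must be > 0")
        label = self.spin_label_total
        if label and label >= 0.05 * self.lipid_total:
            raise CompositionError(
                f"spin label at {label} mM is not a trace probe "
                f"(>= 5% of {self.lipid_total} mM lipid)"
            )

    @property
    def lipid_total(self) -> float:
        """Structural-lipid pool (PC + PE + sterol), the mol% denominator."""
        return sum(c for s, c in self.entries.items() if s.is_lipid)

    @property
    def spin_label_total(self) -> float:
        return sum(
            c for s, c in self.entries.items() if s.headgroup_class == "spin_label"
        )

    def with_retinoid(self, name: str, concentration_mM: float = 1.0) -> "MembraneComposition":
        if name not in RETINOIDS:
            raise CompositionError(
                f"unknown retinoid {name!r}; expected one of {RETINOIDS}"
            )
        return replace(self, retinoid_entry=(SPECIES[name], concentration_mM))

    @property
    def condition(self) -> str:
        """'control' or the retinoid name."""
        if self.retinoid_entry is None or self.retinoid_entry[1] == 0:
            return "control"
        return self.retinoid_entry[0].name


# Concentrations in mM for the three membrane models (species -> PM, YDM, ODM).
_PRESET_TABLE = {
    "DMPC": (2.0, 1.0, 1.0),
    "POPC": (3.0, 1.5, 2.75),
    "PDHAPC": (0.0, 1.0, 1.0),
    "PDHAPE": (0.5, 2.5, 2.5),
    "POPE": (0.5, 1.0, 2.25),
    "cholesterol": (4.0, 3.0, 0.5),
    "n-PC": (0.1, 0.1, 0.1),
}


def preset(
    membrane_class: str,
    retinoid: Optional[str] = None,
    retinoid_mM: float = 1.0,
) -> MembraneComposition:
    """Return one of the three frozen membrane models.

    Parameters
    ----------
    membrane_class : {"PM", "YDM", "ODM"}
    retinoid : optional retinoid name (``RETINOIDS``); omitted for control.
    retinoid_mM : retinoid concentration, default 1 mM (10 mol% of the
        10 mM lipid pool of every preset).
    """
    if membrane_class not in MEMBRANE_CLASSES:
        raise CompositionError(
            f"unknown membrane class {membrane_class!r}; "
            f"expected one of {MEMBRANE_CLASSES}"
        )
    col = MEMBRANE_CLASSES.index(membrane_class)
    entries = {
        SPECIES[name]: concs[col]
        for name, concs in _PRESET_TABLE.items()
        if concs[col] > 0
    }
    comp = MembraneComposition(membrane_class, entries)
    if retinoid is not None:
        comp = comp.with_retinoid(retinoid, retinoid_mM)
    return comp


def mole_percent(
    comp: MembraneComposition,
    selector: Callable[[LipidSpecies], bool],
) -> float:
    """Mole percentage of the selected species within the structural-lipid pool.

    The denominator is PC + PE + sterol; the trace spin label and retinoid
    are excluded (this is the only convention under which all of the model
    membranes' stated percentages hold simultaneously).  A selector matching
    nothing yields 0.
    """
    if not comp.entries:
        raise CompositionError("empty composition")
    selected = sum(c for s, c in comp.entries.items() if s.is_lipid and selector(s))
    return 100.0 * selected / comp.lipid_total


def pc_pe_ratio(comp: MembraneComposition) -> float:
    """PC:PE molar ratio; the spin label's PC headgroup is not counted."""
    pc = sum(c for s, c in comp.entries.items() if s.headgroup_class == "PC")
    pe = sum(c for s, c in comp.entries.items() if s.headgroup_class == "PE")
    if pe <= 0:
        raise CompositionError("PC:PE ratio undefined: no PE in composition")
    return pc / pe


def retinoid_mole_percent(comp: MembraneComposition) -> float:
    """Retinoid concentration as mol% of the structural-lipid pool (0 for control)."""
    if comp.retinoid_entry is None:
        return 0.0
    return 100.0 * comp.retinoid_entry[1] / comp.lipid_total


def composition_report(comp: MembraneComposition) -> str:
    """Plain-text summary table of a composition and its derived quantities."""
    lines = [f"membrane class: {comp.membrane_class} ({comp.condition})"]
    lines.append(f"{'species':<14}{'class':<12}{'mM':>8}")
    for species, conc in comp.entries.items():
        lines.append(f"{species.name:<14}{species.headgroup_class:<12}{conc:>8.2f}")
    if comp.retinoid_entry is not None:
        species, conc = comp.retinoid_entry
        lines.append(f"{species.name:<14}{'retinoid':<12}{conc:>8.2f}")
    lines.append(f"lipid pool (PC+PE+sterol): {comp.lipid_total:.2f} mM")
    lines.append(
        "cholesterol: %.1f mol%%"
        % mole_percent(comp, lambda s: s.headgroup_class == "sterol")
    )
    lines.append("PUFA (22:6): %.1f mol%%" % mole_percent(comp, lambda s: s.contains_dha))
    lines.append("PC:PE ratio: %.2f" % pc_pe_ratio(comp))
    lines.append("retinoid: %.1f mol%%" % retinoid_mole_percent(comp))
    return "\n".join(lines)
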