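"""Cross-linker chemistry definitions and monoisotopic mass accounting.

Three chemistries are built in:

* **ADH** (adipic acid dihydrazide) — links carboxylate pairs (D/E x D/E)
  through a six-carbon bridge, losing one water per hydrazide coupling;
  used as a light/heavy h8/d8 isotope pair.
* **DMTMM** — a coupling reagent that forms a direct zero-length amide
  bond between a lysine amine and a carboxylate, with net loss of one
  water; the reagent itself leaves no atoms behind.
* **DSS** (disuccinimidyl suberate) — links lysine pairs via a suberate
  bridge; isotope pair h12/d12.

All mass shifts are computed from an atomic monoisotopic mass table, never
hard-coded, so the chemistry registry stays auditable against first
principles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

# IUPAC 2021 monoisotopic masses (Da). D is deuterium (2H).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

DEUTERIUM_DELTA = ATOMIC_MASSES["D"] - ATOMIC_MASSES["H"]  # ≈ 1.0062767 Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str, masses: dict[str, float] | None = None) -> float:
    """Monoisotopic mass of an elemental formula such as ``"C6H14N4O2"``.

    The empty formula has mass 0. Raises ``ValueError`` naming the first
    element not present in the mass table.
    """
    table = ATOMIC_MASSES if masses is None else masses
    total = 0.0
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in table:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        total += table[element] * (int(count) if count else 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return total


WATER_MASS = formula_mass("H2O")


@dataclass(frozen=True)
class MonolinkComposition:
    """A single-ended reaction product: elemental delta relative to the
    unmodified peptide, expressed as (bridge formula, waters lost)."""

    name: str
    formula: str
    water_loss_count: int


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Definition of one cross-linking chemistry.

    ``reactive_pair`` holds the two residue sets that can be joined;
    ``bridge_composition`` is the elemental formula added upon forming a
    cross-link (empty for a zero-length coupling); ``water_loss_count``
    waters leave per cross-linking reaction. ``label_count`` is the number
    of H→D substitutions in the heavy isotopologue. ``max_distance`` is
    the Cα–Cα satisfaction bound in Å.
    """

    name: str
    reactive_pair: tuple[frozenset[str], frozenset[str]]
    bridge_composition: str
    water_loss_count: int
    label_count: int
    monolink_compositions: tuple[MonolinkComposition, ...]
    max_distance: float

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not (self.reactive_pair[0] and self.reactive_pair[1]):
            raise ValueError("reactive sets must be non-empty")
        if self.label_count < 0:
            raise ValueError("label_count must be >= 0")

    def reactive_compatible(self, restype_a: str, restype_b: str) -> bool:
        """True if the unordered residue-type pair matches the chemistry."""
        sa, sb = self.reactive_pair
        return (restype_a in sa and restype_b in sb) or (
            restype_a in sb and restype_b in sa
        )


def crosslink_mass_shift(spec: CrosslinkerSpec) -> float:
    """Mass added to a cross-linked peptide pair (may be negative for a
    zero-length dehydration coupling)."""
    return formula_mass(spec.bridge_composition) - spec.water_loss_count * WATER_MASS


def monolink_mass_shifts(spec: CrosslinkerSpec) -> list[float]:
    """Mass shifts of each single-ended reaction product, in registry order."""
    return [
        formula_mass(m.formula) - m.water_loss_count * WATER_MASS
        for m in spec.monolink_compositions
    ]


def heavy_light_delta(spec: CrosslinkerSpec) -> float:
    """Precursor mass difference between heavy and light isotopologues."""
    return spec.label_count * DEUTERIUM_DELTA


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# Fixed modification used in the MS searches; handy for table validation.
CARBAMIDOMETHYL_MASS = formula_mass("C2H3NO")

ACIDIC = frozenset("DE")
LYSINE = frozenset("K")

#: Built-in chemistry registry. DSS max_distance is a configurable
#: convention (the lysine side chains plus the suberate spacer reach
#: ~24 Å between Cβ atoms; 30 Å Cα–Cα is the common literature bound).
REGISTRY: dict[str, CrosslinkerSpec] = {
    "ADH": CrosslinkerSpec(
        name="ADH",
        reactive_pair=(ACIDIC, ACIDIC),
        bridge_composition="C6H14N4O2",
        water_loss_count=2,
        label_count=8,
        monolink_compositions=(
            MonolinkComposition("hydrolyzed", "C6H14N4O2", 1),
        ),
        max_distance=21.0,
    ),
    "DMTMM": CrosslinkerSpec(
        name="DMTMM",
        reactive_pair=(LYSINE, ACIDIC),
        bridge_composition="",
        water_loss_count=1,
        label_count=0,
        monolink_compositions=(),
        max_distance=16.0,
    ),
    "DSS": CrosslinkerSpec(
        name="DSS",
        reactive_pair=(LYSINE, LYSINE),
        bridge_composition="C8H10O2",
        water_loss_count=0,
        label_count=12,
        monolink_compositions=(
            MonolinkComposition("hydrolyzed", "C8H12O3", 0),
            # Ammonolysis product; printed search masses for this species
            # differ from the elemental computation by ~2 mDa (documented,
            # not asserted).
            MonolinkComposition("aminolyzed", "C8H13NO2", 0),
        ),
        max_distance=30.0,
    ),
}


def get_chemistry(name: str, registry: dict[str, CrosslinkerSpec] | None = None
                  ) -> CrosslinkerSpec:
    reg = REGISTRY if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown chemistry {name!r}; registered: {sorted(reg)}"
        ) from None


def spec_to_dict(spec: CrosslinkerSpec) -> dict:
    """Serializable view of a chemistry, including derived mass shifts."""
    return {
        "name": spec.name,
        "reactive_pair": [sorted(spec.reactive_pair[0]), sorted(spec.reactive_pair[1])],
        "bridge_composition": spec.bridge_composition,
        "water_loss_count": spec.water_loss_count,
        "label_count": spec.label_count,
        "monolinks": [
            {"name": m.name, "formula": m.formula, "water_loss_count": m.water_loss_count}
            for m in spec.monolink_compositions
        ],
        "max_distance_A": spec.max_distance,
        "crosslink_mass_shift_Da": crosslink_mass_shift(spec),
        "monolink_mass_shifts_Da": monolink_mass_shifts(spec),
        "heavy_light_delta_Da": heavy_light_delta(spec),
    }


def load_registry(path: str) -> dict[str, CrosslinkerSpec]:
    """Read a YAML chemistry registry (same fields as ``spec_to_dict``
    minus the derived masses)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry: dict[str, CrosslinkerSpec] = {}
    for entry in raw:
        registry[entry["name"]] = CrosslinkerSpec(
            name=entry["name"],
            reactive_pair=(
                frozenset(entry["reactive_pair"][0]),
                frozenset(entry["reactive_pair"][1]),
            ),
            bridge_composition=entry.get("bridge_composition", ""),
            water_loss_count=int(entry.get("water_loss_count", 0)),
            label_count=int(entry.get("label_count", 0)),
            monolink_compositions=tuple(
                MonolinkComposition(
                    m["name"], m["formula"], int(m.get("water_loss_count", 0))
                )
                for m in entry.get("monolinks", [])
            ),
            max_distance=float(entry["max_distance_A"]),
        )
    return registry


def dump_registry(registry: dict[str, CrosslinkerSpec], path: str) -> None:
    entries = []
    for spec in registry.values():
        d = spec_to_dict(spec)
        for k in ("crosslink_mass_shift_Da", "monolink_mass_shifts_Da",
                  "heavy_light_delta_Da"):
            d.pop(k)
        d["max_distance_A"] = spec.max_distance
        entries.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
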