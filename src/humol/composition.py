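"""Material composition types and the bundled atomic-constants table.

Two complementary descriptions of a material are used throughout:

* :class:`ElementalComposition` — mass fractions by chemical element, the
  representation needed for photon cross sections (mixture rule) and for
  the electron-per-mass sum ``sum_i omega_i Z_i / A_i``.
* :class:`MolecularComposition` — mass fractions over the four-component
  tissue model (water, lipid, protein, mineral/hydroxyapatite), the
  representation in which the HU–density relations become linear.

A single bundled table of standard atomic weights supplies every ``Z`` and
``A`` in the package, including the ``Z/A`` of liquid water that normalizes
relative electron density; self-consistency of that normalization matters
more than any particular authority's digits.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CompositionError",
    "UnknownElementError",
    "atomic_number",
    "atomic_mass",
    "z_over_a",
    "z_over_a_water",
    "water_mass_fractions",
    "ElementalComposition",
    "MolecularComposition",
    "MOLECULE_NAMES",
]

logger = logging.getLogger(__name__)

#: Mass-fraction sums farther than this from 1 are rejected outright.
SUM_TOLERANCE = 1e-3
#: Sums within SUM_TOLERANCE but beyond this are silently-logged renormalized.
EXACT_TOLERANCE = 1e-6

MOLECULE_NAMES = ("water", "lipid", "protein", "mineral")


class CompositionError(ValueError):
    """Invalid material composition (fractions out of range or bad sum)."""


class UnknownElementError(KeyError):
    """Element symbol absent from the bundled atomic-constants table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError repr-quotes; keep the message plain
        return f"unknown element symbol: {self.symbol!r}"


@lru_cache(maxsize=1)
def _atomic_table() -> pd.DataFrame:
    with resources.files("humol.data").joinpath("atomic_weights.csv").open() as fh:
        return pd.read_csv(fh, comment="#").set_index("symbol")


def atomic_number(symbol: str) -> int:
    """Atomic number Z for an element symbol."""
    try:
        return int(_atomic_table().loc[symbol, "Z"])
    except KeyError:
        raise UnknownElementError(symbol) from None


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight A (g/mol) for an element symbol."""
    try:
        return float(_atomic_table().loc[symbol, "A"])
    except KeyError:
        raise UnknownElementError(symbol) from None


def z_over_a(symbol: str) -> float:
    """Electrons per unit mass, Z/A (mol/g), for an element."""
    return atomic_number(symbol) / atomic_mass(symbol)


def water_mass_fractions() -> dict[str, float]:
    """Mass fractions of H and O in H2O from the bundled atomic weights."""
    m_h = 2.0 * atomic_mass("H")
    m_o = atomic_mass("O")
    total = m_h + m_o
    return {"H": m_h / total, "O": m_o / total}


@lru_cache(maxsize=1)
def z_over_a_water() -> float:
    """Z/A of liquid water, the electron-density normalization constant."""
    return sum(w * z_over_a(el) for el, w in water_mass_fractions().items())


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    """Parse a chemical formula such as ``Ca5(PO4)3(OH)`` into atom counts."""
    stack: list[dict[str, int]] = [{}]
    pos = 0
    while pos < len(formula):
        match = _FORMULA_TOKEN.match(formula, pos)
        if match is None or match.end() == pos:
            raise CompositionError(f"cannot parse formula {formula!r} at {pos}")
        symbol, count, open_par, close_par, group_count = match.groups()
        if symbol:
            n = int(count) if count else 1
            stack[-1][symbol] = stack[-1].get(symbol, 0) + n
        elif open_par:
            stack.append({})
        elif close_par is not None:
            if len(stack) < 2:
                raise CompositionError(f"unbalanced parentheses in {formula!r}")
            group = stack.pop()
            n = int(group_count) if group_count else 1
            for el, cnt in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + cnt * n
        pos = match.end()
    if len(stack) != 1:
        raise CompositionError(f"unbalanced parentheses in {formula!r}")
    return stack[0]


def _normalize(fractions: Mapping[str, float], what: str) -> dict[str, float]:
    clean = {k: float(v) for k, v in fractions.items() if float(v) != 0.0}
    for key, value in clean.items():
        if not 0.0 <= value <= 1.0:
            raise CompositionError(f"{what}: fraction {key}={value} outside [0, 1]")
    total = sum(clean.values())
    if abs(total - 1.0) > SUM_TOLERANCE:
        raise CompositionError(f"{what}: mass fractions sum to {total:.6f}, not 1")
    if abs(total - 1.0) > EXACT_TOLERANCE:
        logger.info("%s: renormalizing mass-fraction sum %.6f to 1", what, total)
    return {k: v / total for k, v in clean.items()}


@dataclass(frozen=True)
class ElementalComposition:
    """Mass fractions by chemical element.

    Fractions must lie in [0, 1] and sum to 1; sums off by at most 1e-3
    (hand-entered tables) are renormalized with a log entry, larger
    deviations raise :class:`CompositionError`. Every symbol must exist in
    the bundled atomic-constants table.
    """

    fractions: Mapping[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        clean = _normalize(self.fractions, self.name or "elemental composition")
        for symbol in clean:
            atomic_number(symbol)  # raises UnknownElementError
        object.__setattr__(self, "fractions", clean)

    @classmethod
    def from_formula(cls, formula: str, name: str = "") -> "ElementalComposition":
        """Build from a stoichiometric formula, e.g. ``Ca5(PO4)3(OH)``."""
        counts = _parse_formula(formula)
        masses = {el: n * atomic_mass(el) for el, n in counts.items()}
        total = sum(masses.values())
        return cls({el: m / total for el, m in masses.items()}, name=name or formula)

    @classmethod
    def mix(
        cls,
        components: Iterable[tuple["ElementalComposition", float]],
        name: str = "",
    ) -> "ElementalComposition":
        """Mass-weighted mixture of elemental compositions."""
        out: dict[str, float] = {}
        for comp, weight in components:
            for el, frac in comp.fractions.items():
                out[el] = out.get(el, 0.0) + weight * frac
        return cls(out, name=name)

    def __getitem__(self, symbol: str) -> float:
        return self.fractions.get(symbol, 0.0)

    def items(self):
        return self.fractions.items()

    def z_over_a(self) -> float:
        """Electrons per unit mass of the mixture, ``sum_i omega_i Z_i/A_i``."""
        return sum(w * z_over_a(el) for el, w in self.fractions.items())


WATER_ELEMENTAL = None  # populated lazily below


def water_elemental() -> ElementalComposition:
    """Elemental composition of liquid water from the constants table."""
    global WATER_ELEMENTAL
    if WATER_ELEMENTAL is None:
        WATER_ELEMENTAL = ElementalComposition(water_mass_fractions(), name="water")
    return WATER_ELEMENTAL


@dataclass(frozen=True)
class MolecularComposition:
    """Mass fractions over the four-component tissue model.

    The components are water, lipid, protein, and mineral (hydroxyapatite).
    The same renormalization policy as :class:`ElementalComposition`
    applies.
    """

    water: float = 0.0
    lipid: float = 0.0
    protein: float = 0.0
    mineral: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        raw = {m: getattr(self, m) for m in MOLECULE_NAMES}
        clean = _normalize(raw, self.name or "molecular composition")
        for m in MOLECULE_NAMES:
            object.__setattr__(self, m, clean.get(m, 0.0))

    @classmethod
    def pure(cls, molecule: str, name: str = "") -> "MolecularComposition":
        if molecule not in MOLECULE_NAMES:
            raise CompositionError(f"unknown molecule type {molecule!r}")
        return cls(**{molecule: 1.0}, name=name or molecule)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MOLECULE_NAMES}

    def nonwater(self) -> tuple[float, float, float]:
        """(lipid, protein, mineral) — the fractions that carry coefficients."""
        return (self.lipid, self.protein, self.mineral)

    def elemental(
        self, library: Mapping[str, ElementalComposition], name: str = ""
    ) -> ElementalComposition:
        """Expand to elements using a molecule library (e.g. the bundled one)."""
        return ElementalComposition.mix(
            [(library[m], w) for m, w in self.as_dict().items() if w > 0],
            name=name or self.name,
        )

    def to_json(self) -> str:
        return json.dumps(self.as_dict())
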