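"""Elemental-formula arithmetic for small-molecule mass spectrometry.

Monoisotopic masses, ion m/z for protonated/deprotonated species, ppm
errors, and bounded enumeration of candidate formulas for an observed
precursor mass.  Formulas are restricted to C, H, N, O, P and S — the
element set covering plant specialized metabolites and their phosphorylated
biosynthetic precursors.

Ion formulas follow the convention used when reporting [M+H]+ / [M-H]-
species with the proton already included: ``ion_mz`` only corrects for the
electron, so the formula passed in must be the formula *of the ion*.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

from pyteomics import mass as _ptmass

SUPPORTED_ELEMENTS: Tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

#: Monoisotopic atomic masses (Da), from the NIST table shipped with pyteomics.
MONOISOTOPIC: Dict[str, float] = {
    el: _ptmass.nist_mass[el][0][0] for el in SUPPORTED_ELEMENTS
}

#: Rest mass of the electron (Da).
ELECTRON_MASS: float = _ptmass.nist_mass["e*"][0][0]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Ring-plus-double-bond equivalents: valence contribution per element.
# O and S are divalent and contribute 0.
_RDBE_COEF = {"C": 1.0, "H": -0.5, "N": 0.5, "O": 0.0, "P": 0.5, "S": 0.0}


class FormulaError(ValueError):
    """Raised for malformed formulas or unsupported elements."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element → count map with monoisotopic-mass semantics.

    Counts are non-negative integers; the empty formula (all zero) is the
    additive identity.  Instances are immutable and hashable.
    """

    counts: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        cleaned = []
        for el, n in sorted(dict(self.counts).items()):
            if el not in MONOISOTOPIC:
                raise FormulaError(f"unsupported element: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                cleaned.append((el, int(n)))
        object.__setattr__(self, "counts", tuple(cleaned))

    # -- constructors -----------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation formula string.

        Underscores are tolerated (some sources typeset subscripts as
        ``C_20_H_17_N_2_O_5_``).
        """
        s = text.replace("_", "").strip()
        if not s:
            return cls()
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r}")
            el = m.group(1)
            if el not in MONOISOTOPIC:
                raise FormulaError(f"unsupported element: {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(s):
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(tuple(counts.items()))

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(counts.items()))

    # -- accessors --------------------------------------------------------

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def hill(self) -> str:
        """Hill notation: C, then H, then other elements alphabetically."""
        d = self.as_dict()
        parts: List[str] = []
        for el in ("C", "H"):
            if d.get(el):
                parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        for el in sorted(set(d) - {"C", "H"}):
            parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill() or "(empty)"

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalFormula(tuple(d.items()))

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise FormulaError(
                    f"subtraction gives negative {el} count: {self} - {other}"
                )
        return ElementalFormula(tuple(d.items()))

    def rdbe(self) -> float:
        """Rings-plus-double-bond equivalents, 1 + Σ coef_el · n_el.

        Half-integer values occur for even-electron ions (formulas with the
        charge-carrying proton included), which is expected.
        """
        return 1.0 + sum(_RDBE_COEF[el] * n for el, n in self.counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass of a (neutral or ion) formula in Da."""
    return sum(MONOISOTOPIC[el] * n for el, n in f.counts)


def ion_mz(f: ElementalFormula, polarity: str) -> float:
    """m/z of a singly charged ion whose formula is ``f``.

    ``f`` must already include the ionizing proton ([M+H]+) or lack one
    ([M-H]-), exactly as ion formulas are printed; only the electron mass is
    added or removed here.
    """
    if polarity == "+":
        return monoisotopic_mass(f) - ELECTRON_MASS
    if polarity == "-":
        return monoisotopic_mass(f) + ELECTRON_MASS
    raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class ElementBounds:
    """Search space for formula enumeration: per-element count ranges and
    an RDBE window."""

    min_counts: Tuple[Tuple[str, int], ...] = ()
    max_counts: Tuple[Tuple[str, int], ...] = (
        ("C", 40), ("H", 60), ("N", 4), ("O", 16), ("P", 2), ("S", 2),
    )
    rdbe_min: float = 0.0
    rdbe_max: float = 25.0

    def __post_init__(self) -> None:
        lo, hi = dict(self.min_counts), dict(self.max_counts)
        for el in set(lo) | set(hi):
            if el not in MONOISOTOPIC:
                raise FormulaError(f"unsupported element in bounds: {el!r}")
            if lo.get(el, 0) > hi.get(el, 0):
                raise FormulaError(f"min > max for element {el}")
        if not (math.isfinite(self.rdbe_min) and math.isfinite(self.rdbe_max)):
            raise FormulaError("RDBE bounds must be finite")

    def range_of(self, element: str) -> Tuple[int, int]:
        return (dict(self.min_counts).get(element, 0),
                dict(self.max_counts).get(element, 0))

    def n_candidates(self) -> int:
        n = 1
        for el in SUPPORTED_ELEMENTS:
            lo, hi = self.range_of(el)
            n *= hi - lo + 1
        return n


DEFAULT_BOUNDS = ElementBounds()


def enumerate_formulas(
    mz: float,
    polarity: str,
    tol_ppm: float = 5.0,
    bounds: ElementBounds = DEFAULT_BOUNDS,
) -> List[ElementalFormula]:
    """All ion formulas within ``bounds`` whose m/z lies within ``tol_ppm``
    of ``mz``, ranked by |ppm error| (ties broken by Hill notation).

    The heavy elements are enumerated with mass-based pruning and the H
    count is solved arithmetically from the residual mass window, so the
    search is fast even for the default CHNOPS bounds.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if bounds.n_candidates() > 10 ** 7:
        raise ValueError(
            "element bounds produce more than 1e7 candidates; "
            "tighten the per-element ranges"
        )
    electron = -ELECTRON_MASS if polarity == "+" else ELECTRON_MASS
    if polarity not in "+-":
        raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
    target = mz - electron  # required formula mass
    tol = tol_ppm * 1e-6 * mz
    mH = MONOISOTOPIC["H"]

    heavy = [el for el in ("C", "N", "O", "P", "S")]
    out: List[Tuple[float, str, ElementalFormula]] = []

    ranges = {el: bounds.range_of(el) for el in SUPPORTED_ELEMENTS}

    def recurse(idx: int, counts: Dict[str, int], mass_so_far: float) -> None:
        if mass_so_far > target + tol:
            return
        if idx == len(heavy):
            lo_h, hi_h = ranges["H"]
            resid = target - mass_so_far
            h_lo = max(lo_h, math.ceil((resid - tol) / mH))
            h_hi = min(hi_h, math.floor((resid + tol) / mH))
            for h in range(h_lo, h_hi + 1):
                m = mass_so_far + h * mH
                if abs(m - target) > tol:
                    continue
                d = {el: n for el, n in counts.items() if n}
                if h:
                    d["H"] = h
                f = ElementalFormula(tuple(d.items()))
                if not (bounds.rdbe_min <= f.rdbe() <= bounds.rdbe_max):
                    continue
                out.append((abs(ppm_error(mz, m + electron)), f.hill(), f))
            return
        el = heavy[idx]
        lo, hi = ranges[el]
        for n in range(lo, hi + 1):
            m = mass_so_far + n * MONOISOTOPIC[el]
            if m > target + tol:
                break
            counts[el] = n
            recurse(idx + 1, counts, m)
        counts[el] = 0

    recurse(0, {}, 0.0)
    out.sort(key=lambda t: (t[0], t[1]))
    return [f for _, _, f in out]
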