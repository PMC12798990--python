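"""Exact-mass arithmetic for CHO compounds.

Monoisotopic masses, [M+H]+ adduct conversion, ring-and-double-bond
equivalents (RDBE), ppm-bounded molecular-formula enumeration and a
simple coarse isotope-pattern model — everything downstream of a
high-resolution accurate mass that the screening pipeline needs.

Only the elements C, H and O are supported: the screen targets plant
flavonoids, which are CHO-only, and the extraction step constrains the
element composition to at most C90 H190 O90.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
# IUPAC 2021 monoisotopic atomic masses (Da); pinned here as the single
# source of truth so results are bit-reproducible across platforms.
MASS_C = 12.0
MASS_H = 1.00782503207
MASS_O = 15.99491461956
PROTON_MASS = 1.007276  # m(1H) - m(e-)

# Natural heavy-isotope abundances used by the coarse pattern model.
P_13C = 0.0107
P_18O = 0.00205
A1_MASS_OFFSET = 1.00336  # 13C - 12C

# Element-composition ceiling applied during compound extraction.
MAX_ELEMENT_COUNTS = (90, 190, 90)

_HILL_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidFormulaError(ValueError):
    """Raised for negative element counts or unsupported elements."""


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """A CHO elemental composition, e.g. ``MolecularFormula(19, 18, 7)``."""

    n_C: int
    n_H: int
    n_O: int

    def __post_init__(self) -> None:
        for n in (self.n_C, self.n_H, self.n_O):
            if n < 0:
                raise InvalidFormulaError(f"negative element count in {self!r}")

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse Hill notation, e.g. ``"C19H18O7"``, ``"CH4"``, ``"H2O"``."""
        counts = {"C": 0, "H": 0, "O": 0}
        pos = 0
        for m in _HILL_RE.finditer(text.strip()):
            if m.start() != pos or not m.group(0):
                break
            pos = m.end()
            elem, num = m.group(1), m.group(2)
            if elem not in counts:
                raise InvalidFormulaError(
                    f"unsupported element {elem!r} in {text!r} (CHO only)"
                )
            counts[elem] += int(num) if num else 1
        if pos != len(text.strip()) or pos == 0:
            raise InvalidFormulaError(f"cannot parse formula {text!r}")
        return cls(counts["C"], counts["H"], counts["O"])

    def __str__(self) -> str:
        parts = []
        for elem, n in (("C", self.n_C), ("H", self.n_H), ("O", self.n_O)):
            if n == 1:
                parts.append(elem)
            elif n > 1:
                parts.append(f"{elem}{n}")
        return "".join(parts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(
            self.n_C + other.n_C, self.n_H + other.n_H, self.n_O + other.n_O
        )

    @property
    def is_empty(self) -> bool:
        return self.n_C == 0 and self.n_H == 0 and self.n_O == 0


@dataclass(frozen=True)
class MassTolerance:
    """Relative mass window in parts per million (default 5 ppm)."""

    ppm: float = 5.0

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError(f"ppm tolerance must be > 0, got {self.ppm}")

    def window(self, reference_mass: float) -> float:
        """Absolute half-width (Da) of the window at ``reference_mass``."""
        return reference_mass * self.ppm * 1e-6


@dataclass(frozen=True)
class FormulaCandidate:
    """One formula explaining a query mass within tolerance."""

    formula: MolecularFormula
    theoretical_mass: float
    ppm_error: float
    rdbe: float


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic mass in Da (sum of the lightest-isotope atomic masses)."""
    return formula.n_C * MASS_C + formula.n_H * MASS_H + formula.n_O * MASS_O


def rdbe(formula: MolecularFormula) -> float:
    """Ring-and-double-bond equivalents, C - H/2 + 1 for CHO.

    May be half-integer (odd-electron species) or negative (chemically
    implausible); callers use it as a plausibility filter.
    """
    return formula.n_C - formula.n_H / 2.0 + 1.0


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative deviation of ``measured`` from ``theoretical`` in ppm."""
    return (measured - theoretical) / theoretical * 1e6


SUPPORTED_ADDUCTS = {"[M+H]+": PROTON_MASS}


def _adduct_shift(adduct: str) -> float:
    try:
        return SUPPORTED_ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: "
            + ", ".join(sorted(SUPPORTED_ADDUCTS))
        ) from None


def mz_from_neutral(mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of the adduct ion of a neutral of monoisotopic ``mass`` (Da)."""
    if mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {mass}")
    return mass + _adduct_shift(adduct)


def neutral_from_mz(mz: float, adduct: str = "[M+H]+") -> float:
    """Neutral monoisotopic mass recovered from an adduct m/z."""
    shift = _adduct_shift(adduct)
    if mz <= shift:
        raise ValueError(f"m/z {mz} is not above the {adduct} adduct mass")
    return mz - shift


def enumerate_formulas(
    query_mass: float,
    tol: MassTolerance = MassTolerance(5.0),
    min_counts: MolecularFormula = MolecularFormula(1, 0, 0),
    max_counts: MolecularFormula = MolecularFormula(*MAX_ELEMENT_COUNTS),
    rdbe_bounds: tuple[float, float] = (0.0, 40.0),
) -> list[FormulaCandidate]:
    """All CHO formulas whose monoisotopic mass lies within ``tol`` of
    ``query_mass``, subject to element-count and RDBE bounds.

    The default element floor is C1 H0 O0 — an organic compound must
    contain carbon — and the ceiling is the extraction constraint
    C90 H190 O90.  Candidates are sorted by \\|ppm error\\| ascending,
    ties broken by (n_C, n_H, n_O).
    """
    if query_mass <= 0:
        raise ValueError(f"query mass must be positive, got {query_mass}")
    if not (
        min_counts.n_C <= max_counts.n_C
        and min_counts.n_H <= max_counts.n_H
        and min_counts.n_O <= max_counts.n_O
    ):
        raise ValueError("min element counts must not exceed max counts")
    half = tol.window(query_mass)
    lo, hi = query_mass - half, query_mass + half
    out: list[FormulaCandidate] = []
    rd_lo, rd_hi = rdbe_bounds
    for c in range(min_counts.n_C, max_counts.n_C + 1):
        mass_c = c * MASS_C
        if mass_c > hi:
            break
        for o in range(min_counts.n_O, max_counts.n_O + 1):
            rest = mass_c + o * MASS_O
            if rest > hi:
                break
            h_min = max(min_counts.n_H, math.ceil((lo - rest) / MASS_H - 1e-12))
            h_max = min(max_counts.n_H, math.floor((hi - rest) / MASS_H + 1e-12))
            for h in range(h_min, h_max + 1):
                mass = rest + h * MASS_H
                if not (lo <= mass <= hi):
                    continue
                f = MolecularFormula(c, h, o)
                r = rdbe(f)
                if not (rd_lo <= r <= rd_hi):
                    continue
                out.append(
                    FormulaCandidate(f, mass, ppm_error(query_mass, mass), r)
                )
    out.sort(key=lambda cand: (abs(cand.ppm_error), cand.formula))
    return out


def isotope_pattern(
    formula: MolecularFormula, n_isotopologues: int = 3
) -> list[tuple[float, float]]:
    """Coarse A, A+1, ... A+k isotopologue pattern.

    Heavy-isotope substitution is modelled as independent binomial 13C
    (p = 0.0107) and 18O (p = 0.00205; contributes at A+2) draws, which
    is accurate to a few percent for CHO compounds below ~1 kDa.  All
    isotopologues at nominal offset k are lumped at monoisotopic mass
    + k x 1.00336 Da, and abundances are reported relative to the
    monoisotopic peak (A = 1).
    """
    if formula.is_empty:
        raise InvalidFormulaError("cannot compute a pattern for an empty formula")
    if n_isotopologues < 1:
        raise ValueError("n_isotopologues must be >= 1")
    mono = monoisotopic_mass(formula)
    nC, nO = formula.n_C, formula.n_O
    # abundance of (i heavy carbons, j heavy oxygens), relative to (0, 0)
    pattern = []
    for k in range(n_isotopologues):
        rel = 0.0
        for j in range(0, min(k // 2, nO) + 1):
            i = k - 2 * j
            if i > nC:
                continue
            rel += (
                math.comb(nC, i) * (P_13C / (1 - P_13C)) ** i
                * math.comb(nO, j) * (P_18O / (1 - P_18O)) ** j
            )
        pattern.append((mono + k * A1_MASS_OFFSET, rel))
    return pattern
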