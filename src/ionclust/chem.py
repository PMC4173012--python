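"""Molecular formulas, aggregated isotope patterns, adduct rules and the
theoretical peak library.

The library materialises, for every formula ``m`` and adduct rule ``a``, the
series of isotope entries ``i`` with an m/z value and a theoretical relative
proportion (the fraction of the ion's total abundance carried by that
isotopologue group).  Fine isotopic structure is aggregated by nominal mass
shift from the monoisotopic species (M, M+1, M+2, ...), with each aggregated
entry's mass the abundance-weighted mean of the isotopologues it contains —
the appropriate granularity for orbitrap-class resolution.
"""

from __future__ import annotations

import bisect
import math
import re
from dataclasses import dataclass, field

from .elements import ELECTRON_MASS, ISOTOPES, lightest_mass

__all__ = [
    "Formula",
    "IsotopePattern",
    "AdductRule",
    "TheoreticalPeak",
    "PeakLibrary",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "isotope_pattern",
    "parse_adduct_rule",
    "apply_adduct",
    "build_library",
]


class FormulaError(ValueError):
    """Raised for malformed formula or adduct-rule strings."""


@dataclass(frozen=True)
class Formula:
    """Elemental composition, e.g. ``{"C": 6, "H": 12, "O": 6}``.

    Stored counts are strictly positive; zero-count elements are dropped.
    """

    element_counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "Formula":
        clean = {}
        for sym, n in counts.items():
            if sym not in ISOTOPES:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {sym}")
            if n > 0:
                clean[sym] = n
        return cls(tuple(sorted(clean.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.element_counts)

    def n_atoms(self) -> int:
        return sum(n for _, n in self.element_counts)

    def __mul__(self, k: int) -> "Formula":
        return Formula.from_dict({s: n * k for s, n in self.element_counts})

    def __add__(self, other: "Formula") -> "Formula":
        counts = self.as_dict()
        for s, n in other.element_counts:
            counts[s] = counts.get(s, 0) + n
        return Formula.from_dict(counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        counts = self.as_dict()
        parts = []
        for sym in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
            if sym in counts:
                n = counts[sym]
                parts.append(sym + (str(n) if n > 1 else ""))
        return "".join(parts)


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotope distribution: ``entries[i] = (mass_da, proportion)``
    for nominal shift ``i`` = 0 (monoisotopic), 1, 2, ...  Proportions sum to
    one up to the truncation tolerance."""

    entries: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.entries)

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.entries)


@dataclass(frozen=True)
class AdductRule:
    """An electrospray adduct transformation such as ``M+H`` or ``2M+3H``.

    ``multiplicity`` is the number of copies of the neutral molecule (the *n*
    in *n*M); ``gained``/``lost`` are the atoms added/removed; ``charge`` is
    the signed ion charge (supplied explicitly, never inferred)."""

    name: str
    multiplicity: int
    gained: Formula
    lost: Formula
    charge: int

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise FormulaError(f"adduct multiplicity must be >= 1: {self.name}")
        if self.charge == 0:
            raise FormulaError(f"adduct charge must be non-zero: {self.name}")


@dataclass(frozen=True)
class TheoreticalPeak:
    """One theoretical ion species: formula ``m`` x adduct ``a`` x isotope
    index ``i``, with its m/z and relative proportion beta."""

    formula_index: int
    adduct_index: int
    isotope_index: int
    mz: float
    proportion: float


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a molecular formula string like ``"C6H12O6"``.

    Repeated element symbols accumulate (``"CHCH"`` -> C2H2).  Raises
    :class:`FormulaError` on empty input or unknown element symbols.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in ISOTOPES:
            raise FormulaError(f"unknown element symbol: {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return Formula.from_dict(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of count x lightest-isotope mass over the formula's elements."""
    return sum(n * lightest_mass(sym) for sym, n in f.element_counts)


def _atom_pattern(symbol: str) -> dict[int, tuple[float, float]]:
    """Single-atom pattern keyed by nominal shift: shift -> (prob, prob*mass)."""
    isos = ISOTOPES[symbol]
    base = isos[0][0]
    out: dict[int, tuple[float, float]] = {}
    for mass, ab in isos:
        if ab <= 0.0:
            continue
        shift = round(mass - base)
        p, pm = out.get(shift, (0.0, 0.0))
        out[shift] = (p + ab, pm + ab * mass)
    return out


def _convolve(
    a: dict[int, tuple[float, float]],
    b: dict[int, tuple[float, float]],
    prune: float,
) -> dict[int, tuple[float, float]]:
    out: dict[int, tuple[float, float]] = {}
    for sa, (pa, ma) in a.items():
        mean_a = ma / pa
        for sb, (pb, mb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            s = sa + sb
            mean = mean_a + mb / pb
            acc_p, acc_pm = out.get(s, (0.0, 0.0))
            out[s] = (acc_p + p, acc_pm + p * mean)
    return out


def _element_pattern(symbol: str, count: int, prune: float) -> dict[int, tuple[float, float]]:
    """Pattern of ``count`` atoms of one element by binary exponentiation."""
    result: dict[int, tuple[float, float]] | None = None
    base = _atom_pattern(symbol)
    while count > 0:
        if count & 1:
            result = base if result is None else _convolve(result, base, prune)
        count >>= 1
        if count:
            base = _convolve(base, base, prune)
    assert result is not None
    return result


def isotope_pattern(
    f: Formula, min_proportion: float = 1e-4, _prune: float = 1e-12
) -> IsotopePattern:
    """Aggregated isotope pattern of a formula by iterated convolution.

    Entries below ``min_proportion`` of the total abundance are discarded and
    the remainder renormalised to sum to one.  ``_prune`` is the internal
    floor applied during convolution to bound intermediate pattern size.
    """
    if not f.element_counts:
        raise FormulaError("cannot compute isotope pattern of an empty formula")
    if not (0.0 < min_proportion < 1.0):
        raise ValueError("min_proportion must lie in (0, 1)")
    pattern: dict[int, tuple[float, float]] | None = None
    for sym, n in f.element_counts:
        elem = _element_pattern(sym, n, _prune)
        pattern = elem if pattern is None else _convolve(pattern, elem, _prune)
    assert pattern is not None
    kept = {
        s: (p, pm) for s, (p, pm) in pattern.items() if p >= min_proportion
    }
    if not kept:  # pathological min_proportion: keep the dominant entry
        s, val = max(pattern.items(), key=lambda kv: kv[1][0])
        kept = {s: val}
    total = sum(p for p, _ in kept.values())
    entries = tuple(
        (pm / p, p / total) for _, (p, pm) in sorted(kept.items())
    )
    return IsotopePattern(entries)


_ADDUCT_RE = re.compile(r"^(\d*)M((?:[+-]\d*[A-Za-z][A-Za-z0-9]*)*)$")
_ADDUCT_PART = re.compile(r"([+-])(\d*)([A-Za-z][A-Za-z0-9]*)")


def parse_adduct_rule(text: str, charge: int) -> AdductRule:
    """Parse an adduct rule string such as ``"M+H"``, ``"M-H"`` or ``"2M+3H"``.

    The leading integer is the molecular multiplicity (dimer, trimer, ...);
    each signed part gains or loses ``k`` copies of a formula fragment.  The
    ion charge is supplied explicitly alongside the string.
    """
    if charge == 0:
        raise FormulaError(f"adduct charge must be non-zero: {text!r}")
    m = _ADDUCT_RE.match(text.replace(" ", ""))
    if not m:
        raise FormulaError(f"cannot parse adduct rule: {text!r}")
    mult = int(m.group(1)) if m.group(1) else 1
    if mult < 1:
        raise FormulaError(f"adduct multiplicity must be >= 1: {text!r}")
    gained: dict[str, int] = {}
    lost: dict[str, int] = {}
    for sign, num, part in _ADDUCT_PART.findall(m.group(2)):
        k = int(num) if num else 1
        frag = parse_formula(part)
        target = gained if sign == "+" else lost
        for sym, n in frag.element_counts:
            target[sym] = target.get(sym, 0) + k * n
    return AdductRule(
        name=text,
        multiplicity=mult,
        gained=Formula.from_dict(gained),
        lost=Formula.from_dict(lost),
        charge=charge,
    )


def apply_adduct(pattern: IsotopePattern, rule: AdductRule) -> list[tuple[float, float]]:
    """Transform neutral isotope-pattern masses into ion m/z values.

    For each entry mass ``y``::

        mz = (multiplicity*y + mass(gained) - mass(lost) - charge*m_e) / |charge|

    Proportions are carried through unchanged.  For multiplicity >= 2 the
    caller should supply the pattern of the multiplied formula (see
    :func:`build_library`), since a dimer's isotope distribution is the
    convolution of the monomer with itself, not a mass-scaled copy.
    """
    delta = (
        monoisotopic_mass(rule.gained)
        - monoisotopic_mass(rule.lost)
        - rule.charge * ELECTRON_MASS
    )
    out = []
    for y, p in pattern.entries:
        mz = (rule.multiplicity * y + delta) / abs(rule.charge)
        if mz <= 0:
            raise FormulaError(
                f"adduct {rule.name!r} yields non-positive m/z for mass {y}"
            )
        out.append((mz, p))
    return out


@dataclass
class PeakLibrary:
    """Indexed collection of theoretical peaks with ppm-window lookup.

    ``peaks`` holds every materialised (formula, adduct, isotope) species;
    ``series[(m, a)]`` groups the isotope entries of one formula-adduct pair;
    ``n_adducts[m]`` is A_m, the number of adduct forms of formula m.
    """

    formulas: list[Formula]
    adducts: list[AdductRule]
    peaks: list[TheoreticalPeak]
    series: dict[tuple[int, int], list[TheoreticalPeak]] = field(default_factory=dict)
    formula_ids: list[str] | None = None
    formula_names: list[str] | None = None
    _sorted_mz: list[float] = field(default_factory=list, repr=False)
    _sorted_peaks: list[TheoreticalPeak] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.series:
            for p in self.peaks:
                self.series.setdefault((p.formula_index, p.adduct_index), []).append(p)
            for entries in self.series.values():
                entries.sort(key=lambda p: p.isotope_index)
        order = sorted(self.peaks, key=lambda p: p.mz)
        self._sorted_peaks = order
        self._sorted_mz = [p.mz for p in order]

    @property
    def n_formulas(self) -> int:
        return len(self.formulas)

    def n_adducts(self, formula_index: int) -> int:
        """A_m: number of adduct forms materialised for this formula."""
        return sum(1 for (m, _a) in self.series if m == formula_index)

    def n_isotopes(self, formula_index: int, adduct_index: int) -> int:
        """I_ma: number of isotope entries of one formula-adduct series."""
        return len(self.series[(formula_index, adduct_index)])

    def lookup(self, mz: float, window_ppm: float) -> list[TheoreticalPeak]:
        """All theoretical peaks with ``|log(mz/theoretical)| <= window_ppm*1e-6``.

        The log-space window matches the truncated mass likelihood, so lookup
        results coincide exactly with the sampler's candidate sets.
        """
        tol = window_ppm * 1e-6
        lo = mz * math.exp(-tol)
        hi = mz * math.exp(tol)
        i = bisect.bisect_left(self._sorted_mz, lo)
        j = bisect.bisect_right(self._sorted_mz, hi)
        return self._sorted_peaks[i:j]


def build_library(
    formulas: list[Formula],
    adducts: list[AdductRule],
    min_proportion: float = 1e-4,
    formula_ids: list[str] | None = None,
    formula_names: list[str] | None = None,
) -> PeakLibrary:
    """Materialise every (formula, adduct, isotope) theoretical peak.

    Dimer and higher-multiplicity adducts use the isotope pattern of the
    multiplied formula (element counts times multiplicity).
    """
    if not formulas:
        raise ValueError("formula list must be non-empty")
    peaks: list[TheoreticalPeak] = []
    # cache patterns per (formula index, multiplicity)
    pattern_cache: dict[tuple[int, int], IsotopePattern] = {}
    for m, f in enumerate(formulas):
        for a, rule in enumerate(adducts):
            key = (m, rule.multiplicity)
            pat = pattern_cache.get(key)
            if pat is None:
                eff = f if rule.multiplicity == 1 else f * rule.multiplicity
                pat = isotope_pattern(eff, min_proportion)
                pattern_cache[key] = pat
            # multiplicity already folded into the pattern
            flat_rule = AdductRule(rule.name, 1, rule.gained, rule.lost, rule.charge)
            for i, (mz, p) in enumerate(apply_adduct(pat, flat_rule)):
                peaks.append(TheoreticalPeak(m, a, i, mz, p))
    return PeakLibrary(
        formulas=list(formulas),
        adducts=list(adducts),
        peaks=peaks,
        formula_ids=formula_ids,
        formula_names=formula_names,
    )
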