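"""Embedded isotope table (IUPAC 2013 atomic masses and representative abundances).

Each entry maps an element symbol to a list of ``(mass_da, abundance)`` tuples
sorted by increasing isotope mass.  Abundances are the representative natural
terrestrial values; monoisotopic masses follow the convention of taking the
*lightest* isotope (which for all elements here is also the most abundant,
except none — the lightest is the reference for nominal mass shifts).

The table covers the elements that occur in small-molecule metabolomics and in
the common electrospray adducts.  Additional elements can be supplied at run
time via :func:`register_element` or a YAML config file.
"""

from __future__ import annotations

ELECTRON_MASS = 0.00054857990946  # Da

# symbol -> [(isotope mass in Da, relative abundance), ...] ordered by mass
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "P": [(30.97376151, 1.0)],
    "S": [
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ],
    "Na": [(22.98976928, 1.0)],
    "K": [
        (38.9637069, 0.932581),
        (39.96399867, 0.000117),
        (40.96182597, 0.067302),
    ],
    "Cl": [(34.96885271, 0.7576), (36.96590260, 0.2424)],
    "F": [(18.99840322, 1.0)],
    "Br": [(78.9183376, 0.5069), (80.9162906, 0.4931)],
    "Si": [
        (27.97692653, 0.92223),
        (28.97649466, 0.04685),
        (29.97377001, 0.03092),
    ],
    "Fe": [
        (53.9396105, 0.05845),
        (55.9349375, 0.91754),
        (56.9353940, 0.02119),
        (57.9332756, 0.00282),
    ],
    "Ca": [
        (39.9625912, 0.96941),
        (41.9586183, 0.00647),
        (42.9587668, 0.00135),
        (43.9554811, 0.02086),
        (45.9536928, 0.00004),
        (47.952534, 0.00187),
    ],
    "Mg": [(23.9850417, 0.7899), (24.9858370, 0.1000), (25.9825930, 0.1101)],
}


def register_element(symbol: str, isotopes: list[tuple[float, float]]) -> None:
    """Add or replace an element in the embedded table.

    ``isotopes`` is a list of ``(mass, abundance)`` pairs; abundances must be
    positive and are normalised to sum to one.
    """
    if not symbol or not symbol[0].isupper():
        raise ValueError(f"invalid element symbol: {symbol!r}")
    if not isotopes:
        raise ValueError("at least one isotope required")
    total = sum(ab for _, ab in isotopes)
    if total <= 0 or any(m <= 0 or ab < 0 for m, ab in isotopes):
        raise ValueError("isotope masses must be positive and abundances non-negative")
    ISOTOPES[symbol] = sorted(((m, ab / total) for m, ab in isotopes), key=lambda t: t[0])


def lightest_mass(symbol: str) -> float:
    """Mass of the lightest isotope of ``symbol`` (the monoisotopic reference)."""
    try:
        return ISOTOPES[symbol][0][0]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None
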