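"""Monoisotopic atomic masses, formula arithmetic, and ESI adduct tables.

Masses are CODATA/IUPAC monoisotopic values, tabulated to 1e-6 Da. A
formula is a plain ``{element: count}`` mapping; helpers add, subtract and
render them in Hill order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

# Monoisotopic masses of the light isotopes relevant to lipid chemistry.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Na": 22.989770,
    "K": 38.963707,
    "Cl": 34.968853,
}

PROTON_MASS = 1.007276  # mass of H minus electron mass

Formula = dict[str, int]


def formula_mass(formula: Formula) -> float:
    """Monoisotopic mass (Da) of a neutral formula."""
    try:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - guarded by rule tables
        raise ValueError(f"unknown element {exc} in formula {formula}") from exc


def formula_add(*formulas: Formula) -> Formula:
    total: Counter[str] = Counter()
    for f in formulas:
        total.update(f)
    return {el: n for el, n in total.items() if n != 0}


def formula_subtract(a: Formula, b: Formula) -> Formula:
    total = Counter(a)
    total.subtract(b)
    if any(n < 0 for n in total.values()):
        raise ValueError(f"negative element count subtracting {b} from {a}")
    return {el: n for el, n in total.items() if n != 0}


def formula_to_string(formula: Formula) -> str:
    """Render in Hill order: C, H, then alphabetical."""
    parts = []
    for el in ["C", "H"] + sorted(k for k in formula if k not in ("C", "H")):
        n = formula.get(el, 0)
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-order formula string like ``C42H82NO8P``."""
    import re

    out: Counter[str] = Counter()
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if el:
            out[el] += int(num) if num else 1
    return dict(out)


@dataclass(frozen=True)
class Adduct:
    """An ESI charge carrier: name, polarity, mass delta and charge.

    ``template_source`` names the adduct whose fragmentation template this
    adduct reuses; ``None`` means the adduct carries its own template.
    """

    name: str
    polarity: int
    mass_delta: float
    charge: int = 1
    template_source: str | None = None


# Deltas are (adduct mass - electron bookkeeping), singly charged throughout.
_H2O = MONOISOTOPIC_MASS["H"] * 2 + MONOISOTOPIC_MASS["O"]
_FORMIC = formula_mass({"C": 1, "H": 2, "O": 2})
_ACETIC = formula_mass({"C": 2, "H": 4, "O": 2})

ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, PROTON_MASS),
    "[M+Na]+": Adduct("[M+Na]+", +1, MONOISOTOPIC_MASS["Na"] - 0.000549),
    "[M+NH4]+": Adduct(
        "[M+NH4]+",
        +1,
        formula_mass({"N": 1, "H": 4}) - 0.000549,
        template_source="[M+Na]+",
    ),
    "[M+K]+": Adduct(
        "[M+K]+",
        +1,
        MONOISOTOPIC_MASS["K"] - 0.000549,
        template_source="[M+Na]+",
    ),
    "[M-H]-": Adduct("[M-H]-", -1, -PROTON_MASS),
    "[M+FA-H]-": Adduct("[M+FA-H]-", -1, _FORMIC - PROTON_MASS),
    "[M+Cl]-": Adduct(
        "[M+Cl]-",
        -1,
        MONOISOTOPIC_MASS["Cl"] + 0.000549,
        template_source="[M+FA-H]-",
    ),
    "[M+AcOH-H]-": Adduct(
        "[M+AcOH-H]-",
        -1,
        _ACETIC - PROTON_MASS,
        template_source="[M+FA-H]-",
    ),
}
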