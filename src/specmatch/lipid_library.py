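"""Rule-based in-silico lipid fragmentation library generator.

Enumerates lipid species per class over acyl-chain composition ranges and
emits adduct-specific fragment spectra from declarative rule templates,
mimicking stepped-energy HCD spectra. The shipped rule set covers six
classes (PC, PE, PG, TG, SM, CE); the engine is class-agnostic, and rule
tables can be supplied as YAML files with the same schema, so new classes
need no code changes.

Fragment intensities are template values on a base-peak-100 scale; peaks
below 0.2% of the base peak are removed, matching the convention that low
intensity peaks are kept only down to that cutoff. Adducts without their
own template borrow a donor's ([M+NH4]+ and [M+K]+ reuse the [M+Na]+
rules): rules that retain the charge carrier are re-evaluated at the
borrower's mass delta, all others keep the donor's fragment m/z.

The shipped intensity templates are synthetic stand-ins chosen to rank
the canonical diagnostic ions of each class (head-group ions, acyl
losses, carboxylates) the way published HCD spectra do; they are not
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb
from pathlib import Path
import warnings

import numpy as np

from specmatch.chem import (
    ADDUCTS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    Adduct,
    formula_add,
    formula_mass,
    formula_subtract,
    formula_to_string,
    parse_formula,
)
from specmatch.spectra_io import LibraryEntry, SpectralLibrary, Spectrum

H2O = {"H": 2, "O": 1}
H2O_MASS = formula_mass(H2O)
INTENSITY_CUTOFF_PCT = 0.2  # of base peak (base peak = 100)


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty-acyl chain: total carbons and C=C double bonds."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("acyl chain needs at least 2 carbons")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ValueError(
                f"invalid double bond count {self.double_bonds} for "
                f"{self.carbons} carbons"
            )

    @property
    def fa_formula(self) -> dict[str, int]:
        """Free fatty acid CcH(2c-2d)O2."""
        return {"C": self.carbons, "H": 2 * self.carbons - 2 * self.double_bonds, "O": 2}

    @property
    def fa_mass(self) -> float:
        return formula_mass(self.fa_formula)

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass
class FragmentRule:
    """One fragment-generating reaction of a class/adduct template.

    ``kind`` selects the mass expression:

    - ``precursor``          — the intact adduct ion
    - ``constant``           — fixed product ion; param is its neutral
                               formula, ionized by (de)protonation
    - ``neutral_loss``       — precursor minus param formula
    - ``chain_loss_fa``      — precursor minus each acyl chain as free acid
    - ``chain_loss_ketene``  — precursor minus each chain as ketene (FA - H2O)
    - ``chain_carboxylate``  — each chain as RCOO- (negative mode)
    - ``mh_minus_fa``        — [M-H]- minus each chain as free acid
                               (adduct-cluster dissociation products)

    ``retains_adduct`` marks rules whose product still carries the adduct
    charge carrier; only these shift when a template is borrowed by
    another adduct.
    """

    kind: str
    intensity: float
    param: str | None = None
    label: str = ""
    retains_adduct: bool = False


@dataclass
class LipidClassRules:
    """Backbone chemistry and per-adduct fragment templates of one class."""

    name: str
    backbone_formula: str  # head alcohol/base acylated by the chains
    n_chains: int
    templates: dict[str, list[FragmentRule]]
    chain_prefix: str = ""  # e.g. "d18:1/" for SM's fixed sphingoid base
    measured: bool = True  # False: mass-only template, uniform intensities


@dataclass
class LipidSpecies:
    """One enumerated species of a lipid class."""

    lipid_class: str
    chains: tuple[AcylChain, ...]
    formula: dict[str, int] = field(default_factory=dict)
    name: str = ""
    summed_name: str = ""

    @property
    def monoisotopic_mass(self) -> float:
        return formula_mass(self.formula)


def _species_formula(rules: LipidClassRules, chains: tuple[AcylChain, ...]) -> dict:
    """Backbone + chains, minus one water per esterification/amidation."""
    formula = parse_formula(rules.backbone_formula)
    for chain in chains:
        formula = formula_subtract(formula_add(formula, chain.fa_formula), H2O)
    return formula


def make_species(rules: LipidClassRules, chains: tuple[AcylChain, ...]) -> LipidSpecies:
    chains = tuple(sorted(chains))
    base_c, base_d = 0, 0
    if rules.chain_prefix:  # sphingoid base counts toward the summed composition
        pref = rules.chain_prefix.rstrip("/").lstrip("dt")
        base_c, base_d = (int(v) for v in pref.split(":"))
    total_c = sum(c.carbons for c in chains) + base_c
    total_d = sum(c.double_bonds for c in chains) + base_d
    chain_str = rules.chain_prefix + "/".join(str(c) for c in chains)
    return LipidSpecies(
        lipid_class=rules.name,
        chains=chains,
        formula=_species_formula(rules, chains),
        name=f"{rules.name} {chain_str}",
        summed_name=f"{rules.name} {total_c}:{total_d}",
    )


def enumerate_species(
    rules: LipidClassRules,
    carbon_range: list[int],
    db_range: list[int],
    chains_count: int | None = None,
) -> list[LipidSpecies]:
    """All chain-composition-distinct species over the given chain space.

    Chain order is chemically unresolved here, so compositions are
    de-duplicated as sorted multisets (PC 16:0/18:1 == PC 18:1/16:0);
    the species count is the multiset coefficient
    C(n_chain_types + chains - 1, chains). Chain types with an impossible
    double-bond count are skipped with a warning.
    """
    chains_count = chains_count or rules.n_chains
    chain_types = []
    for c in carbon_range:
        for d in db_range:
            try:
                chain_types.append(AcylChain(c, d))
            except ValueError as exc:
                warnings.warn(f"skipping chain {c}:{d}: {exc}", stacklevel=2)
    species = [
        make_species(rules, combo)
        for combo in combinations_with_replacement(sorted(chain_types), chains_count)
    ]
    expected = comb(len(chain_types) + chains_count - 1, chains_count)
    assert len(species) == expected
    return species


def expected_species_count(n_chain_types: int, chains_count: int) -> int:
    """Closed-form combinations-with-repetition count."""
    return comb(n_chain_types + chains_count - 1, chains_count)


def _resolve_template(
    rules: LipidClassRules, adduct: Adduct
) -> tuple[list[FragmentRule], Adduct]:
    """Template for an adduct: its own, else its donor's (one hop)."""
    if adduct.name in rules.templates:
        return rules.templates[adduct.name], adduct
    if adduct.template_source and adduct.template_source in rules.templates:
        return rules.templates[adduct.template_source], ADDUCTS[adduct.template_source]
    raise ValueError(
        f"no fragmentation template for class {rules.name} with adduct {adduct.name}"
    )


def _rule_mzs(
    rule: FragmentRule,
    species: LipidSpecies,
    delta: float,
    polarity: int,
) -> list[float]:
    M = species.monoisotopic_mass
    precursor = M + delta
    if rule.kind == "precursor":
        return [precursor]
    if rule.kind == "constant":
        return [formula_mass(parse_formula(rule.param)) + polarity * PROTON_MASS]
    if rule.kind == "neutral_loss":
        return [precursor - formula_mass(parse_formula(rule.param))]
    if rule.kind == "chain_loss_fa":
        return [precursor - ch.fa_mass for ch in set(species.chains)]
    if rule.kind == "chain_loss_ketene":
        return [precursor - (ch.fa_mass - H2O_MASS) for ch in set(species.chains)]
    if rule.kind == "chain_carboxylate":
        return [ch.fa_mass - PROTON_MASS for ch in set(species.chains)]
    if rule.kind == "mh_minus_fa":
        return [(M - PROTON_MASS) - ch.fa_mass for ch in set(species.chains)]
    raise ValueError(f"unknown fragment rule kind: {rule.kind}")


def fragment_spectrum(
    species: LipidSpecies,
    adduct_name: str,
    rules: LipidClassRules,
) -> LibraryEntry:
    """Predict the fragment spectrum of one species/adduct pair.

    Precursor m/z is (monoisotopic mass + adduct delta) / charge. The
    template's peaks are evaluated, duplicate m/z merged (summed), peaks
    below 0.2% of the base peak removed, and the result normalized to
    base peak 100.
    """
    adduct = ADDUCTS[adduct_name]
    template, donor = _resolve_template(rules, adduct)
    precursor_mz = (species.monoisotopic_mass + adduct.mass_delta) / adduct.charge
    peaks: list[tuple[float, float]] = []
    intensity = (
        (lambda r: r.intensity)
        if rules.measured
        else (lambda r: 100.0)  # mass-only template: uniform nominal intensity
    )
    for rule in template:
        # borrowed template: charge-retaining products shift to the
        # borrower's delta, charge-independent products keep the donor m/z
        delta = adduct.mass_delta if rule.retains_adduct else donor.mass_delta
        if rule.kind in ("constant", "chain_carboxylate", "mh_minus_fa"):
            delta = adduct.mass_delta  # adduct-independent expressions
        for mz in _rule_mzs(rule, species, delta, adduct.polarity):
            if mz > 0:
                peaks.append((mz, intensity(rule)))
    spectrum = Spectrum.from_peaks(peaks)
    base = spectrum.base_peak_intensity()
    keep = spectrum.intensity >= base * INTENSITY_CUTOFF_PCT / 100.0
    spectrum = Spectrum(spectrum.mz[keep], spectrum.intensity[keep] * (100.0 / base))
    chain_comp = rules.chain_prefix + "/".join(str(c) for c in species.chains)
    return LibraryEntry(
        compound_name=species.name,
        precursor_mz=precursor_mz,
        adduct=adduct.name,
        polarity=adduct.polarity,
        spectrum=spectrum,
        formula=formula_to_string(species.formula),
        metadata={
            "class": species.lipid_class,
            "summed_composition": species.summed_name.split(" ", 1)[1],
            "chain_composition": chain_comp,
            "adduct": adduct.name,
        },
    )


# ---------------------------------------------------------------------------
# Shipped class rule tables
# ---------------------------------------------------------------------------

def _r(kind, intensity, param=None, label="", retains=False) -> FragmentRule:
    return FragmentRule(kind, intensity, param, label, retains)


SHIPPED_CLASSES: dict[str, LipidClassRules] = {
    "PC": LipidClassRules(
        name="PC",
        backbone_formula="C8H20NO6P",  # glycerophosphocholine
        n_chains=2,
        templates={
            "[M+H]+": [
                _r("constant", 100.0, "C5H14NO4P", "phosphocholine head group"),
                _r("precursor", 25.0, label="[M+H]+", retains=True),
                _r("chain_loss_ketene", 12.0, label="lyso-PC (ketene loss)", retains=True),
                _r("chain_loss_fa", 8.0, label="acyl loss as free acid", retains=True),
            ],
            "[M+Na]+": [
                _r("precursor", 100.0, label="[M+Na]+", retains=True),
                _r("neutral_loss", 60.0, "C3H9N", "trimethylamine loss", retains=True),
                _r("neutral_loss", 40.0, "C5H14NO4P", "phosphocholine loss", retains=True),
                _r("chain_loss_fa", 5.0, label="acyl loss as free acid", retains=True),
            ],
        },
    ),
    "PE": LipidClassRules(
        name="PE",
        backbone_formula="C5H14NO6P",  # glycerophosphoethanolamine
        n_chains=2,
        templates={
            "[M+H]+": [
                _r("neutral_loss", 100.0, "C2H8NO4P", "phosphoethanolamine loss", retains=True),
                _r("precursor", 10.0, label="[M+H]+", retains=True),
                _r("chain_loss_fa", 5.0, label="acyl loss as free acid", retains=True),
                _r("chain_loss_ketene", 5.0, label="lyso-PE (ketene loss)", retains=True),
            ],
            "[M-H]-": [
                _r("chain_carboxylate", 100.0, label="fatty acyl RCOO-"),
                _r("chain_loss_ketene", 20.0, label="lyso-PE (ketene loss)", retains=True),
                _r("chain_loss_fa", 15.0, label="acyl loss as free acid", retains=True),
                _r("precursor", 10.0, label="[M-H]-", retains=True),
                _r("constant", 8.0, "C3H8O5P", "glycerophosphate - H2O"),
            ],
            "[M+FA-H]-": [
                _r("chain_carboxylate", 100.0, label="fatty acyl RCOO-"),
                _r("precursor", 15.0, label="[M+FA-H]-", retains=True),
                _r("mh_minus_fa", 10.0, label="[M-H]- minus acyl"),
            ],
        },
    ),
    "PG": LipidClassRules(
        name="PG",
        backbone_formula="C6H15O8P",  # glycerophosphoglycerol
        n_chains=2,
        templates={
            "[M-H]-": [
                _r("chain_carboxylate", 100.0, label="fatty acyl RCOO-"),
                _r("precursor", 20.0, label="[M-H]-", retains=True),
                _r("chain_loss_ketene", 15.0, label="lyso-PG (ketene loss)", retains=True),
                _r("chain_loss_fa", 10.0, label="acyl loss as free acid", retains=True),
                _r("constant", 8.0, "C3H8O5P", "glycerophosphate - H2O"),
            ],
            "[M+FA-H]-": [
                _r("chain_carboxylate", 100.0, label="fatty acyl RCOO-"),
                _r("precursor", 15.0, label="[M+FA-H]-", retains=True),
                _r("mh_minus_fa", 10.0, label="[M-H]- minus acyl"),
            ],
        },
    ),
    "TG": LipidClassRules(
        name="TG",
        backbone_formula="C3H8O3",  # glycerol
        n_chains=3,
        templates={
            "[M+Na]+": [
                _r("chain_loss_fa", 100.0, label="DG fragment (acyl loss)", retains=True),
                _r("precursor", 40.0, label="[M+Na]+", retains=True),
            ],
        },
    ),
    "SM": LipidClassRules(
        name="SM",
        backbone_formula="C23H49N2O5P",  # sphingosylphosphorylcholine (d18:1)
        n_chains=1,
        chain_prefix="d18:1/",
        templates={
            "[M+H]+": [
                _r("constant", 100.0, "C5H14NO4P", "phosphocholine head group"),
                _r("precursor", 30.0, label="[M+H]+", retains=True),
                _r("neutral_loss", 5.0, "H2O", "water loss", retains=True),
            ],
            "[M+Na]+": [
                _r("precursor", 100.0, label="[M+Na]+", retains=True),
                _r("neutral_loss", 50.0, "C3H9N", "trimethylamine loss", retains=True),
            ],
        },
    ),
    "CE": LipidClassRules(
        name="CE",
        backbone_formula="C27H46O",  # cholesterol
        n_chains=1,
        templates={
            "[M+H]+": [
                _r("constant", 100.0, "C27H44", "cholestadienyl cation"),
                _r("precursor", 3.0, label="[M+H]+", retains=True),
            ],
            "[M+Na]+": [
                _r("precursor", 100.0, label="[M+Na]+", retains=True),
                _r("constant", 20.0, "C27H44", "cholestadienyl cation"),
            ],
        },
    ),
}

DEFAULT_CARBON_RANGE = list(range(12, 23, 2))  # even carbons 12-22
DEFAULT_DB_RANGE = list(range(0, 7))  # 0-6 double bonds

# adducts offered per class by default: own templates plus borrowers
DEFAULT_CLASS_ADDUCTS: dict[str, list[str]] = {
    "PC": ["[M+H]+", "[M+Na]+", "[M+NH4]+"],
    "PE": ["[M+H]+", "[M-H]-", "[M+FA-H]-"],
    "PG": ["[M-H]-", "[M+FA-H]-", "[M+Cl]-"],
    "TG": ["[M+Na]+", "[M+NH4]+"],
    "SM": ["[M+H]+", "[M+Na]+"],
    "CE": ["[M+H]+", "[M+Na]+", "[M+NH4]+"],
}


@dataclass
class LibraryBuildConfig:
    classes: list[str] = field(default_factory=lambda: list(SHIPPED_CLASSES))
    carbon_range: list[int] = field(default_factory=lambda: list(DEFAULT_CARBON_RANGE))
    db_range: list[int] = field(default_factory=lambda: list(DEFAULT_DB_RANGE))
    adducts: dict[str, list[str]] | None = None  # per class; None = defaults
    name: str = "insilico_lipids"


def build_library(
    config: LibraryBuildConfig | None = None, msp_path: str | Path | None = None
) -> SpectralLibrary:
    """Enumerate species x adducts for the configured classes.

    Output order is deterministic: class (config order), species name,
    adduct (config order). Optionally writes the library as msp.
    """
    from specmatch.spectra_io import write_msp

    config = config or LibraryBuildConfig()
    entries: list[LibraryEntry] = []
    for class_name in config.classes:
        rules = SHIPPED_CLASSES[class_name]
        adducts = (config.adducts or DEFAULT_CLASS_ADDUCTS)[class_name]
        species = enumerate_species(rules, config.carbon_range, config.db_range)
        species.sort(key=lambda s: s.name)
        for sp in species:
            for adduct_name in adducts:
                entries.append(fragment_spectrum(sp, adduct_name, rules))
    library = SpectralLibrary(config.name, entries)
    if msp_path is not None:
        write_msp(library, msp_path)
    return library


def load_class_rules_yaml(path: str | Path) -> LipidClassRules:
    """Load a user-supplied class rule table (YAML, same schema as shipped)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    templates = {
        adduct: [
            FragmentRule(
                kind=r["kind"],
                intensity=float(r["intensity"]),
                param=r.get("param"),
                label=r.get("label", ""),
                retains_adduct=bool(r.get("retains_adduct", False)),
            )
            for r in rules
        ]
        for adduct, rules in data["templates"].items()
    }
    return LipidClassRules(
        name=data["name"],
        backbone_formula=data["backbone_formula"],
        n_chains=int(data["n_chains"]),
        templates=templates,
        chain_prefix=data.get("chain_prefix", ""),
        measured=bool(data.get("measured", True)),
    )
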