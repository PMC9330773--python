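"""Cross-library annotation concordance and the Retention Balance Point.

When the same dataset is annotated against two spectral libraries, each
feature's pair of annotations is classified on an agreement hierarchy
(same class < same class+adduct < same summed composition+adduct < full
agreement). Collapsing per-feature agreements and disagreements over a
score threshold gives a single objective,

    objective(t) = (#agreements with score >= t) / (#agreements)
                 - (#disagreements with score >= t) / (#disagreements)

whose maximizing threshold is the Retention Balance Point (RBP). The RBP
of each library is then used to discard that library's annotations below
threshold; a feature annotated by both libraries but surviving only one
library's threshold keeps the surviving annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "LipidAnnotation",
    "AgreementLevel",
    "RbpResult",
    "parse_lipid_name",
    "classify_agreement",
    "compute_rbp",
    "reconcile",
]


class AgreementLevel(IntEnum):
    """Hierarchy of cross-library agreement, lowest to highest."""

    FULL_DISAGREEMENT = 0
    CLASS = 1
    CLASS_ADDUCT = 2
    SUMMED_ADDUCT = 3
    FULL_AGREEMENT = 4

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass
class LipidAnnotation:
    """A parsed lipid annotation at whatever level the name resolves."""

    lipid_class: str
    summed_composition: tuple[int, int] | None = None  # (carbons, double bonds)
    chain_composition: tuple[tuple[int, int], ...] | None = None
    adduct: str = ""
    compound_name: str = ""
    score: float = float("nan")
    parse_ok: bool = True


_CHAIN_RE = re.compile(r"^[a-z]*?(\d+):(\d+)$")


def parse_lipid_name(name: str, adduct: str = "", score: float = float("nan")) -> LipidAnnotation:
    """Parse shorthand lipid names.

    Grammar: ``CLASS C:D`` (summed form) or ``CLASS chain1/chain2[/...]``
    (chain form; an optional sphingoid prefix letter like ``d18:1`` is
    tolerated). Unknown grammar yields a class-only annotation with
    ``parse_ok=False``. Empty names are an error.
    """
    name = name.strip()
    if not name:
        raise ValueError("empty lipid name")
    parts = name.split(None, 1)
    lipid_class = parts[0]
    ann = LipidAnnotation(
        lipid_class=lipid_class, adduct=adduct, compound_name=name, score=score
    )
    if len(parts) == 1:
        ann.parse_ok = False
        return ann
    body = parts[1].strip()
    chain_tokens = body.split("/")
    chains: list[tuple[int, int]] = []
    for token in chain_tokens:
        match = _CHAIN_RE.match(token.strip().lower())
        if not match:
            ann.parse_ok = False
            return ann
        chains.append((int(match.group(1)), int(match.group(2))))
    total = (sum(c for c, _ in chains), sum(d for _, d in chains))
    if len(chain_tokens) == 1:
        ann.summed_composition = total  # "PC 34:1" — summed form only
    else:
        ann.chain_composition = tuple(sorted(chains))
        ann.summed_composition = total
    return ann


def classify_agreement(a: LipidAnnotation, b: LipidAnnotation) -> AgreementLevel:
    """Highest satisfied level of the agreement hierarchy.

    Same class -> CLASS; plus same adduct -> CLASS_ADDUCT; plus same
    summed composition -> SUMMED_ADDUCT; plus same chain composition (or
    identical compound names when chains are absent) -> FULL_AGREEMENT.
    Adducts compare as exact strings.
    """
    if a.lipid_class != b.lipid_class:
        return AgreementLevel.FULL_DISAGREEMENT
    level = AgreementLevel.CLASS
    if a.adduct != b.adduct:
        return level
    level = AgreementLevel.CLASS_ADDUCT
    if a.summed_composition is None or a.summed_composition != b.summed_composition:
        return level
    level = AgreementLevel.SUMMED_ADDUCT
    if a.chain_composition is not None and a.chain_composition == b.chain_composition:
        return AgreementLevel.FULL_AGREEMENT
    if a.chain_composition is None and b.chain_composition is None:
        if a.compound_name == b.compound_name:
            return AgreementLevel.FULL_AGREEMENT
    return level


@dataclass
class RbpResult:
    """The score threshold maximizing agreement minus disagreement retention."""

    threshold: float
    objective: float
    library_name: str = ""


@dataclass
class ComparisonSet:
    """Per-library score lists for agreeing and disagreeing features."""

    library_name: str
    agreements: list[float] = field(default_factory=list)
    disagreements: list[float] = field(default_factory=list)


def compute_rbp(
    agreement_scores: list[float] | np.ndarray,
    disagreement_scores: list[float] | np.ndarray,
    library_name: str = "",
) -> RbpResult:
    """Retention Balance Point of one library's score distributions.

    The objective

        frac(agreements >= t) - frac(disagreements >= t)

    is a step function changing only at observed scores, so candidate
    thresholds are exactly the distinct observed values (union of both
    lists). Returns the maximizing threshold; on ties, the lowest such
    threshold (retaining the most annotations at equal objective).
    """
    agree = np.sort(np.asarray(agreement_scores, dtype=float))
    disagree = np.sort(np.asarray(disagreement_scores, dtype=float))
    if agree.size == 0 or disagree.size == 0:
        raise ValueError("compute_rbp requires non-empty agreement and disagreement lists")
    candidates = np.unique(np.concatenate([agree, disagree]))
    # integer counts first, one division each: bit-identical to the
    # definition ((scores >= t).mean()) so threshold ties break exactly
    n_agree = agree.size - np.searchsorted(agree, candidates, side="left")
    n_disagree = disagree.size - np.searchsorted(disagree, candidates, side="left")
    objective = n_agree / agree.size - n_disagree / disagree.size
    # candidates ascend, argmax returns the first maximum -> lowest threshold
    best = int(np.argmax(objective))
    return RbpResult(float(candidates[best]), float(objective[best]), library_name)


def _annotation_from_row(row: pd.Series, lib: str) -> LipidAnnotation | None:
    compound = row.get(f"{lib}_compound")
    if compound is None or (isinstance(compound, float) and np.isnan(compound)):
        return None
    return parse_lipid_name(
        str(compound),
        adduct=str(row.get(f"{lib}_adduct") or ""),
        score=float(row.get(f"{lib}_score", np.nan)),
    )


def comparison_sets(
    annotations: pd.DataFrame, lib_a: str, lib_b: str
) -> tuple[ComparisonSet, ComparisonSet]:
    """Split doubly-annotated features into agreement/disagreement score
    sets for each library. Agreement means any class-level-or-better
    match of the two annotations."""
    set_a = ComparisonSet(lib_a)
    set_b = ComparisonSet(lib_b)
    for _, row in annotations.iterrows():
        ann_a = _annotation_from_row(row, lib_a)
        ann_b = _annotation_from_row(row, lib_b)
        if ann_a is None or ann_b is None:
            continue
        agree = classify_agreement(ann_a, ann_b) > AgreementLevel.FULL_DISAGREEMENT
        (set_a.agreements if agree else set_a.disagreements).append(ann_a.score)
        (set_b.agreements if agree else set_b.disagreements).append(ann_b.score)
    return set_a, set_b


def compute_library_rbps(
    annotations: pd.DataFrame, lib_a: str, lib_b: str
) -> dict[str, RbpResult]:
    """Library-specific RBP thresholds from a two-library annotation table."""
    set_a, set_b = comparison_sets(annotations, lib_a, lib_b)
    return {
        lib_a: compute_rbp(set_a.agreements, set_a.disagreements, lib_a),
        lib_b: compute_rbp(set_b.agreements, set_b.disagreements, lib_b),
    }


_SUMMARY_ROWS = [
    ("both_full_agreement", "Both libraries, same compound and adduct"),
    ("both_summed_adduct", "Both libraries, same summed composition and adduct"),
    ("both_class_adduct", "Both libraries, same lipid class and adduct"),
    ("both_class", "Both libraries, same lipid class"),
    ("both_full_disagreement", "Both libraries, full disagreement"),
    ("only_a", "Annotated by first library only"),
    ("only_b", "Annotated by second library only"),
    ("unannotated", "Unannotated"),
]

_LEVEL_TO_ROW = {
    AgreementLevel.FULL_AGREEMENT: "both_full_agreement",
    AgreementLevel.SUMMED_ADDUCT: "both_summed_adduct",
    AgreementLevel.CLASS_ADDUCT: "both_class_adduct",
    AgreementLevel.CLASS: "both_class",
    AgreementLevel.FULL_DISAGREEMENT: "both_full_disagreement",
}


def _compound_key(ann: LipidAnnotation) -> tuple:
    """Adduct-collapsed compound identity for compound-level counts."""
    return (
        ann.lipid_class,
        ann.chain_composition
        if ann.chain_composition is not None
        else ann.summed_composition,
    )


def reconcile(
    annotations: pd.DataFrame,
    rbp_by_library: dict[str, RbpResult | float],
    lib_a: str,
    lib_b: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RBP-threshold annotations and classify every feature.

    An annotation survives when its score is at or above its own
    library's threshold (one-library features face only their own
    library's RBP). Each feature lands in exactly one category:
    unannotated / only-A / only-B / both (at its agreement level).

    Returns (per-feature table, summary). The summary has one row per
    category with feature counts, percentages, and adduct-collapsed
    compound counts for the "both" categories.
    """
    thresholds = {
        lib: (r.threshold if isinstance(r, RbpResult) else float(r))
        for lib, r in rbp_by_library.items()
    }
    records = []
    compound_keys: dict[str, set] = {key: set() for key, _ in _SUMMARY_ROWS}
    for _, row in annotations.iterrows():
        ann_a = _annotation_from_row(row, lib_a)
        ann_b = _annotation_from_row(row, lib_b)
        if ann_a is not None and ann_a.score < thresholds[lib_a]:
            ann_a = None
        if ann_b is not None and ann_b.score < thresholds[lib_b]:
            ann_b = None
        if ann_a is None and ann_b is None:
            category = "unannotated"
            level = None
        elif ann_b is None:
            category, level = "only_a", None
            compound_keys[category].add(_compound_key(ann_a))
        elif ann_a is None:
            category, level = "only_b", None
            compound_keys[category].add(_compound_key(ann_b))
        else:
            level = classify_agreement(ann_a, ann_b)
            category = _LEVEL_TO_ROW[level]
            compound_keys[category].add(_compound_key(ann_a))
        records.append(
            {
                "group_id": row["group_id"],
                "category": category,
                "agreement_level": level.label if level is not None else "",
                f"{lib_a}_compound": ann_a.compound_name if ann_a else None,
                f"{lib_b}_compound": ann_b.compound_name if ann_b else None,
            }
        )
    per_feature = pd.DataFrame(records)
    total = len(per_feature)
    counts = per_feature["category"].value_counts()
    summary = pd.DataFrame(
        [
            {
                "category": key,
                "description": desc,
                "features": int(counts.get(key, 0)),
                "feature_pct": 100.0 * counts.get(key, 0) / total if total else 0.0,
                "compounds": len(compound_keys[key]),
            }
            for key, desc in _SUMMARY_ROWS
        ]
    )
    return per_feature, summary
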