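"""Gene-disease validity scoring (case-level point rules, SOP v9 style).

Implements the case-point rules used for the six RASopathy gene-disease
recurations: a de novo missense variant earns the default 0.5 points, a
missense variant with functional data supporting a gain-of-function
mechanism earns 1 point, and a de novo missense variant *with* GoF
functional support earns the maximum 1.5 points.  Genetic evidence is
capped at 12 points and experimental evidence at 6; the total maps to
Limited / Moderate / Strong, with Strong-range totals replicated over time
qualifying as Definitive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

GENETIC_CAP = 12.0
EXPERIMENTAL_CAP = 6.0
TOTAL_CAP = 18.0

#: Default case points by rule: the de novo missense default, the GoF
#: functional uplift, and the maximum for both together.  ``other_case`` is
#: the SOP default for case types the recurations did not detail.
DE_NOVO_MISSENSE_POINTS = 0.5
GOF_MISSENSE_POINTS = 1.0
DE_NOVO_GOF_MISSENSE_POINTS = 1.5
OTHER_CASE_DEFAULT_POINTS = 0.5
CASE_POINT_BOUNDS = (0.0, 1.5)


class ValidityClassification(str, enum.Enum):
    Limited = "Limited"
    Moderate = "Moderate"
    Strong = "Strong"
    Definitive = "Definitive"


class CaseClass(str, enum.Enum):
    de_novo_missense = "de_novo_missense"
    other_case = "other_case"


@dataclass(frozen=True)
class CaseEntry:
    variant_class: CaseClass
    has_gof_functional: bool = False
    points_override: Optional[float] = None


@dataclass(frozen=True)
class ExperimentalEntry:
    category: str
    points: float


@dataclass
class ValidityEvidence:
    cases: list[CaseEntry] = field(default_factory=list)
    experimental: list[ExperimentalEntry] = field(default_factory=list)
    first_report_year: Optional[int] = None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ValidityEvidence":
        """Read an evidence table: columns entry_type (case|experimental),
        variant_class, has_gof_functional, points ('.' for default)."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
        ev = cls()
        for _, r in df.iterrows():
            if r["entry_type"] == "case":
                override = r.get("points", ".")
                ev.cases.append(
                    CaseEntry(
                        variant_class=CaseClass(r["variant_class"]),
                        has_gof_functional=str(r.get("has_gof_functional", "false"))
                        .strip().lower() in {"1", "true", "yes"},
                        points_override=None
                        if override in (".", "")
                        else float(override.replace("−", "-")),
                    )
                )
            elif r["entry_type"] == "experimental":
                ev.experimental.append(
                    ExperimentalEntry(
                        category=r.get("variant_class", "experimental"),
                        points=float(str(r["points"]).replace("−", "-")),
                    )
                )
            else:
                raise ValueError(f"unknown entry_type {r['entry_type']!r}")
        return ev


@dataclass(frozen=True)
class ValidityResult:
    genetic_points: float
    experimental_points: float
    total_points: float
    classification: ValidityClassification
    warnings: tuple[str, ...] = ()


def case_points(entry: CaseEntry) -> float:
    """Points for one case per the recuration rules (override wins, bounded)."""
    if entry.points_override is not None:
        lo, hi = CASE_POINT_BOUNDS
        return min(max(entry.points_override, lo), hi)
    if entry.variant_class is CaseClass.de_novo_missense:
        return (
            DE_NOVO_GOF_MISSENSE_POINTS
            if entry.has_gof_functional
            else DE_NOVO_MISSENSE_POINTS
        )
    if entry.has_gof_functional:
        return GOF_MISSENSE_POINTS
    return OTHER_CASE_DEFAULT_POINTS


def score_validity(
    evidence: ValidityEvidence, replicated_over_time: bool = False
) -> ValidityResult:
    """Score a gene-disease relationship from case and experimental evidence.

    Classification bins: total 12-18 is Strong (Definitive when replicated
    over time), 7-11 Moderate, 0.1-6 Limited.
    """
    warnings: list[str] = []
    genetic = sum(case_points(c) for c in evidence.cases)
    if genetic > GENETIC_CAP:
        warnings.append(
            f"genetic evidence {genetic:g} capped at {GENETIC_CAP:g}"
        )
        genetic = GENETIC_CAP
    experimental = sum(e.points for e in evidence.experimental)
    if experimental > EXPERIMENTAL_CAP:
        warnings.append(
            f"experimental evidence {experimental:g} capped at {EXPERIMENTAL_CAP:g}"
        )
        experimental = EXPERIMENTAL_CAP
    total = min(genetic + experimental, TOTAL_CAP)

    if total >= 12.0:
        classification = (
            ValidityClassification.Definitive
            if replicated_over_time
            else ValidityClassification.Strong
        )
    elif total >= 7.0:
        classification = ValidityClassification.Moderate
    else:
        classification = ValidityClassification.Limited
        if total < 0.1:
            warnings.append("no scorable evidence; treated as Limited (0 points)")

    return ValidityResult(
        genetic_points=genetic,
        experimental_points=experimental,
        total_points=total,
        classification=classification,
        warnings=tuple(warnings),
    )
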