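"""Bookkeeping for docking scores and MM-PBSA binding free energies.

Docking and MM-PBSA numbers are produced by external engines (Surflex-Dock,
g_mmpbsa); this module consumes their tabulated output.  It grades
Surflex Total Scores into binding-activity classes (> 4 certain, > 5 good,
> 7 strong, strict comparisons), checks the additivity of MM-PBSA
components,

    dG_bind = dE_vdW + dE_elec + dG_polar + dG_SASA   (kJ/mol),

and calls *critical residues* from per-residue energy decompositions: a
residue is critical when its contribution exceeds +threshold or falls below
-threshold (default 5 kJ/mol, strict).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

__all__ = [
    "GRADES",
    "ADDITIVITY_TOL",
    "DockScore",
    "EnergyComponents",
    "ResidueEnergyProfile",
    "classify_total_score",
    "grade_rank",
    "total_binding_energy",
    "critical_residues",
    "rank_residues",
    "ScoreMatrixReport",
    "score_matrix_report",
]

#: Binding-activity grades in increasing order of affinity.
GRADES = ("none", "certain", "good", "strong")

#: Tolerance (kJ/mol) when validating an externally supplied total against
#: the sum of its components; accommodates 3-decimal rounding of each term.
ADDITIVITY_TOL = 0.005


@dataclass(frozen=True)
class DockScore:
    """One docking result: Surflex Total Score of a compound-target pair."""

    compound: str
    target: str
    total_score: float


@dataclass(frozen=True)
class EnergyComponents:
    """MM-PBSA energy decomposition of one protein-ligand complex (kJ/mol)."""

    complex_id: str
    e_vdw: float | None = None   # van der Waals interaction energy
    e_elec: float | None = None  # electrostatic interaction energy
    g_polar: float | None = None  # polar solvation energy
    g_sasa: float | None = None  # non-polar (SASA) solvation energy
    g_bind: float | None = None  # total binding free energy, optional on input


@dataclass(frozen=True)
class ResidueEnergyProfile:
    """Per-residue decomposition of one complex's binding free energy."""

    complex_id: str
    contributions: dict[str, float] = field(default_factory=dict)


def classify_total_score(score: float) -> str:
    """Grade a Surflex Total Score: >7 strong, >5 good, >4 certain, else none.

    All comparisons are strict, so a score of exactly 4.0 grades as 'none'.
    """
    if score is None or not math.isfinite(score):
        raise ValidationError(f"total score must be finite, got {score!r}")
    if score > 7.0:
        return "strong"
    if score > 5.0:
        return "good"
    if score > 4.0:
        return "certain"
    return "none"


def grade_rank(grade: str) -> int:
    """Position of a grade in the none < certain < good < strong order."""
    return GRADES.index(grade)


def total_binding_energy(c: EnergyComponents, tol: float = ADDITIVITY_TOL) -> float:
    """Sum of the four MM-PBSA components.

    If the record carries an externally supplied total, it is checked
    against the computed sum and a warning is emitted when they disagree
    beyond ``tol``.
    """
    parts = {"e_vdw": c.e_vdw, "e_elec": c.e_elec,
             "g_polar": c.g_polar, "g_sasa": c.g_sasa}
    missing = [name for name, v in parts.items() if v is None]
    if missing:
        raise ValidationError(
            f"complex {c.complex_id!r} lacks component(s): {', '.join(missing)}"
        )
    total = c.e_vdw + c.e_elec + c.g_polar + c.g_sasa
    if c.g_bind is not None and abs(total - c.g_bind) > tol:
        warnings.warn(
            f"complex {c.complex_id!r}: supplied total {c.g_bind} differs from "
            f"component sum {total:.3f} by more than {tol} kJ/mol",
            stacklevel=2,
        )
    return total


def critical_residues(profile: ResidueEnergyProfile, threshold: float = 5.0) -> set[str]:
    """Residues whose energy contribution exceeds +/- threshold (strict).

    An empty profile yields an empty set.  The set shrinks (weakly) as the
    threshold grows.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    return {
        res for res, e in profile.contributions.items()
        if e > threshold or e < -threshold
    }


def rank_residues(profile: ResidueEnergyProfile) -> list[tuple[str, float]]:
    """All residues sorted by |energy| descending (ties by residue id)."""
    return sorted(
        profile.contributions.items(), key=lambda kv: (-abs(kv[1]), kv[0])
    )


@dataclass(frozen=True)
class ScoreMatrixReport:
    """Compound x target docking-score matrix with per-pair grades."""

    scores: pd.DataFrame  # float matrix, NaN where a pair is absent
    grades: pd.DataFrame  # grade strings, 'absent' where missing
    grade_counts: dict[str, int]

    @property
    def n_cells(self) -> int:
        return int(self.scores.size)


def score_matrix_report(scores: list[DockScore]) -> ScoreMatrixReport:
    """Arrange docking scores as a compound x target matrix and grade them.

    Duplicate (compound, target) rows with identical scores are collapsed;
    conflicting duplicates raise.  Matrix dimensions are the number of
    distinct compounds x distinct targets; pairs never docked are NaN in
    the score matrix and 'absent' in the grade matrix.
    """
    if not scores:
        raise ValidationError("no docking scores supplied")
    seen: dict[tuple[str, str], float] = {}
    for s in scores:
        key = (s.compound, s.target)
        if key in seen and not math.isclose(seen[key], s.total_score,
                                            rel_tol=0.0, abs_tol=1e-9):
            raise ValidationError(
                f"conflicting scores for pair {key}: {seen[key]} vs {s.total_score}"
            )
        seen[key] = s.total_score
    compounds = sorted({c for c, _ in seen})
    targets = sorted({t for _, t in seen})
    mat = pd.DataFrame(float("nan"), index=compounds, columns=targets)
    for (c, t), v in seen.items():
        mat.loc[c, t] = v
    grades = mat.map(
        lambda v: "absent" if pd.isna(v) else classify_total_score(v)
    )
    counts = {g: int((grades == g).sum().sum()) for g in GRADES}
    return ScoreMatrixReport(scores=mat, grades=grades, grade_counts=counts)
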