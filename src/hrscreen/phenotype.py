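"""Graded phenotype classification for validated hits.

Each validated gene receives a row of symbolic grades summarising the
secondary assays:

* **HR grade** per trigger, from the control-based z of the recombination
  assay: ``↓↓↓``/``↓↓``/``↓`` at z < −4/−2/−1.5 and ``↑``/``↑↑``/``↑↑↑`` at
  z > 1.5/2/4 (strict cut-offs; the strongest satisfied wins); otherwise "−".
* **GFP level** counterscreen: "+" when GFP levels in constitutive-GFP cells
  drop beyond z −4, else "−".
* **Viability**: relative cell-number decrease r = 1 − mean_gene/mean_Rluc in
  untreated wells; r > 0.50 → "++" (excluded downstream), r > 0.25 → "+".
* **Drug/IR sensitivity** per condition: the drug-specific decrease
  d = 1 − (treated/untreated)_gene ÷ (treated/untreated)_Rluc, means over
  three replicates; d ≥ 0.40 → "+++", ≥ 0.30 → "++", ≥ 0.10 → "+" (inclusive
  cut-offs). The double ratio removes baseline viability effects so only the
  treatment-specific loss registers.
* **gamma-H2AX kinetics**: per post-irradiation timepoint (1 h, 6 h), a
  two-sided Student's t test (pooled variance, df = 4 for 3 vs 3 replicates)
  of percent gamma-H2AX-positive cells against Rluc; p < 0.05 annotates an
  arrow with the sign of the mean difference, e.g. ``"↓ 6h"``.

The t statistic and p-value are computed directly (scipy supplies only the t
distribution CDF) so that library t-test routines remain available as an
independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import MissingDataError, ScreenError, UndefinedRatioError

# Grade symbols (as printed in screen summary tables).
DOWN3, DOWN2, DOWN1 = "↓↓↓", "↓↓", "↓"
UP1, UP2, UP3 = "↑", "↑↑", "↑↑↑"
NONE = "−"
NOT_DONE = "n.d."
NOT_AVAILABLE = "n.a."

HR_GRADES = (DOWN3, DOWN2, DOWN1, NONE, UP1, UP2, UP3)


@dataclass(frozen=True)
class GradeScale:
    """Numeric cut-offs behind the symbolic grades (defaults as published)."""

    hr_cuts: tuple[float, float, float] = (4.0, 2.0, 1.5)  # strict, symmetric
    viability_cuts: tuple[float, float] = (0.50, 0.25)     # strict, on decrease r
    sensitivity_cuts: tuple[float, float, float] = (0.40, 0.30, 0.10)  # inclusive
    gfp_level_cut: float = 4.0                              # strict, decreasing only
    h2ax_alpha: float = 0.05

    def __post_init__(self) -> None:
        for cuts in (self.hr_cuts, self.viability_cuts, self.sensitivity_cuts):
            if list(cuts) != sorted(cuts, reverse=True):
                raise ValueError(f"cut-offs must be strictly decreasing: {cuts}")


DEFAULT_SCALE = GradeScale()


def grade_hr(avg_z: float, scale: GradeScale = DEFAULT_SCALE) -> str:
    """Symbolic HR grade from a control-based average z (strict cut-offs)."""
    if not math.isfinite(avg_z):
        raise ScreenError(f"non-finite z: {avg_z}")
    strong, mid, weak = scale.hr_cuts
    if avg_z < -strong:
        return DOWN3
    if avg_z < -mid:
        return DOWN2
    if avg_z < -weak:
        return DOWN1
    if avg_z > strong:
        return UP3
    if avg_z > mid:
        return UP2
    if avg_z > weak:
        return UP1
    return NONE


def grade_gfp_level(z: float, scale: GradeScale = DEFAULT_SCALE) -> str:
    """Counterscreen grade: "+" when GFP levels drop beyond −cut (strict)."""
    return "+" if z < -scale.gfp_level_cut else NONE


def grade_viability(
    gene_untreated_counts: Sequence[float],
    rluc_untreated_counts: Sequence[float],
    scale: GradeScale = DEFAULT_SCALE,
) -> str:
    """Grade the untreated cell-number decrease relative to Rluc."""
    rluc_mean = float(np.mean(rluc_untreated_counts))
    if rluc_mean == 0:
        raise UndefinedRatioError("Rluc untreated mean is zero")
    r = round(1.0 - float(np.mean(gene_untreated_counts)) / rluc_mean, 12)
    severe, mild = scale.viability_cuts
    if r > severe:
        return "++"
    if r > mild:
        return "+"
    return NONE


def grade_sensitivity(
    gene_counts: Mapping[str, Sequence[float]],
    rluc_counts: Mapping[str, Sequence[float]],
    scale: GradeScale = DEFAULT_SCALE,
) -> dict[str, str]:
    """Grade drug-specific sensitivity per treated condition.

    ``gene_counts``/``rluc_counts`` map condition → replicate cell counts and
    must include ``"untreated"``. Returns a grade for every treated condition.
    """
    for counts, who in ((gene_counts, "gene"), (rluc_counts, "Rluc")):
        if "untreated" not in counts:
            raise MissingDataError(f"{who}: untreated counts are required")
    gene_unt = float(np.mean(gene_counts["untreated"]))
    rluc_unt = float(np.mean(rluc_counts["untreated"]))
    if gene_unt == 0 or rluc_unt == 0:
        raise UndefinedRatioError("untreated mean cell count is zero")
    grades: dict[str, str] = {}
    for condition in gene_counts:
        if condition == "untreated":
            continue
        if condition not in rluc_counts:
            raise MissingDataError(f"Rluc counts missing for condition {condition!r}")
        gene_ratio = float(np.mean(gene_counts[condition])) / gene_unt
        rluc_ratio = float(np.mean(rluc_counts[condition])) / rluc_unt
        if rluc_ratio == 0:
            raise UndefinedRatioError(f"Rluc treated/untreated ratio is zero ({condition})")
        # rounded to printed precision so the inclusive cut-offs hold at
        # exact decimal boundaries despite binary float representation
        d = round(1.0 - gene_ratio / rluc_ratio, 12)
        strong, mid, weak = scale.sensitivity_cuts
        if d >= strong:
            grades[condition] = "+++"
        elif d >= mid:
            grades[condition] = "++"
        elif d >= weak:
            grades[condition] = "+"
        else:
            grades[condition] = NONE
    return grades


# ---------------------------------------------------------------------------
# gamma-H2AX kinetics
# ---------------------------------------------------------------------------

def student_t_test(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t test; returns (t, p).

    Pooled-variance Student form by default; Welch with ``equal_var=False``.
    Computed from first principles (only the t CDF comes from scipy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise MissingDataError("need at least 2 replicates per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1 / na + 1 / nb)
        df = na + nb - 2
    else:
        se2 = va / na + vb / nb
        if se2 == 0:
            df = na + nb - 2
        else:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if se2 == 0:
        # Degenerate: identical constant replicates.
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(se2)
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return float(t), p


def classify_h2ax(
    gene: Mapping[str, Sequence[float]],
    rluc: Mapping[str, Sequence[float]],
    scale: GradeScale = DEFAULT_SCALE,
    equal_var: bool = True,
    timepoints: Sequence[str] = ("1h", "6h"),
) -> list[str]:
    """Arrow annotations for gamma-H2AX kinetics differences vs Rluc.

    ``gene``/``rluc`` map timepoint → replicate percent-positive values.
    Returns e.g. ``["↓ 1h", "↓ 6h"]`` (empty list = no significant change).
    """
    annotations: list[str] = []
    for tp in timepoints:
        if tp not in gene or tp not in rluc:
            raise MissingDataError(f"timepoint {tp!r} missing")
        t, p = student_t_test(gene[tp], rluc[tp], equal_var=equal_var)
        if p < scale.h2ax_alpha:
            arrow = UP1 if t > 0 else DOWN1
            annotations.append(f"{arrow} {tp}")
    return annotations


def render_h2ax(annotations: Sequence[str]) -> str:
    return ", ".join(annotations) if annotations else NONE


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSummary:
    """One summary-table row per validated gene."""

    gene: str
    hr_grade_trigger1: str = NOT_AVAILABLE
    hr_grade_trigger2: str = NOT_AVAILABLE
    gfp_grade: str = NONE
    viability_grade: str = NOT_DONE
    cisplatin_grade: str = NOT_DONE
    mmc_grade: str = NOT_DONE
    ir_grade: str = NOT_DONE
    h2ax: str = NOT_DONE


_COLUMNS = [
    "gene", "hr_grade_trigger1", "hr_grade_trigger2", "gfp_grade",
    "viability_grade", "cisplatin_grade", "mmc_grade", "ir_grade", "h2ax",
]


def build_summary_table(rows: Iterable[PhenotypeSummary]) -> pd.DataFrame:
    """Assemble summary rows into a sortable, serialisable table.

    Raises on conflicting duplicate rows for the same gene; identical
    duplicates collapse to one row.
    """
    by_gene: dict[str, PhenotypeSummary] = {}
    for row in rows:
        if row.gene in by_gene and by_gene[row.gene] != row:
            raise ScreenError(f"conflicting duplicate rows for gene {row.gene}")
        by_gene[row.gene] = row
    records = [vars(by_gene[g]) for g in sorted(by_gene)]
    return pd.DataFrame(records, columns=_COLUMNS)
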