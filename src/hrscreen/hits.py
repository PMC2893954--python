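"""Hit calling: the funnel from a genome-scale primary screen to a final list.

Stages, in order:

1. **Primary hits** — esiRNAs whose replicate-averaged plate z is below −2 or
   above 2 (strict inequalities).
2. **Validated hits** — genes for which, in the validation screen (4
   replicates, control-based z), one silencing trigger is beyond ±2 and a
   second independent trigger is beyond ±1.5 in the *same* direction. Either
   trigger may satisfy the stronger threshold. A gene with only a single
   usable trigger validates only beyond ±4 and is flagged.
3. **Counterscreen** — validated genes whose knockdown also depresses GFP
   levels in constitutively GFP-expressing cells (z beyond −4) are excluded:
   they likely perturb GFP expression itself, not recombination.
4. **Secondary cohort** — validated decreasers that survived the
   counterscreen and are not graded "++" for viability loss proceed to
   drug/IR-sensitivity and gamma-H2AX secondary assays.

All thresholds are strict ("below −2" means z < −2); boundary values never
call a hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import MissingDataError

logger = logging.getLogger(__name__)

DECREASED = "decreased"
INCREASED = "increased"

PRIMARY = "primary"
VALIDATED = "validated"
POST_COUNTERSCREEN = "post_counterscreen"
SECONDARY_ELIGIBLE = "secondary_eligible"


@dataclass(frozen=True)
class HitThresholds:
    """z cut-offs used throughout the funnel (all applied strictly)."""

    primary_abs_z: float = 2.0
    validation_strong: float = 2.0
    validation_weak: float = 1.5
    counterscreen_abs_z: float = 4.0
    single_trigger_abs_z: float = 4.0

    def __post_init__(self) -> None:
        if not (self.validation_strong >= self.validation_weak > 0):
            raise ValueError("require validation_strong >= validation_weak > 0")


@dataclass
class HitCall:
    gene: str
    direction: str
    stage: str
    evidence: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def call_primary_hits(
    avg_z: Mapping[str, float], thresholds: HitThresholds | None = None
) -> list[HitCall]:
    """esiRNAs with average z strictly below −2 or strictly above 2."""
    th = thresholds or HitThresholds()
    calls: list[HitCall] = []
    for esirna in sorted(avg_z):
        z = avg_z[esirna]
        if z < -th.primary_abs_z:
            direction = DECREASED
        elif z > th.primary_abs_z:
            direction = INCREASED
        else:
            continue
        calls.append(
            HitCall(gene=esirna, direction=direction, stage=PRIMARY,
                    evidence={"avg_z": z})
        )
    return calls


def _dual_trigger_validated(z1: float, z2: float, th: HitThresholds) -> str | None:
    """Direction if the two triggers validate together, else None."""
    if (z1 > 0) != (z2 > 0) or z1 == 0 or z2 == 0:
        return None
    a, b = abs(z1), abs(z2)
    ok = (a > th.validation_strong and b > th.validation_weak) or (
        b > th.validation_strong and a > th.validation_weak
    )
    if not ok:
        return None
    return DECREASED if z1 < 0 else INCREASED


def call_validated_hits(
    trigger_z: Mapping[str, Mapping[int, float | None]],
    thresholds: HitThresholds | None = None,
) -> list[HitCall]:
    """Dual-trigger validation over per-gene, per-trigger average z (4 reps).

    ``trigger_z[gene]`` maps trigger index → averaged z (``None`` = not
    available). A gene with no trigger at all raises
    :class:`MissingDataError`.
    """
    th = thresholds or HitThresholds()
    calls: list[HitCall] = []
    for gene in sorted(trigger_z):
        zs = {t: z for t, z in trigger_z[gene].items() if z is not None}
        if not trigger_z[gene]:
            raise MissingDataError(f"gene {gene}: no triggers supplied")
        if len(zs) == 0:
            raise MissingDataError(f"gene {gene}: no usable trigger z values")
        evidence = {f"trigger_{t}_z": z for t, z in sorted(zs.items())}
        if len(zs) == 1:
            (z,) = zs.values()
            if abs(z) > th.single_trigger_abs_z:
                calls.append(
                    HitCall(
                        gene=gene,
                        direction=DECREASED if z < 0 else INCREASED,
                        stage=VALIDATED,
                        evidence=evidence,
                        flags=["single_trigger"],
                    )
                )
            continue
        z1, z2 = (zs[t] for t in sorted(zs))
        direction = _dual_trigger_validated(z1, z2, th)
        if direction is not None:
            calls.append(
                HitCall(gene=gene, direction=direction, stage=VALIDATED,
                        evidence=evidence)
            )
    return calls


def apply_counterscreen(
    validated: Iterable[HitCall],
    gfp_level_z: Mapping[str, float],
    thresholds: HitThresholds | None = None,
) -> tuple[list[HitCall], list[HitCall]]:
    """Exclude genes that depress GFP levels in constitutive-GFP cells.

    Only the decreasing direction excludes (z strictly below −cut-off): the
    confound being removed is loss of GFP signal masquerading as loss of
    recombination. Genes without a counterscreen measurement are retained and
    flagged ``counterscreen_untested``.
    """
    th = thresholds or HitThresholds()
    retained: list[HitCall] = []
    excluded: list[HitCall] = []
    for call in validated:
        z = gfp_level_z.get(call.gene)
        updated = HitCall(
            gene=call.gene,
            direction=call.direction,
            stage=POST_COUNTERSCREEN,
            evidence={**call.evidence, "gfp_level_z": z},
            flags=list(call.flags),
        )
        if z is None:
            updated.flags.append("counterscreen_untested")
            retained.append(updated)
        elif z < -th.counterscreen_abs_z:
            updated.flags.append("counterscreen_failed")
            excluded.append(updated)
        else:
            retained.append(updated)
    return retained, excluded


def select_secondary_cohort(
    decreasers: Iterable[HitCall],
    viability_grades: Mapping[str, str],
) -> list[HitCall]:
    """Decreasers continuing into secondary assays (viability "++" excluded)."""
    decreasers = list(decreasers)
    if not viability_grades:
        logger.warning(
            "empty viability table: retaining all %d decreasers", len(decreasers)
        )
    cohort: list[HitCall] = []
    for call in decreasers:
        if call.direction != DECREASED:
            continue
        grade = viability_grades.get(call.gene, "−")
        if grade == "++":
            continue
        cohort.append(
            HitCall(
                gene=call.gene,
                direction=call.direction,
                stage=SECONDARY_ELIGIBLE,
                evidence={**call.evidence, "viability_grade": grade},
                flags=list(call.flags),
            )
        )
    return cohort
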