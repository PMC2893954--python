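"""AP-MS identification filters.

Two successive filters turn raw MS identifications from tagged-bait
immunoprecipitations into a specific interactor list:

* **Confident hits** — a protein counts in an experiment only when supported
  by at least three peptides whose MASCOT ions score is strictly above 20.
* **Common-background exclusion** — proteins seen in more than 15% (strict)
  of a registry of independent control immunoprecipitations from unrelated
  baits are frequent-flyer contaminants and are removed. Bait proteins are
  exempt (they are trivially abundant in their own pull-downs).

With the published registry size of 193 control IPs the exclusion boundary
falls between 28 (14.5%, retained) and 29 (15.03%, excluded) occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ScreenError


@dataclass
class IdentificationRecord:
    protein_id: str
    experiment_id: str
    peptide_scores: list[float]
    bait: bool = False


def confident_hits(
    records: Iterable[IdentificationRecord],
    min_peptides: int = 3,
    min_score: float = 20.0,
) -> set[tuple[str, str]]:
    """(protein, experiment) pairs with >= min_peptides scores strictly > min_score."""
    hits: set[tuple[str, str]] = set()
    for rec in records:
        n_good = sum(1 for s in rec.peptide_scores if s > min_score)
        if n_good >= min_peptides:
            hits.add((rec.protein_id, rec.experiment_id))
    return hits


@dataclass
class BackgroundRegistry:
    """Occurrence counts of proteins across independent control IPs."""

    counts: dict[str, int]
    n_control_ips: int = 193

    def __post_init__(self) -> None:
        if self.n_control_ips <= 0:
            raise ScreenError("registry requires n_control_ips > 0")
        bad = {p: c for p, c in self.counts.items() if not 0 <= c <= self.n_control_ips}
        if bad:
            raise ScreenError(f"counts outside [0, {self.n_control_ips}]: {bad}")

    def frequency(self, protein: str) -> float:
        return self.counts.get(protein, 0) / self.n_control_ips


def filter_common_background(
    hits: Iterable[str],
    registry: BackgroundRegistry,
    fraction: float = 0.15,
    baits: Iterable[str] = (),
) -> tuple[list[str], list[str], list[str]]:
    """Split ``hits`` into (retained, excluded, unregistered).

    A protein is excluded iff its control-IP frequency strictly exceeds
    ``fraction``; baits are never excluded. Proteins absent from the registry
    are retained (count 0) and reported in ``unregistered``.
    """
    baits = set(baits)
    retained: list[str] = []
    excluded: list[str] = []
    unregistered: list[str] = []
    for protein in hits:
        if protein not in registry.counts:
            unregistered.append(protein)
        if protein in baits:
            retained.append(protein)
        elif registry.frequency(protein) > fraction:
            excluded.append(protein)
        else:
            retained.append(protein)
    return retained, excluded, unregistered
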