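"""z-score normalisation of percent-GFP-positive readouts.

Two schemes are used at different screen stages:

* **plate_samples** (primary screen): for each plate, z = (x − μ)/σ with μ and
  σ taken over all *sample* wells of that plate, controls excluded. Every
  well, controls included, then receives a z against those plate statistics.
* **negative_control** (validation): z = (x − μ_neg)/σ_neg against the Rluc
  negative-control wells measured alongside.

Replicate z-scores are combined by arithmetic mean; the number of available
replicates is recorded so partial data (a missing trigger/replicate) stays
visible downstream.

Standard deviations are sample sd (ddof=1) by default; a population-sd mode
is available via ``ddof=0`` and the mode in effect is recorded in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DegeneratePlateError, MissingDataError
from .plates import PlateReadout, SAMPLE, WellAddress

PLATE_SAMPLES = "plate_samples"
NEGATIVE_CONTROL = "negative_control"


@dataclass(frozen=True)
class PlateStats:
    """Mean/sd of percent GFP-positive over the wells included in normalisation."""

    mean: float
    sd: float
    n_included: int
    ddof: int = 1


@dataclass
class ZScoreRecord:
    """Per-esiRNA z statistics across replicates."""

    esirna_id: str
    z_by_replicate: list[float | None]
    avg_z: float
    normalization_mode: str
    n_replicates: int = 0
    partial: bool = False

    def __post_init__(self) -> None:
        finite = [z for z in self.z_by_replicate if z is not None and math.isfinite(z)]
        self.n_replicates = len(finite)
        self.partial = self.n_replicates < len(self.z_by_replicate)


def _stats(values: Sequence[float], ddof: int, what: str) -> PlateStats:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegeneratePlateError(f"{what}: need at least 2 values, got {arr.size}")
    sd = float(arr.std(ddof=ddof))
    if sd == 0.0:
        raise DegeneratePlateError(f"{what}: standard deviation is zero")
    return PlateStats(mean=float(arr.mean()), sd=sd, n_included=int(arr.size), ddof=ddof)


def plate_zscores(
    readout: PlateReadout, ddof: int = 1
) -> tuple[dict[WellAddress, float], PlateStats]:
    """Per-plate z-scores: μ/σ over sample wells only, z for every valued well.

    Controls receive a z (useful for QC) but never contribute to μ or σ.
    Raises :class:`DegeneratePlateError` when fewer than two sample wells are
    valued or their sd is zero.
    """
    sample_values = [
        v for w, v in readout.values.items() if readout.layout.roles[w] == SAMPLE
    ]
    stats = _stats(sample_values, ddof, f"plate {readout.plate_id}")
    z = {w: (v - stats.mean) / stats.sd for w, v in readout.values.items()}
    return z, stats


def control_based_zscores(
    esirna_id: str,
    values_by_replicate: Sequence[float | None],
    negative_control_values: Sequence[Sequence[float]],
    ddof: int = 1,
) -> ZScoreRecord:
    """z against the negative-control (Rluc) wells, per replicate, then averaged.

    ``negative_control_values[i]`` are the Rluc readouts measured alongside
    replicate ``i``. A ``None`` sample value marks a missing replicate: the
    average is taken over the remaining replicates and the record is flagged
    ``partial``.
    """
    if len(values_by_replicate) != len(negative_control_values):
        raise MissingDataError(
            f"{esirna_id}: {len(values_by_replicate)} sample replicates but "
            f"{len(negative_control_values)} control sets"
        )
    zs: list[float | None] = []
    for x, neg in zip(values_by_replicate, negative_control_values):
        if x is None:
            zs.append(None)
            continue
        stats = _stats(neg, ddof, f"{esirna_id}: negative controls")
        zs.append((float(x) - stats.mean) / stats.sd)
    avg, _ = average_replicates(zs)
    return ZScoreRecord(
        esirna_id=esirna_id,
        z_by_replicate=zs,
        avg_z=avg,
        normalization_mode=NEGATIVE_CONTROL,
    )


def average_replicates(z_by_replicate: Sequence[float | None]) -> tuple[float, int]:
    """Arithmetic mean over the finite replicate z values; returns (mean, n).

    Raises :class:`MissingDataError` when no finite value is available.
    """
    finite = [
        float(z) for z in z_by_replicate if z is not None and math.isfinite(float(z))
    ]
    if not finite:
        raise MissingDataError("no finite replicate z values to average")
    return float(np.mean(finite)), len(finite)


def estimate_fold(readouts, esirna_id: str) -> float:
    """Fold-depletion estimate: negative-control mean / knockdown mean.

    Pools the knockdown wells of ``esirna_id`` and the negative-control wells
    across the given replicate readouts. A fold of 3.4 means the knockdown
    left 1/3.4 of the control percent-GFP-positive signal.
    """
    from .plates import NEGATIVE_CONTROL as NEG_ROLE

    gene_vals: list[float] = []
    neg_vals: list[float] = []
    for ro in readouts:
        for well, esirna in ro.layout.esirna.items():
            if esirna == esirna_id and well in ro.values:
                gene_vals.append(ro.values[well])
        neg_vals.extend(ro.values_with_role(NEG_ROLE))
    if not gene_vals or not neg_vals:
        raise MissingDataError(f"no wells found for {esirna_id} or controls")
    gene_mean = float(np.mean(gene_vals))
    if gene_mean == 0:
        raise MissingDataError(f"{esirna_id}: knockdown mean is zero")
    return float(np.mean(neg_vals)) / gene_mean


def average_z_table(
    z_by_esirna: Mapping[str, Sequence[float | None]],
    mode: str = PLATE_SAMPLES,
) -> dict[str, ZScoreRecord]:
    """Build :class:`ZScoreRecord` per esiRNA from per-replicate z values."""
    out: dict[str, ZScoreRecord] = {}
    for esirna, zs in z_by_esirna.items():
        avg, _ = average_replicates(zs)
        out[esirna] = ZScoreRecord(
            esirna_id=esirna,
            z_by_replicate=list(zs),
            avg_z=avg,
            normalization_mode=mode,
        )
    return out
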