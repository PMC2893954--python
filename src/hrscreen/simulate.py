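"""Synthetic screens with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised without the original flow-cytometry
data:

* each well holds ``cells_per_well`` cells (default 2,000) of which a
  baseline fraction (default 5%) would be GFP-positive under a neutral
  knockdown;
* a gene's true effect is a multiplicative fold change on that fraction
  (fold > 1 depletes GFP-positive cells, fold < 1 enriches them);
* whole plates fluctuate by a multiplicative log-normal plate effect
  (``plate_effect_sd`` on the log scale), mimicking day/transfection batch
  variation that per-plate normalisation is designed to remove;
* the measured value is 100 × Binomial(cells, p)/cells — pure cell-sampling
  noise on a percent-positive readout.

Positive-control wells (Rad51) use ``positive_control_fold`` (default 5),
negative-control wells (Rluc) fold 1. One deterministic random stream is
derived per (plate, replicate) from the master seed, so identical configs
give byte-identical output and plates can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .plates import (
    LibraryMap,
    NEGATIVE_CONTROL,
    PlateReadout,
    POSITIVE_CONTROL,
    SAMPLE,
    default_control_layout,
)


@dataclass
class SyntheticConfig:
    n_plates: int = 1
    cells_per_well: int = 2000
    baseline_pos_fraction: float = 0.05
    plate_effect_sd: float = 0.1
    positive_control_fold: float = 5.0
    effect_table: dict[str, float] = field(default_factory=dict)
    replicate_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_pos_fraction < 1.0:
            raise ConfigError("baseline_pos_fraction must be in (0, 1)")
        if self.cells_per_well < 1 or self.n_plates < 1 or self.replicate_count < 1:
            raise ConfigError("counts must be positive")
        bad = {g: f for g, f in self.effect_table.items() if not f > 0}
        if bad:
            raise ConfigError(f"fold changes must be > 0: {bad}")
        if self.plate_effect_sd < 0:
            raise ConfigError("plate_effect_sd must be >= 0")


def _rng(config: SyntheticConfig, plate: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(plate), int(replicate)])


def _well_value(
    rng: np.random.Generator, config: SyntheticConfig, fold: float, plate_effect: float
) -> float:
    p = float(np.clip(config.baseline_pos_fraction * plate_effect / fold, 0.0, 1.0))
    count = int(rng.binomial(config.cells_per_well, p))
    return 100.0 * count / config.cells_per_well


def _plate_effect(rng: np.random.Generator, config: SyntheticConfig) -> float:
    if config.plate_effect_sd == 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, config.plate_effect_sd)))


def generate_primary_screen(
    config: SyntheticConfig,
) -> tuple[list[PlateReadout], LibraryMap, pd.DataFrame]:
    """Simulate the duplicate primary screen.

    Sample wells are filled plate by plate with the configured effect genes
    first, then null genes (fold 1) up to 368 genes per plate. Returns the
    readouts (n_plates × replicate_count), the library map (one trigger per
    gene in the primary screen) and the truth table.
    """
    layout_template = default_control_layout()
    sample_wells = layout_template.sample_wells
    n_genes = config.n_plates * len(sample_wells)
    genes = list(config.effect_table)
    if len(genes) > n_genes:
        raise ConfigError(
            f"effect table has {len(genes)} genes but the screen holds {n_genes}"
        )
    genes += [f"NULL{i:05d}" for i in range(n_genes - len(genes))]

    library = LibraryMap({f"{g}_t1": (g, 1) for g in genes})
    truth = pd.DataFrame(
        {
            "gene": genes,
            "true_fold": [config.effect_table.get(g, 1.0) for g in genes],
        }
    )
    truth["direction"] = np.select(
        [truth.true_fold > 1, truth.true_fold < 1], ["decreased", "increased"], "null"
    )
    truth["is_null"] = truth.true_fold == 1.0

    readouts: list[PlateReadout] = []
    for p in range(config.n_plates):
        plate_genes = genes[p * len(sample_wells): (p + 1) * len(sample_wells)]
        for r in range(1, config.replicate_count + 1):
            rng = _rng(config, p, r)
            plate_effect = _plate_effect(rng, config)
            layout = default_control_layout(f"plate{p + 1:03d}")
            values = {}
            for well, gene in zip(sample_wells, plate_genes):
                layout.esirna[well] = f"{gene}_t1"
                values[well] = _well_value(
                    rng, config, config.effect_table.get(gene, 1.0), plate_effect
                )
            for well in layout.wells_with_role(POSITIVE_CONTROL):
                layout.esirna[well] = "RAD51_ctrl"
                values[well] = _well_value(
                    rng, config, config.positive_control_fold, plate_effect
                )
            for well in layout.wells_with_role(NEGATIVE_CONTROL):
                layout.esirna[well] = "RLUC_ctrl"
                values[well] = _well_value(rng, config, 1.0, plate_effect)
            readouts.append(PlateReadout(layout=layout, values=values, replicate_id=r))
    return readouts, library, truth


def generate_validation_screen(
    config: SyntheticConfig,
    genes: Sequence[str],
    trigger_folds: Mapping[tuple[str, int], float] | None = None,
    single_trigger: Sequence[str] = (),
    n_replicates: int = 4,
) -> tuple[list[PlateReadout], LibraryMap]:
    """Simulate the validation screen: two triggers per gene, 4 replicates.

    Per-trigger folds default to the gene's ``effect_table`` entry; override
    with ``trigger_folds[(gene, trigger)]``. Genes in ``single_trigger`` get
    only trigger 1 (the second trigger is absent, the "n.a." path).
    """
    entries: dict[str, tuple[str, int]] = {}
    for g in genes:
        entries[f"{g}_t1"] = (g, 1)
        if g not in set(single_trigger):
            entries[f"{g}_t2"] = (g, 2)
    library = LibraryMap(entries)
    esirnas = sorted(entries)
    layout_template = default_control_layout("validation")
    sample_wells = layout_template.sample_wells
    if len(esirnas) > len(sample_wells):
        raise ConfigError("too many esiRNAs for a single validation plate")

    def fold_of(esirna: str) -> float:
        gene, trigger = entries[esirna]
        if trigger_folds and (gene, trigger) in trigger_folds:
            return trigger_folds[(gene, trigger)]
        return config.effect_table.get(gene, 1.0)

    readouts: list[PlateReadout] = []
    for r in range(1, n_replicates + 1):
        rng = _rng(config, plate=10_000, replicate=r)
        plate_effect = _plate_effect(rng, config)
        layout = default_control_layout("validation")
        values = {}
        for well, esirna in zip(sample_wells, esirnas):
            layout.esirna[well] = esirna
            values[well] = _well_value(rng, config, fold_of(esirna), plate_effect)
        for well in layout.wells_with_role(POSITIVE_CONTROL):
            layout.esirna[well] = "RAD51_ctrl"
            values[well] = _well_value(rng, config, config.positive_control_fold, plate_effect)
        for well in layout.wells_with_role(NEGATIVE_CONTROL):
            layout.esirna[well] = "RLUC_ctrl"
            values[well] = _well_value(rng, config, 1.0, plate_effect)
        readouts.append(PlateReadout(layout=layout, values=values, replicate_id=r))
    return readouts, library


# ---------------------------------------------------------------------------
# Secondary assays
# ---------------------------------------------------------------------------

CONDITIONS = ("untreated", "cisplatin", "MMC", "IR")
TIMEPOINTS = ("no_IR", "1h", "6h")

#: Rluc condition means: untreated cell count and survival ratios per treatment.
RLUC_BASELINE_COUNT = 1000.0
RLUC_TREATED_RATIO = {"cisplatin": 0.65, "MMC": 0.65, "IR": 0.75}
#: Rluc percent gamma-H2AX-positive means per timepoint and replicate noise sd.
RLUC_H2AX_MEAN = {"no_IR": 2.0, "1h": 80.0, "6h": 30.0}
H2AX_NOISE_SD = 3.0


@dataclass
class SecondaryEffect:
    """Ground-truth secondary phenotype of one gene.

    ``viability_factor`` scales the untreated cell count (0.4 = 60% fewer
    cells). ``drug_depletion[cond]`` is the drug-specific extra depletion d on
    top of the Rluc response. ``h2ax_shift[tp]`` additively shifts percent
    gamma-H2AX-positive at a timepoint.
    """

    viability_factor: float = 1.0
    drug_depletion: dict[str, float] = field(default_factory=dict)
    h2ax_shift: dict[str, float] = field(default_factory=dict)


def generate_secondary_assays(
    effects: Mapping[str, SecondaryEffect],
    seed: int = 0,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sensitivity and gamma-H2AX replicate tables (Rluc included).

    Cell counts are Poisson around condition means; percent positives are
    Gaussian around timepoint means, clipped to [0, 100]. Three replicates per
    condition by default.
    """
    rng = np.random.default_rng([int(seed), 20_000])
    sens_rows = []
    h2ax_rows = []
    all_effects: dict[str, SecondaryEffect] = {"RLUC": SecondaryEffect()}
    all_effects.update(effects)
    for gene, eff in all_effects.items():
        for cond in CONDITIONS:
            base = RLUC_BASELINE_COUNT * eff.viability_factor
            if cond == "untreated":
                mean = base
            else:
                d = eff.drug_depletion.get(cond, 0.0)
                mean = base * RLUC_TREATED_RATIO[cond] * (1.0 - d)
            for rep in range(1, n_replicates + 1):
                sens_rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "cell_count": int(rng.poisson(mean)),
                    }
                )
        for tp in TIMEPOINTS:
            mean = RLUC_H2AX_MEAN[tp] + eff.h2ax_shift.get(tp, 0.0)
            for rep in range(1, n_replicates + 1):
                value = float(np.clip(rng.normal(mean, H2AX_NOISE_SD), 0.0, 100.0))
                h2ax_rows.append(
                    {
                        "gene": gene,
                        "timepoint": tp,
                        "replicate": rep,
                        "percent_positive": value,
                    }
                )
    return pd.DataFrame(sens_rows), pd.DataFrame(h2ax_rows)


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A screen with no true effects (every gene fold 1)."""
    return replace(SyntheticConfig(seed=seed), **overrides)
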