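"""Config-driven orchestration: simulate → score → call → classify.

``run_pipeline`` executes the screen analysis end to end on either synthetic
inputs (generated from a seed) or readout CSVs on disk, writing every stage's
table plus a run manifest (config hash, input checksums, stage record counts)
so a run is fully reproducible and the hit funnel is a first-class artifact
of the logs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .hits import (
    DECREASED,
    HitThresholds,
    apply_counterscreen,
    call_primary_hits,
    call_validated_hits,
    select_secondary_cohort,
)
from .plates import read_readout_table, write_library_map, write_readout_table
from .scoring import PLATE_SAMPLES, average_replicates, plate_zscores
from .simulate import SyntheticConfig, generate_primary_screen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything that determines a run (together with the input files)."""

    out_dir: str = "screen_run"
    readouts_path: str | None = None        # None → simulate
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    sd_ddof: int = 1
    counterscreen_z_path: str | None = None  # CSV gene,z
    viability_path: str | None = None        # CSV gene,grade

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synthetic = SyntheticConfig(**raw.pop("synthetic", {}))
        thresholds = HitThresholds(**raw.pop("thresholds", {}))
        return cls(synthetic=synthetic, thresholds=thresholds, **raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the funnel and write all stage outputs under ``config.out_dir``.

    Returns a summary dict with per-stage counts and output paths. Outputs
    are deterministic given the config and inputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": {},
        "decisions": {"sd_ddof": config.sd_ddof, "t_test": "student_pooled"},
    }

    # --- inputs -----------------------------------------------------------
    if config.readouts_path is not None:
        readouts = read_readout_table(config.readouts_path)
        manifest["inputs"]["readouts"] = _sha256(Path(config.readouts_path))
        library = None
    else:
        readouts, library, truth = generate_primary_screen(config.synthetic)
        write_readout_table(readouts, out / "readouts.csv")
        write_library_map(library, out / "library.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        manifest["inputs"]["synthetic_seed"] = config.synthetic.seed
    manifest["stages"]["readouts"] = len(readouts)
    logger.info("loaded %d plate readouts", len(readouts))

    # --- plate z-scoring --------------------------------------------------
    z_rows = []
    for ro in readouts:
        z, stats = plate_zscores(ro, ddof=config.sd_ddof)
        for well in sorted(z):
            z_rows.append(
                {
                    "plate_id": ro.plate_id,
                    "replicate_id": ro.replicate_id,
                    "well": well.label,
                    "esirna_id": ro.layout.esirna.get(well),
                    "role": ro.layout.roles[well],
                    "z": z[well],
                    "mode": PLATE_SAMPLES,
                }
            )
    ztable = pd.DataFrame(z_rows)
    ztable.to_csv(out / "ztable.csv", index=False)
    manifest["stages"]["z_scores"] = len(ztable)

    # --- replicate averaging + primary hit calling ------------------------
    samples = ztable[(ztable.role == "sample") & ztable.esirna_id.notna()]
    avg = {
        esirna: average_replicates(list(group.z))[0]
        for esirna, group in samples.groupby("esirna_id")
    }
    avg_df = pd.DataFrame(
        {"esirna_id": list(avg), "avg_z": list(avg.values())}
    ).sort_values("esirna_id")
    avg_df.to_csv(out / "avg_ztable.csv", index=False)

    primary = call_primary_hits(avg, config.thresholds)
    pd.DataFrame(
        [
            {"esirna_id": c.gene, "direction": c.direction, "avg_z": c.evidence["avg_z"]}
            for c in primary
        ]
    ).to_csv(out / "hits_primary.csv", index=False)
    manifest["stages"]["primary_hits"] = len(primary)
    logger.info("funnel: %d esiRNAs -> %d primary hits", len(avg), len(primary))

    summary: dict[str, Any] = {
        "out_dir": str(out),
        "n_readouts": len(readouts),
        "n_esirnas": len(avg),
        "n_primary_hits": len(primary),
        "primary_decreased": sum(c.direction == DECREASED for c in primary),
    }

    # --- optional validation-stage inputs ---------------------------------
    if config.counterscreen_z_path or config.viability_path:
        trigger_z = {c.gene: {1: c.evidence["avg_z"]} for c in primary}
        validated = call_validated_hits(trigger_z, config.thresholds)
        gfp_z = {}
        if config.counterscreen_z_path:
            cs = pd.read_csv(config.counterscreen_z_path)
            gfp_z = dict(zip(cs.gene, cs.z))
            manifest["inputs"]["counterscreen"] = _sha256(Path(config.counterscreen_z_path))
        retained, excluded = apply_counterscreen(validated, gfp_z, config.thresholds)
        viability = {}
        if config.viability_path:
            vt = pd.read_csv(config.viability_path)
            viability = dict(zip(vt.gene, vt.grade))
            manifest["inputs"]["viability"] = _sha256(Path(config.viability_path))
        cohort = select_secondary_cohort(
            [c for c in retained if c.direction == DECREASED], viability
        )
        manifest["stages"]["post_counterscreen"] = len(retained)
        summary["post_counterscreen"] = len(retained)
        summary["secondary_cohort"] = len(cohort)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary["manifest"] = str(out / "manifest.json")
    return summary
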