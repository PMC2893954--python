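import numpy as np
import pytest
from scipy import stats as sps

from hrscreen import errors
from hrscreen.hits import call_validated_hits
from hrscreen.phenotype import NONE, grade_sensitivity, grade_viability, student_t_test
from hrscreen.plates import NEGATIVE_CONTROL, SAMPLE
from hrscreen.scoring import average_replicates, control_based_zscores, plate_zscores
from hrscreen.simulate import (
    SecondaryEffect,
    SyntheticConfig,
    generate_primary_screen,
    generate_secondary_assays,
    generate_validation_screen,
)


def gene_values(readouts, esirna):
    out = []
    for ro in readouts:
        for w, e in ro.layout.esirna.items():
            if e == esirna and w in ro.values:
                out.append(ro.values[w])
    return out


def control_z_for_gene(readouts, esirna):
    vals, negs = [], []
    for ro in sorted(readouts, key=lambda r: r.replicate_id):
        per_rep = [ro.values[w] for w, e in ro.layout.esirna.items() if e == esirna]
        if per_rep:
            vals.append(per_rep[0])
            negs.append(ro.values_with_role(NEGATIVE_CONTROL))
    return control_based_zscores(esirna, vals, negs).avg_z


class TestPrimaryScreen:
    def test_seed_determinism_is_exact(self):
        cfg = SyntheticConfig(seed=99, effect_table={"G": 5.0})
        a, _, _ = generate_primary_screen(cfg)
        b, _, _ = generate_primary_screen(cfg)
        assert all(x.values == y.values for x, y in zip(a, b))

    def test_null_screen_sits_at_baseline(self):
        cfg = SyntheticConfig(seed=1, plate_effect_sd=0.0)
        readouts, _, truth = generate_primary_screen(cfg)
        values = [v for ro in readouts for v in ro.values.values()]
        assert np.mean(values) == pytest.approx(5.0, abs=0.1)
        assert truth.is_null.all()

    def test_fivefold_depletion_lands_at_one_percent(self):
        cfg = SyntheticConfig(seed=2, plate_effect_sd=0.0, effect_table={"KD": 5.0})
        readouts, lib, _ = generate_primary_screen(cfg)
        vals = gene_values(readouts, "KD_t1")
        assert len(vals) == cfg.replicate_count
        assert np.mean(vals) == pytest.approx(1.0, abs=0.35)

    def test_effect_gene_count_bounded_by_plate(self):
        effect = {f"G{i}": 2.0 for i in range(400)}
        with pytest.raises(errors.ConfigError):
            generate_primary_screen(SyntheticConfig(effect_table=effect))

    def test_plate_z_null_calibration_matches_normal_tail(self):
        """Null per-replicate plate z exceeds |2| at about the N(0,1) tail rate."""
        n_exceed = n_total = 0
        for seed in range(40):
            cfg = SyntheticConfig(seed=seed, replicate_count=1)
            readouts, _, _ = generate_primary_screen(cfg)
            z, _ = plate_zscores(readouts[0])
            sample_z = [
                zv for w, zv in z.items()
                if readouts[0].layout.roles[w] == SAMPLE
            ]
            n_exceed += sum(abs(v) > 2 for v in sample_z)
            n_total += len(sample_z)
        expected = 2 * sps.norm.sf(2.0)
        se = np.sqrt(expected * (1 - expected) / n_total)
        assert abs(n_exceed / n_total - expected) < 4 * se + 0.005

    def test_invalid_configs_rejected(self):
        with pytest.raises(errors.ConfigError):
            SyntheticConfig(baseline_pos_fraction=1.5)
        with pytest.raises(errors.ConfigError):
            SyntheticConfig(effect_table={"G": -1.0})


class TestValidationScreen:
    def test_structure_two_triggers_four_replicates(self):
        cfg = SyntheticConfig(seed=3)
        readouts, lib = generate_validation_screen(cfg, ["A", "B"], n_replicates=4)
        assert len(readouts) == 4
        assert lib.triggers_for_gene("A") == {1: "A_t1", 2: "A_t2"}

    def test_single_trigger_gene_has_no_second_esirna(self):
        cfg = SyntheticConfig(seed=3)
        _, lib = generate_validation_screen(cfg, ["A"], single_trigger=["A"])
        assert lib.triggers_for_gene("A") == {1: "A_t1"}

    def test_strong_knockdown_validates_in_most_seeds(self):
        hits = 0
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed, effect_table={"KD": 4.0})
            readouts, lib = generate_validation_screen(cfg, ["KD"])
            zs = {
                t: control_z_for_gene(readouts, e)
                for t, e in lib.triggers_for_gene("KD").items()
            }
            if call_validated_hits({"KD": zs}):
                hits += 1
        assert hits >= 95

    def test_fold_recovery_across_both_triggers(self):
        """Pooling a gene's two triggers recovers a 3-fold effect within 15%.

        Two triggers x four replicates give eight knockdown wells; at 2,000
        cells/well the pooled fold estimate then sits within +/-15% of truth
        in at least 95% of seeds.
        """
        from hrscreen.scoring import estimate_fold

        ok = 0
        for seed in range(200):
            cfg = SyntheticConfig(
                seed=seed, plate_effect_sd=0.0, effect_table={"KD": 3.0}
            )
            readouts, lib = generate_validation_screen(cfg, ["KD"])
            gene_vals, neg_vals = [], []
            for ro in readouts:
                for w, e in ro.layout.esirna.items():
                    if e in ("KD_t1", "KD_t2") and w in ro.values:
                        gene_vals.append(ro.values[w])
                neg_vals.extend(ro.values_with_role(NEGATIVE_CONTROL))
            fold = np.mean(neg_vals) / np.mean(gene_vals)
            if abs(fold - 3.0) / 3.0 <= 0.15:
                ok += 1
        assert ok >= 190

    def test_null_gene_rarely_validates(self):
        hits = 0
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed)
            readouts, lib = generate_validation_screen(cfg, ["NULLG"])
            zs = {
                t: control_z_for_gene(readouts, e)
                for t, e in lib.triggers_for_gene("NULLG").items()
            }
            if call_validated_hits({"NULLG": zs}):
                hits += 1
        assert hits <= 10


class TestSecondaryAssays:
    def test_structure_three_replicates_with_rluc(self):
        sens, h2ax = generate_secondary_assays({"G": SecondaryEffect()}, seed=5)
        assert set(sens.gene) == {"G", "RLUC"}
        assert sens.groupby(["gene", "condition"]).size().eq(3).all()
        assert h2ax.groupby(["gene", "timepoint"]).size().eq(3).all()

    def _sens_grades(self, seed, effect):
        sens, _ = generate_secondary_assays({"G": effect}, seed=seed)
        counts = {
            gene: {
                cond: list(g.cell_count)
                for cond, g in df.groupby("condition")
            }
            for gene, df in sens.groupby("gene")
        }
        return grade_sensitivity(counts["G"], counts["RLUC"])

    def test_strong_drug_effect_grades_three_plus(self):
        eff = SecondaryEffect(drug_depletion={"cisplatin": 0.45})
        n = sum(
            self._sens_grades(seed, eff)["cisplatin"] == "+++" for seed in range(100)
        )
        assert n >= 90

    def test_no_effect_grades_null(self):
        n = sum(
            self._sens_grades(seed, SecondaryEffect())["cisplatin"] == NONE
            for seed in range(100)
        )
        assert n >= 90

    def test_viability_factor_recovered(self):
        sens, _ = generate_secondary_assays(
            {"G": SecondaryEffect(viability_factor=0.4)}, seed=8
        )
        unt = sens[sens.condition == "untreated"]
        gene = unt[unt.gene == "G"].cell_count.tolist()
        rluc = unt[unt.gene == "RLUC"].cell_count.tolist()
        assert grade_viability(gene, rluc) == "++"

    def test_null_h2ax_p_values_are_uniform(self):
        """Comparing two no-effect knockdowns gives U(0,1) t-test p-values."""
        ps = []
        for seed in range(500):
            _, h2ax = generate_secondary_assays(
                {"G": SecondaryEffect()}, seed=seed
            )
            at_6h = h2ax[h2ax.timepoint == "6h"]
            _, p = student_t_test(
                at_6h[at_6h.gene == "G"].percent_positive.tolist(),
                at_6h[at_6h.gene == "RLUC"].percent_positive.tolist(),
            )
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01
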