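"""Synthetic repertoire generator: determinism, composition, planted structure."""

import math

import numpy as np
import pytest

from tcrpair.core import Lineage, Scope, deduplicate, filter_cells
from tcrpair.simulate import (
    SimConfig,
    default_effect_config,
    generate_annotation_db,
    generate_repertoire,
)


def small_config(**overrides):
    defaults = dict(n_cells=3000, seed=5)
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("field", ["f_shared", "f_dual", "f_unlabeled", "p_cd4"])
    def test_fractions_bounded(self, field):
        with pytest.raises(ValueError):
            SimConfig(**{field: 1.5})

    def test_unknown_effect_gene_rejected(self):
        with pytest.raises(ValueError, match="TRAV99"):
            SimConfig(v_alpha_effects={"TRAV99": 1.0})
        with pytest.raises(ValueError):
            SimConfig(interaction_effects={("TRAV1", "TRBV999"): 1.0})

    def test_prob_vector_length_checked(self):
        with pytest.raises(ValueError):
            SimConfig(n_v_alpha=5, v_alpha_probs=np.full(4, 0.25))

    def test_prob_vector_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(n_v_alpha=4, v_alpha_probs=np.full(4, 0.3))

    def test_intercept_defaults_to_logit_of_p_cd4(self):
        cfg = SimConfig(p_cd4=0.6)
        assert cfg.mu == pytest.approx(math.log(0.6 / 0.4))
        assert SimConfig(intercept=0.25).mu == 0.25

    def test_dict_round_trip(self):
        cfg = default_effect_config(seed=3, n_cells=500)
        again = SimConfig.from_dict(cfg.to_dict())
        assert again.interaction_effects == cfg.interaction_effects
        assert again.v_alpha_effects == cfg.v_alpha_effects
        np.testing.assert_allclose(again.v_beta_probs, cfg.v_beta_probs)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = default_effect_config(seed=3, n_cells=500)
        p = tmp_path / "sim.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        again = SimConfig.from_yaml(p)
        assert again.interaction_effects == cfg.interaction_effects
        assert again.annotation == cfg.annotation
        for aa in cfg.composition:
            assert again.composition[aa] == pytest.approx(cfg.composition[aa])
        np.testing.assert_allclose(again.v_alpha_probs, cfg.v_alpha_probs)


class TestGenerateRepertoire:
    def test_exact_cell_count(self):
        cells, _ = generate_repertoire(small_config())
        assert len(cells) == 3000

    def test_deterministic_for_fixed_seed(self):
        a, _ = generate_repertoire(small_config(seed=17))
        b, _ = generate_repertoire(small_config(seed=17))
        assert a == b

    def test_seed_changes_output(self):
        a, _ = generate_repertoire(small_config(seed=17))
        b, _ = generate_repertoire(small_config(seed=18))
        assert a != b

    def test_null_lineage_fraction_matches_p_cd4(self):
        # no effects planted: every clone is CD4 with probability p_cd4
        cfg = small_config(n_cells=8000, f_dual=0.0, f_unlabeled=0.0,
                           f_shared=0.0, p_cd4=0.6, seed=23)
        cells, _ = generate_repertoire(cfg)
        frac = np.mean([c.lineage == Lineage.CD4 for c in cells])
        # cells within a clone share a lineage draw, so the effective sample
        # size is the clone count, not the cell count
        n_clones = 8000 * cfg.expansion_geom_p
        sd = math.sqrt(0.6 * 0.4 / n_clones)
        assert abs(frac - 0.6) < 4 * sd

    def test_exclusion_fractions(self):
        cfg = small_config(n_cells=10000, seed=29)
        cells, _ = generate_repertoire(cfg)
        _, report = filter_cells(cells)
        f_excl = (report["dual_receptor"] + report["no_lineage"]) / len(cells)
        target = cfg.f_dual + cfg.f_unlabeled
        sd = math.sqrt(target * (1 - target) / len(cells))
        assert abs(f_excl - target) < 4 * sd
        assert report.get("unpaired", 0) == 0

    def test_shared_clones_present_in_both_lineages(self):
        cfg = small_config(n_cells=8000, f_dual=0.0, f_unlabeled=0.0,
                           f_shared=0.02, seed=31)
        cells, truth = generate_repertoire(cfg)
        reps = deduplicate(cells, Scope.PAIRED)
        both = reps[Lineage.CD4].members & reps[Lineage.CD8].members
        assert truth.shared_keys, "generator planted no shared clones"
        assert set(truth.shared_keys) <= both

    def test_shared_clones_have_shorter_cdr3s_on_average(self):
        cfg = small_config(n_cells=12000, f_shared=0.05,
                           shared_length_offset=3.0, seed=37)
        cells, truth = generate_repertoire(cfg)
        shared = set(truth.shared_keys)
        lens_shared = [len(k[1]) + len(k[3]) for k in shared]
        reps = deduplicate(cells, Scope.PAIRED)
        exclusive = (reps[Lineage.CD4].members | reps[Lineage.CD8].members) - shared
        lens_excl = [len(k[1]) + len(k[3]) for k in exclusive]
        assert np.mean(lens_shared) < np.mean(lens_excl)

    def test_planted_v_effect_shifts_usage(self):
        # strong Vα effect, everything else off: TRAV1 must be enriched in CD4
        cfg = small_config(
            n_cells=10000, seed=41, f_shared=0.0, f_dual=0.0, f_unlabeled=0.0,
            alpha_chain_pool=None, beta_chain_pool=None,
            v_alpha_effects={"TRAV1": math.log(4)})
        cells, _ = generate_repertoire(cfg)
        reps = deduplicate(cells, Scope.PAIRED)
        f_cd4 = (reps[Lineage.CD4].table["v_a"] == "TRAV1").mean()
        f_cd8 = (reps[Lineage.CD8].table["v_a"] == "TRAV1").mean()
        odds = (f_cd4 / (1 - f_cd4)) / (f_cd8 / (1 - f_cd8))
        assert odds > 2.0

    def test_truth_records_planted_parameters(self):
        cfg = default_effect_config(seed=43, n_cells=1000)
        _, truth = generate_repertoire(cfg)
        assert truth.v_alpha_log_or == cfg.v_alpha_effects
        assert truth.interaction_effects == cfg.interaction_effects
        assert truth.synergy_planted

    def test_finite_pools_raise_single_chain_sharing(self):
        pooled = small_config(n_cells=8000, seed=47)
        fresh = small_config(n_cells=8000, seed=47,
                             alpha_chain_pool=None, beta_chain_pool=None)

        def alpha_share(cfg):
            cells, _ = generate_repertoire(cfg)
            reps = deduplicate(cells, Scope.ALPHA)
            cd4, cd8 = reps[Lineage.CD4].members, reps[Lineage.CD8].members
            return len(cd4 & cd8) / len(cd4 | cd8)

        assert alpha_share(pooled) > alpha_share(fresh)


class TestGenerateAnnotationDB:
    def test_row_count_matches_plan(self, reference_run):
        cfg = reference_run["config"]
        db = generate_annotation_db(reference_run["cells"], cfg)
        plan = cfg.annotation
        expected = (2 * (plan.n_matched_pairs + plan.n_diff_species_pairs
                         + plan.n_same_species_pairs)
                    + plan.n_alpha_only + plan.n_beta_only + plan.n_decoys)
        assert len(db) == expected
        assert list(db.columns) == ["gene", "cdr3", "antigen.epitope",
                                    "antigen.species", "mhc.class"]

    def test_plant_recorded_on_truth(self, reference_run):
        truth = reference_run["truth"]
        generate_annotation_db(reference_run["cells"], reference_run["config"],
                               truth=truth)
        plant = truth.annotation_plant
        plan = reference_run["config"].annotation
        assert len(plant["matched"]) == plan.n_matched_pairs
        assert len(plant["diff_species"]) == plan.n_diff_species_pairs
        assert len(plant["same_species"]) == plan.n_same_species_pairs

    def test_impossible_plan_rejected(self):
        from tcrpair.simulate import AnnotationPlan

        cfg = small_config(n_cells=60,
                           annotation=AnnotationPlan(n_matched_pairs=500))
        cells, _ = generate_repertoire(cfg)
        with pytest.raises(ValueError, match="annotation plan"):
            generate_annotation_db(cells, cfg)
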