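"""Synthetic-data generators: mutant tiling, sequences, MaP rates, translation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from utrfold.io import TranscriptRecord
from utrfold.reactivity import normalize_profile, raw_reactivity
from utrfold.synthetic import (
    SimulationConfig,
    planted_structure,
    random_structured_sequence,
    simulate_luciferase_table,
    simulate_map_rates,
    simulate_structure_archetypes,
    simulate_translation_panel,
    tile_mutants,
)


def _native(n=300, seed=4):
    return random_structured_sequence(n, 0.58, seed=seed)


class TestTiling:
    def test_panel_of_42_named_6_to_252(self):
        mutants = tile_mutants(_native(), 252)
        assert len(mutants) == 42
        assert [m.name for m in mutants] == list(range(6, 253, 6))

    def test_windows_partition_region(self):
        mutants = tile_mutants(_native(), 252)
        covered = []
        for m in mutants:
            covered.extend(range(m.window[0], m.window[1] + 1))
        assert covered == list(range(1, 253))  # no gaps, no overlaps

    def test_single_window(self):
        mutants = tile_mutants(_native(), 6)
        assert len(mutants) == 1 and mutants[0].name == 6
        assert mutants[0].sequence[:6] == "UUAUUA"

    def test_mutation_confined_to_window(self):
        native = _native()
        for m in tile_mutants(native, 48):
            s, e = m.window
            assert m.sequence[:s - 1] == native.sequence[:s - 1]
            assert m.sequence[e:] == native.sequence[e:]
            assert m.sequence[s - 1:e] == "UUAUUA"

    def test_region_shorter_than_window_gives_empty_panel(self):
        assert tile_mutants(_native(), 5) == []

    def test_trailing_partial_window_dropped(self):
        assert len(tile_mutants(_native(), 27)) == 4

    def test_degenerate_flag(self):
        native = TranscriptRecord(id="x", sequence="UUAUUA" + "GCGCGC")
        mutants = tile_mutants(native, 12)
        assert mutants[0].is_degenerate and not mutants[1].is_degenerate


class TestRandomSequence:
    def test_gc_content_near_target(self):
        rec = random_structured_sequence(1000, 0.58, seed=1)
        gc = (rec.sequence.count("G") + rec.sequence.count("C")) / 1000
        assert abs(gc - 0.58) < 0.05

    def test_gc_zero_uses_only_au(self):
        rec = random_structured_sequence(200, 0.0, seed=1)
        assert set(rec.sequence) <= {"A", "U"}

    def test_deterministic_under_seed(self):
        a = random_structured_sequence(100, 0.5, seed=3)
        b = random_structured_sequence(100, 0.5, seed=3)
        assert a.sequence == b.sequence


class TestMapRateSimulation:
    def test_loops_more_mutated_than_stems(self, planted):
        record, structure = planted
        rates = simulate_map_rates(structure, SimulationConfig(seed=0))
        partner = structure.partner()
        paired = np.array([partner[i] != 0 for i in range(1, len(record) + 1)])
        assert rates.rate_mod[~paired].mean() > rates.rate_mod[paired].mean()

    def test_equal_modification_probabilities_rejected(self):
        # a null model (no unpaired/paired separation) violates the config invariant
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, p_mod_unpaired=0.004, p_mod_paired=0.004)

    def test_near_null_model_shows_little_separation(self, planted):
        _, structure = planted
        cfg = SimulationConfig(seed=0, p_mod_unpaired=0.00401, p_mod_paired=0.004)
        rates = simulate_map_rates(structure, cfg)
        partner = structure.partner()
        paired = np.array([partner[i] != 0
                           for i in range(1, len(structure.sequence) + 1)])
        gap = abs(rates.rate_mod[~paired].mean() - rates.rate_mod[paired].mean())
        assert gap < 0.002

    def test_zero_depth_flagged_for_masking(self, planted):
        _, structure = planted
        rates = simulate_map_rates(structure, SimulationConfig(seed=0, depth=0))
        profile = raw_reactivity(rates)
        assert np.isnan(profile.values).all()

    def test_bit_reproducible(self, planted):
        _, structure = planted
        r1 = simulate_map_rates(structure, SimulationConfig(seed=5))
        r2 = simulate_map_rates(structure, SimulationConfig(seed=5))
        assert np.array_equal(r1.rate_mod, r2.rate_mod)
        assert np.array_equal(r1.rate_unt, r2.rate_unt)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_background=0.01, p_mod_paired=0.004)
        with pytest.raises(ValueError):
            SimulationConfig(p_mod_unpaired=1.5)


class TestTranslationSimulation:
    def test_no_coupling_no_noise_gives_unity(self):
        cfg = SimulationConfig(seed=0, beta=0.0, translation_sigma=0.0)
        recs = simulate_translation_panel({"a": 3.0, "b": 9.0}, cfg)
        assert all(r.relative == pytest.approx(1.0) for r in recs)

    def test_noiseless_coupling_strictly_decreasing(self):
        cfg = SimulationConfig(seed=0, beta=0.2, translation_sigma=0.0)
        dg = {f"m{i}": float(i) for i in range(10)}
        recs = simulate_translation_panel(dg, cfg)
        rels = [r.relative for r in recs]
        assert all(a > b for a, b in zip(rels, rels[1:]))

    def test_replicate_count_is_six(self):
        recs = simulate_translation_panel({"a": 1.0}, SimulationConfig(seed=1))
        assert recs[0].n == 6 and len(recs[0].ratios) == 6

    def test_luciferase_table_recovers_coupling(self):
        from utrfold.translation import relative_translation

        rng = np.random.default_rng(2)
        dg = {"native": 0.0}
        dg.update({f"m{i}": float(rng.uniform(0, 15)) for i in range(20)})
        table = simulate_luciferase_table(dg, "native",
                                          SimulationConfig(seed=8, beta=0.1))
        recs = relative_translation(table, "native")
        by_label = {r.label: r.relative for r in recs}
        x = np.array([dg[l] for l in dg if l != "native"])
        y = np.log([by_label[l] for l in dg if l != "native"])
        slope = np.polyfit(x, y, 1)[0]
        assert -slope == pytest.approx(0.1, rel=0.35)


class TestArchetypePanel:
    def test_panel_shape_and_labels(self):
        labels, mats, truth = simulate_structure_archetypes(seed=0)
        assert len(labels) == 43 and labels[0] == "native"
        assert len(set(labels)) == 43
        assert np.bincount(truth).tolist() == [26, 6, 6, 5]
        assert all(m.p.shape == (270, 270) for m in mats)

    def test_within_group_similarity_exceeds_between(self):
        from utrfold.landscape import build_similarity_matrix

        labels, mats, truth = simulate_structure_archetypes(seed=1)
        sim = build_similarity_matrix(list(zip(labels, mats)), region=(1, 270))
        vals = sim.values
        same = [vals[a, b] for a in range(43) for b in range(43)
                if a != b and truth[a] == truth[b]]
        diff = [vals[a, b] for a in range(43) for b in range(43)
                if truth[a] != truth[b]]
        assert np.mean(same) > np.mean(diff) + 0.3


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_probing_pipeline_recovers_planted_structure(self, seed):
        """Simulated rates -> reactivity -> SHAPE-directed MFE recovers truth."""
        from utrfold.compare import sens_ppv
        from utrfold.fold import mfe_fold

        record, truth = planted_structure(n_hairpins=3, stem=9, loop=6,
                                          linker=7, seed=seed)
        assert 80 <= len(record) <= 150
        rates = simulate_map_rates(truth, SimulationConfig(seed=seed + 100))
        profile = normalize_profile(raw_reactivity(rates))
        folded = mfe_fold(record, profile)
        score = sens_ppv(folded.pairs, truth.pairs)
        assert score.sens >= 0.8 and score.ppv >= 0.8
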