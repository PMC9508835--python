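"""Start-codon accessibility (dG_unfold), relative translation, uORF scanning."""

import numpy as np
import pandas as pd
import pytest

from utrfold.energy import evaluate_energy
from utrfold.fold import mfe_fold
from utrfold.io import TranscriptRecord
from utrfold.structure import SecondaryStructure
from utrfold.synthetic import (
    SimulationConfig,
    planted_structure,
    random_structured_sequence,
    simulate_translation_panel,
)
from utrfold.translation import (
    classify_effect,
    constrain_structure,
    delta_g_unfold,
    delta_g_unfold_sweep,
    group_ttest,
    relative_translation,
    scan_uorfs,
    structure_translation_report,
)


class TestConstrainStructure:
    def test_untouched_when_window_clear(self, planted):
        _, structure = planted
        n = len(structure.sequence)
        # place the window on an unpaired linker at the very 3' end
        out = constrain_structure(structure, n, window=3)
        assert out.pairs == structure.pairs

    def test_hairpin_inside_window_fully_removed(self, model):
        seq = "AAAAAGGGGCAAAACCCCAAAAA"
        st = SecondaryStructure(seq, pairs=((6, 18), (7, 17), (8, 16), (9, 15)))
        out = constrain_structure(st, a_position=12, window=15)
        assert out.pairs == ()

    def test_single_endpoint_membership_suffices(self):
        seq = "G" * 30 + "A" * 10 + "C" * 30
        st = SecondaryStructure(seq, pairs=((5, 45),))
        # A = 60, w = 15 -> window [45, 70]; pair (5, 45) has one end inside
        out = constrain_structure(st, a_position=60, window=15)
        assert out.pairs == ()

    def test_window_clipped_at_bounds(self, planted):
        _, structure = planted
        out = constrain_structure(structure, a_position=1, window=15)
        assert all(j > 16 and i > 16 for i, j in out.pairs)


class TestDeltaGUnfold:
    def test_zero_iff_no_pairs_removed(self, planted):
        _, structure = planted
        n = len(structure.sequence)
        res = delta_g_unfold(structure, a_position=n, window=3)
        assert res.pairs_removed == 0 and res.dg_unfold == 0.0

    def test_hairpin_inside_window_costs_its_stability(self, model):
        seq = "AAAAAGGGGCAAAACCCCAAAAA"
        st = SecondaryStructure(seq, pairs=((6, 18), (7, 17), (8, 16), (9, 15)))
        hairpin_dg = evaluate_energy(st, None, model)
        assert hairpin_dg < 0
        res = delta_g_unfold(st, a_position=12, window=15, model=model)
        assert res.dg_unfold == pytest.approx(-hairpin_dg)

    def test_nonnegative_on_mfe_references(self, model, rng):
        for _ in range(15):
            rec = random_structured_sequence(
                60, 0.58, seed=int(rng.integers(0, 10_000)))
            ref = mfe_fold(rec, model=model)
            a = int(rng.integers(1, 61))
            res = delta_g_unfold(ref, a_position=a, model=model)
            assert res.dg_unfold >= -1e-9
            assert (res.pairs_removed == 0) == (abs(res.dg_unfold) < 1e-12)

    def test_window_widening_removes_superset_of_pairs(self, model):
        rec = random_structured_sequence(120, 0.58, seed=7)
        ref = mfe_fold(rec, model=model)
        sweep = delta_g_unfold_sweep(ref, a_position=60, model=model)
        counts = [r.pairs_removed for r in sweep]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_out_of_range_start_rejected(self, planted):
        _, structure = planted
        with pytest.raises(ValueError):
            delta_g_unfold(structure, a_position=0)


class TestRelativeTranslation:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["construct", "nl", "ff"])

    def test_native_is_exactly_one(self):
        table = self._table([("native", 100, 10)] * 6)
        (rec,) = relative_translation(table, "native")
        assert rec.relative == 1.0 and rec.n == 6

    def test_ratio_arithmetic(self):
        rows = [("native", 100, 10)] * 3 + [("mut180", 68, 10)] * 3
        recs = relative_translation(self._table(rows), "native")
        mut = next(r for r in recs if r.label == "mut180")
        assert mut.relative == pytest.approx(0.68)
        assert mut.effect == "decrease"

    def test_scale_invariance(self):
        rows = [("native", 100, 10)] * 3 + [("m", 50, 10)] * 3
        doubled = [(c, nl * 2, ff * 2) for c, nl, ff in rows]
        a = relative_translation(self._table(rows), "native")
        b = relative_translation(self._table(doubled), "native")
        assert [r.relative for r in a] == pytest.approx([r.relative for r in b])

    def test_nonpositive_firefly_dropped(self):
        rows = [("native", 100, 10)] * 3 + [("m", 50, 10), ("m", 50, 0.0)]
        recs = relative_translation(self._table(rows), "native")
        mut = next(r for r in recs if r.label == "m")
        assert mut.n == 1

    def test_all_replicates_dropped_is_error(self):
        rows = [("native", 100, 10)] * 3 + [("m", 50, 0.0)]
        with pytest.raises(ValueError, match="dropped"):
            relative_translation(self._table(rows), "native")

    def test_missing_native_rejected(self):
        with pytest.raises(ValueError, match="native"):
            relative_translation(self._table([("m", 1, 1)]), "native")


class TestClassifyEffect:
    @pytest.mark.parametrize("relative,expected", [
        (0.68, "decrease"),
        (1.10, "no_effect"),
        (0.85, "decrease"),   # boundary: a 15% change counts as an effect
        (1.15, "increase"),
        (0.86, "no_effect"),
        (1.32, "increase"),
    ])
    def test_threshold_classes(self, relative, expected):
        assert classify_effect(relative) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_effect(0.0)


class TestGroupTtest:
    def test_identical_groups_p_one(self):
        t, p = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, 4)
        b = 1 + rng.normal(0, 0.01, 4)
        t, p = group_ttest(a, b)
        assert p < 0.001

    def test_swap_symmetry(self):
        a, b = [0.1, 0.2, 0.3], [0.5, 0.7, 0.6]
        t1, p1 = group_ttest(a, b)
        t2, p2 = group_ttest(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0], [1.0, 2.0])


class TestUorfScan:
    def test_polyA_utr_has_no_uorfs(self):
        rec = TranscriptRecord(id="x", sequence="A" * 60 + "AUG" + "GCC" * 10,
                               annotations={"start_codon": 61})
        assert scan_uorfs(rec) == []

    def test_constructed_cug_orf_called_once(self):
        # CUG + 10 codons (30 nt incl. start) + in-frame UAA
        utr = "AAAA" + "CUG" + "GCA" * 9 + "UAA" + "AA"
        seq = utr + "AUG" + "GGC" * 5
        rec = TranscriptRecord(id="x", sequence=seq,
                               annotations={"start_codon": len(utr) + 1})
        calls = scan_uorfs(rec, min_len=30)
        assert len(calls) == 1
        call = calls[0]
        assert call.start == 5 and call.codon == "CUG"
        assert call.stop == 5 + 30
        assert call.length == 30
        assert call.cug_g is True  # next codon GCA starts with G

    def test_non_g_context_not_flagged(self):
        utr = "AAAA" + "CUG" + "ACA" * 10 + "UAA"
        seq = utr + "AUG" + "GGC" * 5
        rec = TranscriptRecord(id="x", sequence=seq,
                               annotations={"start_codon": len(utr) + 1})
        (call,) = scan_uorfs(rec, min_len=30)
        assert call.cug_g is False

    def test_short_orf_filtered(self):
        utr = "AAAA" + "CUG" + "GCA" * 3 + "UAA" + "A" * 30
        seq = utr + "AUG" + "GGC" * 5
        rec = TranscriptRecord(id="x", sequence=seq,
                               annotations={"start_codon": len(utr) + 1})
        assert scan_uorfs(rec, min_len=30) == []

    def test_stopless_orf_flagged(self):
        utr = "AAAA" + "CUG" + "GCA" * 12
        seq = utr + "AUG" + "GCA" * 2
        rec = TranscriptRecord(id="x", sequence=seq,
                               annotations={"start_codon": len(utr) + 1})
        calls = scan_uorfs(rec, min_len=30)
        assert len(calls) == 1 and calls[0].stop is None


class TestStructureTranslationReport:
    def _panel(self, seed=0, beta=0.1, sigma=0.1, n=43):
        rng = np.random.default_rng(seed)
        dg = {f"m{i}": float(rng.uniform(0, 15)) for i in range(n)}
        recs = simulate_translation_panel(
            dg, SimulationConfig(seed=seed, beta=beta, translation_sigma=sigma))

        class FakeUnfold:
            def __init__(self, label, value):
                self.label = label
                self.dg_unfold = value

        unfold = [FakeUnfold(k, v) for k, v in dg.items()]
        return unfold, recs, dg

    def test_negative_spearman_recovered(self):
        unfold, recs, _ = self._panel()
        report = structure_translation_report(unfold, recs)
        assert report["spearman_rho"] < 0

    def test_beta_recovered_within_30_percent(self):
        unfold, recs, dg = self._panel(seed=1)
        x = np.array([u.dg_unfold for u in unfold])
        y = np.log([next(r for r in recs if r.label == u.label).relative
                    for u in unfold])
        slope = np.polyfit(x, y, 1)[0]
        assert -slope == pytest.approx(0.1, rel=0.3)

    def test_missing_labels_reported_not_dropped(self):
        unfold, recs, _ = self._panel(n=10)
        report = structure_translation_report(unfold[:-2], recs)
        assert set(report["missing_labels"]) == {u.label for u in unfold[-2:]}

    def test_planted_group_offset_detected(self):
        rng = np.random.default_rng(3)
        a = 1.0 + rng.normal(0, 0.05, 10)
        b = 0.7 + rng.normal(0, 0.05, 10)
        t, p = group_ttest(a, b)
        assert p <= 0.05


def test_window_placement_specificity():
    """The translation coupling is strongest for the start-codon window."""
    rng = np.random.default_rng(4)
    panel = []
    for i in range(30):
        rec = random_structured_sequence(150, 0.58, seed=1000 + i)
        ref = mfe_fold(rec)
        panel.append((f"m{i}", ref))
    a_pos = 120
    dg_at = {lab: delta_g_unfold(ref, a_pos).dg_unfold for lab, ref in panel}
    recs = simulate_translation_panel(
        dg_at, SimulationConfig(seed=5, beta=0.1, translation_sigma=0.1))
    rel = {r.label: r.relative for r in recs}

    from scipy import stats

    def corr(dg_map):
        labs = list(dg_map)
        return stats.spearmanr([dg_map[l] for l in labs],
                               [rel[l] for l in labs]).statistic

    at_site = corr(dg_at)
    away = corr({lab: delta_g_unfold(ref, 40).dg_unfold for lab, ref in panel})
    assert at_site < 0
    assert at_site < away  # anti-correlation specific to the planted window
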