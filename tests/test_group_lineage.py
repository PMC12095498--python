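"""Diagnostic-position group calls, contamination estimation and k-mer
lineage assignment."""

import numpy as np
import pytest

from palaeosed import (DamageProfile, Fragment, PanelIndex, assign_lineage,
                       call_group, estimate_contamination, process_sample,
                       simulate_fragment_set)
from palaeosed.reads import Alignment


def frag_at(panel, pos, derived=None, fid="f", deam=False, flank=25):
    """Fragment copied from the TestFam genome around 1-based ``pos``;
    optionally carrying ``derived`` at that position."""
    g = panel.genomes["TestFam"]["TestFam_1"]
    start0 = pos - 1 - flank
    seq = g[start0:pos - 1 + flank + 1]
    if derived is not None:
        seq = seq[:flank] + derived + seq[flank + 1:]
    f = Fragment(id=fid, sequence=seq, alignment=Alignment(
        family="TestFam", genome="TestFam_1", start=start0 + 1,
        end=start0 + len(seq), strand="+", n_mismatches=0 if derived is None
        else 1, identity=1.0, score=len(seq), mapq=60))
    if deam:
        f.terminal_ct_5p = True
    return f


class TestCallGroup:
    def test_support_at_two_positions_not_called(self, custom_group_panel):
        """90% support but at only 2 unique positions misses the 3-position
        rule."""
        t = custom_group_panel.diagnostic_table
        d = {int(r.pos): r.derived for r in t[t.group == "G1"].itertuples()}
        frags = []
        for i in range(18):  # supporting, alternating between 2 positions
            p = [100, 400][i % 2]
            frags.append(frag_at(custom_group_panel, p, d[p], fid=f"s{i}"))
        frags += [frag_at(custom_group_panel, 800, None, fid=f"a{i}")
                  for i in range(2)]
        gc = call_group(frags, t, "G1", genome_length=2000)
        assert gc.support_fraction == pytest.approx(0.9)
        assert gc.lower_bound > 0.10
        assert gc.n_unique_diag_positions_supported == 2
        assert not gc.called

    def test_forty_of_hundred_across_five_positions_called(
            self, custom_group_panel):
        t = custom_group_panel.diagnostic_table
        diag = t[t.group == "G1"]
        d = {int(r.pos): r.derived for r in diag.itertuples()}
        positions = sorted(d)
        frags = [frag_at(custom_group_panel, positions[i % 5],
                         d[positions[i % 5]], fid=f"s{i}") for i in range(40)]
        frags += [frag_at(custom_group_panel, positions[i % 5], None,
                          fid=f"a{i}") for i in range(60)]
        gc = call_group(frags, t, "G1", genome_length=2000)
        assert gc.n_informative == 100 and gc.n_supporting == 40
        assert gc.lower_bound == pytest.approx(0.303, abs=5e-4)
        assert gc.n_unique_diag_positions_supported == 5
        assert gc.called

    def test_modern_human_requires_deaminated(self, panel, index):
        """Undamaged modern-human support must not produce a call."""
        t = panel.diagnostic_table
        mh = t[t.group == "ModernHuman"]
        hap = panel.lineage_haplotypes["ModernHuman"]
        frags = []
        for i, row in enumerate(mh.itertuples()):
            p = int(row.pos)
            for j in range(10):
                start0 = (p - 1 - 20) % 2000
                seq = (hap + hap)[start0:start0 + 45]
                f = Fragment(id=f"m{i}_{j}", sequence=seq)
                from palaeosed import assign_family
                assign_family(f, index)
                frags.append(f)
        gc = call_group(frags, t, "ModernHuman", genome_length=2000)
        assert gc.deaminated_only
        assert gc.n_informative == 0 and not gc.called

    def test_order_invariance(self, custom_group_panel):
        t = custom_group_panel.diagnostic_table
        d = {int(r.pos): r.derived
             for r in t[t.group == "G1"].itertuples()}
        frags = [frag_at(custom_group_panel, p, d[p], fid=f"s{p}")
                 for p in sorted(d)] * 4
        a = call_group(frags, t, "G1", genome_length=2000)
        b = call_group(list(reversed(frags)), t, "G1", genome_length=2000)
        assert (a.n_supporting, a.lower_bound) == (b.n_supporting, b.lower_bound)

    def test_no_informative_fragments_not_called(self, custom_group_panel):
        t = custom_group_panel.diagnostic_table
        gc = call_group([], t, "G2", genome_length=2000)  # exactly 3 positions
        assert gc.n_informative == 0 and not gc.called

    def test_too_few_diagnostics_rejected(self, custom_group_panel):
        t = custom_group_panel.diagnostic_table
        with pytest.raises(ValueError):
            call_group([], t, "NoSuchGroup", genome_length=2000)


class TestContamination:
    def test_no_overlap_gives_zero(self, custom_group_panel):
        t = custom_group_panel.diagnostic_table
        modern = t[t.group == "G1"].copy()
        frags = [frag_at(custom_group_panel, 1500, None, fid="x")]
        assert estimate_contamination(frags, modern, genome_length=2000) == 0

    def test_counts_modern_supporting_fragments(self, custom_group_panel):
        t = custom_group_panel.diagnostic_table
        modern = t[t.group == "G1"].copy()
        d = {int(r.pos): r.derived for r in modern.itertuples()}
        frags = [frag_at(custom_group_panel, 100, d[100], fid="c1"),
                 frag_at(custom_group_panel, 400, None, fid="a1"),
                 frag_at(custom_group_panel, 800, d[800], fid="c2")]
        assert estimate_contamination(frags, modern, genome_length=2000) == 2

    def test_empty_diagnostics_rejected(self, custom_group_panel):
        t = custom_group_panel.diagnostic_table
        with pytest.raises(ValueError):
            estimate_contamination([], t[t.group == "ZZ"], genome_length=2000)

    def test_estimate_tracks_truth_on_simulation(self, panel, index):
        """With a 10% contaminant fraction the estimate matches the truth
        scaled by the probability of overlapping a modern-specific site."""
        frags = simulate_fragment_set(
            panel, {"Hominidae": 1.0}, lineage_mix={"Denisova3": 1.0},
            n_fragments=2000, contaminant_fraction=0.10, seed=21)
        _, kept = process_sample(frags, index, mode="coordinate")
        hom = [f for f in kept if f.alignment.family == "Hominidae"]
        modern = panel.diagnostic_table[panel.diagnostic_table.modern_specific]
        est = estimate_contamination(hom, modern, genome_length=2000)
        # overlap probability per fragment: total modern-diag footprint
        mean_len = np.mean([len(f) for f in hom])
        p_overlap = min(len(modern) * mean_len / 2000.0, 1.0)
        truth = sum(1 for f in hom if f.truth.get("contaminant"))
        expected = truth * p_overlap
        se = np.sqrt(max(expected * (1 - p_overlap), 1.0))
        assert abs(est - expected) <= 3 * se + 2


class TestAssignLineage:
    def _hominin_frags(self, panel, lineage, n, prefix="h", length=100,
                       shift=0):
        """Unique fragments from one lineage haplotype, each covering a site
        where that haplotype differs from at least one other lineage; start
        offsets vary so no two fragments share a sequence."""
        hap = panel.lineage_haplotypes[lineage]
        others = {lin: h for lin, h in panel.lineage_haplotypes.items()
                  if lin != lineage}
        diffs = [i for i in range(len(hap))
                 if any(hap[i] != h[i] for h in others.values())]
        frags = []
        seen = set()
        j = -1
        while len(frags) < n:
            j += 1
            p = diffs[j % len(diffs)]
            off = 10 + (j // len(diffs)) + shift
            start0 = (p - off) % len(hap)
            seq = (hap + hap)[start0:start0 + length]
            if seq in seen:
                continue
            seen.add(seq)
            frags.append(Fragment(id=f"{prefix}{j}", sequence=seq,
                                  alignment=Alignment(
                                      family="Hominidae", genome="Hominidae_1",
                                      start=start0 + 1, end=start0 + length,
                                      strand="+", n_mismatches=0, identity=1.0,
                                      score=length, mapq=60)))
        return frags

    def test_min_total_gate(self, panel):
        frags = self._hominin_frags(panel, "Denisova3", 249)
        lc = assign_lineage(frags, panel.lineage_haplotypes)
        assert lc.n_hominin_unique == 249
        assert not lc.eligible and lc.called == []
        lc2 = assign_lineage(self._hominin_frags(panel, "Denisova3", 250),
                             panel.lineage_haplotypes)
        assert lc2.eligible and lc2.called

    def test_pooling_arithmetic(self, panel):
        frags = (self._hominin_frags(panel, "Denisova3", 120, "d3", shift=0)
                 + self._hominin_frags(panel, "Denisova4", 90, "d4", shift=25)
                 + self._hominin_frags(panel, "Neanderthal", 40, "ne", shift=50))
        lc = assign_lineage(frags, panel.lineage_haplotypes)
        assert lc.pooled_counts["Denisova3/4"] == \
            lc.assigned_counts["Denisova3"] + lc.assigned_counts["Denisova4"]
        total = sum(lc.pooled_counts.values())
        share = lc.pooled_counts["Denisova3/4"] / total
        assert lc.shares["Denisova3/4"] == pytest.approx(share)
        assert share >= 0.20
        assert "Denisova3/4" in lc.called

    def test_share_sum_bounded(self, panel):
        frags = self._hominin_frags(panel, "Denisova2", 300)
        lc = assign_lineage(frags, panel.lineage_haplotypes)
        assert sum(lc.shares.values()) <= 1 + 1e-9

    def test_duplication_invariance_with_collapsing(self, panel):
        frags = self._hominin_frags(panel, "Denisova8", 300)
        a = assign_lineage(frags, panel.lineage_haplotypes)
        b = assign_lineage(frags + frags, panel.lineage_haplotypes)
        assert a.shares == b.shares

    def test_pure_denisova2_recovered_across_seeds(self, panel, index):
        """Fragments simulated purely from the Denisova 2 haplotype call only
        the Denisova 2/8 pool."""
        modern = panel.diagnostic_table[panel.diagnostic_table.modern_specific]
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            frags = simulate_fragment_set(
                panel, {"Hominidae": 1.0}, lineage_mix={"Denisova2": 1.0},
                n_fragments=500, damage=DamageProfile(p_terminal_ct=0.3),
                seed=100 + seed)
            _, kept = process_sample(frags, index, mode="coordinate")
            hom = [f for f in kept if f.alignment.family == "Hominidae"]
            lc = assign_lineage(hom, panel.lineage_haplotypes,
                                modern_diagnostics=modern, genome_length=2000)
            hits += lc.eligible and lc.called == ["Denisova2/8"]
        assert hits == n_seeds

    def test_invalid_inputs(self, panel):
        with pytest.raises(ValueError):
            assign_lineage([], {"only": "ACGT" * 100})
        with pytest.raises(ValueError):
            assign_lineage([], panel.lineage_haplotypes, k=5000)
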