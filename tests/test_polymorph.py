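"""Empty-allele evidence, uniqueness screening and heterozygous-locus calls."""

import numpy as np
import pytest

from ere_scout import discovery, polymorph, synth
from ere_scout.discovery import ERE1Locus, FilterStatus
from ere_scout.polymorph import (
    TraceRead,
    check_locus_uniqueness,
    detect_empty_allele,
    extract_window,
    match_trace,
)
from ere_scout.seqs import revcomp


def _rand(n, seed=0):
    return synth._rand_seq(np.random.default_rng(seed), n)


def _locus(chrom="chr1", start=10_000, end=10_225):
    return ERE1Locus("L1", chrom, start, end, "+", 95.0)


class TestExtractWindow:
    def test_window_arithmetic(self):
        genome = {"chr1": _rand(30_000, 1)}
        w = extract_window(genome, _locus())
        assert (w.start, w.end, w.element_offset) == (9_000, 11_225, 1_000)
        assert w.sequence == genome["chr1"][9_000:11_225]
        assert not (w.truncated_left or w.truncated_right)

    def test_truncation_near_contig_start(self):
        genome = {"chr1": _rand(5_000, 2)}
        w = extract_window(genome, ERE1Locus("L", "chr1", 300, 525, "+", 95.0))
        assert w.start == 0
        assert w.truncated_left and not w.truncated_right
        assert w.element_offset == 300

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            extract_window({"chr1": _rand(1_000, 3)}, _locus())


class TestMatchTrace:
    def _window(self, consensus):
        seq = _rand(1000, 4) + consensus + _rand(1000, 5)
        return seq

    def test_exact_copy_no_gap(self, consensus):
        w = self._window(consensus)
        trace = w[600:1300]
        aln = match_trace(w, trace)
        assert aln.identity == 100.0
        assert not aln.gaps

    def test_excised_element_single_gap(self, consensus):
        w = self._window(consensus)
        empty = w[:1000] + w[1225:]
        trace = empty[600:1400]
        aln = match_trace(w, trace)
        assert len(aln.gaps) == 1
        assert aln.gaps[0].length == 225
        assert aln.identity == 100.0

    def test_reverse_complement_same_gap_call(self, consensus):
        w = self._window(consensus)
        empty = w[:1000] + w[1225:]
        trace = empty[600:1400]
        fwd = match_trace(w, trace)
        rev = match_trace(w, revcomp(trace))
        assert rev.strand == "-"
        assert [(g.window_start, g.length) for g in rev.gaps] == [
            (g.window_start, g.length) for g in fwd.gaps
        ]

    def test_unrelated_trace_no_alignment(self, consensus):
        aln = match_trace(self._window(consensus), _rand(700, 99))
        assert aln is None


class TestDetectEmptyAllele:
    def _setup(self, consensus, tsd=8, seed=6):
        flank_l, flank_r = _rand(1000, seed), _rand(1000, seed + 1)
        tsd_seq = _rand(tsd, seed + 2)
        window_seq = flank_l + tsd_seq + consensus + tsd_seq + flank_r
        genome = {"chr1": window_seq}
        locus = ERE1Locus("L1", "chr1", 1000 + tsd, 1000 + tsd + 225, "+", 99.0)
        w = extract_window(genome, locus)
        empty = flank_l + tsd_seq + flank_r
        return w, empty

    def test_het_locus_produces_evidence(self, consensus):
        w, empty = self._setup(consensus)
        trace = TraceRead("t1", empty[600:1400], "G836")
        evs = detect_empty_allele(w, [trace])
        assert len(evs) == 1
        ev = evs[0]
        assert ev.gap_length == 225 + 8
        assert ev.left_flank_identity == 100.0 and ev.right_flank_identity == 100.0
        assert ev.left_anchor >= 50 and ev.right_anchor >= 50

    def test_decoy_project_filtered(self, consensus):
        w, empty = self._setup(consensus)
        trace = TraceRead("t1", empty[600:1400], "G999")
        assert detect_empty_allele(w, [trace]) == []

    def test_gap_outside_band_rejected(self, consensus):
        w, _ = self._setup(consensus)
        # excise only 200 bp of the element: perfect flanks, short gap
        s = w.sequence
        short = s[:1008] + s[1208:]
        trace = TraceRead("t1", short[600:1400], "G836")
        assert detect_empty_allele(w, [trace]) == []

    def test_oversized_gap_rejected(self, consensus):
        """The element+TSD gap of a 14-bp-TSD locus exceeds the ±10 rule."""
        w, empty = self._setup(consensus, tsd=14, seed=20)
        trace = TraceRead("t1", empty[600:1400], "G836")
        assert detect_empty_allele(w, [trace]) == []

    def test_diverged_flank_rejected(self, consensus):
        w, empty = self._setup(consensus)
        read = list(empty[600:1400])
        # ~5% substitutions on the left anchor segment only
        rng = np.random.default_rng(0)
        for i in rng.choice(380, size=19, replace=False):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        evs = detect_empty_allele(w, [TraceRead("t1", "".join(read), "G836")])
        assert evs == []

    def test_evidence_invariant_to_trace_order_and_strand(self, consensus):
        w, empty = self._setup(consensus)
        t1 = TraceRead("t1", empty[600:1400], "G836")
        t2 = TraceRead("t2", revcomp(empty[550:1350]), "G836")
        t3 = TraceRead("t3", w.sequence[100:800], "G836")
        a = detect_empty_allele(w, [t1, t2, t3])
        b = detect_empty_allele(w, [t3, t2, t1])
        assert sorted(e.trace_id for e in a) == sorted(e.trace_id for e in b) == ["t1", "t2"]
        assert {e.gap_length for e in a} == {233}


class TestUniqueness:
    def test_single_copy_is_unique(self, consensus):
        genome = {"chr1": _rand(20_000, 7) + consensus + _rand(20_000, 8)}
        locus = ERE1Locus("L", "chr1", 20_000, 20_225, "+", 100.0)
        w = extract_window(genome, locus)
        assert check_locus_uniqueness(w, genome) == "unique"

    def test_duplicated_window_is_multicopy(self, consensus):
        left, right = _rand(20_000, 9), _rand(20_000, 10)
        window = left[-1000:] + consensus + right[:1000]
        genome = {"chr1": left + consensus + right + window + _rand(5_000, 11)}
        locus = ERE1Locus("L", "chr1", 20_000, 20_225, "+", 100.0)
        w = extract_window(genome, locus)
        assert check_locus_uniqueness(w, genome) == "multicopy"

    def test_element_only_similarity_stays_unique(self, consensus):
        # a second element copy elsewhere, but with unrelated flanks
        genome = {
            "chr1": _rand(20_000, 12) + consensus + _rand(15_000, 13)
            + consensus + _rand(5_000, 14)
        }
        locus = ERE1Locus("L", "chr1", 20_000, 20_225, "+", 100.0)
        w = extract_window(genome, locus)
        assert check_locus_uniqueness(w, genome) == "unique"


class TestCalling:
    def test_call_logic(self):
        loci = [ERE1Locus("a", "chr1", 0, 225, "+", 99.0),
                ERE1Locus("b", "chr1", 1000, 1225, "+", 99.0)]
        ev = [polymorph.EmptyAlleleEvidence("a", "t1", 225, 100, 100, 300, 300),
              polymorph.EmptyAlleleEvidence("b", "t2", 225, 100, 100, 300, 300)]
        calls = polymorph.call_polymorphic_loci(
            loci, ev, {"a": "unique", "b": "multicopy"}
        )
        assert calls.locus_id.tolist() == ["a"]
        assert calls.iloc[0].trace_ids == "t1"

    def test_round_trip_calls_match_truth(self, small_dataset, small_calls):
        calls, evidence, uniq = small_calls
        tt = small_dataset.truth_table
        tmap = {(r.start, r.end): r.locus_id for r in tt.itertuples()}
        called = {tmap[(r.start_1based - 1, r.end_1based)] for r in calls.itertuples()}
        expected = set(tt[tt.is_het & ~tt.multicopy].locus_id)
        assert called == expected

    def test_multicopy_loci_flagged_not_called(self, small_dataset, small_calls):
        calls, evidence, uniq = small_calls
        tt = small_dataset.truth_table
        assert sum(v == "multicopy" for v in uniq.values()) == tt.multicopy.sum()
        called_ids = set(calls.locus_id)
        for locus_id, verdict in uniq.items():
            if verdict == "multicopy":
                assert locus_id not in called_ids

    def test_no_false_calls_without_het_loci(self):
        cfg = synth.SimulationConfig(
            seed=21, genome_length=150_000, n_loci=12, n_het_loci=0,
            n_repeat_embedded=0, n_multicopy=0, n_decoy_repeats=4,
        )
        ds = synth.simulate_dataset(cfg)
        loci = discovery.discover(
            ds.consensus, ds.contigs, discovery.PlacementTable(ds.placement), ds.repeats
        )
        calls, _, _ = polymorph.find_heterozygous_loci(ds.chromosomes, loci, ds.traces)
        assert len(calls) == 0
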