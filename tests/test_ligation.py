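"""Junction classification, in-silico ligation and replicate statistics."""

import numpy as np
import pytest
from scipy import stats

import okaseq as ok
from okaseq.fragments import FragmentRecord
from okaseq.ligation import read_reports, write_reports

from conftest import ligate_oracle_geometry, ligation_signal_oracle


def frag(start, end, strand="+", chrom="chrI", state=None, flen=None, name="."):
    return FragmentRecord(chrom, start, end, strand, name=name,
                          junction_state=state, gap_or_flap_len=flen)


class TestClassifyJunctions:
    def test_geometric_labels(self):
        assert ok.classify_junctions([frag(100, 200), frag(200, 300)]) == ["nick"]
        assert ok.classify_junctions([frag(100, 200), frag(205, 300)]) == ["gap"]
        assert ok.classify_junctions([frag(100, 200), frag(195, 300)]) == ["flap_overlap"]

    def test_cross_chromosome_is_none(self):
        pair = [frag(100, 200, chrom="chrI"), frag(100, 200, chrom="chrII")]
        assert ok.classify_junctions(pair) == ["none"]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="unsorted"):
            ok.classify_junctions([frag(300, 400), frag(100, 200)])

    def test_annotation_takes_precedence_on_the_five_prime_side(self):
        # plus strand: the downstream fragment's 5' end faces the junction
        pair = [frag(100, 200), frag(200, 300, state="gap", flen=3)]
        assert ok.classify_junctions(pair) == ["gap"]
        assert ok.classify_junctions(pair, prefer_annotation=False) == ["nick"]
        # minus strand: the upstream fragment's 5' end faces the junction
        pair = [frag(100, 200, "-", state="nick"), frag(205, 300, "-")]
        assert ok.classify_junctions(pair) == ["nick"]
        assert ok.classify_junctions(pair, prefer_annotation=False) == ["gap"]


class TestLigateInSilico:
    def test_abutting_pair_merges(self):
        out = ok.ligate_in_silico([frag(100, 200), frag(200, 300)])
        assert len(out) == 1 and (out[0].start, out[0].end) == (100, 300)

    def test_chain_of_three_collapses(self):
        chain = [frag(100, 200), frag(200, 300), frag(300, 450)]
        out = ok.ligate_in_silico(chain)
        assert len(out) == 1 and (out[0].start, out[0].end) == (100, 450)

    def test_gap_left_unmerged(self):
        frags = [frag(100, 200), frag(205, 300)]
        assert ok.ligate_in_silico(frags) == sorted(
            frags, key=lambda f: (f.chrom, f.start, f.end, f.strand))

    def test_flap_overlap_never_trimmed_then_ligated(self):
        frags = [frag(100, 200), frag(195, 300)]
        assert len(ok.ligate_in_silico(frags)) == 2

    def test_idempotent_and_count_conserving(self, sims):
        records, _ = sims["WT"]
        subset = records[:5_000]
        once = ok.ligate_in_silico(subset)
        twice = ok.ligate_in_silico(once)
        assert once == twice
        n_nicks = sum(
            lab == "nick"
            for key in {(f.chrom, f.strand) for f in subset}
            for lab in ok.classify_junctions(sorted(
                (f for f in subset if (f.chrom, f.strand) == key),
                key=lambda f: (f.start, f.end, f.name)))
        )
        assert len(once) == len(subset) - n_nicks

    def test_covered_length_conserved_for_abutting_runs(self):
        rng = np.random.default_rng(2)
        frags, pos = [], 0
        for length in rng.integers(60, 300, 40):
            frags.append(frag(pos, pos + int(length)))
            pos += int(length) + int(rng.choice([0, 0, 5]))  # mostly abutting
        out = ok.ligate_in_silico(frags)
        assert sum(f.length for f in out) == sum(f.length for f in frags)

    def test_matches_brute_force_oracle_on_small_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            frags, pos = [], 0
            for length in rng.integers(60, 200, 40):
                strand = "+" if rng.random() < 0.5 else "-"
                frags.append(frag(pos, pos + int(length), strand))
                pos += int(length) + int(rng.choice([0, 0, 0, 7]))
            out = ok.ligate_in_silico(frags)
            # oracle merges any abutting same-strand pair until fixpoint
            assert sorted((f.chrom, f.start, f.end, f.strand) for f in out) == \
                ligate_oracle_geometry(frags)


class TestSignalQuantification:
    def test_counts_fragments_below_cutoff(self):
        frags = [frag(0, 150), frag(0, 300), frag(0, 1200)]
        assert ok.end_label_signal(frags, 1000) == 2
        assert ok.end_label_signal(frags, 1) == 0
        assert ok.end_label_signal([], 1000) == 0

    def test_percent_lost_arithmetic(self):
        pre = [frag(i * 10, i * 10 + 5, name=f"f{i}") for i in range(100)]
        post = pre[:55]
        report = ok.percent_signal_lost(pre, post, 1000)
        assert report.percent_lost == pytest.approx(45.0)

    def test_no_nicks_loses_nothing(self):
        frags = [frag(0, 150, state="gap", flen=3), frag(155, 300, state="flap", flen=5)]
        out = ok.ligate_in_silico(frags)
        assert ok.percent_signal_lost(frags, out).percent_lost == 0.0

    def test_zero_pre_signal_rejected(self):
        big = [frag(0, 5000)]
        with pytest.raises(ValueError, match="signal"):
            ok.percent_signal_lost(big, big, 1000)

    def test_simulated_percent_lost_matches_independent_oracle(self, sims):
        records, _ = sims["WT"]
        merged = ok.ligate_in_silico(records)
        report = ok.percent_signal_lost(records, merged, 1000)
        assert report.percent_lost == pytest.approx(
            ligation_signal_oracle(records, 1000), abs=3.0)

    def test_report_tsv_round_trip(self, tmp_path):
        rep = ok.LigationReport(100, 60, 100, 55, 1000, 45.0, "repA")
        path = tmp_path / "r.tsv"
        write_reports([rep], path)
        assert read_reports(path) == [rep]


class TestPairedTTest:
    def test_worked_difference_set(self):
        # differences [2, 4, 6]: t = mean / (sd / sqrt(3)) = 2*sqrt(3)
        pairs = [(10.0, 8.0), (10.0, 6.0), (10.0, 4.0)]
        t, df, p = ok.paired_t_test(pairs)
        assert t == pytest.approx(2 * np.sqrt(3.0), abs=1e-9)
        assert round(t, 4) == 3.4641
        assert df == 2
        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3.0), 2), rel=1e-12)
        assert round(p, 4) == 0.0742

    def test_tiny_variance_large_t(self):
        pairs = [(10.0, 5.0), (10.0, 4.999999), (10.0, 5.000001)]
        t, df, p = ok.paired_t_test(pairs)
        assert p < 0.001

    def test_symmetric_differences_give_t_zero(self):
        t, df, p = ok.paired_t_test([(0.0, 1.0), (0.0, -1.0)])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ok.paired_t_test([(1.0, 2.0)])
        with pytest.raises(ValueError, match="variance"):
            ok.paired_t_test([(5.0, 1.0), (6.0, 2.0), (7.0, 3.0)])
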