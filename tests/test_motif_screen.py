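import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apatwinscan.datamodel import DataError, PASRecord, ShiftTest
from apatwinscan.motif_screen import (
    extract_pas_window,
    hits_in_window,
    loss_of_use_pas,
    mutate_ugua_to_uggg,
    reverse_complement,
    scan_ugua_motifs,
    screen_twin_candidates,
    single_hits,
    twin_hits,
)

from tests.oracles import naive_motif_scan


def rec(site, strand="+", chrom="chr1", gene="g", label="P"):
    return PASRecord(gene, label, chrom, strand, site, {})


class TestWindowExtraction:
    genome = {"chr1": "".join(
        np.random.default_rng(0).choice(list("ACGT"), size=400))}

    def test_plus_strand_window(self):
        seq, trunc = extract_pas_window(self.genome, rec(200), window=100)
        assert seq == self.genome["chr1"][100:200]
        assert not trunc

    def test_minus_strand_window_is_revcomp_downstream(self):
        seq, trunc = extract_pas_window(self.genome, rec(200, "-"), window=100)
        assert seq == reverse_complement(self.genome["chr1"][201:301])
        assert not trunc

    def test_truncation_at_chromosome_edge(self):
        seq, trunc = extract_pas_window(self.genome, rec(30), window=100)
        assert len(seq) == 30 and trunc

    def test_missing_chromosome_raises(self):
        with pytest.raises(DataError, match="absent"):
            extract_pas_window(self.genome, rec(10, chrom="chrX"), window=10)

    def test_mirrored_locus_yields_identical_window(self):
        """Reverse-complementing the genome and flipping the strand gives
        the same transcribed-strand window."""
        g = self.genome["chr1"]
        L = len(g)
        mirrored = {"chr1": reverse_complement(g)}
        fwd, _ = extract_pas_window(self.genome, rec(200, "+"), window=50)
        back, _ = extract_pas_window(mirrored, rec(L - 1 - 200, "-"), window=50)
        assert fwd == back


class TestScanner:
    @pytest.mark.parametrize(
        "seq,n_single,n_twin,n_restricted",
        [
            ("UGUACUGUA", 2, 1, 1),  # human-form pyrimidine spacer
            ("UGUATUGUA", 2, 1, 1),  # mouse-form spacer
            ("UGUAGUGUA", 2, 1, 0),  # purine spacer: twin but not restricted
            ("UGUAUGUA", 2, 0, 0),   # starts 4 apart: no twin
            ("ACGTACGT", 0, 0, 0),
        ],
    )
    def test_pinned_patterns(self, seq, n_single, n_twin, n_restricted):
        hits = scan_ugua_motifs(seq)
        assert len(single_hits(hits)) == n_single
        assert len(twin_hits(hits)) == n_twin
        assert len(twin_hits(hits, restricted=True)) == n_restricted

    def test_distances_measured_to_cleavage_site(self):
        hits = scan_ugua_motifs("UGUACUGUA")
        twin = twin_hits(hits)[0]
        assert twin.start_distance == 9
        assert twin.spacer_base == "C"
        assert sorted(h.start_distance for h in single_hits(hits)) == [4, 9]

    def test_illegal_character_named(self):
        with pytest.raises(DataError, match="position 2"):
            scan_ugua_motifs("AC!T")

    @given(st.text(alphabet="ACGTU", min_size=0, max_size=300))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_naive_oracle(self, seq):
        hits = scan_ugua_motifs(seq)
        oracle = naive_motif_scan(seq)
        assert sorted(h.start for h in single_hits(hits)) == oracle["single"]
        assert sorted(h.start for h in twin_hits(hits)) == oracle["twin"]
        assert sorted(h.start for h in twin_hits(hits, restricted=True)) == \
            oracle["twin_restricted"]

    @given(st.text(alphabet="ACGT", min_size=9, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_twin_decomposition_properties(self, seq):
        """Every twin decomposes into two reported singles, and the twin
        count never exceeds C(singles, 2)."""
        hits = scan_ugua_motifs(seq)
        singles = {h.start for h in single_hits(hits)}
        twins = twin_hits(hits)
        n = len(singles)
        assert len(twins) <= n * (n - 1) // 2
        for t in twins:
            assert t.start in singles and t.start + 5 in singles

    def test_in_window_rule_first_base(self):
        seq = "UGUACUGUA" + "A" * 95  # twin first base at distance 104
        hits = scan_ugua_motifs(seq)
        assert twin_hits(hits)[0].start_distance == 104
        assert hits_in_window(twin_hits(hits), 100) == []
        assert hits_in_window(twin_hits(hits), 104) != []


class TestMutation:
    def test_both_ugua_to_uggg(self):
        assert mutate_ugua_to_uggg("UGUACUGUA", "all") == "UGGGCUGGG"

    def test_single_selection(self):
        assert mutate_ugua_to_uggg("UGUACUGUA", [0]) == "UGGGCUGUA"

    def test_rescan_of_mutated_sequence_is_clean(self):
        mutated = mutate_ugua_to_uggg("GGUGUACUGUAGG", "all")
        assert scan_ugua_motifs(mutated) == []

    def test_non_ugua_start_rejected(self):
        with pytest.raises(DataError, match="not UGUA starts"):
            mutate_ugua_to_uggg("UGUACUGUA", [1])

    def test_dna_alphabet_preserved(self):
        assert mutate_ugua_to_uggg("TGTACTGTA", "all") == "TGGGCTGGG"


class TestLossOfUse:
    def test_positive_ratio_change_means_distal_loss(self):
        t = ShiftTest("g", 1, 0.01, 0.5, +1.5)
        assert loss_of_use_pas(t) == "D"
        t2 = ShiftTest("g", 1, 0.01, -0.5, -1.5)
        assert loss_of_use_pas(t2) == "P"


class TestScreen:
    def _setup(self, twin_in_loss=True, twin_in_other=False,
               significant=True, switch=True):
        from apatwinscan.datamodel import ShiftClassification, TwoPASTable
        from apatwinscan.synthetic import plant_motif_sequence

        W = 120
        loss_w = plant_motif_sequence(
            W, 0.45, "UGUACUGUA" if twin_in_loss else None, 50, rng=1)
        other_w = plant_motif_sequence(
            W, 0.45, "UGUAUUGUA" if twin_in_other else None, 40, rng=2)
        # '+' gene: P at 300, D at 600; loss-of-use = D (ratio change > 0)
        pad = "".join(np.random.default_rng(3).choice(list("ACG"), size=700))
        g = list(pad)
        g[600 - W:600] = list(loss_w)
        g[300 - W:300] = list(other_w)
        genome = {"chr1": "".join(g)}
        table = TwoPASTable(
            "g", PASRecord("g", "P", "chr1", "+", 300, {}),
            PASRecord("g", "D", "chr1", "+", 600, {}))
        test = ShiftTest("g", 30.0, 1e-6, 1.0, 2.0, q_value=1e-5,
                         significant=significant)
        cls = ShiftClassification("g", "D", "P", switch, "UTR-APA", "proximal")
        return [(table, test, cls)], genome

    def test_planted_candidate_recovered(self):
        results, genome = self._setup()
        (cand,) = screen_twin_candidates(results, genome, window=100)
        assert cand.gene_id == "g"
        assert cand.loss_of_use_pas == "D"
        assert cand.twin_distance == 50
        assert cand.other_ugua_count == 0

    def test_twin_in_other_window_rejects(self):
        results, genome = self._setup(twin_in_other=True)
        assert screen_twin_candidates(results, genome, window=100) == []

    def test_non_significant_rejected(self):
        results, genome = self._setup(significant=False)
        assert screen_twin_candidates(results, genome, window=100) == []

    def test_major_switch_gate(self):
        results, genome = self._setup(switch=False)
        assert screen_twin_candidates(results, genome, window=100) == []
        assert screen_twin_candidates(
            results, genome, window=100, require_major_switch=False)

    def test_strict_mode_excludes_single_ugua_in_other_window(self):
        from apatwinscan.synthetic import plant_motif_sequence

        results, genome = self._setup()
        # rebuild other window with a lone UGUA
        W = 120
        lone = plant_motif_sequence(W, 0.45, "UGUA", 40, rng=5)
        g = list(genome["chr1"])
        g[300 - W:300] = list(lone)
        genome = {"chr1": "".join(g)}
        assert screen_twin_candidates(results, genome, window=100)  # default ok
        assert screen_twin_candidates(
            results, genome, window=100, strict_exclusion=True) == []
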