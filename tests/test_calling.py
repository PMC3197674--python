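"""Mismatch recovery, the three calling criteria and site mapping."""

import numpy as np
import pytest

from ultraedit.align import Genome, LocalAlignment
from ultraedit.calling import (
    MismatchProfile,
    classify,
    map_sites,
    recover_mismatches,
)
from ultraedit.config import PipelineConfig
from ultraedit.prefilter import SeqRecord
from ultraedit.transform import MISMATCH_TYPES, enumerate_combos, reverse_complement

COMBOS = {c.combo_id: c for c in enumerate_combos()}


def _aln(ops, genome_start, read_len=None, oriented_rc=False, combo="AG_p_p",
         contig="chr1"):
    n_m = ops.count("M")
    n_i = ops.count("I")
    n_d = ops.count("D")
    read_len = read_len if read_len is not None else n_m + n_i
    return LocalAlignment(
        read_id="r", combo_id=combo, contig=contig,
        genome_start=genome_start, genome_end=genome_start + n_m + n_d,
        read_start=0, read_end=n_m + n_i, ops=ops, score=n_m, matches=n_m,
        n_columns=len(ops), gaps_read=n_d, gaps_genome=n_i, evalue=0.0,
        oriented_rc=oriented_rc,
    )


def _profile(counts_positions, contig="chr1", gaps=(0, 0)):
    counts = {t: 0 for t in MISMATCH_TYPES}
    positions = {t: [] for t in MISMATCH_TYPES}
    for t, pos in counts_positions.items():
        counts[t] = len(pos)
        positions[t] = sorted(pos)
    return MismatchProfile("r", "AG_p_p", contig, counts, positions, *gaps)


@pytest.fixture(scope="module")
def striped_genome():
    # A at every even position: a span [0, x] holds (x // 2) + 1 adenosines
    return Genome({"chr1": "AC" * 200})


class TestRecoverMismatches:
    def test_all_match_alignment_has_zero_counts(self, toy_genome):
        read = SeqRecord("r", toy_genome.sequence("chr1", 100, 200))
        prof = recover_mismatches(
            _aln("M" * 100, 100), read, toy_genome, COMBOS["AG_p_p"]
        )
        assert prof.total_mismatches == 0

    def test_toy_a_to_g_columns_counted(self, toy_genome):
        gseq = toy_genome.sequence("chr1", 300, 400)
        a_pos = [i for i, b in enumerate(gseq) if b == "A"]
        edited = a_pos[:3]
        read_seq = "".join(
            "G" if i in edited else b for i, b in enumerate(gseq)
        )
        prof = recover_mismatches(
            _aln("M" * 100, 300), SeqRecord("r", read_seq), toy_genome,
            COMBOS["AG_p_p"],
        )
        assert prof.counts["A-to-G"] == 3
        assert prof.positions["A-to-G"] == [300 + i for i in edited]
        assert sum(prof.counts.values()) == 3

    def test_reverse_complemented_read_recovers_identically(self, toy_genome):
        gseq = toy_genome.sequence("chr1", 300, 400)
        a_pos = [i for i, b in enumerate(gseq) if b == "A"][:3]
        fwd = "".join("G" if i in a_pos else b for i, b in enumerate(gseq))
        rc_read = SeqRecord("r", reverse_complement(fwd))
        prof = recover_mismatches(
            _aln("M" * 100, 300, oriented_rc=True, combo="AG_p_m"),
            rc_read, toy_genome, COMBOS["AG_p_m"],
        )
        assert prof.counts["A-to-G"] == 3
        assert prof.positions["A-to-G"] == [300 + i for i in a_pos]

    def test_inconsistent_columns_raise(self, toy_genome):
        read = SeqRecord("r", toy_genome.sequence("chr1", 100, 180))
        with pytest.raises(ValueError):
            recover_mismatches(
                _aln("M" * 100, 100), read, toy_genome, COMBOS["AG_p_p"]
            )


class TestClassifyBoundaries:
    """The three criteria flip exactly at the published thresholds."""

    def test_twelve_sites_purity_above_point9_rate_point2_is_ultra(self, striped_genome):
        # 12 A-to-G spanning [0,118]: 60 As, rate 12/60 = 0.20 exactly
        dom = [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 118]
        prof = _profile({"A-to-G": dom, "C-to-T": [1]})
        call = classify(prof, striped_genome)
        assert call.purity == pytest.approx(12 / 13)
        assert call.editing_rate == pytest.approx(0.2)
        assert call.status == "ultra"

    def test_eleven_sites_is_hyper_not_ultra(self, striped_genome):
        dom = [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        call = classify(_profile({"A-to-G": dom}), striped_genome)
        assert call.editing_rate == pytest.approx(11 / 51)
        assert call.status == "hyper"

    def test_purity_exactly_point9_fails_strict_criterion(self, striped_genome):
        dom = [2 * k for k in range(17)] + [118]
        assert len(dom) == 18
        other = [1, 3]
        call = classify(_profile({"A-to-G": dom, "G-to-A": other}), striped_genome)
        assert call.purity == pytest.approx(0.9)
        assert call.status == "none" and call.reason == "low_purity"

    def test_purity_just_above_point9_passes(self, striped_genome):
        dom = [2 * k for k in range(18)] + [118]
        call = classify(_profile({"A-to-G": dom, "G-to-A": [1, 3]}), striped_genome)
        assert call.purity > 0.9
        assert call.status == "ultra"

    def test_rate_just_below_point2_fails_non_strict_criterion(self, striped_genome):
        # span [0,120] has 61 As: 12/61 < 0.20
        dom = [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 120]
        call = classify(_profile({"A-to-G": dom}), striped_genome)
        assert call.editing_rate == pytest.approx(12 / 61)
        assert call.status == "none" and call.reason == "low_rate"

    def test_dominant_tie_is_unclassifiable(self, striped_genome):
        call = classify(
            _profile({"A-to-G": [0, 2, 4], "G-to-A": [1, 3, 5]}), striped_genome
        )
        assert call.status == "none" and call.reason == "ambiguous"

    def test_too_few_sites(self, striped_genome):
        call = classify(_profile({"A-to-G": [0, 2, 4, 6]}), striped_genome)
        assert call.status == "none" and call.reason == "too_few_sites"


class TestMapSites:
    def test_plus_strand_sites_and_neighbors(self):
        genome = Genome({"chr1": "TTCAGTT" + "A" * 400})
        # site at position 3: ...C[A]G...
        dom = [3] + [7 + k for k in range(11)]
        prof = _profile({"A-to-G": dom})
        call = classify(prof, genome)
        assert call.status == "ultra" and call.strand == "+"
        sites = map_sites(call, genome)
        assert sites[0].position == 3
        assert sites[0].upstream_base == "C"
        assert sites[0].downstream_base == "G"

    def test_t_to_c_cluster_maps_to_minus_strand(self):
        genome = Genome({"chr1": "GGCTGAA" + "T" * 400})
        # + genome ...C[T]G... is A edited on the − strand, read 5'→3' on −:
        # upstream = complement of base at pos+1, downstream = complement at pos-1
        dom = [3] + [7 + k for k in range(11)]
        prof = _profile({"T-to-C": dom})
        call = classify(prof, genome)
        assert call.status == "ultra"
        assert call.mismatch_type == "A-to-G" and call.strand == "-"
        sites = map_sites(call, genome)
        assert sites[0].position == 3
        assert sites[0].upstream_base == "C"  # complement of G at pos 4
        assert sites[0].downstream_base == "G"  # complement of C at pos 2

    def test_site_off_the_expected_base_is_an_integrity_error(self):
        genome = Genome({"chr1": "CCCC" + "A" * 400})
        dom = [1] + [5 + k for k in range(11)]  # position 1 is C, not A
        prof = _profile({"A-to-G": dom})
        call = classify(prof, genome)
        with pytest.raises(ValueError):
            map_sites(call, genome)

    def test_every_emitted_site_overlies_the_edited_base(self, clean_run):
        sim, _, _, result = clean_run
        for call in result.ultra_calls:
            for s in call.sites:
                base = sim.genome.sequence(s.contig, s.position, s.position + 1)
                assert base == ("A" if s.strand == "+" else "T")
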