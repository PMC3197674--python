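"""Catalog statistics: dedup/regions, motif, clusters, dsRNA proxy, BED."""

import math

import numpy as np
import pytest

from ultraedit.align import Genome, LocalAlignment
from ultraedit.calling import EditingCall, EditingSite
from ultraedit.characterize import (
    BedFeature,
    Region,
    annotate_overlap,
    category_enrichment,
    cluster_sites,
    context_table,
    dedupe_and_regions,
    dsrna_self_pairing,
    export_bed,
    inverted_repeat_stats,
    read_bed,
    strand_preference,
)
from ultraedit.transform import reverse_complement


def _site(pos, strand="+", up="C", down="G", contig="chr1", read_id="r"):
    return EditingSite(contig, pos, strand, up, down, read_id)


def _call(read_id, sites, start, end, strand="+"):
    n = end - start
    aln = LocalAlignment(
        read_id=read_id, combo_id="AG_p_p", contig="chr1",
        genome_start=start, genome_end=end, read_start=0, read_end=n,
        ops="M" * n, score=n, matches=n, n_columns=n,
        gaps_read=0, gaps_genome=0, evalue=0.0,
    )
    return EditingCall(
        read_id=read_id, combo_id="AG_p_p", status="ultra",
        mismatch_type="A-to-G", raw_type="A-to-G", strand=strand,
        sites=sites, alignment=aln,
    )


class TestDedupeAndRegions:
    def test_shared_site_collapses_and_region_counts_reads(self):
        s = _site(150)
        calls = [
            _call("r1", [s], 100, 400),
            _call("r2", [_site(150, read_id="r2")], 120, 420),
        ]
        cat = dedupe_and_regions(calls)
        assert len(cat.sites) == 2
        assert len(cat.unique_sites) == 1
        assert len(cat.regions) == 1
        assert cat.regions[0].n_reads == 2

    def test_disjoint_alignments_make_two_regions(self):
        calls = [_call("r1", [_site(150)], 100, 400),
                 _call("r2", [_site(1150)], 1100, 1400)]
        cat = dedupe_and_regions(calls)
        assert len(cat.regions) == 2

    def test_eleven_reads_one_region(self):
        calls = [
            _call(f"r{i}", [_site(200 + i, read_id=f"r{i}")], 100, 400)
            for i in range(11)
        ]
        cat = dedupe_and_regions(calls)
        assert len(cat.regions) == 1
        assert cat.regions[0].n_reads == 11


class TestContextTable:
    def test_single_site_vectors(self):
        genome = Genome({"chr1": "CCAGG"})
        t = context_table([_site(2, up="C", down="G")], genome)
        assert t.upstream_freq.tolist() == [0, 1, 0, 0]
        assert t.downstream_freq.tolist() == [0, 0, 1, 0]
        assert t.dinucleotide[1, 2] == 1.0

    def test_normalization(self, clean_run):
        sim, _, _, result = clean_run
        t = context_table(result.catalog.unique_sites, sim.genome)
        assert math.isclose(t.upstream_freq.sum(), 1.0, abs_tol=1e-9)
        assert math.isclose(t.downstream_freq.sum(), 1.0, abs_tol=1e-9)
        assert math.isclose(t.dinucleotide.sum(), 1.0, abs_tol=1e-9)

    def test_edge_sites_skipped(self):
        genome = Genome({"chr1": "ACGTA"})
        with pytest.raises(ValueError):
            context_table([_site(0, up="N", down="C")], genome)


def _bf_cluster(positions, gap):
    """O(n^2) single-linkage oracle."""
    positions = sorted(positions)
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if abs(positions[i] - positions[j]) < gap:
                parent[find(j)] = find(i)
    groups = {}
    for i in range(len(positions)):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())


class TestClusterSites:
    def test_299_separation_joins(self):
        cl = cluster_sites([_site(0), _site(299)], gap=300)
        assert len(cl) == 1 and cl[0].size == 2

    def test_300_separation_splits(self):
        cl = cluster_sites([_site(0), _site(300)], gap=300)
        assert len(cl) == 2

    def test_twelve_sites_are_ultra_scale(self):
        sites = [_site(i * 8) for i in range(12)]
        (cl,) = cluster_sites(sites, gap=300)
        assert cl.tier == "ultra-scale"

    def test_tiers(self):
        assert cluster_sites([_site(5)], 300)[0].tier == "singleton"
        assert cluster_sites([_site(5), _site(10)], 300)[0].tier == "short"

    def test_strands_cluster_separately(self):
        cl = cluster_sites([_site(0, "+"), _site(10, "-")], gap=300)
        assert len(cl) == 2

    def test_matches_brute_force_oracle_on_random_sets(self):
        rg = np.random.default_rng(17)
        for _ in range(20):
            n = int(rg.integers(2, 120))
            positions = sorted(set(rg.integers(0, 5000, size=n).tolist()))
            sites = [_site(p) for p in positions]
            ours = sorted(sorted(c.positions) for c in cluster_sites(sites, 300))
            assert ours == _bf_cluster(positions, 300)


class TestStrandPreference:
    def test_sense_antisense_counting(self):
        reps = [BedFeature("chr1", 100, 400, "alu1", 0, "+"),
                BedFeature("chr1", 1100, 1400, "alu2", 0, "-")]
        calls = [_call("r1", [], 100, 400, strand="+"),
                 _call("r2", [], 1100, 1400, strand="+")]
        counts = strand_preference(calls, reps)
        assert counts["sense"] == 1 and counts["antisense"] == 1

    def test_no_overlap_is_unlabeled(self):
        counts = strand_preference([_call("r1", [], 100, 400)], [])
        assert counts["unlabeled"] == 1


class TestDsrnaSelfPairing:
    def test_perfect_palindrome_pairs_fully(self):
        rg = np.random.default_rng(0)
        half = "".join(rg.choice(list("ACGT"), 50))
        assert dsrna_self_pairing(half + reverse_complement(half)) == 100

    def test_planted_inverted_repeat_detected(self):
        rg = np.random.default_rng(1)

        def rand(n):
            return "".join(rg.choice(list("ACGT"), n))

        arm = rand(200)
        seq = rand(150) + arm + rand(120) + reverse_complement(arm) + rand(150)
        assert dsrna_self_pairing(seq) >= 190

    def test_random_sequence_is_near_zero(self):
        rg = np.random.default_rng(2)
        vals = [
            dsrna_self_pairing("".join(rg.choice(list("ACGT"), 1000)))
            for _ in range(3)
        ]
        assert max(vals) <= 30

    def test_invariant_under_reverse_complement(self):
        rg = np.random.default_rng(3)

        def rand(n):
            return "".join(rg.choice(list("ACGT"), n))

        arm = rand(150)
        seq = rand(100) + arm + rand(80) + reverse_complement(arm) + rand(100)
        assert dsrna_self_pairing(seq) == dsrna_self_pairing(reverse_complement(seq))


class TestInvertedRepeatStats:
    def _reps(self):
        return [
            BedFeature("chr1", 1000, 1300, "a", 0, "+"),
            BedFeature("chr1", 2000, 2300, "b", 0, "+"),
            BedFeature("chr1", 3000, 3300, "c", 0, "+"),
            BedFeature("chr1", 4000, 4300, "d", 0, "-"),
            BedFeature("chr1", 5000, 5300, "e", 0, "-"),
        ]

    def test_min_of_plus_minus_counts(self):
        region = Region("chr1", 2000, 2300, ["r"])
        n_min, dist = inverted_repeat_stats(region, self._reps(), flank=5000)
        assert n_min == 2
        assert dist == 4000 - 2300

    def test_abutting_inverted_repeat_distance_zero(self):
        reps = [BedFeature("chr1", 100, 400, "a", 0, "+"),
                BedFeature("chr1", 400, 700, "b", 0, "-")]
        region = Region("chr1", 100, 400, ["r"])
        _, dist = inverted_repeat_stats(region, reps, flank=5000)
        assert dist == 0

    def test_no_inverted_repeat_flagged(self):
        reps = [BedFeature("chr1", 100, 400, "a", 0, "+")]
        region = Region("chr1", 100, 400, ["r"])
        n_min, dist = inverted_repeat_stats(region, reps, flank=5000)
        assert n_min == 0 and dist is None


class TestCategoryEnrichment:
    def test_proportional_category_is_unenriched(self):
        e = category_enrichment(
            {"brain": 10, "liver": 90}, {"brain": 100, "liver": 900}
        )
        assert e["brain"] == pytest.approx(1.0)

    def test_doubled_share_gives_two(self):
        e = category_enrichment(
            {"brain": 20, "liver": 80}, {"brain": 100, "liver": 900}
        )
        assert e["brain"] == pytest.approx(2.0)

    def test_zero_total_category_flagged(self):
        e = category_enrichment({"x": 1}, {"x": 10, "y": 0})
        assert math.isnan(e["y"])

    def test_weighted_average_is_one(self):
        rg = np.random.default_rng(4)
        totals = {f"c{i}": int(rg.integers(50, 500)) for i in range(8)}
        edited = {c: int(rg.integers(0, 40)) for c in totals}
        enr = category_enrichment(edited, totals)
        grand = sum(totals.values())
        avg = sum(enr[c] * totals[c] / grand for c in totals)
        assert avg == pytest.approx(1.0)


class TestAnnotateOverlapAndBed:
    def test_half_open_boundary(self):
        feats = [BedFeature("chr1", 100, 200, "f", 0, "+")]
        calls = [_call("r", [_site(199, read_id="a"), _site(200, read_id="b")],
                       100, 300)]
        cat = dedupe_and_regions(calls)
        labels = annotate_overlap(cat, feats)
        assert labels[("chr1", 199, "+")] == ["f"]
        assert labels[("chr1", 200, "+")] == []

    def test_multiple_features_all_retained(self):
        feats = [BedFeature("chr1", 100, 200, "f1", 0, "+"),
                 BedFeature("chr1", 150, 250, "f2", 0, "-")]
        cat = dedupe_and_regions([_call("r", [_site(160)], 100, 300)])
        assert annotate_overlap(cat, feats)[("chr1", 160, "+")] == ["f1", "f2"]

    def test_export_bed_format_dedupe_and_roundtrip(self, tmp_path):
        calls = [_call("r1", [_site(100), _site(50, "-")], 0, 300),
                 _call("r2", [_site(100, read_id="r2")], 0, 300)]
        cat = dedupe_and_regions(calls)
        path = tmp_path / "sites.bed"
        export_bed(cat, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "chr1\t50\t51\t.\t0\t-"
        assert lines[1] == "chr1\t100\t101\t.\t0\t+"
        assert len(lines) == 2  # duplicates collapsed
        feats = read_bed(path)
        assert {(f.contig, f.start, f.strand) for f in feats} == {
            ("chr1", 50, "-"), ("chr1", 100, "+")
        }
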