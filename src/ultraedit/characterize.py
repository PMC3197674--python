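"""Post-hoc statistics on the editing-site catalog.

Site deduplication and region merging, the ADAR neighbor-preference tables,
short-cluster construction, sense/antisense repeat preference, the
dsRNA-length proxy (a region aligned against its own reverse complement),
inverted-repeat geometry, category enrichment, annotation overlap and BED
export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import AlignParams, Genome, seed_extend_align
from .calling import EditingCall, EditingSite
from .transform import reverse_complement

__all__ = [
    "BedFeature",
    "Region",
    "SiteCatalog",
    "ContextTable",
    "SiteCluster",
    "read_bed",
    "write_bed",
    "dedupe_and_regions",
    "context_table",
    "cluster_sites",
    "strand_preference",
    "dsrna_self_pairing",
    "inverted_repeat_stats",
    "category_enrichment",
    "annotate_overlap",
    "export_bed",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class BedFeature:
    contig: str
    start: int  # 0-based half-open
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


@dataclass
class Region:
    contig: str
    start: int
    end: int
    read_ids: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass
class SiteCatalog:
    sites: list[EditingSite]
    unique_sites: list[EditingSite]
    regions: list[Region]


@dataclass
class ContextTable:
    """Neighbor-nucleotide frequencies around editing sites (5'→3' on the
    edited strand); the dinucleotide matrix is upstream × downstream."""

    upstream_freq: np.ndarray  # length 4, order A C G T
    downstream_freq: np.ndarray
    dinucleotide: np.ndarray  # 4x4
    n_sites: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dinucleotide, index=list(_BASES), columns=list(_BASES)
        )


@dataclass
class SiteCluster:
    contig: str
    strand: str
    positions: list[int]

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def tier(self) -> str:
        if self.size == 1:
            return "singleton"
        if self.size < 12:
            return "short"
        return "ultra-scale"


# ---------------------------------------------------------------------------
# BED I/O

_BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_bed(path) -> list[BedFeature]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=_BED_COLUMNS[: 6], usecols=range(6), dtype={0: str, 3: str, 5: str},
    )
    return [
        BedFeature(r.contig, int(r.start), int(r.end), str(r.name),
                   float(r.score), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def write_bed(features: Iterable[BedFeature], path) -> None:
    rows = sorted(features, key=lambda f: (f.contig, f.start, f.end, f.strand))
    with open(path, "w") as fh:
        for f in rows:
            fh.write(
                f"{f.contig}\t{f.start}\t{f.end}\t{f.name}\t{f.score:g}\t{f.strand}\n"
            )


# ---------------------------------------------------------------------------
# Catalog construction


def dedupe_and_regions(calls: Sequence[EditingCall]) -> SiteCatalog:
    """Unique sites keyed by (contig, position, strand); regions are merged
    overlapping alignment intervals with the contributing read ids."""
    sites: list[EditingSite] = []
    for call in calls:
        sites.extend(call.sites)
    seen: dict[tuple, EditingSite] = {}
    for s in sites:
        seen.setdefault(s.key, s)
    unique = sorted(seen.values(), key=lambda s: (s.contig, s.position, s.strand))

    intervals: list[tuple[str, int, int, str]] = []
    for call in calls:
        aln = call.alignment
        if aln is not None:
            intervals.append((aln.contig, aln.genome_start, aln.genome_end, call.read_id))
    intervals.sort()
    regions: list[Region] = []
    for contig, start, end, rid in intervals:
        if regions and regions[-1].contig == contig and start < regions[-1].end:
            regions[-1].end = max(regions[-1].end, end)
            regions[-1].read_ids.append(rid)
        else:
            regions.append(Region(contig, start, end, [rid]))
    return SiteCatalog(sites=sites, unique_sites=unique, regions=regions)


def context_table(sites: Sequence[EditingSite], genome: Genome) -> ContextTable:
    """Neighbor frequencies; sites at contig edges (neighbor unknown) are
    skipped.  Vectors and the matrix are normalized to sum to 1."""
    di = np.zeros((4, 4))
    idx = {b: i for i, b in enumerate(_BASES)}
    n = 0
    for s in sites:
        up, down = s.upstream_base, s.downstream_base
        if up not in idx or down not in idx:
            continue
        di[idx[up], idx[down]] += 1
        n += 1
    if n == 0:
        raise ValueError("no sites with defined neighbors")
    di /= n
    return ContextTable(
        upstream_freq=di.sum(axis=1),
        downstream_freq=di.sum(axis=0),
        dinucleotide=di,
        n_sites=n,
    )


def cluster_sites(unique_sites: Sequence[EditingSite], gap: int = 300) -> list[SiteCluster]:
    """Single-linkage grouping per contig and strand; neighbors joined when
    separated by strictly less than ``gap`` bases."""
    by_group: dict[tuple[str, str], list[int]] = {}
    for s in unique_sites:
        by_group.setdefault((s.contig, s.strand), []).append(s.position)
    clusters: list[SiteCluster] = []
    for (contig, strand), positions in sorted(by_group.items()):
        positions = sorted(positions)
        current = [positions[0]]
        for p in positions[1:]:
            if p - current[-1] < gap:
                current.append(p)
            else:
                clusters.append(SiteCluster(contig, strand, current))
                current = [p]
        clusters.append(SiteCluster(contig, strand, current))
    return clusters


def _tree_by_contig(features: Iterable[BedFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        if f.end > f.start:
            trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)
    return trees


def strand_preference(calls: Sequence[EditingCall],
                      repeats: Sequence[BedFeature]) -> dict[str, int]:
    """Count edited repeat instances that are sense (repeat strand equals the
    editing strand) vs antisense; calls without repeat overlap are unlabeled."""
    trees = _tree_by_contig(repeats)
    counts = {"sense": 0, "antisense": 0, "unlabeled": 0}
    for call in calls:
        aln = call.alignment
        if aln is None or call.strand is None:
            continue
        tree = trees.get(aln.contig)
        hits = tree.overlap(aln.genome_start, aln.genome_end) if tree else ()
        if not hits:
            counts["unlabeled"] += 1
            continue
        for iv in hits:
            rep: BedFeature = iv.data
            if rep.strand == call.strand:
                counts["sense"] += 1
            else:
                counts["antisense"] += 1
    return counts


def dsrna_self_pairing(region_seq: str, params: AlignParams | None = None,
                       min_columns: int = 20) -> int:
    """Alignment-based proxy for fold-back dsRNA length.

    Aligns the region against its own reverse complement with the internal
    aligner under untransformed scoring and returns the total number of
    paired (matching) bases of the best alignment; alignments shorter than
    ``min_columns`` (chance self-pairing) count as zero.  Invariant under
    reverse-complementing the input.
    """
    params = params or AlignParams(
        word_size=8, evalue_max=1e-3, identity_min=0.6, length_min=20
    )
    rc = reverse_complement(region_seq)
    aln = seed_extend_align(region_seq, rc, params)
    if aln is None or aln.ops.count("M") < min_columns:
        return 0
    return aln.matches


def inverted_repeat_stats(region: Region, repeats: Sequence[BedFeature],
                          flank: int = 5000,
                          contig_length: int | None = None) -> tuple[int, int | None]:
    """Inverted-repeat geometry around an edited region.

    Returns (min(#+ repeats, #− repeats) within the flanked window, distance
    in bases between the edited repeat and the nearest opposite-strand
    repeat; None when no inverted repeat lies in the window).  The edited
    repeat is the one with the largest overlap with the region; when the
    region overlaps no repeat the region itself is used.  Windows are
    clipped at contig ends.
    """
    lo = max(0, region.start - flank)
    hi = region.end + flank
    if contig_length is not None:
        hi = min(hi, contig_length)
    in_window = [
        r for r in repeats
        if r.contig == region.contig and r.start < hi and r.end > lo
    ]
    n_plus = sum(1 for r in in_window if r.strand == "+")
    n_minus = sum(1 for r in in_window if r.strand == "-")

    overlapping = [
        r for r in in_window if r.start < region.end and r.end > region.start
    ]
    if overlapping:
        edited = max(
            overlapping,
            key=lambda r: min(r.end, region.end) - max(r.start, region.start),
        )
        e_start, e_end, e_strand = edited.start, edited.end, edited.strand
    else:
        e_start, e_end, e_strand = region.start, region.end, None
    best: int | None = None
    for r in in_window:
        if r.strand not in "+-":
            continue
        if e_strand is not None and r.strand == e_strand:
            continue
        if r.start < e_end and r.end > e_start:
            gap = 0
        else:
            gap = max(e_start, r.start) - min(e_end, r.end)
        if best is None or gap < best:
            best = gap
    return min(n_plus, n_minus), best


def category_enrichment(edited_counts: dict[str, int],
                        total_counts: dict[str, int]) -> dict[str, float]:
    """Observed/expected enrichment per category.

    expected = (category total / grand total) × total edited; categories with
    zero total are flagged with NaN.
    """
    grand = sum(total_counts.values())
    total_edited = sum(edited_counts.get(c, 0) for c in total_counts)
    out: dict[str, float] = {}
    for cat, tot in total_counts.items():
        if tot == 0 or grand == 0 or total_edited == 0:
            out[cat] = float("nan")
            continue
        expected = tot / grand * total_edited
        out[cat] = edited_counts.get(cat, 0) / expected
    return out


def annotate_overlap(catalog: SiteCatalog,
                     features: Sequence[BedFeature]) -> dict[tuple, list[str]]:
    """Half-open interval join: each unique site gets the names of every
    overlapping feature."""
    trees = _tree_by_contig(features)
    labels: dict[tuple, list[str]] = {}
    for s in catalog.unique_sites:
        tree = trees.get(s.contig)
        hits = tree.overlap(s.position, s.position + 1) if tree else ()
        labels[s.key] = sorted(iv.data.name for iv in hits)
    return labels


def export_bed(catalog: SiteCatalog, path) -> None:
    """Unique sites as a sorted 6-column BED track of single-base intervals."""
    feats = [
        BedFeature(s.contig, s.position, s.position + 1, ".", 0, s.strand)
        for s in catalog.unique_sites
    ]
    write_bed(feats, path)
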