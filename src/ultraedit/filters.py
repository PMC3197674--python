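"""Post-call cleanup: five independent filters against alignment artifacts.

A genuine ultra-edited molecule is masked by exactly one transformation /
strand combination, aligns without excessive gaps, is not a shadow of a
better-matching paralogous locus, has unremarkable base composition, and is
not contradicted by the annotated transcription direction of its locus.
Each filter can be applied in any order; the verdict is the union of
failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .align import AlignParams, Genome, LocalAlignment, align_candidates
from .calling import EditingCall
from .config import PipelineConfig
from .prefilter import SeqRecord
from .transform import reverse_complement

__all__ = [
    "FilterVerdict",
    "TranscriptAnnotation",
    "multi_combo_filter",
    "homogeneity_filter",
    "gap_filter",
    "paralog_filter",
    "strand_support_filter",
    "apply_filters",
]

FILTER_NAMES = ("multi_combo", "homogeneity", "gaps", "paralog", "strand_support")


@dataclass
class FilterVerdict:
    read_id: str
    kept: bool
    failed_filters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.kept == (not self.failed_filters)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A stranded transcript interval (6-column BED semantics)."""

    contig: str
    start: int
    end: int
    strand: str
    name: str = ""


def multi_combo_filter(calls: Iterable[EditingCall]) -> bool:
    """Fails (returns False) iff the read is ultra-edited in >= 2 combos.

    Hyper-tier calls in other combos do not count against the read.
    """
    n_ultra = sum(1 for c in calls if c.status == "ultra")
    return n_ultra < 2


def _longest_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def homogeneity_filter(read_segment: str, genome_segment: str,
                       cfg: PipelineConfig | None = None) -> bool:
    """Fails iff either aligned subsequence is too homogeneous.

    Checked on the original (untransformed) aligned subsequences: a
    mononucleotide run longer than ``max_run`` bases, or any ACGT frequency
    outside the [nt_freq_min, nt_freq_max] band.
    """
    cfg = cfg or PipelineConfig()
    for seg in (read_segment, genome_segment):
        if _longest_run(seg) > cfg.max_run:
            return False
        n_acgt = sum(seg.count(b) for b in "ACGT")
        if n_acgt == 0:
            return False
        for b in "ACGT":
            f = seg.count(b) / n_acgt
            if not (cfg.nt_freq_min <= f <= cfg.nt_freq_max):
                return False
    return True


def gap_filter(aln: LocalAlignment, cfg: PipelineConfig | None = None) -> bool:
    """Fails iff gaps exceed the overall or per-sequence limits."""
    cfg = cfg or PipelineConfig()
    total = aln.gaps_read + aln.gaps_genome
    return not (
        total > cfg.max_gaps_total
        or aln.gaps_read > cfg.max_gaps_each
        or aln.gaps_genome > cfg.max_gaps_each
    )


def _overlaps(a: LocalAlignment, contig: str, start: int, end: int) -> bool:
    return a.contig == contig and a.genome_start < end and a.genome_end > start


def paralog_filter(read: SeqRecord, genome: Genome, aln: LocalAlignment,
                   cfg: PipelineConfig | None = None) -> bool:
    """Fails iff an untransformed search finds a better alignment elsewhere.

    "Better" compares Smith–Waterman scores of the untransformed search:
    the best hit at a non-overlapping locus against the best hit overlapping
    the called locus (masking inflates the transformed score, so the
    comparison must stay within the untransformed search).  The competing
    alignment must cover >= ``paralog_cover`` of the original column count.
    """
    cfg = cfg or PipelineConfig()
    params = AlignParams.from_config(cfg)
    score_at_locus = 0
    best_elsewhere = 0
    for strand_seq in (read.seq, reverse_complement(read.seq)):
        for hit in align_candidates(strand_seq, genome, None, params):
            if _overlaps(hit, aln.contig, aln.genome_start, aln.genome_end):
                score_at_locus = max(score_at_locus, hit.score)
            elif hit.n_columns >= cfg.paralog_cover * aln.n_columns:
                best_elsewhere = max(best_elsewhere, hit.score)
    return best_elsewhere <= score_at_locus


def strand_support_filter(call: EditingCall,
                          transcripts: Iterable[TranscriptAnnotation] | None,
                          cfg: PipelineConfig | None = None) -> bool:
    """Fails iff annotated transcription contradicts the call strand.

    Requires at least ``strand_support_count`` transcripts overlapping the
    call region on the opposite strand AND none on the call strand; without
    annotation the filter passes vacuously.  Operationally this removes
    clusters that are better explained as T-to-C events on the annotated
    transcript.
    """
    cfg = cfg or PipelineConfig()
    if transcripts is None:
        return True
    aln = call.alignment
    if aln is None or call.strand is None:
        return True
    same = opposite = 0
    for tx in transcripts:
        if tx.contig != aln.contig:
            continue
        if tx.start < aln.genome_end and tx.end > aln.genome_start:
            if tx.strand == call.strand:
                same += 1
            else:
                opposite += 1
    return not (opposite >= cfg.strand_support_count and same == 0)


def apply_filters(read: SeqRecord, call: EditingCall,
                  all_calls_of_read: Iterable[EditingCall], genome: Genome,
                  transcripts: Iterable[TranscriptAnnotation] | None = None,
                  cfg: PipelineConfig | None = None) -> FilterVerdict:
    """Run all five filters on one (read, call); order-insensitive union."""
    cfg = cfg or PipelineConfig()
    aln = call.alignment
    failed: list[str] = []
    if not multi_combo_filter(all_calls_of_read):
        failed.append("multi_combo")
    oriented = reverse_complement(read.seq) if aln.oriented_rc else read.seq
    if aln.oriented_rc:
        qs, qe = len(read.seq) - aln.read_end, len(read.seq) - aln.read_start
    else:
        qs, qe = aln.read_start, aln.read_end
    read_seg = oriented[qs:qe]
    genome_seg = genome.sequence(aln.contig, aln.genome_start, aln.genome_end)
    if not homogeneity_filter(read_seg, genome_seg, cfg):
        failed.append("homogeneity")
    if not gap_filter(aln, cfg):
        failed.append("gaps")
    if not paralog_filter(read, genome, aln, cfg):
        failed.append("paralog")
    if not strand_support_filter(call, transcripts, cfg):
        failed.append("strand_support")
    return FilterVerdict(read.id, kept=not failed, failed_filters=failed)
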