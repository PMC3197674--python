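"""Sequence input and candidate-extraction quality filters.

Reads entering the screen are single-pass cDNA sequences that failed to
align to the reference genome.  Before any transformation they are screened
for length, skewed base composition, excess ambiguity codes and
simple-repeat content, and finally re-aligned untransformed to drop reads
that in fact match the genome nearly perfectly (>= 98% identity over >= 90%
of their length) — those carry no masked signal worth recovering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO

from .config import PipelineConfig
from .transform import reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .align import Genome

__all__ = [
    "SeqRecord",
    "PrefilterVerdict",
    "read_fasta",
    "composition_filter",
    "low_complexity_fraction",
    "genome_identity_screen",
    "prefilter_record",
]


@dataclass
class SeqRecord:
    """A candidate read: accession, uppercase nucleotide sequence, metadata."""

    id: str
    seq: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has empty sequence")


@dataclass
class PrefilterVerdict:
    record_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)


class FastaFormatError(ValueError):
    pass


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into ordered, uppercased records.

    Raises :class:`FastaFormatError` on an empty file, duplicate ids or
    entries without sequence.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FastaFormatError(f"{path}: FASTA entry with empty header")
        if not seq:
            raise FastaFormatError(f"{path}: entry {rec.id!r} has no sequence")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=seq))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def composition_filter(rec: SeqRecord, cfg: PipelineConfig | None = None) -> PrefilterVerdict:
    """Length, mononucleotide-percentage and ambiguity-fraction rules.

    Mononucleotide percentages are taken over ACGT positions only, while the
    ambiguity fraction is over the full length, so N-rich reads are not
    penalized twice.
    """
    cfg = cfg or PipelineConfig()
    reasons: list[str] = []
    n = len(rec.seq)
    if n <= cfg.min_len:
        reasons.append("too_short")
    acgt_counts = {b: rec.seq.count(b) for b in "ACGT"}
    n_acgt = sum(acgt_counts.values())
    if n_acgt > 0:
        fracs = {b: c / n_acgt for b, c in acgt_counts.items()}
        if max(fracs.values()) > cfg.mono_max:
            reasons.append("mono_nucleotide_high")
        if min(fracs.values()) < cfg.mono_min:
            reasons.append("mono_nucleotide_low")
    if (n - n_acgt) / n > cfg.ambig_max:
        reasons.append("ambiguous_excess")
    return PrefilterVerdict(rec.id, passed=not reasons, reasons=reasons)


def low_complexity_fraction(seq: str, max_period: int = 6, window: int = 24,
                            purity: float = 0.90) -> float:
    """Fraction of positions covered by simple (short-period tandem) repeats.

    A windowed scan over period lengths 1..max_period: a window is repetitive
    when, for some period p, at least ``purity`` of its position pairs (i,
    i+p) agree; all positions of such windows count as covered.  This is a
    declared stand-in for the dedicated repeat maskers used on real data.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if n < 2:
        return 1.0 if n == 1 else 0.0
    w = min(window, n)
    covered = bytearray(n)
    starts = range(0, n - w + 1, max(1, w // 4))
    for s in starts:
        seg = seq[s : s + w]
        for p in range(1, max_period + 1):
            if w <= p:
                break
            agree = sum(1 for i in range(w - p) if seg[i] == seg[i + p])
            if agree / (w - p) >= purity:
                covered[s : s + w] = b"\x01" * w
                break
    # tail window so the last < step positions are scanned too
    if n > w:
        seg = seq[n - w :]
        for p in range(1, max_period + 1):
            if w <= p:
                break
            agree = sum(1 for i in range(w - p) if seg[i] == seg[i + p])
            if agree / (w - p) >= purity:
                covered[n - w :] = b"\x01" * w
                break
    return sum(covered) / n


def genome_identity_screen(rec: SeqRecord, genome: "Genome",
                           cfg: PipelineConfig | None = None) -> PrefilterVerdict:
    """Drop reads that align untransformed at near-perfect identity.

    Fails with ``genome_identity`` iff some untransformed local alignment, on
    either strand, reaches ``identity_screen`` identity over at least
    ``cover_screen`` of the read length.
    """
    from .align import AlignParams, align_candidates

    cfg = cfg or PipelineConfig()
    params = AlignParams.from_config(cfg)
    for strand_seq in (rec.seq, reverse_complement(rec.seq)):
        for hit in align_candidates(strand_seq, genome, None, params):
            if (hit.identity >= cfg.identity_screen
                    and (hit.read_end - hit.read_start) >= cfg.cover_screen * len(rec.seq)):
                return PrefilterVerdict(rec.id, passed=False, reasons=["genome_identity"])
    return PrefilterVerdict(rec.id, passed=True)


def prefilter_record(rec: SeqRecord, genome: "Genome | None" = None,
                     cfg: PipelineConfig | None = None) -> PrefilterVerdict:
    """Combined verdict: composition + simple-repeat + genome-identity rules."""
    cfg = cfg or PipelineConfig()
    verdict = composition_filter(rec, cfg)
    reasons = list(verdict.reasons)
    if low_complexity_fraction(rec.seq) > cfg.simple_max:
        reasons.append("low_complexity")
    if genome is not None and "too_short" not in reasons:
        gv = genome_identity_screen(rec, genome, cfg)
        reasons.extend(gv.reasons)
    return PrefilterVerdict(rec.id, passed=not reasons, reasons=reasons)
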