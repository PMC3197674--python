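"""Mismatch recovery and the ultra-editing decision rules.

Once a reduced read has aligned, the original four-letter sequences are laid
back along the same alignment path and every mismatching column is
classified into one of the 12 genomic-base→read-base types (expressed on
the + genome).  A read is called ultra-edited when the dominant type has at
least 12 occurrences, makes up more than 90% of all mismatches, and covers
at least 20% of the edited-strand adenosines in the genomic span between the
first and last dominant-type mismatch; 5–11 occurrences with the same purity
and rate conditions is the hyper tier.  Clusters whose dominant type is the
complement-strand manifestation (e.g. T-to-C on the + genome) are folded to
A-to-G calls on the − strand when sites are mapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import Genome, LocalAlignment
from .config import PipelineConfig
from .prefilter import SeqRecord
from .transform import (
    MISMATCH_TYPES,
    TransformationCombo,
    canonical_type,
    reverse_complement,
)

__all__ = [
    "MismatchProfile",
    "EditingSite",
    "EditingCall",
    "recover_mismatches",
    "classify",
    "map_sites",
    "call_read",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class MismatchProfile:
    """Per-alignment tally of original-sequence mismatches.

    ``counts``/``positions`` are keyed by raw mismatch type on the + genome;
    ``span`` is the inclusive genomic interval from the first to the last
    mismatch of the dominant type, and ``n_src_in_span`` counts occurrences
    of the dominant type's genomic base inside it (adenosines of the edited
    strand, for an editing-type cluster).
    """

    read_id: str
    combo_id: str
    contig: str
    counts: dict[str, int]
    positions: dict[str, list[int]]
    gaps_read: int
    gaps_genome: int

    @property
    def total_mismatches(self) -> int:
        return sum(self.counts.values())

    def dominant(self) -> str | None:
        """Raw type with the highest count; None on a tie or no mismatches."""
        if self.total_mismatches == 0:
            return None
        best = max(self.counts.values())
        leaders = [t for t, c in self.counts.items() if c == best]
        return leaders[0] if len(leaders) == 1 else None

    def span(self, mtype: str) -> tuple[int, int] | None:
        pos = self.positions.get(mtype, [])
        if not pos:
            return None
        return pos[0], pos[-1]


@dataclass(frozen=True)
class EditingSite:
    """A single edited position, on the strand of the edited sense RNA."""

    contig: str
    position: int  # 0-based on the + genome
    strand: str
    upstream_base: str  # 5' neighbor read on the edited strand
    downstream_base: str
    read_id: str = field(compare=False, default="")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.strand)


@dataclass
class EditingCall:
    """A read's verdict under one transformation/strand combination."""

    read_id: str
    combo_id: str
    status: str  # ultra | hyper | none
    mismatch_type: str | None  # canonical label, e.g. "A-to-G"
    raw_type: str | None  # dominant type as seen on the + genome
    strand: str | None
    sites: list[EditingSite] = field(default_factory=list)
    editing_rate: float = 0.0
    purity: float = 0.0
    n_dominant: int = 0
    reason: str | None = None
    alignment: LocalAlignment | None = None
    profile: MismatchProfile | None = None


def recover_mismatches(aln: LocalAlignment, read: SeqRecord, genome: Genome,
                       combo: TransformationCombo) -> MismatchProfile:
    """Walk the alignment columns on the original, untransformed sequences.

    The read is oriented onto the + genome exactly as it was for the combo's
    alignment; each non-gap mismatching column with two unambiguous bases is
    tallied as genomic-base-to-read-base; gap columns are tallied separately.
    """
    oriented = reverse_complement(read.seq) if aln.oriented_rc else read.seq
    if aln.oriented_rc:
        qs = len(read.seq) - aln.read_end
        qe = len(read.seq) - aln.read_start
    else:
        qs, qe = aln.read_start, aln.read_end
    gseq = genome.sequence(aln.contig)
    n_m = aln.ops.count("M")
    if (qe - qs != n_m + aln.ops.count("I")
            or aln.genome_end - aln.genome_start != n_m + aln.ops.count("D")
            or qe > len(read.seq) or aln.genome_end > len(gseq)):
        raise ValueError(
            f"alignment columns inconsistent with intervals for read {read.id!r}"
        )
    counts = {t: 0 for t in MISMATCH_TYPES}
    positions: dict[str, list[int]] = {t: [] for t in MISMATCH_TYPES}
    i, j = qs, aln.genome_start
    for op in aln.ops:
        if op == "M":
            rb, gb = oriented[i], gseq[j]
            if rb != gb and rb in "ACGT" and gb in "ACGT":
                t = f"{gb}-to-{rb}"
                counts[t] += 1
                positions[t].append(j)
            i += 1
            j += 1
        elif op == "I":
            i += 1
        else:
            j += 1
    if i != qe or j != aln.genome_end:
        raise ValueError(
            f"alignment columns inconsistent with intervals for read {read.id!r}"
        )
    return MismatchProfile(
        read_id=read.id, combo_id=combo.combo_id, contig=aln.contig,
        counts=counts, positions=positions,
        gaps_read=aln.gaps_read, gaps_genome=aln.gaps_genome,
    )


def classify(profile: MismatchProfile, genome: Genome,
             cfg: PipelineConfig | None = None) -> EditingCall:
    """Apply the three cluster criteria to a mismatch profile.

    Dominant type by majority (ties are unclassifiable); purity over mismatch
    columns only; the rate denominator counts the dominant type's genomic
    base in the inclusive first-to-last-mismatch span, i.e. adenosines on
    the edited strand for an editing cluster.
    """
    cfg = cfg or PipelineConfig()
    base = EditingCall(
        read_id=profile.read_id, combo_id=profile.combo_id, status="none",
        mismatch_type=None, raw_type=None, strand=None, profile=profile,
    )
    dom = profile.dominant()
    if dom is None:
        base.reason = "ambiguous" if profile.total_mismatches else "no_mismatches"
        return base
    n_dom = profile.counts[dom]
    purity = n_dom / profile.total_mismatches
    lo, hi = profile.span(dom)
    src_base = dom.split("-to-")[0]
    span_seq = genome.sequence(profile.contig, lo, hi + 1)
    n_src = span_seq.count(src_base)
    rate = n_dom / n_src if n_src else 0.0
    canon, strand = canonical_type(dom)
    base.raw_type = dom
    base.mismatch_type = canon
    base.strand = strand
    base.n_dominant = n_dom
    base.purity = purity
    base.editing_rate = rate
    if purity <= cfg.purity_min:
        base.reason = "low_purity"
        return base
    if rate < cfg.rate_min:
        base.reason = "low_rate"
        return base
    if n_dom >= cfg.min_sites_ultra:
        base.status = "ultra"
    elif n_dom >= cfg.min_sites_hyper:
        base.status = "hyper"
    else:
        base.reason = "too_few_sites"
    return base


def map_sites(call: EditingCall, genome: Genome) -> list[EditingSite]:
    """Turn each dominant-type mismatch into a stranded genomic site.

    For −-strand calls (dominant type is the complement manifestation, e.g.
    T-to-C for A-to-G editing) neighbors are read 5'→3' on the − strand.
    Verifies that the genomic base at every site is the edited base on the
    call strand.
    """
    if call.status not in ("ultra", "hyper"):
        return []
    profile = call.profile
    gseq = genome.sequence(profile.contig)
    src = call.raw_type.split("-to-")[0]
    expected = src  # on the + genome
    sites = []
    for pos in profile.positions[call.raw_type]:
        if gseq[pos] != expected:
            raise ValueError(
                f"site {profile.contig}:{pos} is {gseq[pos]}, expected {expected}"
            )
        if call.strand == "+":
            up = gseq[pos - 1] if pos > 0 else "N"
            down = gseq[pos + 1] if pos + 1 < len(gseq) else "N"
        else:
            up = _COMP[gseq[pos + 1]] if pos + 1 < len(gseq) else "N"
            down = _COMP[gseq[pos - 1]] if pos > 0 else "N"
        sites.append(
            EditingSite(
                contig=profile.contig, position=pos, strand=call.strand,
                upstream_base=up, downstream_base=down, read_id=call.read_id,
            )
        )
    return sites


def call_read(read: SeqRecord, alignments: dict[str, LocalAlignment],
              genome: Genome, combos_by_id: dict[str, TransformationCombo],
              cfg: PipelineConfig | None = None) -> list[EditingCall]:
    """Recover, classify and map sites for every passing combo alignment."""
    cfg = cfg or PipelineConfig()
    calls: list[EditingCall] = []
    for combo_id, aln in alignments.items():
        combo = combos_by_id[combo_id]
        profile = recover_mismatches(aln, read, genome, combo)
        call = classify(profile, genome, cfg)
        call.alignment = aln
        if call.status in ("ultra", "hyper"):
            call.sites = map_sites(call, genome)
        calls.append(call)
    return calls
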