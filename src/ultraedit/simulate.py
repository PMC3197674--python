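"""Synthetic genomes and reads with ground truth.

The generator emulates the data the screen was designed for: a genome
carrying ~300 bp Alu-like repeat copies (mutually ~4% diverged, a fraction
inserted on the − strand so that inverted pairs exist), transcripts copied
from either strand of a repeat locus, A-to-I editing applied independently
per adenosine at a base rate modulated by the ADAR neighbor preference
(G depleted 5', enriched 3' of the edited A), uniform sequencing errors, and
an arbitrary sequencing strand.  Dedicated artifact classes (random mismatch
clusters, strand-biased G-to-A clusters, homopolymer loci, paralog shadows)
exercise the calling criteria and each cleanup filter.  Every read is
emitted together with a machine-checkable truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Genome
from .characterize import BedFeature
from .prefilter import SeqRecord
from .transform import reverse_complement

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimulatedGenome",
    "make_genome",
    "simulate_edited_read",
    "simulate_artifact_read",
    "simulate_cohort",
]

_BASES = np.array(list("ACGT"))

#: sense-strand repeat composition: A-rich, A > T, like the Alu consensus
_CONSENSUS_PROBS = (0.33, 0.23, 0.25, 0.19)
_BACKGROUND_PROBS = (0.25, 0.25, 0.25, 0.25)


@dataclass
class SimConfig:
    genome_length: int = 60_000
    n_repeats: int = 20
    repeat_length: int = 300
    repeat_divergence: float = 0.04      # substitutions between copies
    inverted_pair_fraction: float = 0.5  # probability a copy is on the − strand
    paralog_copies: int = 0              # extra (source, shadow) repeat pairs
    homopolymer_loci: int = 0            # repeat copies with an embedded A-run
    homopolymer_run: int = 40
    editing_rate: float = 0.25           # per-adenosine base rate p
    upstream_weights: dict = field(
        default_factory=lambda: {"A": 1.0, "C": 1.0, "G": 0.2, "T": 1.0}
    )
    downstream_weights: dict = field(
        default_factory=lambda: {"A": 1.0, "C": 1.0, "G": 2.0, "T": 1.0}
    )
    error_rate: float = 0.001
    rc_probability: float = 0.5
    read_flank: int = 10                 # unedited genomic flank on each side
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("inverted_pair_fraction", "editing_rate", "error_rate",
                     "rc_probability", "repeat_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SyntheticTruth:
    read_id: str
    kind: str                 # edited | random_mismatch_cluster | g_to_a_plus_strand
    #                           | homopolymer | paralog_shadow | unedited
    contig: str
    locus_start: int
    locus_end: int
    edited_strand: str        # strand of the sense (edited) RNA
    sequenced_rc: bool        # read emitted as reverse complement of the sense RNA
    site_positions: tuple[int, ...]   # genomic + coordinates of planted edits
    error_positions: tuple[int, ...]  # genomic + coordinates of sequencing errors
    source_locus_index: int = -1


@dataclass
class SimulatedGenome:
    genome: Genome
    repeats: list[BedFeature]
    cfg: SimConfig
    homopolymer_indices: list[int] = field(default_factory=list)
    paralog_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def clean_indices(self) -> list[int]:
        special = set(self.homopolymer_indices)
        for a, b in self.paralog_pairs:
            special.update((a, b))
        return [i for i in range(len(self.repeats)) if i not in special]


def _random_seq(rng: np.random.Generator, n: int, probs) -> str:
    return "".join(rng.choice(_BASES, size=n, p=probs))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    n_mut = int(round(rate * len(seq)))
    if n_mut:
        for i in rng.choice(len(seq), size=n_mut, replace=False):
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(3)]
    return "".join(out)


def make_genome(cfg: SimConfig) -> SimulatedGenome:
    """Background i.i.d. genome with planted, mutually diverged repeat copies.

    Copies are placed on an even grid with wide spacing so loci (plus read
    flanks) never overlap; each copy independently lands on the − strand with
    probability ``inverted_pair_fraction``.  Optional special copies: the
    first ``homopolymer_loci`` carry an embedded A-run, and ``paralog_copies``
    extra (source, shadow) pairs are appended where the shadow equals the
    source with its adenosines partially replaced by G — a decoy whose
    transcripts mimic A-to-G editing of the source locus.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n_copies = cfg.n_repeats + 2 * cfg.paralog_copies
    slot = cfg.genome_length // max(1, n_copies)
    if slot < cfg.repeat_length + 2 * cfg.read_flank + 200:
        raise ValueError("genome too short for the requested repeat copies")
    genome_arr = list(_random_seq(rng, cfg.genome_length, _BACKGROUND_PROBS))
    consensus = _random_seq(rng, cfg.repeat_length, _CONSENSUS_PROBS)

    repeats: list[BedFeature] = []
    homopoly: list[int] = []
    pairs: list[tuple[int, int]] = []
    copy_seqs: list[str] = []

    def plant(index: int, seq: str, strand: str, name: str) -> None:
        margin = cfg.read_flank + 100
        lo = index * slot + margin
        hi = (index + 1) * slot - cfg.repeat_length - margin
        start = int(rng.integers(lo, max(lo + 1, hi)))
        inserted = seq if strand == "+" else reverse_complement(seq)
        genome_arr[start : start + len(seq)] = list(inserted)
        repeats.append(BedFeature("chr1", start, start + len(seq), name, 0, strand))

    for i in range(cfg.n_repeats):
        copy = _mutate(rng, consensus, cfg.repeat_divergence)
        if i < cfg.homopolymer_loci:
            mid = cfg.repeat_length // 2
            run = "A" * cfg.homopolymer_run
            copy = copy[: mid] + run + copy[mid + cfg.homopolymer_run :]
            homopoly.append(i)
        strand = "-" if rng.random() < cfg.inverted_pair_fraction else "+"
        plant(i, copy, strand, f"repeat_{i}")
        copy_seqs.append(copy)

    for k in range(cfg.paralog_copies):
        src = _mutate(rng, consensus, cfg.repeat_divergence)
        a_pos = [i for i, b in enumerate(src) if b == "A"]
        n_shadow = max(12, int(0.2 * len(a_pos)))
        chosen = rng.choice(len(a_pos), size=min(n_shadow, len(a_pos)), replace=False)
        shadow = list(src)
        for ci in chosen:
            shadow[a_pos[ci]] = "G"
        i_src = cfg.n_repeats + 2 * k
        i_sha = i_src + 1
        plant(i_src, src, "+", f"repeat_{i_src}")
        plant(i_sha, "".join(shadow), "+", f"repeat_{i_sha}")
        pairs.append((i_src, i_sha))
        copy_seqs.extend([src, "".join(shadow)])

    genome = Genome({"chr1": "".join(genome_arr)})
    return SimulatedGenome(genome, repeats, cfg, homopoly, pairs)


def _apply_errors(rng: np.random.Generator, sense: list[str], rate: float,
                  skip: set[int]) -> list[int]:
    """Uniform substitution errors on positions not in ``skip`` (sense coords)."""
    err: list[int] = []
    for i in range(len(sense)):
        if i in skip:
            continue
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != sense[i]]
            sense[i] = choices[rng.integers(3)]
            err.append(i)
    return err


def _sense_to_plus(i: int, region_start: int, region_len: int, strand: str) -> int:
    if strand == "+":
        return region_start + i
    return region_start + region_len - 1 - i


def simulate_edited_read(sim: SimulatedGenome, locus_index: int,
                         rng: np.random.Generator, read_id: str,
                         editing_rate: float | None = None) -> tuple[SeqRecord, SyntheticTruth]:
    """One edited transcript copied from a repeat locus.

    The locus sequence (plus unedited flanks) is taken on its sense strand;
    each adenosine inside the repeat is edited independently with probability
    min(1, p × upstream weight × downstream weight); sequencing errors hit
    unedited positions uniformly; the read is reverse-complemented with
    probability ``rc_probability``.
    """
    cfg = sim.cfg
    p = cfg.editing_rate if editing_rate is None else editing_rate
    rep = sim.repeats[locus_index]
    gseq = sim.genome.sequence(rep.contig)
    rs = max(0, rep.start - cfg.read_flank)
    re_ = min(len(gseq), rep.end + cfg.read_flank)
    region = gseq[rs:re_]
    sense = list(region) if rep.strand == "+" else list(reverse_complement(region))
    rlen = len(sense)
    # sense-coordinate interval of the repeat proper (editable part)
    if rep.strand == "+":
        ed_lo, ed_hi = rep.start - rs, rep.end - rs
    else:
        ed_lo, ed_hi = re_ - rep.end, re_ - rep.start

    edited_sense: list[int] = []
    for i in range(max(1, ed_lo), min(rlen - 1, ed_hi)):
        if sense[i] != "A":
            continue
        w = cfg.upstream_weights.get(sense[i - 1], 1.0) * cfg.downstream_weights.get(
            sense[i + 1], 1.0
        )
        if rng.random() < min(1.0, p * w):
            edited_sense.append(i)
    for i in edited_sense:
        sense[i] = "G"
    errors_sense = _apply_errors(rng, sense, cfg.error_rate, set(edited_sense))

    rc = bool(rng.random() < cfg.rc_probability)
    seq = "".join(sense)
    if rc:
        seq = reverse_complement(seq)
    sites = tuple(sorted(_sense_to_plus(i, rs, rlen, rep.strand) for i in edited_sense))
    errs = tuple(sorted(_sense_to_plus(i, rs, rlen, rep.strand) for i in errors_sense))
    truth = SyntheticTruth(
        read_id=read_id, kind="edited", contig=rep.contig,
        locus_start=rs, locus_end=re_, edited_strand=rep.strand,
        sequenced_rc=rc, site_positions=sites, error_positions=errs,
        source_locus_index=locus_index,
    )
    return SeqRecord(id=read_id, seq=seq), truth


def simulate_artifact_read(sim: SimulatedGenome, kind: str, locus_index: int,
                           rng: np.random.Generator, read_id: str) -> tuple[SeqRecord, SyntheticTruth]:
    """One read of a named artifact class.

    ``random_mismatch_cluster``: 5% uniform substitutions, no editing — a
    low-quality read whose mismatch mix fails the purity criterion.
    ``g_to_a_plus_strand``: a fixed-count G→A cluster always sequenced
    forward — the control mismatch type with its tell-tale strand bias.
    ``homopolymer``: an edited read from a locus carrying a long genomic
    A-run — target of the homogeneity filter.
    ``paralog_shadow``: a transcript of the shadow copy of a paralog pair,
    carrying a fixed ~3% error load — apparent A-to-G editing of the source
    locus that an untransformed search resolves to the shadow.
    """
    cfg = sim.cfg
    rep = sim.repeats[locus_index]
    gseq = sim.genome.sequence(rep.contig)
    rs = max(0, rep.start - cfg.read_flank)
    re_ = min(len(gseq), rep.end + cfg.read_flank)
    region = gseq[rs:re_]
    sense = list(region) if rep.strand == "+" else list(reverse_complement(region))
    rlen = len(sense)

    if kind == "random_mismatch_cluster":
        n_err = int(round(0.05 * rlen))
        idx = rng.choice(rlen, size=n_err, replace=False)
        for i in idx:
            choices = [b for b in "ACGT" if b != sense[i]]
            sense[i] = choices[rng.integers(3)]
        rc = bool(rng.random() < cfg.rc_probability)
        seq = "".join(sense)
        if rc:
            seq = reverse_complement(seq)
        errs = tuple(sorted(_sense_to_plus(int(i), rs, rlen, rep.strand) for i in idx))
        truth = SyntheticTruth(read_id, kind, rep.contig, rs, re_, rep.strand,
                               rc, (), errs, locus_index)
        return SeqRecord(read_id, seq), truth

    if kind == "g_to_a_plus_strand":
        # cluster planted on the +-genome G's, read always emitted forward
        plus = list(region)
        g_pos = [i for i, b in enumerate(plus) if b == "G"]
        n = min(18, len(g_pos))
        idx = sorted(rng.choice(len(g_pos), size=n, replace=False))
        for ci in idx:
            plus[g_pos[ci]] = "A"
        errs = tuple(rs + g_pos[ci] for ci in idx)
        truth = SyntheticTruth(read_id, kind, rep.contig, rs, re_, "+",
                               False, (), errs, locus_index)
        return SeqRecord(read_id, "".join(plus)), truth

    if kind == "homopolymer":
        if locus_index not in sim.homopolymer_indices:
            raise ValueError("homopolymer artifact requires a homopolymer locus")
        rec, truth = simulate_edited_read(sim, locus_index, rng, read_id)
        truth.kind = kind
        return rec, truth

    if kind == "paralog_shadow":
        shadows = {b for _, b in sim.paralog_pairs}
        if locus_index not in shadows:
            raise ValueError("paralog_shadow artifact requires a shadow locus")
        # a lightly edited transcript of the shadow copy: eight genuine edits
        # put it below the untransformed identity screen, while the shadow's
        # A→G divergence from its source inflates an apparent ultra cluster
        # at the source locus — the target of the paralog filter.  The read
        # covers the repeat exactly (no flanks) so the masked alignment ties
        # between the two copies and resolves to the leftmost (source) locus.
        rs, re_ = rep.start, rep.end
        region = gseq[rs:re_]
        sense = list(region) if rep.strand == "+" else list(reverse_complement(region))
        rlen = len(sense)
        a_idx = [i for i in range(1, rlen - 1) if sense[i] == "A"]
        k = min(8, len(a_idx))
        chosen = sorted(rng.choice(len(a_idx), size=k, replace=False))
        edited = [a_idx[ci] for ci in chosen]
        for i in edited:
            sense[i] = "G"
        rc = bool(rng.random() < cfg.rc_probability)
        seq = "".join(sense)
        if rc:
            seq = reverse_complement(seq)
        sites = tuple(sorted(_sense_to_plus(i, rs, rlen, rep.strand) for i in edited))
        truth = SyntheticTruth(read_id, kind, rep.contig, rs, re_, rep.strand,
                               rc, sites, (), locus_index)
        return SeqRecord(read_id, seq), truth

    raise ValueError(f"unknown artifact kind {kind!r}")


def simulate_cohort(cfg: SimConfig, preset: str = "clean", n_reads: int = 50
                    ) -> tuple[SimulatedGenome, list[SeqRecord], list[SyntheticTruth]]:
    """Generate a genome plus a read cohort for one preset.

    ``clean``: edited reads from normal repeat loci.  ``artifacts``: equal
    parts random-mismatch clusters, +-strand G-to-A clusters, homopolymer
    reads and paralog shadows.  ``mixed``: half clean, half artifacts.
    """
    if preset not in ("clean", "artifacts", "mixed"):
        raise ValueError(f"unknown preset {preset!r}")
    need_special = preset in ("artifacts", "mixed")
    cfg_eff = cfg
    if need_special and (cfg.paralog_copies == 0 or cfg.homopolymer_loci == 0):
        cfg_eff = SimConfig(**{**cfg.__dict__,
                               "paralog_copies": max(1, cfg.paralog_copies),
                               "homopolymer_loci": max(1, cfg.homopolymer_loci)})
    sim = make_genome(cfg_eff)
    rng = np.random.default_rng([cfg_eff.seed, 1])
    reads: list[SeqRecord] = []
    truths: list[SyntheticTruth] = []
    clean = sim.clean_indices

    def add_clean(i: int) -> None:
        locus = clean[int(rng.integers(len(clean)))]
        rec, tr = simulate_edited_read(sim, locus, rng, f"read_{len(reads):04d}")
        reads.append(rec)
        truths.append(tr)

    def add_artifact(j: int) -> None:
        kinds = ("random_mismatch_cluster", "g_to_a_plus_strand",
                 "homopolymer", "paralog_shadow")
        kind = kinds[j % 4]
        if kind == "homopolymer":
            locus = sim.homopolymer_indices[int(rng.integers(len(sim.homopolymer_indices)))]
        elif kind == "paralog_shadow":
            shadows = [b for _, b in sim.paralog_pairs]
            locus = shadows[int(rng.integers(len(shadows)))]
        else:
            locus = clean[int(rng.integers(len(clean)))]
        rec, tr = simulate_artifact_read(sim, kind, locus, rng, f"read_{len(reads):04d}")
        reads.append(rec)
        truths.append(tr)

    if preset == "clean":
        for i in range(n_reads):
            add_clean(i)
    elif preset == "artifacts":
        for j in range(n_reads):
            add_artifact(j)
    else:
        for i in range(n_reads // 2):
            add_clean(i)
        for j in range(n_reads - n_reads // 2):
            add_artifact(j)
    return sim, reads, truths
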