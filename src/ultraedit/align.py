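"""Seed-and-extend local alignment over the reduced alphabet.

The screen aligns each reduced read against the reduced genome with a
MEGABLAST-like strategy: exact word seeding, gapped Smith–Waterman extension
in a window around the seeded diagonals, and acceptance only for the single
best alignment passing E-value / identity / length thresholds.  The dynamic
programming kernel is exact within each window (affine gaps), so on small
targets the result coincides with a full Smith–Waterman whenever a seed
exists.  E-values use the ungapped Karlin–Altschul statistics of the scoring
scheme under the background composition of the reduced target; with the
default scoring, gaps open rarely enough in random alignments that the
ungapped statistics describe the null well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit
from scipy.optimize import brentq

from Bio import SeqIO

from .config import PipelineConfig
from .transform import Transformation, reduce_alphabet, reverse_complement

__all__ = [
    "AlignParams",
    "LocalAlignment",
    "Genome",
    "seed_extend_align",
    "align_candidates",
    "run_all_combos",
    "sw_oracle",
    "evalue",
    "karlin_parameters",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme and acceptance thresholds of the reduced aligner."""

    word_size: int = 12
    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = -4
    gap_extend: int = -2
    evalue_max: float = 1e-50
    identity_min: float = 0.95
    length_min: int = 100

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (0 < self.identity_min <= 1):
            raise ValueError("identity_min must be in (0, 1]")
        if self.length_min < 1:
            raise ValueError("length_min must be >= 1")

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "AlignParams":
        return cls(
            word_size=cfg.word_size,
            match_score=cfg.match_score,
            mismatch_score=cfg.mismatch_score,
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
            evalue_max=cfg.evalue_max,
            identity_min=cfg.identity_min,
            length_min=cfg.length_min,
        )


@dataclass
class LocalAlignment:
    """A gapped local alignment mapped onto the + strand of the genome.

    ``ops`` is the column string in genome-forward order: ``M`` an aligned
    pair (match or mismatch), ``D`` a gap in the read row, ``I`` a gap in the
    genome row.  ``read_start``/``read_end`` are 0-based half-open in the
    *original* read orientation; ``oriented_rc`` records whether the read was
    reverse-complemented to lie in +-genome orientation.
    """

    read_id: str
    combo_id: str
    contig: str
    genome_start: int
    genome_end: int
    read_start: int
    read_end: int
    ops: str
    score: int
    matches: int
    n_columns: int
    gaps_read: int
    gaps_genome: int
    evalue: float
    oriented_rc: bool = False

    @property
    def identity(self) -> float:
        return self.matches / self.n_columns

    def check_consistency(self) -> None:
        """Recompute interval lengths and gap tallies from the column string."""
        n_m = self.ops.count("M")
        n_d = self.ops.count("D")
        n_i = self.ops.count("I")
        assert n_m + n_d + n_i == self.n_columns == len(self.ops)
        assert self.gaps_read == n_d and self.gaps_genome == n_i
        assert self.genome_end - self.genome_start == n_m + n_d
        assert self.read_end - self.read_start == n_m + n_i
        assert 0 <= self.matches <= n_m


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes; anything non-ACGT becomes 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


@njit(cache=True)
def _sw_kernel(q, t, match, mismatch, go, ge):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    neg = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), neg, np.int32)
    F = np.full((n + 1, m + 1), neg, np.int32)
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i - 1, j] + go + ge
            e_ext = E[i - 1, j] + ge
            if e_ext > e_open:
                e_val = e_ext
                flags = 4
            else:
                e_val = e_open
                flags = 0
            E[i, j] = e_val
            f_open = H[i, j - 1] + go + ge
            f_ext = F[i, j - 1] + ge
            if f_ext > f_open:
                f_val = f_ext
                flags |= 8
            else:
                f_val = f_open
            F[i, j] = f_val
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            d = H[i - 1, j - 1] + s
            h = 0
            src = 0
            if d > h:
                h = d
                src = 1
            if e_val > h:
                h = e_val
                src = 2
            if f_val > h:
                h = f_val
                src = 3
            H[i, j] = h
            ptr[i, j] = np.uint8(src | flags)
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr


def _traceback(ptr: np.ndarray, bi: int, bj: int) -> tuple[int, int, str]:
    """Walk the pointer matrix back from (bi, bj); returns (qstart, tstart, ops)."""
    i, j = bi, bj
    ops: list[str] = []
    state = "H"
    while True:
        cell = int(ptr[i, j])
        if state == "H":
            src = cell & 3
            if src == 0:
                break
            if src == 1:
                ops.append("M")
                i -= 1
                j -= 1
            elif src == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in genome row, consumes read base
            ops.append("I")
            ext = cell & 4
            i -= 1
            state = "E" if ext else "H"
        else:  # gap in read row, consumes genome base
            ops.append("D")
            ext = cell & 8
            j -= 1
            state = "F" if ext else "H"
    ops.reverse()
    return i, j, "".join(ops)


@dataclass
class _RawHit:
    """Window-best alignment in query/target coordinates, pre-threshold."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    ops: str
    matches: int

    @property
    def n_columns(self) -> int:
        return len(self.ops)

    @property
    def identity(self) -> float:
        return self.matches / len(self.ops) if self.ops else 0.0


def _align_window(q: np.ndarray, t: np.ndarray, p: AlignParams,
                  t_offset: int, q_str: str, t_str: str) -> _RawHit | None:
    score, bi, bj, ptr = _sw_kernel(
        q, t, p.match_score, p.mismatch_score, p.gap_open, p.gap_extend
    )
    if score <= 0:
        return None
    qs, ts, ops = _traceback(ptr, bi, bj)
    matches = 0
    i, j = qs, ts
    for op in ops:
        if op == "M":
            if q_str[i] == t_str[t_offset + j] and q_str[i] in "ACGT":
                matches += 1
            i += 1
            j += 1
        elif op == "I":
            i += 1
        else:
            j += 1
    return _RawHit(int(score), qs, bi, t_offset + ts, t_offset + bj, ops, matches)


def _seed_windows(query: str, target_index: dict[str, list[int]], qlen: int,
                  tlen: int, word_size: int, pad: int = 96,
                  max_windows: int = 24) -> list[tuple[int, int]]:
    """Merge seeded diagonals into candidate target windows."""
    diag_counts: dict[int, int] = {}
    for i in range(0, qlen - word_size + 1):
        hits = target_index.get(query[i : i + word_size])
        if hits:
            for j in hits:
                d = j - i
                diag_counts[d] = diag_counts.get(d, 0) + 1
    if not diag_counts:
        return []
    if tlen <= 4096:
        # small target: a single exact window, equality with full SW guaranteed
        return [(0, tlen)]
    diags = sorted(diag_counts)
    clusters: list[tuple[int, int, int]] = []  # (lo_diag, hi_diag, n_seeds)
    lo = hi = diags[0]
    count = diag_counts[lo]
    for d in diags[1:]:
        if d - hi <= pad:
            hi = d
            count += diag_counts[d]
        else:
            clusters.append((lo, hi, count))
            lo = hi = d
            count = diag_counts[d]
    clusters.append((lo, hi, count))
    windows = sorted(
        (max(0, lo - pad), min(tlen, hi + qlen + pad), n) for lo, hi, n in clusters
    )
    merged: list[list[int]] = []
    for s, e, n in windows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] += n
        else:
            merged.append([s, e, n])
    if len(merged) > max_windows:
        # keep the best-supported windows (seed count, then size)
        merged = sorted(merged, key=lambda w: (-w[2], -(w[1] - w[0])))[:max_windows]
        merged.sort()
    return [(s, e) for s, e, _ in merged]


def build_word_index(seq: str, word_size: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(0, len(seq) - word_size + 1):
        word = seq[j : j + word_size]
        index.setdefault(word, []).append(j)
    return index


class Genome:
    """A multi-contig reference with cached reduced variants and word indexes."""

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("genome has no contigs")
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self._reduced: dict[str | None, dict[str, str]] = {}
        self._encoded: dict[str | None, dict[str, np.ndarray]] = {}
        self._indexes: dict[tuple[str | None, int], dict[str, dict[str, list[int]]]] = {}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def sequence(self, contig: str, start: int | None = None, end: int | None = None) -> str:
        return self.contigs[contig][start:end]

    def _key(self, t: Transformation | None) -> str | None:
        return None if t is None else t.name

    def reduced(self, t: Transformation | None) -> dict[str, str]:
        key = self._key(t)
        if key not in self._reduced:
            if t is None:
                self._reduced[key] = dict(self.contigs)
            else:
                self._reduced[key] = {
                    name: reduce_alphabet(seq, t) for name, seq in self.contigs.items()
                }
        return self._reduced[key]

    def encoded(self, t: Transformation | None) -> dict[str, np.ndarray]:
        key = self._key(t)
        if key not in self._encoded:
            self._encoded[key] = {
                name: encode(seq) for name, seq in self.reduced(t).items()
            }
        return self._encoded[key]

    def word_index(self, t: Transformation | None, word_size: int) -> dict[str, dict[str, list[int]]]:
        key = (self._key(t), word_size)
        if key not in self._indexes:
            self._indexes[key] = {
                name: build_word_index(seq, word_size)
                for name, seq in self.reduced(t).items()
            }
        return self._indexes[key]

    def background_freqs(self, t: Transformation | None) -> tuple[float, ...]:
        total = self.total_length
        counts = {b: 0 for b in "ACGT"}
        for seq in self.reduced(t).values():
            for b in "ACGT":
                counts[b] += seq.count(b)
        n = max(1, sum(counts.values()))
        return tuple(counts[b] / n for b in "ACGT")


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics


@lru_cache(maxsize=64)
def karlin_parameters(match: int, mismatch: int,
                      freqs: tuple[float, ...]) -> tuple[float, float, float]:
    """Ungapped Karlin–Altschul (lambda, K, H) for a match/mismatch scheme.

    The per-column score distribution under the background composition
    ``freqs`` is two-valued: +match with probability sum(p_i^2), mismatch
    otherwise.  lambda solves sum_s p(s) exp(lambda s) = 1; K is computed
    from the classical renewal series for integer-lattice walks,

        sigma = sum_k (1/k) [ P(S_k >= 0) + E(exp(lambda S_k); S_k < 0) ],
        K = delta * lambda * exp(-2 sigma) / (H * (1 - exp(-lambda delta))),

    with delta the lattice span of the step distribution and H the relative
    entropy of the tilted walk.
    """
    p_match = float(sum(f * f for f in freqs))
    if not (0 < p_match < 1):
        raise ValueError("degenerate background composition")
    vals = np.array([match, mismatch], dtype=np.int64)
    probs = np.array([p_match, 1.0 - p_match])
    mean = float(np.dot(vals, probs))
    if mean >= 0:
        raise ValueError(
            "expected score per column is non-negative; E-value statistics undefined"
        )

    def f(lam: float) -> float:
        return float(np.dot(probs, np.exp(lam * vals))) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("failed to bracket lambda")
    lam = brentq(f, 1e-9, hi, xtol=1e-12)

    # relative entropy of the lambda-tilted step distribution
    tilted = probs * np.exp(lam * vals)
    H = lam * float(np.dot(vals, tilted))

    # lattice span of the step distribution
    delta = int(np.gcd.reduce(np.abs(vals - vals[0])[1:])) if len(vals) > 1 else 1
    if delta == 0:
        delta = 1

    # renewal series over k-step convolutions of the score distribution
    lo_s, hi_s = int(vals.min()), int(vals.max())
    dist = np.zeros(hi_s - lo_s + 1)
    for v, p in zip(vals, probs):
        dist[int(v) - lo_s] += p
    conv = dist.copy()
    offset = lo_s  # value of index 0 of conv for current k
    sigma = 0.0
    for k in range(1, 61):
        support = np.arange(offset, offset + len(conv))
        nonneg = float(conv[support >= 0].sum())
        neg_mask = support < 0
        e_neg = float(np.dot(conv[neg_mask], np.exp(lam * support[neg_mask])))
        sigma += (nonneg + e_neg) / k
        conv = np.convolve(conv, dist)
        offset += lo_s
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return lam, K, H


def evalue(score: int, read_len: int, genome_len: int,
           params: AlignParams, freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)) -> float:
    """Expected number of chance alignments scoring >= score: K m n e^{-lambda S}."""
    if score < 0:
        raise ValueError("score must be non-negative")
    lam, K, _ = karlin_parameters(params.match_score, params.mismatch_score, tuple(freqs))
    return K * read_len * genome_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# Alignment entry points


def _window_hits(query: str, target: str, target_encoded: np.ndarray,
                 index: dict[str, list[int]], params: AlignParams) -> list[_RawHit]:
    windows = _seed_windows(query, index, len(query), len(target), params.word_size)
    q_codes = encode(query)
    hits: list[_RawHit] = []
    for ws, we in windows:
        hit = _align_window(q_codes, target_encoded[ws:we], params, ws, query, target)
        if hit is not None:
            hits.append(hit)
    return hits


def seed_extend_align(reduced_read: str, reduced_target: str,
                      params: AlignParams | None = None,
                      search_space: int | None = None,
                      freqs: tuple[float, ...] | None = None) -> LocalAlignment | None:
    """Best accepted local alignment of one reduced read vs one target.

    Returns the single highest-scoring alignment passing the E-value,
    identity and column-count thresholds, or None.  Ties are broken by lower
    E-value (equal by construction), more columns, then leftmost target
    start.
    """
    params = params or AlignParams()
    index = build_word_index(reduced_target, params.word_size)
    t_codes = encode(reduced_target)
    hits = _window_hits(reduced_read, reduced_target, t_codes, index, params)
    if freqs is None:
        counts = [reduced_target.count(b) for b in "ACGT"]
        total = max(1, sum(counts))
        freqs = tuple(c / total for c in counts)
    n = search_space if search_space is not None else len(reduced_target)
    best: tuple | None = None
    best_aln: LocalAlignment | None = None
    for h in hits:
        e = evalue(h.score, len(reduced_read), n, params, freqs)
        aln = LocalAlignment(
            read_id="", combo_id="", contig="",
            genome_start=h.t_start, genome_end=h.t_end,
            read_start=h.q_start, read_end=h.q_end,
            ops=h.ops, score=h.score, matches=h.matches,
            n_columns=h.n_columns,
            gaps_read=h.ops.count("D"), gaps_genome=h.ops.count("I"),
            evalue=e,
        )
        if not (e <= params.evalue_max and aln.identity >= params.identity_min
                and aln.n_columns >= params.length_min):
            continue
        key = (-aln.score, aln.evalue, -aln.n_columns, aln.genome_start)
        if best is None or key < best:
            best = key
            best_aln = aln
    return best_aln


def align_candidates(query: str, genome: Genome, t: Transformation | None,
                     params: AlignParams) -> list[LocalAlignment]:
    """All window-best alignments of ``query`` against every contig (no
    acceptance thresholds applied); used by the identity screen and the
    paralog filter.  The query must already be reduced consistently with
    ``t`` (or raw for untransformed searches)."""
    freqs = genome.background_freqs(t)
    n = genome.total_length
    out: list[LocalAlignment] = []
    reduced = genome.reduced(t)
    encoded = genome.encoded(t)
    indexes = genome.word_index(t, params.word_size)
    for contig, tseq in reduced.items():
        for h in _window_hits(query, tseq, encoded[contig], indexes[contig], params):
            e = evalue(h.score, len(query), n, params, freqs)
            out.append(
                LocalAlignment(
                    read_id="", combo_id="", contig=contig,
                    genome_start=h.t_start, genome_end=h.t_end,
                    read_start=h.q_start, read_end=h.q_end,
                    ops=h.ops, score=h.score, matches=h.matches,
                    n_columns=h.n_columns,
                    gaps_read=h.ops.count("D"), gaps_genome=h.ops.count("I"),
                    evalue=e,
                )
            )
    return out


def _orient_read_coords(aln: LocalAlignment, read_len: int, rc: bool) -> None:
    """Convert oriented-read coordinates to original-read orientation."""
    aln.oriented_rc = rc
    if rc:
        qs, qe = aln.read_start, aln.read_end
        aln.read_start, aln.read_end = read_len - qe, read_len - qs


def run_all_combos(read, genome: Genome, params: AlignParams | None = None,
                   combos=None) -> dict[str, LocalAlignment]:
    """Best accepted alignment per transformation/strand combination.

    Each combo is executed in +-genome orientation: the read is
    reverse-complemented when the combo requires it, reduced with the combo's
    effective transformation, and aligned against the correspondingly reduced
    + genome.  Reported coordinates are always on the + genome; read
    intervals are mapped back to the original read orientation.
    """
    from .transform import enumerate_combos

    params = params or AlignParams()
    combos = combos if combos is not None else enumerate_combos()
    results: dict[str, LocalAlignment] = {}
    rc_cache: dict[bool, str] = {}
    for combo in combos:
        rc = combo.oriented_rc
        if rc not in rc_cache:
            rc_cache[rc] = reverse_complement(read.seq) if rc else read.seq
        eff = combo.effective_transformation
        reduced_read = reduce_alphabet(rc_cache[rc], eff)
        freqs = genome.background_freqs(eff)
        best: LocalAlignment | None = None
        best_key = None
        for cand in align_candidates(reduced_read, genome, eff, params):
            if not (cand.evalue <= params.evalue_max
                    and cand.identity >= params.identity_min
                    and cand.n_columns >= params.length_min):
                continue
            key = (-cand.score, cand.evalue, -cand.n_columns, cand.contig, cand.genome_start)
            if best_key is None or key < best_key:
                best_key = key
                best = cand
        if best is not None:
            best.read_id = read.id
            best.combo_id = combo.combo_id
            _orient_read_coords(best, len(read.seq), rc)
            results[combo.combo_id] = best
    return results


# ---------------------------------------------------------------------------
# Independent oracle


def sw_oracle(query: str, target: str, params: AlignParams | None = None):
    """Exact full-matrix Smith–Waterman via Biopython's PairwiseAligner.

    Independent of the seed-and-extend path; intended for cross-checks on
    ACGT-only sequences up to a few kilobases.  Returns (score, alignment)
    where alignment is one optimal Bio.Align.Alignment (or None when the best
    local score is 0).
    """
    from Bio import Align

    params = params or AlignParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    score = int(aligner.score(query, target))
    if score <= 0:
        return 0, None
    return score, next(iter(aligner.align(query, target)))
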