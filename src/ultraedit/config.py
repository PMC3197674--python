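"""Pipeline configuration: every numeric threshold of the screen in one place.

Defaults follow the screen's published operating point: candidate reads must
be long (>250 bp) and compositionally sane; reduced-alphabet alignments are
accepted at E ≤ 1e-50, identity ≥ 95%, ≥ 100 columns; an ultra-edited call
needs ≥ 12 dominant-type mismatches forming > 90% of all mismatches and
covering ≥ 20% of the adenosines in the edited span (5–11 sites is the
hyper tier); cleanup limits alignment gaps to ≤ 5 overall and ≤ 3 per
sequence, mononucleotide runs to ≤ 36 bp and per-base frequencies to the
10%–60% band.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any


@dataclass
class PipelineConfig:
    # candidate prefilter
    min_len: int = 250              # candidates must be > min_len bases
    mono_max: float = 0.60          # fail if any single base > 60%
    mono_min: float = 0.10          # fail if any single base < 10%
    ambig_max: float = 0.10         # fail if non-ACGT fraction > 10%
    simple_max: float = 0.50        # fail if simple-repeat coverage > 50%
    identity_screen: float = 0.98   # drop reads aligning untransformed ...
    cover_screen: float = 0.90      # ... at >= 98% identity over >= 90% length

    # reduced aligner
    word_size: int = 12
    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = -4              # charged once per gap, on top of extend
    gap_extend: int = -2            # per gapped column
    evalue_max: float = 1e-50
    identity_min: float = 0.95
    length_min: int = 100           # alignment columns, gap columns included

    # editing caller
    min_sites_ultra: int = 12       # non-strict >=
    min_sites_hyper: int = 5        # non-strict >=, upper bound ultra-1
    purity_min: float = 0.9         # strict >
    rate_min: float = 0.2           # non-strict >=

    # artifact filters
    max_run: int = 36               # strict >, in either aligned subsequence
    nt_freq_min: float = 0.10
    nt_freq_max: float = 0.60
    max_gaps_total: int = 5
    max_gaps_each: int = 3
    paralog_cover: float = 0.90
    strand_support_count: int = 2

    # characterization
    cluster_gap: int = 300          # strict <, the Alu length

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)
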