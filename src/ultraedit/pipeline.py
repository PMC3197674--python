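"""End-to-end orchestration: prefilter → align → call → filter → characterize.

Execution is deterministic for fixed inputs and configuration; the manifest
records the configuration snapshot, input digests and the per-stage record
funnel so a run can be reproduced and audited.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .align import AlignParams, Genome, LocalAlignment, run_all_combos
from .calling import EditingCall, call_read
from .characterize import BedFeature, SiteCatalog, dedupe_and_regions
from .config import PipelineConfig
from .filters import FilterVerdict, TranscriptAnnotation, apply_filters
from .prefilter import PrefilterVerdict, SeqRecord, prefilter_record
from .transform import CANONICAL_TYPES, enumerate_combos

__all__ = ["PipelineResult", "ReadResult", "run_pipeline", "report_mismatch_type_table"]

logger = logging.getLogger("ultraedit")

VERSION = "0.1.0"


@dataclass
class ReadResult:
    read_id: str
    prefilter: PrefilterVerdict
    alignments: dict[str, LocalAlignment] = field(default_factory=dict)
    calls: list[EditingCall] = field(default_factory=list)
    filter_verdicts: dict[str, FilterVerdict] = field(default_factory=dict)
    final_call: EditingCall | None = None
    final_status: str = "none"


@dataclass
class PipelineResult:
    read_results: list[ReadResult]
    ultra_calls: list[EditingCall]     # kept, post-filter
    hyper_calls: list[EditingCall]     # kept, post-filter
    catalog: SiteCatalog               # from kept A-to-G ultra calls
    manifest: dict

    def call_report(self) -> pd.DataFrame:
        rows = []
        for rr in self.read_results:
            for call in rr.calls:
                verdict = rr.filter_verdicts.get(call.combo_id)
                rows.append(
                    {
                        "read_id": call.read_id,
                        "combo_id": call.combo_id,
                        "status": call.status,
                        "mismatch_type": call.mismatch_type or "",
                        "strand": call.strand or "",
                        "n_sites": call.n_dominant,
                        "purity": round(call.purity, 4),
                        "editing_rate": round(call.editing_rate, 4),
                        "contig": call.alignment.contig if call.alignment else "",
                        "genome_start": call.alignment.genome_start if call.alignment else -1,
                        "genome_end": call.alignment.genome_end if call.alignment else -1,
                        "kept": verdict.kept if verdict else "",
                        "failed_filters": ",".join(verdict.failed_filters) if verdict else "",
                    }
                )
        return pd.DataFrame(rows)

    def prefilter_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": rr.read_id,
                    "passed": rr.prefilter.passed,
                    "reasons": ",".join(rr.prefilter.reasons),
                }
                for rr in self.read_results
            ]
        )


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(reads: Sequence[SeqRecord], genome: Genome,
                 cfg: PipelineConfig | None = None,
                 repeats: Sequence[BedFeature] | None = None,
                 transcripts: Sequence[TranscriptAnnotation] | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run the whole screen on a read set against a genome.

    Stages: candidate prefilter (composition, simple repeats, untransformed
    genome-identity screen), the 12 reduced alignments per survivor, mismatch
    recovery and cluster calling, the five artifact filters on every ultra-
    or hyper-tier call, and catalog construction from the surviving A-to-G
    ultra calls.
    """
    cfg = cfg or PipelineConfig()
    params = AlignParams.from_config(cfg)
    combos = enumerate_combos()
    combos_by_id = {c.combo_id: c for c in combos}

    t0 = time.monotonic()
    read_results: list[ReadResult] = []
    for read in reads:
        verdict = prefilter_record(read, genome, cfg)
        read_results.append(ReadResult(read.id, verdict))
    n_pass = sum(1 for rr in read_results if rr.prefilter.passed)
    logger.info("stage=prefilter in=%d out=%d t=%.1fs", len(reads),
                n_pass, time.monotonic() - t0)

    t0 = time.monotonic()
    reads_by_id = {r.id: r for r in reads}
    n_aligned = 0
    n_alignments = 0
    for rr in read_results:
        if not rr.prefilter.passed:
            continue
        read = reads_by_id[rr.read_id]
        rr.alignments = run_all_combos(read, genome, params, combos)
        n_alignments += len(rr.alignments)
        if rr.alignments:
            n_aligned += 1
        rr.calls = call_read(read, rr.alignments, genome, combos_by_id, cfg)
    logger.info("stage=align in=%d out=%d alignments=%d t=%.1fs", n_pass,
                n_aligned, n_alignments, time.monotonic() - t0)

    t0 = time.monotonic()
    ultra_kept: list[EditingCall] = []
    hyper_kept: list[EditingCall] = []
    for rr in read_results:
        callable_calls = [c for c in rr.calls if c.status in ("ultra", "hyper")]
        for call in callable_calls:
            fv = apply_filters(reads_by_id[rr.read_id], call, rr.calls, genome,
                               transcripts, cfg)
            rr.filter_verdicts[call.combo_id] = fv
            if not fv.kept:
                continue
            if call.status == "ultra":
                ultra_kept.append(call)
            else:
                hyper_kept.append(call)
        surviving_ultra = [
            c for c in callable_calls
            if c.status == "ultra" and rr.filter_verdicts[c.combo_id].kept
        ]
        surviving_hyper = [
            c for c in callable_calls
            if c.status == "hyper" and rr.filter_verdicts[c.combo_id].kept
        ]
        if len(surviving_ultra) == 1:
            rr.final_call = surviving_ultra[0]
            rr.final_status = "ultra"
        elif not surviving_ultra and len(surviving_hyper) == 1:
            rr.final_call = surviving_hyper[0]
            rr.final_status = "hyper"
    logger.info("stage=filter ultra=%d hyper=%d t=%.1fs", len(ultra_kept),
                len(hyper_kept), time.monotonic() - t0)

    catalog = dedupe_and_regions(
        [c for c in ultra_kept if c.mismatch_type == "A-to-G"]
    )

    manifest = {
        "tool_version": VERSION,
        "seed": seed,
        "config": cfg.to_dict(),
        "input_digests": {
            "reads": _sha256("".join(f">{r.id}\n{r.seq}\n" for r in reads)),
            "genome": _sha256(
                "".join(f">{c}\n{s}\n" for c, s in sorted(genome.contigs.items()))
            ),
        },
        "counts": {
            "candidates_in": len(reads),
            "prefilter_passed": n_pass,
            "reads_aligned": n_aligned,
            "alignments_passing": n_alignments,
            "reads_ultra": sum(
                1 for rr in read_results if any(c.status == "ultra" for c in rr.calls)
            ),
            "reads_kept_ultra": sum(
                1 for rr in read_results if rr.final_status == "ultra"
            ),
            "reads_kept_hyper": sum(
                1 for rr in read_results if rr.final_status == "hyper"
            ),
            "sites_total": len(catalog.sites),
            "sites_unique": len(catalog.unique_sites),
            "regions": len(catalog.regions),
        },
    }
    funnel = manifest["counts"]
    assert funnel["prefilter_passed"] <= funnel["candidates_in"]
    assert funnel["reads_aligned"] <= funnel["prefilter_passed"]
    assert funnel["reads_ultra"] <= funnel["reads_aligned"]
    assert funnel["reads_kept_ultra"] <= funnel["reads_ultra"]
    return PipelineResult(read_results, ultra_kept, hyper_kept, catalog, manifest)


def report_mismatch_type_table(calls: Sequence[EditingCall]) -> pd.DataFrame:
    """Ultra-call counts per canonical mismatch type, broken by edited strand."""
    table = pd.DataFrame(0, index=list(CANONICAL_TYPES), columns=["+", "-"])
    for call in calls:
        if call.status != "ultra" or call.mismatch_type is None:
            continue
        table.loc[call.mismatch_type, call.strand] += 1
    return table
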