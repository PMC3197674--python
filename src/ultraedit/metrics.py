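"""Recovery metrics against simulator ground truth.

A simulated read counts as truly ultra-edited when its *planted* sites would
satisfy the calling criteria: at least the ultra site minimum, and a planted
editing rate (planted sites over edited-strand adenosines in the planted
span) at or above the rate threshold.  Sensitivity is measured over those
reads — a read whose stochastic editing draw fell below the definition is
not a detection target.
"""

from __future__ import annotations

from typing import Sequence

from .align import Genome
from .config import PipelineConfig
from .pipeline import PipelineResult
from .simulate import SyntheticTruth

__all__ = ["truth_is_ultra", "truth_site_keys", "evaluate_recovery"]


def truth_is_ultra(truth: SyntheticTruth, genome: Genome,
                   cfg: PipelineConfig | None = None) -> bool:
    cfg = cfg or PipelineConfig()
    if truth.kind != "edited" or len(truth.site_positions) < cfg.min_sites_ultra:
        return False
    lo, hi = min(truth.site_positions), max(truth.site_positions)
    span = genome.sequence(truth.contig, lo, hi + 1)
    src = "A" if truth.edited_strand == "+" else "T"
    n_src = span.count(src)
    return n_src > 0 and len(truth.site_positions) / n_src >= cfg.rate_min


def truth_site_keys(truths: Sequence[SyntheticTruth]) -> set[tuple[str, int, str]]:
    keys: set[tuple[str, int, str]] = set()
    for t in truths:
        for pos in t.site_positions:
            keys.add((t.contig, pos, t.edited_strand))
    return keys


def evaluate_recovery(result: PipelineResult, truths: Sequence[SyntheticTruth],
                      genome: Genome, cfg: PipelineConfig | None = None) -> dict:
    """Read-level sensitivity and site-level precision/recall vs truth."""
    cfg = cfg or PipelineConfig()
    truth_by_id = {t.read_id: t for t in truths}
    target_ids = {
        t.read_id for t in truths if truth_is_ultra(t, genome, cfg)
    }
    called_ultra_ids = {
        rr.read_id for rr in result.read_results if rr.final_status == "ultra"
    }
    tp_reads = target_ids & called_ultra_ids
    sensitivity = len(tp_reads) / len(target_ids) if target_ids else float("nan")

    planted = truth_site_keys(truths)
    called = {s.key for s in result.catalog.unique_sites}
    tp_sites = called & planted
    precision = len(tp_sites) / len(called) if called else float("nan")
    recall = len(tp_sites) / len(planted) if planted else float("nan")
    return {
        "n_reads": len(truths),
        "n_truth_ultra_reads": len(target_ids),
        "n_called_ultra_reads": len(called_ultra_ids),
        "read_sensitivity": sensitivity,
        "n_planted_sites": len(planted),
        "n_called_sites": len(called),
        "site_precision": precision,
        "site_recall": recall,
        "extra_called_read_ids": sorted(called_ultra_ids - set(truth_by_id) | set()),
    }
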