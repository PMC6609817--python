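"""Scaled simulation study: the self-contained benchmark the package uses
to demonstrate the caller end to end.

Simulates a diploid region at 30X with known mosaic truth, trains a
sample-specific forest on spike-ins disjoint from the truth sites, calls
variants in one or more model variants, and evaluates MAF-binned precision
and recall (with the support-aware denominator: a truth site the sequencer
covered with fewer than four alt reads cannot be recovered by a caller
that requires four discordant reads).
"""
from __future__ import annotations

import logging
import tempfile
from pathlib import Path
from typing import Optional, Sequence

from .calling import CallConfig, call_variants
from .evaluation import precision_recall
from .io_model import read_phased_vcf
from .phasing import HetIndex
from .pileup import RegionPileup
from .simdata import SimConfig, simulate_dataset
from .sitescan import ScanConfig
from .training import build_training_set, select_training_sites, train_model

log = logging.getLogger(__name__)


def load_pipeline_context(dataset: dict, scan_cfg: Optional[ScanConfig] = None) -> dict:
    """Read a simulated dataset back through the standard-format boundary
    (BAM + VCF) into a pipeline-ready pileup context."""
    scan_cfg = scan_cfg or ScanConfig()
    genome = dataset["genome"]
    cfg = dataset["config"]
    hets, germ = read_phased_vcf(dataset["vcf"])
    het_index = HetIndex(hets, chrom=cfg.chrom)
    pileup = RegionPileup.from_bam(
        dataset["bam"], het_index, genome.reference, cfg.chrom, 0,
        cfg.region_length, min_bq=scan_cfg.min_bq, min_mapq=scan_cfg.min_mapq)
    return {"genome": genome, "cfg": cfg, "pileup": pileup, "germ": germ,
            "scan_cfg": scan_cfg, "truth": genome.truth.mosaic,
            "support": genome.truth.support}


def run_benchmark(seed: int = 1, sim_cfg: Optional[SimConfig] = None,
                  modes: Sequence[str] = ("full", "short_only", "no_phasing"),
                  n_train: int = 200, min_support: int = 4,
                  work_dir=None) -> dict:
    """Simulate, train and call under each model variant; return metrics.

    ``n_train`` spike-in positives (and as many germline negatives) are
    drawn from sites at least 1 kb away from every evaluation truth site.
    """
    sim_cfg = sim_cfg or SimConfig(seed=seed)
    work_dir = Path(work_dir) if work_dir else Path(tempfile.mkdtemp(prefix="svlr_bench_"))
    dataset = simulate_dataset(sim_cfg, work_dir)
    ctx = load_pipeline_context(dataset)
    truth = ctx["truth"]
    support = ctx["support"]
    truth_pos = {m.pos for m in truth}
    out = {"n_truth": len(truth),
           "n_truth_supported": sum(1 for m in truth if support[m.pos] >= min_support),
           "modes": {}}
    for mode in modes:
        specs, negs = select_training_sites(
            ctx["pileup"], ctx["germ"], n_train, n_train,
            seed=(seed * 7919 + 11) % (2**31 - 1), scan_cfg=ctx["scan_cfg"],
            exclude_positions=truth_pos)
        ts = build_training_set(ctx["pileup"], specs, negs, mode=mode,
                                scan_cfg=ctx["scan_cfg"])
        art = train_model(ts, seed=(seed * 104729 + 3) % (2**31 - 1))
        calls, report = call_variants(ctx["pileup"], ctx["germ"], art,
                                      ctx["scan_cfg"], CallConfig(), mode=mode)
        passed = [c for c in calls if c.passes]
        ev_sup = precision_recall(passed, truth, support=support,
                                  min_support=min_support)
        ev_all = precision_recall(passed, truth, support=support)
        out["modes"][mode] = {
            "precision": ev_sup.precision,
            "recall_supported": ev_sup.recall,
            "recall_all": ev_all.recall,
            "f_supported": ev_sup.f_score,
            "n_pass": len(passed),
            "n_candidates": report["n_candidates"],
            "tp": ev_sup.tp, "fp": ev_sup.fp,
            "artifact": art,
            "calls": calls,
        }
        log.info("benchmark %s: precision %.3f recall %.3f (%d PASS)",
                 mode, ev_sup.precision, ev_sup.recall, len(passed))
    out["context"] = ctx
    return out
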