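"""Steps 4–6: score candidate sites, apply region and alignment-error
filters, and emit final mosaic SNV calls.

Every scored candidate is preserved in the output with its full filter
provenance; a call passes only when no filter failed.  The discordant-read
floor (default 4) is the main stringency knob: relaxing it boosts recall
at some cost in precision.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .features import extract_features
from .io_model import RegionMask, as_ref_array, write_calls_vcf
from .phasing import H1, H2, SiteObservation, UNASSIGNED
from .pileup import RegionPileup
from .sitescan import ScanConfig, scan_candidates
from .training import ModelArtifact

log = logging.getLogger(__name__)

FILTER_LOW_SCORE = "low_score"
FILTER_MIN_DISCORDANT = "min_discordant"
FILTER_ALIGNMENT = "alignment_error"


@dataclass(frozen=True)
class CallConfig:
    """Calling thresholds (steps 4-6)."""

    score_threshold: float = 0.5
    min_discordant: int = 4
    softclip_min_len: int = 5       # a soft-clip this long marks a clipped read
    max_softclip_frac: float = 0.5
    max_mean_mismatch: float = 3.0
    max_improper_frac: float = 0.5
    homopolymer_len: int = 10

    def __post_init__(self):
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in [0, 1]")
        if self.min_discordant < 0:
            raise ValueError("min_discordant must be >= 0")


@dataclass
class MosaicCall:
    """One scored candidate with filter provenance."""

    chrom: str
    pos: int
    ref_allele: str
    mosaic_allele: str
    score: float
    maf: float
    depth: int
    discordant_count: int
    haplotype: str                      # majority haplotype of candidate reads
    filters_failed: set = field(default_factory=set)

    @property
    def passes(self) -> bool:
        return not self.filters_failed

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be in [0, 1]")


def score_sites(model: ModelArtifact, sites: Sequence, mode: Optional[str] = None) -> np.ndarray:
    """Forest scores for a sequence of FeatureVectors (order preserved,
    pure).  Fatal on any feature-name or mode mismatch with the artifact."""
    mode = mode or model.mode
    if mode != model.mode:
        raise ValueError(f"model was trained in mode {model.mode!r}, asked to score {mode!r}")
    for v in sites:
        if tuple(v.names) != tuple(model.feature_names) or v.mode != model.mode:
            raise ValueError("feature vector does not match the model artifact "
                             f"(mode {v.mode!r}, names differ)")
    if not sites:
        return np.zeros(0)
    X = np.vstack([v.values for v in sites])
    return model.score(X)


def apply_region_filters(calls: Sequence[MosaicCall], masks: Sequence[RegionMask]) -> list:
    """Label calls overlapping each mask with that mask's failure label.
    No call is deleted — filter provenance is preserved."""
    for mask in masks:
        label = _mask_filter_label(mask.label)
        for c in calls:
            if mask.contains(c.chrom, c.pos):
                c.filters_failed.add(label)
    return list(calls)


def _mask_filter_label(label: str) -> str:
    norm = label.lower()
    if "repeat" in norm:
        return "region_repeat"
    if "cnv" in norm or "copy" in norm:
        return "region_cnv"
    return f"region_{norm}" if norm else "region_mask"


def homopolymer_run(ref_seq, pos: int, ref_offset: int = 0) -> int:
    """Length of the reference homopolymer run containing ``pos``."""
    arr = as_ref_array(ref_seq)
    j = pos - ref_offset
    if not (0 <= j < len(arr)):
        return 0
    b = arr[j]
    lo = j
    while lo > 0 and arr[lo - 1] == b:
        lo -= 1
    hi = j
    while hi + 1 < len(arr) and arr[hi + 1] == b:
        hi += 1
    return hi - lo + 1


def alignment_error_filter(obs: SiteObservation, ref_seq, ref_offset: int = 0,
                           cfg: Optional[CallConfig] = None):
    """Heuristic filter against alignment-error false positives.

    Fails when candidate reads look misaligned: mostly soft-clipped (a),
    mismatch-laden (b), improperly paired (c), or when the site sits in a
    long reference homopolymer (d).  Returns (passed, diagnostics)."""
    cfg = cfg or CallConfig()
    cand = [r for r in obs.records if r.base == obs.candidate_allele]
    diag: dict = {}
    if cand:
        diag["softclip_frac"] = float(np.mean([r.softclip >= cfg.softclip_min_len for r in cand]))
        diag["mean_mismatch"] = float(np.mean([r.n_mismatch for r in cand]))
        diag["improper_frac"] = float(np.mean([not r.is_proper_pair for r in cand]))
    else:
        diag["softclip_frac"] = diag["mean_mismatch"] = diag["improper_frac"] = 0.0
    diag["homopolymer_run"] = homopolymer_run(ref_seq, obs.pos, ref_offset)
    failed = (diag["softclip_frac"] > cfg.max_softclip_frac
              or diag["mean_mismatch"] > cfg.max_mean_mismatch
              or diag["improper_frac"] > cfg.max_improper_frac
              or diag["homopolymer_run"] >= cfg.homopolymer_len)
    return (not failed), diag


def read_calls_vcf(path) -> list:
    """Read a calls VCF written by ``write_calls_vcf`` back into
    MosaicCall objects (positions back to 0-based)."""
    import pysam
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = set(rec.filter.keys()) - {"PASS"}
            calls.append(MosaicCall(
                chrom=rec.chrom, pos=rec.pos - 1, ref_allele=rec.ref,
                mosaic_allele=rec.alts[0],
                score=float(rec.info["SCORE"]), maf=float(rec.info["MAF"]),
                depth=int(rec.info["DP"]), discordant_count=int(rec.info["DISC"]),
                haplotype=str(rec.info["HAP"]), filters_failed=filters))
    return calls


def _majority_haplotype(obs: SiteObservation) -> str:
    h1 = obs.counts_by_haplotype.get(H1, {}).get(obs.candidate_allele, 0)
    h2 = obs.counts_by_haplotype.get(H2, {}).get(obs.candidate_allele, 0)
    if h1 == h2 == 0:
        return UNASSIGNED
    return H1 if h1 >= h2 else H2


def call_variants(pileup: RegionPileup, germline_sites: Iterable,
                  model: ModelArtifact, scan_cfg: Optional[ScanConfig] = None,
                  call_cfg: Optional[CallConfig] = None,
                  masks: Sequence[RegionMask] = (), mode: Optional[str] = None,
                  vcf_path=None, sample_name: str = "SAMPLE"):
    """End-to-end calling on one region: scan -> features -> score ->
    discordant filter -> region filters -> alignment filter.

    Returns (calls, report).  Every scored candidate appears exactly once,
    with an empty ``filters_failed`` iff it is a PASS call.  The
    min-discordant filter is waived in no_phasing mode, where the
    discordant count is identically zero.
    """
    scan_cfg = scan_cfg or ScanConfig()
    call_cfg = call_cfg or CallConfig()
    mode = mode or model.mode
    if mode != model.mode:
        raise ValueError(f"model artifact is for mode {model.mode!r}, not {mode!r}")

    cands = scan_candidates(pileup, germline_sites, scan_cfg, mode=mode)
    report = {"mode": mode, "n_candidates": len(cands)}
    vectors = [extract_features(obs, mode) for _, obs in cands]
    scores = score_sites(model, vectors)

    calls: list = []
    for (pos, obs), score in zip(cands, scores):
        call = MosaicCall(
            chrom=obs.chrom or pileup.chrom, pos=pos, ref_allele=obs.ref_allele,
            mosaic_allele=obs.candidate_allele, score=float(score), maf=obs.maf,
            depth=obs.depth, discordant_count=len(obs.discordant_reads),
            haplotype=_majority_haplotype(obs))
        if score < call_cfg.score_threshold:
            call.filters_failed.add(FILTER_LOW_SCORE)
        if mode != "no_phasing" and call.discordant_count < call_cfg.min_discordant:
            call.filters_failed.add(FILTER_MIN_DISCORDANT)
        ok, _ = alignment_error_filter(obs, pileup.ref_arr, pileup.start, call_cfg)
        if not ok:
            call.filters_failed.add(FILTER_ALIGNMENT)
        calls.append(call)
    apply_region_filters(calls, masks)
    calls.sort(key=lambda c: (c.chrom, c.pos))

    report["n_scored"] = len(calls)
    report["n_pass"] = sum(1 for c in calls if c.passes)
    for f in (FILTER_LOW_SCORE, FILTER_MIN_DISCORDANT, FILTER_ALIGNMENT,
              "region_repeat", "region_cnv"):
        report[f"n_fail_{f}"] = sum(1 for c in calls if f in c.filters_failed)
    log.info("call_variants: %(n_candidates)d candidates -> %(n_pass)d PASS", report)
    if vcf_path is not None:
        write_calls_vcf(calls, vcf_path, sample_name=sample_name,
                        contigs={pileup.chrom: pileup.end})
    return calls, report
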