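"""Benchmark machinery: MAF-binned precision/recall, region-stratified
metrics, support-aware recall denominators, and orthogonal deep-sequencing
validation.

Precision is the fraction of calls that are truth sites; recall the
fraction of truth sites called.  Because a caller that requires at least
four supporting reads cannot possibly recover a site the sequencer gave
three alt reads, recall is also reported against the denominator of truth
sites with at least ``min_support`` observed alt reads; both denominators
are available side by side.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DEFAULT_MAF_BINS = tuple(np.round(np.arange(0.0, 0.501, 0.05), 2))


@dataclass(frozen=True)
class BinResult:
    lo: float
    hi: float               # bin is (lo, hi]
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


@dataclass
class EvalResult:
    precision: float
    recall: float
    f_score: float
    tp: int
    fp: int
    fn: int
    bins: list = field(default_factory=list)     # list[BinResult]
    bin_edges: tuple = ()
    denominator_rule: str = "all_truth"

    def to_dict(self) -> dict:
        d = {"precision": self.precision, "recall": self.recall, "f": self.f_score,
             "tp": self.tp, "fp": self.fp, "fn": self.fn,
             "denominator": self.denominator_rule}
        d["bins"] = [vars(b) for b in self.bins]
        return d


def _prf(tp: int, fp: int, fn: int):
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def precision_recall(calls: Sequence, truth: Sequence, maf_bins: Optional[Sequence] = None,
                     min_support: Optional[int] = None,
                     support: Optional[dict] = None) -> EvalResult:
    """Precision/recall of a call set against mosaic truth.

    A true positive matches a truth site at exact position and allele.
    ``truth`` items need pos/alt_allele/maf; observed alt-read support
    comes from ``support`` (pos -> count) or a ``support`` attribute.
    When ``min_support`` is given, the recall denominator is restricted to
    truth sites with at least that many observed alt reads.  Bins are
    right-closed intervals over truth (recall) and call (precision) MAF.
    """
    edges = tuple(maf_bins) if maf_bins is not None else DEFAULT_MAF_BINS
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("MAF bin edges must be strictly increasing")

    def site_support(t):
        if support is not None:
            return support.get(t.pos, 0)
        return getattr(t, "support", 0)

    truth_all = list(truth)
    if min_support is not None:
        truth_eval = [t for t in truth_all if site_support(t) >= min_support]
        rule = f"support>={min_support}"
    else:
        truth_eval = truth_all
        rule = "all_truth"
    truth_keys = {(t.chrom, t.pos, t.alt_allele) for t in truth_all}
    eval_keys = {(t.chrom, t.pos, t.alt_allele) for t in truth_eval}

    seen = set()
    tp_calls, fp_calls = [], []
    for c in calls:
        key = (c.chrom, c.pos, c.mosaic_allele)
        if key in seen:
            continue
        seen.add(key)
        (tp_calls if key in truth_keys else fp_calls).append(c)
    hit_keys = {(c.chrom, c.pos, c.mosaic_allele) for c in tp_calls}
    fn_sites = [t for t in truth_eval if (t.chrom, t.pos, t.alt_allele) not in hit_keys]
    tp_eval = sum(1 for k in hit_keys if k in eval_keys)

    tp, fp, fn = len(tp_calls), len(fp_calls), len(fn_sites)
    # precision over all unique calls; recall over the chosen denominator
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp_eval / len(truth_eval) if truth_eval else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0

    bins = []
    truth_by_key = {(t.chrom, t.pos, t.alt_allele): t for t in truth_all}
    for lo, hi in zip(edges, edges[1:]):
        def in_bin(m):
            return lo < m <= hi
        btp = sum(1 for c in tp_calls
                  if in_bin(truth_by_key[(c.chrom, c.pos, c.mosaic_allele)].maf))
        bfp = sum(1 for c in fp_calls if in_bin(c.maf))
        bfn = sum(1 for t in fn_sites if in_bin(t.maf))
        bp, br, bf = _prf(btp, bfp, bfn)
        bins.append(BinResult(lo, hi, btp, bfp, bfn, bp, br, bf))
    return EvalResult(precision=p, recall=r, f_score=f, tp=tp, fp=fp, fn=fn,
                      bins=bins, bin_edges=edges, denominator_rule=rule)


def stratify_by_region(calls: Sequence, truth: Sequence, masks: Sequence,
                       maf_bins: Optional[Sequence] = None,
                       min_support: Optional[int] = None,
                       support: Optional[dict] = None) -> dict:
    """Per-mask metrics: evaluation restricted to calls and truth sites
    inside each mask's intervals."""
    out = {}
    for mask in masks:
        sub_calls = [c for c in calls if mask.contains(c.chrom, c.pos)]
        sub_truth = [t for t in truth if mask.contains(t.chrom, t.pos)]
        out[mask.label] = precision_recall(sub_calls, sub_truth, maf_bins,
                                           min_support, support)
    return out


VALIDATED, UNVALIDATED, UNEVALUABLE = "validated", "unvalidated", "unevaluable"


def wes_validate(calls: Sequence, deep_pileups: dict,
                 germline_a: Sequence = (), germline_b: Sequence = (),
                 min_depth: int = 50, min_alt: int = 4) -> dict:
    """Validate calls against independent deep coverage (e.g. WES).

    A call is *validated* iff its deep pileup has >= ``min_depth`` aligned
    reads AND >= ``min_alt`` reads supporting the mosaic allele AND the
    site is not a germline variant call in either provided germline call
    set.  Depth below ``min_depth`` (or a missing pileup) makes the call
    *unevaluable*.  Returns {(chrom, pos): status} plus a summary under
    the "summary" key (validation rate over evaluable calls).
    """
    germ_keys = {(g.chrom, g.pos) for g in germline_a
                 if g.genotype_class != "hom_ref"}
    germ_keys |= {(g.chrom, g.pos) for g in germline_b
                  if g.genotype_class != "hom_ref"}
    statuses: dict = {}
    for c in calls:
        key = (c.chrom, c.pos)
        if key in statuses:
            continue
        dp = deep_pileups.get(c.pos)
        if dp is None or dp.depth < min_depth:
            statuses[key] = UNEVALUABLE
        elif dp.alt_count >= min_alt and key not in germ_keys:
            statuses[key] = VALIDATED
        else:
            statuses[key] = UNVALIDATED
    n_val = sum(1 for s in statuses.values() if s == VALIDATED)
    n_unval = sum(1 for s in statuses.values() if s == UNVALIDATED)
    evaluable = n_val + n_unval
    return {"statuses": statuses,
            "summary": {"validated": n_val, "unvalidated": n_unval,
                        "unevaluable": sum(1 for s in statuses.values() if s == UNEVALUABLE),
                        "validation_rate": n_val / evaluable if evaluable else 0.0}}
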