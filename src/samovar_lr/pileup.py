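"""In-memory pileup engine for one genomic region.

Loads every read of a region once, reconstructs fragments, assigns
haplotypes, and answers two kinds of queries:

* a fast vectorized sweep that finds positions carrying enough non-reference
  bases to be worth a full look (a superset prefilter for site scanning);
* exact per-site observations (``phasing.site_phase_summary``) which are
  always the authority on counts.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional

import numpy as np

from .io_model import AlignedRead, DNA, as_ref_array, read_alignments
from .phasing import (DEFAULT_MAX_GAP, DEFAULT_MIN_BQ, HetIndex, SiteObservation,
                      assign_haplotype, group_fragments, site_phase_summary)


class RegionPileup:
    """All evidence for one half-open region of one chromosome."""

    def __init__(self, reads: Iterable[AlignedRead], het_index: HetIndex,
                 ref_seq: str, chrom: str, start: int = 0, end: Optional[int] = None,
                 min_bq: int = DEFAULT_MIN_BQ, min_mapq: int = 0,
                 max_gap: int = DEFAULT_MAX_GAP):
        self.chrom = chrom
        self.start = start
        self.end = end if end is not None else start + len(ref_seq)
        self.ref_seq = ref_seq
        self.ref_arr = as_ref_array(ref_seq)
        self.het_index = het_index
        self.min_bq = min_bq
        self.min_mapq = min_mapq
        self.reads = sorted(reads, key=lambda r: r.start)
        self.fragments = group_fragments(self.reads, max_gap=max_gap)
        for frag in self.fragments:
            assign_haplotype(frag, het_index, min_bq=min_bq)
        self.pair_lookup: dict = defaultdict(list)
        for r in self.reads:
            self.pair_lookup[r.pair_id].append(r)
        self._starts = np.array([r.start for r in self.reads], dtype=np.int64)
        self._max_span = max((r.end - r.start for r in self.reads), default=0)

    @classmethod
    def from_bam(cls, bam_path, het_index: HetIndex, ref_seq: str, chrom: str,
                 start: int = 0, end: Optional[int] = None, **kw) -> "RegionPileup":
        end_ = end if end is not None else start + len(ref_seq)
        reads = list(read_alignments(bam_path, (chrom, start, end_)))
        return cls(reads, het_index, ref_seq, chrom, start, end_, **kw)

    # ------------------------------------------------------------------
    def reads_at(self, pos: int) -> list:
        """Reads whose alignment span covers ``pos`` (CIGAR not yet walked)."""
        lo = int(np.searchsorted(self._starts, pos - self._max_span, side="left"))
        hi = int(np.searchsorted(self._starts, pos, side="right"))
        return [r for r in self.reads[lo:hi] if r.start <= pos < r.end]

    def observation(self, pos: int, candidate_allele: Optional[str] = None,
                    mode: str = "full", read_override: Optional[list] = None) -> SiteObservation:
        """Exact site summary at ``pos``.  ``read_override`` substitutes the
        site's reads (used by spike-in editing)."""
        reads = read_override if read_override is not None else self.reads_at(pos)
        return site_phase_summary(
            pos, reads, self.het_index, self.ref_arr, ref_offset=self.start,
            candidate_allele=candidate_allele, mode=mode,
            min_bq=self.min_bq, min_mapq=self.min_mapq,
            pair_lookup=self.pair_lookup)

    # ------------------------------------------------------------------
    def base_counts(self):
        """Vectorized depth and per-base allele counts over the region.

        Counts only reads that count in the pileup (no duplicates/secondary/
        supplementary, mapq >= min_mapq) and bases with quality >= min_bq —
        the same rules the exact per-site summary applies.
        Returns (depth, {base: counts}) as int32 arrays of region length.
        """
        n = self.end - self.start
        depth = np.zeros(n, dtype=np.int32)
        mm_pos: list = []
        mm_base: list = []
        for read in self.reads:
            if not read.counts_in_pileup or read.mapq < self.min_mapq:
                continue
            qarr = np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8)
            for r, q, l in read.aligned_blocks():
                lo = max(r, self.start)
                hi = min(r + l, self.end)
                if hi <= lo:
                    continue
                qs = q + (lo - r)
                quals = read.base_quals[qs:qs + (hi - lo)]
                ok = quals >= self.min_bq
                a, b = lo - self.start, hi - self.start
                if ok.all():
                    depth[a:b] += 1
                else:
                    seg = depth[a:b]
                    seg[ok] += 1
                bseg = qarr[qs:qs + (hi - lo)]
                mism = (bseg != self.ref_arr[a:b]) & ok
                if mism.any():
                    idx = np.nonzero(mism)[0]
                    mm_pos.append(idx + a)
                    mm_base.append(bseg[idx])
        counts = {}
        if mm_pos:
            all_pos = np.concatenate(mm_pos)
            all_base = np.concatenate(mm_base)
            for base in DNA:
                sel = all_pos[all_base == ord(base)]
                counts[base] = np.bincount(sel, minlength=n).astype(np.int32)
        else:
            for base in DNA:
                counts[base] = np.zeros(n, dtype=np.int32)
        return depth, counts

    def candidate_positions(self, min_depth: int, min_candidate_reads: int,
                            min_maf: float, max_maf: float) -> list:
        """Positions (with their preliminary candidate allele) where some
        non-reference base clears the raw count/MAF/depth thresholds.

        A sweep-level prefilter: every position passing the exact site
        filter also passes this (same counting rules, thresholds applied
        with >=/<=), but the exact observation remains the authority.
        """
        depth, counts = self.base_counts()
        best_count = np.zeros_like(depth)
        best_base = np.zeros(depth.shape, dtype=np.uint8)
        # alphabetical iteration + strict > keeps the alphabetical tie-break
        for base in DNA:
            c = counts[base]
            nonref = self.ref_arr != ord(base)
            better = nonref & (c > best_count)
            best_count[better] = c[better]
            best_base[better] = ord(base)
        with np.errstate(divide="ignore", invalid="ignore"):
            maf = np.where(depth > 0, best_count / np.maximum(depth, 1), 0.0)
        hit = (depth >= min_depth) & (best_count >= min_candidate_reads) \
            & (maf >= min_maf) & (maf <= max_maf)
        idx = np.nonzero(hit)[0]
        return [(int(i) + self.start, chr(best_base[i])) for i in idx]
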