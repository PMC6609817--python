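"""Barcode-defined fragment reconstruction, haplotype assignment and
per-site haplotype evidence.

A *fragment* is the long DNA molecule underlying a linked read, recovered by
grouping reads that share a barcode (split when consecutive reads are
separated by more than ``max_gap``).  A fragment is assigned to haplotype H1
or H2 by majority vote over the phased heterozygous variants its reads
cover.  Reads carrying the candidate mosaic allele while sitting on an
assigned haplotype are *haplotype-discordant reads* — the core mosaic
evidence: a true mosaic variant concentrates them on one haplotype, whereas
sequencing error spreads them evenly across both.

H1/H2 labels are only comparable within one phase set, so votes are kept
per phase set and, at a candidate site, only the votes from the phase set
local to that site count.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .io_model import AlignedRead, PhasedHet, DNA, as_ref_array

H1, H2, UNASSIGNED = "H1", "H2", "unassigned"

DEFAULT_MAX_GAP = 50_000
DEFAULT_MIN_BQ = 20


class HetIndex:
    """Position-indexed phased heterozygous SNVs for one chromosome."""

    def __init__(self, hets: Iterable[PhasedHet], chrom: Optional[str] = None):
        hets = [h for h in hets if chrom is None or h.chrom == chrom]
        hets.sort(key=lambda h: h.pos)
        self.hets = hets
        self.pos = np.array([h.pos for h in hets], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.hets)

    def overlapping(self, start: int, end: int) -> list:
        """Hets with pos in [start, end)."""
        i = int(np.searchsorted(self.pos, start, side="left"))
        j = int(np.searchsorted(self.pos, end, side="left"))
        return self.hets[i:j]

    def phase_set_at(self, pos: int) -> Optional[int]:
        """Phase set of the het nearest to ``pos`` (None when there are no
        hets).  A non-het site inherits the phase set local to it."""
        if len(self.hets) == 0:
            return None
        i = int(np.searchsorted(self.pos, pos))
        if i == 0:
            return self.hets[0].phase_set
        if i == len(self.hets):
            return self.hets[-1].phase_set
        before, after = self.hets[i - 1], self.hets[i]
        return before.phase_set if pos - before.pos <= after.pos - pos else after.phase_set


@dataclass(slots=True)
class Fragment:
    """Barcode-defined group of reads from one long molecule."""

    barcode: Optional[str]
    chrom: str
    reads: list
    frag_id: int = -1
    haplotype: str = UNASSIGNED
    votes_h1: int = 0
    votes_h2: int = 0
    votes_by_ps: dict = field(default_factory=dict)  # phase_set -> [v1, v2]

    @property
    def span(self):
        return (min(r.start for r in self.reads), max(r.end for r in self.reads))

    def haplotype_at(self, phase_set: Optional[int]) -> str:
        """Haplotype by strict majority of votes within one phase set;
        cross-phase-set votes are discarded (H1/H2 labels are only
        meaningful within a phase set)."""
        if phase_set is None or phase_set not in self.votes_by_ps:
            return UNASSIGNED
        v1, v2 = self.votes_by_ps[phase_set]
        if v1 > v2:
            return H1
        if v2 > v1:
            return H2
        return UNASSIGNED


def group_fragments(reads: Iterable[AlignedRead], max_gap: int = DEFAULT_MAX_GAP) -> list:
    """Group position-sorted reads of one chromosome into fragments by
    barcode, splitting a barcode into several fragments when consecutive
    reads are separated by more than ``max_gap``.  Barcode-less reads become
    singleton fragments.  Sets ``read.fragment`` on every read."""
    frags: list = []
    open_frags: dict = {}  # barcode -> Fragment (the currently extendable one)
    for read in reads:
        bc = read.barcode
        if bc is None:
            frag = Fragment(barcode=None, chrom=read.chrom, reads=[read])
            read.fragment = frag
            frags.append(frag)
            continue
        frag = open_frags.get(bc)
        if frag is not None and read.start - frag.reads[-1].start <= max_gap \
                and frag.chrom == read.chrom:
            frag.reads.append(read)
        else:
            frag = Fragment(barcode=bc, chrom=read.chrom, reads=[read])
            frags.append(frag)
            open_frags[bc] = frag
        read.fragment = frag
    for i, f in enumerate(frags):
        f.frag_id = i
    return frags


def _votes_from_reads(reads, het_index: HetIndex, min_bq: int) -> dict:
    """Per-phase-set [h1, h2] vote counts from the phased hets covered by
    ``reads``.  A het seen by both mates counts once (higher base quality
    wins); bases matching neither phased allele cast no vote."""
    best: dict = {}  # het pos -> (qual, base, het)
    for read in reads:
        span_hets = het_index.overlapping(read.start, read.end)
        for het in span_hets:
            hit = read.base_at(het.pos)
            if hit is None:
                continue
            base, qual, _ = hit
            if qual < min_bq:
                continue
            prev = best.get(het.pos)
            if prev is None or qual > prev[0]:
                best[het.pos] = (qual, base, het)
    votes: dict = {}
    for qual, base, het in best.values():
        v = votes.setdefault(het.phase_set, [0, 0])
        if base == het.h1_allele:
            v[0] += 1
        elif base == het.h2_allele:
            v[1] += 1
    return votes


def assign_haplotype(fragment: Fragment, het_index: HetIndex,
                     min_bq: int = DEFAULT_MIN_BQ) -> Fragment:
    """Assign a fragment to H1/H2 by strict majority vote over the phased
    hets its reads cover (tie or no votes -> unassigned).  Votes are also
    recorded per phase set for site-local queries."""
    votes = _votes_from_reads(fragment.reads, het_index, min_bq)
    fragment.votes_by_ps = {ps: tuple(v) for ps, v in votes.items()}
    fragment.votes_h1 = sum(v[0] for v in votes.values())
    fragment.votes_h2 = sum(v[1] for v in votes.values())
    if fragment.votes_h1 > fragment.votes_h2:
        fragment.haplotype = H1
    elif fragment.votes_h2 > fragment.votes_h1:
        fragment.haplotype = H2
    else:
        fragment.haplotype = UNASSIGNED
    return fragment


@dataclass(slots=True)
class ReadAtSite:
    """Per-read evidence extracted at one site (feature/filter input)."""

    read: AlignedRead
    base: str
    qual: int
    mapq: int
    is_reverse: bool
    is_proper_pair: bool
    norm_pos: float          # query offset / read length, in [0, 1)
    softclip: int            # longest soft-clip on the read, bp
    n_mismatch: int          # aligned mismatches vs reference, site excluded
    haplotype: str           # site-local assignment (phase-set restricted)
    frag_id: int
    frag_votes: int          # fragment votes in the site's phase set


@dataclass(slots=True)
class SiteObservation:
    """Per-site pileup summary with per-haplotype allele counts."""

    chrom: str
    pos: int
    ref_allele: str
    allele_counts: dict
    depth: int
    candidate_allele: Optional[str]
    maf: float
    counts_by_haplotype: dict      # hap -> {base: count}
    discordant_reads: list
    phased_fraction: float
    records: list                  # list[ReadAtSite]
    mode: str = "full"


def site_phase_summary(pos: int, reads: Iterable[AlignedRead], het_index: HetIndex,
                       ref_seq: str, ref_offset: int = 0,
                       candidate_allele: Optional[str] = None, mode: str = "full",
                       min_bq: int = DEFAULT_MIN_BQ, min_mapq: int = 0,
                       pair_lookup: Optional[dict] = None) -> SiteObservation:
    """Summarize the pileup at ``pos`` with per-haplotype allele counts.

    ``mode`` controls how much phasing information is used:

    - ``full``: a read inherits its long fragment's haplotype (phase-set
      restricted vote majority).
    - ``short_only``: the fragment is redefined as the read pair; a read is
      assigned only via hets overlapped by its own pair's reads.
    - ``no_phasing``: every read is unassigned; discordant_reads is empty.

    Reads not covering ``pos`` after the CIGAR walk, duplicates, secondary/
    supplementary alignments, low-mapq reads and bases below ``min_bq`` are
    excluded from all counts.
    """
    if mode not in ("full", "short_only", "no_phasing"):
        raise ValueError(f"unknown mode {mode!r}")
    site_ps = het_index.phase_set_at(pos)
    ref_arr = as_ref_array(ref_seq)
    j = pos - ref_offset
    ref_base = chr(ref_arr[j]) if 0 <= j < len(ref_arr) else "N"
    records: list = []
    chrom = None
    for read in reads:
        chrom = chrom or read.chrom
        if not read.counts_in_pileup or read.mapq < min_mapq:
            continue
        hit = read.base_at(pos)
        if hit is None:
            continue
        base, qual, off = hit
        if qual < min_bq or base not in DNA:
            continue
        if mode == "no_phasing":
            hap, votes = UNASSIGNED, 0
        elif mode == "short_only":
            if pair_lookup is not None:
                pair_reads = pair_lookup.get(read.pair_id, [read])
            else:
                pair_reads = [read]
            v = _votes_from_reads(pair_reads, het_index, min_bq).get(site_ps, (0, 0))
            votes = v[0] + v[1]
            hap = H1 if v[0] > v[1] else H2 if v[1] > v[0] else UNASSIGNED
        else:
            frag = read.fragment
            if frag is None:
                hap, votes = UNASSIGNED, 0
            else:
                hap = frag.haplotype_at(site_ps)
                v = frag.votes_by_ps.get(site_ps, (0, 0))
                votes = v[0] + v[1]
        records.append(ReadAtSite(
            read=read, base=base, qual=qual, mapq=read.mapq,
            is_reverse=read.is_reverse, is_proper_pair=read.is_proper_pair,
            norm_pos=off / max(len(read.bases), 1),
            softclip=read.softclip_len(),
            n_mismatch=read.mismatch_count(ref_arr, ref_offset, exclude_pos=pos),
            haplotype=hap,
            frag_id=read.fragment.frag_id if read.fragment is not None else -1,
            frag_votes=votes))

    allele_counts = Counter(r.base for r in records)
    depth = len(records)
    if candidate_allele is None:
        nonref = sorted((b for b in allele_counts if b != ref_base),
                        key=lambda b: (-allele_counts[b], b))
        candidate_allele = nonref[0] if nonref else None
    maf = allele_counts.get(candidate_allele, 0) / depth if depth > 0 and candidate_allele else 0.0
    counts_by_haplotype: dict = {H1: Counter(), H2: Counter(), UNASSIGNED: Counter()}
    for r in records:
        counts_by_haplotype[r.haplotype][r.base] += 1
    discordant = [r.read for r in records
                  if r.base == candidate_allele and r.haplotype in (H1, H2)]
    n_assigned = sum(1 for r in records if r.haplotype in (H1, H2))
    return SiteObservation(
        chrom=chrom or "", pos=pos, ref_allele=ref_base,
        allele_counts=dict(allele_counts), depth=depth,
        candidate_allele=candidate_allele, maf=maf,
        counts_by_haplotype={h: dict(c) for h, c in counts_by_haplotype.items()},
        discordant_reads=discordant,
        phased_fraction=n_assigned / depth if depth > 0 else 0.0,
        records=records, mode=mode)
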