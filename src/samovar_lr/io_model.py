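"""Readers/writers for the standard formats the pipeline touches and the
internal data model every other module operates on.

All internal coordinates are 0-based half-open.  Conversion to/from the
1-based conventions of VCF happens only at the file boundary, inside the
functions of this module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pysam

log = logging.getLogger(__name__)

# CIGAR operation codes (SAM spec order, as used by pysam)
CIGAR_M, CIGAR_I, CIGAR_D, CIGAR_N, CIGAR_S, CIGAR_H, CIGAR_P, CIGAR_EQ, CIGAR_X = range(9)
_QUERY_OPS = frozenset((CIGAR_M, CIGAR_I, CIGAR_S, CIGAR_EQ, CIGAR_X))
_REF_OPS = frozenset((CIGAR_M, CIGAR_D, CIGAR_N, CIGAR_EQ, CIGAR_X))
_ALIGN_OPS = frozenset((CIGAR_M, CIGAR_EQ, CIGAR_X))

DNA = "ACGT"


def as_ref_array(ref_seq) -> np.ndarray:
    """Reference sequence as a uint8 byte array (cached form used by the
    hot pileup paths; accepts str or an already-converted array)."""
    if isinstance(ref_seq, np.ndarray):
        return ref_seq
    return np.frombuffer(ref_seq.encode("ascii"), dtype=np.uint8)


@dataclass(slots=True)
class AlignedRead:
    """One aligned short read with barcode — the atomic evidence unit."""

    read_name: str
    chrom: str
    start: int                      # 0-based leftmost aligned reference position
    cigar: list                     # list of (op, length)
    bases: str
    base_quals: np.ndarray          # uint8 Phred scores, one per base
    mapq: int
    is_reverse: bool = False
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_proper_pair: bool = True
    mate_start: Optional[int] = None
    barcode: Optional[str] = None
    pair_id: Optional[str] = None
    fragment: object = None         # set by phasing.group_fragments

    def __post_init__(self) -> None:
        if not isinstance(self.base_quals, np.ndarray):
            self.base_quals = np.asarray(self.base_quals, dtype=np.uint8)
        if self.pair_id is None:
            self.pair_id = self.read_name

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if len(self.bases) != len(self.base_quals):
            raise ValueError("bases and base_quals length mismatch")
        qlen = sum(l for op, l in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.bases):
            raise ValueError("CIGAR query length does not match bases")
        if self.start < 0:
            raise ValueError("negative start")
        if not (0 <= self.mapq <= 60):
            raise ValueError("mapq out of [0, 60]")

    # -- geometry ---------------------------------------------------------
    @property
    def end(self) -> int:
        """Reference end (half-open)."""
        return self.start + sum(l for op, l in self.cigar if op in _REF_OPS)

    @property
    def counts_in_pileup(self) -> bool:
        """Duplicate/secondary/supplementary reads are kept in the model but
        excluded from depth and allele counts."""
        return not (self.is_duplicate or self.is_secondary or self.is_supplementary)

    def aligned_blocks(self) -> list:
        """(ref_start, query_start, length) for each aligned (M/=/X) block."""
        out = []
        r, q = self.start, 0
        for op, l in self.cigar:
            if op in _ALIGN_OPS:
                out.append((r, q, l))
            if op in _REF_OPS:
                r += l
            if op in _QUERY_OPS:
                q += l
        return out

    def base_at(self, pos: int):
        """(base, qual, query_offset) at reference position ``pos``, or None
        if the read does not align a base there (deletion, clip, outside)."""
        for r, q, l in self.aligned_blocks():
            if r <= pos < r + l:
                off = q + (pos - r)
                return self.bases[off], int(self.base_quals[off]), off
        return None

    def softclip_len(self) -> int:
        """Length of the longest soft-clip on this read (0 if none)."""
        return max((l for op, l in self.cigar if op == CIGAR_S), default=0)

    def mismatch_count(self, ref_seq: str, ref_offset: int, exclude_pos: Optional[int] = None) -> int:
        """Number of aligned bases differing from the reference, optionally
        excluding one reference position (the candidate site)."""
        n = 0
        qarr = np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)
        rarr = as_ref_array(ref_seq)
        for r, q, l in self.aligned_blocks():
            lo = max(r, ref_offset)
            hi = min(r + l, ref_offset + len(rarr))
            if hi <= lo:
                continue
            qs = q + (lo - r)
            mism = qarr[qs:qs + (hi - lo)] != rarr[lo - ref_offset:hi - ref_offset]
            n += int(mism.sum())
            if exclude_pos is not None and lo <= exclude_pos < hi \
                    and mism[exclude_pos - lo]:
                n -= 1
        return n


@dataclass(slots=True, frozen=True)
class PhasedHet:
    """A phased heterozygous SNV: the anchor for haplotype assignment."""

    chrom: str
    pos: int            # 0-based
    ref_allele: str
    alt_allele: str
    h1_allele: str
    h2_allele: str
    phase_set: int

    def validate(self) -> None:
        if {self.h1_allele, self.h2_allele} != {self.ref_allele, self.alt_allele}:
            raise ValueError("haplotype alleles must be {ref, alt}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref == alt")


@dataclass(slots=True, frozen=True)
class GermlineSite:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype_class: str  # hom_ref | het | hom_alt
    phased: bool = False


class RegionMask:
    """A labelled set of disjoint half-open intervals per chromosome."""

    def __init__(self, intervals=None, label: str = ""):
        self.label = label
        self._by_chrom: dict = {}
        if intervals:
            tmp: dict = {}
            for chrom, s, e in intervals:
                if e <= s:
                    raise ValueError(f"empty interval {chrom}:{s}-{e}")
                tmp.setdefault(chrom, []).append((s, e))
            for chrom, ivs in tmp.items():
                self._by_chrom[chrom] = self._merge(ivs)

    @staticmethod
    def _merge(ivs):
        ivs = sorted(ivs)
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        starts = np.array([s for s, _ in out], dtype=np.int64)
        ends = np.array([e for _, e in out], dtype=np.int64)
        return starts, ends

    def intervals(self, chrom: str):
        if chrom not in self._by_chrom:
            return []
        starts, ends = self._by_chrom[chrom]
        return list(zip(starts.tolist(), ends.tolist()))

    @property
    def chroms(self):
        return list(self._by_chrom)

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def total_length(self) -> int:
        return sum(int((e - s).sum()) for s, e in self._by_chrom.values())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_phased_vcf(path, region=None, sample: Optional[str] = None):
    """Read biallelic SNVs from a VCF with phased genotypes.

    Returns ``(phased_hets, germline_sites)``.  Phased heterozygous SNVs
    appear in both lists; h1/h2 alleles follow the genotype allele order
    (``0|1`` puts REF on haplotype 1).  Multi-allelic records and indels are
    skipped and counted.  ``region`` is an optional (chrom, start, end)
    half-open 0-based restriction.

    A present but unindexed plain VCF is streamed sequentially.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"VCF not found: {path}")
    if sample is None:
        if len(vf.header.samples) == 0:
            raise ValueError(f"VCF has no sample columns: {path}")
        sample = vf.header.samples[0]

    hets: list = []
    germ: list = []
    n_skipped_indel = n_skipped_multi = n_skipped_nogt = 0
    for rec in vf:
        if region is not None:
            chrom, start, end = region
            if rec.chrom != chrom or not (start < rec.pos <= end):
                # rec.pos is 1-based; a record at internal pos p has rec.pos p+1
                continue
        alts = rec.alts or ()
        if len(alts) != 1:
            n_skipped_multi += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in DNA or alt not in DNA:
            n_skipped_indel += 1
            continue
        call = rec.samples[sample]
        gt = call.get("GT")
        if gt is None or any(a is None for a in gt) or len(gt) != 2:
            n_skipped_nogt += 1
            log.warning("record %s:%d has no usable genotype; skipped", rec.chrom, rec.pos)
            continue
        pos0 = rec.pos - 1
        gtset = set(gt)
        if gtset == {0}:
            klass = "hom_ref"
        elif gtset == {1}:
            klass = "hom_alt"
        else:
            klass = "het"
        phased = bool(call.phased) and klass == "het"
        germ.append(GermlineSite(rec.chrom, pos0, ref, alt, klass, phased))
        if phased:
            alleles = (ref, alt)
            ps = call.get("PS")
            hets.append(PhasedHet(rec.chrom, pos0, ref, alt,
                                  alleles[gt[0]], alleles[gt[1]],
                                  int(ps) if ps is not None else 0))
    if n_skipped_indel or n_skipped_multi or n_skipped_nogt:
        log.info("read_phased_vcf skipped: %d indel/non-SNV, %d multi-allelic, %d no-genotype",
                 n_skipped_indel, n_skipped_multi, n_skipped_nogt)
    return hets, germ


def read_alignments(path, region=None, barcode_tag: str = "BX") -> Iterator[AlignedRead]:
    """Stream mapped reads overlapping ``region`` from a coordinate-sorted,
    indexed BAM (or an unindexed SAM when region is None), as AlignedRead."""
    af = pysam.AlignmentFile(str(path))
    if region is not None:
        chrom, start, end = region
        try:
            it = af.fetch(chrom, start, end)
        except ValueError as exc:
            raise RuntimeError(
                f"cannot fetch {chrom}:{start}-{end} from {path}; "
                f"is the file coordinate-sorted and indexed (samtools index)? ({exc})")
    else:
        it = af
    for r in it:
        if r.is_unmapped:
            continue
        yield _convert_read(r, barcode_tag)


def _convert_read(r: pysam.AlignedSegment, barcode_tag: str = "BX") -> AlignedRead:
    quals = r.query_qualities
    return AlignedRead(
        read_name=r.query_name,
        chrom=r.reference_name,
        start=r.reference_start,
        cigar=list(r.cigartuples or ()),
        bases=r.query_sequence or "",
        base_quals=np.asarray(quals, dtype=np.uint8) if quals is not None
                   else np.zeros(len(r.query_sequence or ""), dtype=np.uint8),
        mapq=r.mapping_quality,
        is_reverse=r.is_reverse,
        is_duplicate=r.is_duplicate,
        is_secondary=r.is_secondary,
        is_supplementary=r.is_supplementary,
        is_proper_pair=r.is_proper_pair,
        mate_start=r.next_reference_start if r.next_reference_start >= 0 else None,
        barcode=r.get_tag(barcode_tag) if r.has_tag(barcode_tag) else None,
        pair_id=r.query_name,
    )


def read_bed(path, label: str = "") -> RegionMask:
    """Read a 3+ column BED (0-based half-open) into a merged RegionMask."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates")
            if e < s:
                raise ValueError(f"{path}:{lineno}: end < start")
            if e > s:
                intervals.append((parts[0], s, e))
    return RegionMask(intervals, label=label or str(path))


_VCF_FILTERS = ("low_score", "min_discordant", "region_repeat", "region_cnv", "alignment_error")


def write_calls_vcf(calls: Sequence, path, sample_name: str = "SAMPLE",
                    contigs: Optional[dict] = None) -> None:
    """Write mosaic calls as VCF 4.2 (1-based positions on disk).

    ``calls`` must be sorted by (chrom, pos).  INFO carries the forest score,
    MAF, depth, haplotype-discordant read count and majority haplotype;
    FILTER mirrors ``filters_failed``.
    """
    for a, b in zip(calls, calls[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError("calls must be sorted by (chrom, pos)")
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    seen = dict(contigs or {})
    for c in calls:
        seen.setdefault(c.chrom, 0)
        seen[c.chrom] = max(seen[c.chrom], c.pos + 2)
    for chrom, length in seen.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SCORE", 1, "Float", "Random-forest mosaic score in [0,1]")
    header.info.add("MAF", 1, "Float", "Mosaic allele fraction (candidate reads / depth)")
    header.info.add("DP", 1, "Integer", "Pileup depth (duplicates excluded)")
    header.info.add("DISC", 1, "Integer", "Haplotype-discordant read count")
    header.info.add("HAP", 1, "String", "Majority haplotype of candidate reads")
    for f in _VCF_FILTERS:
        header.filters.add(f, None, None, f"failed {f} filter")
    header.formats.add("GT", 1, "String", "Genotype (placeholder 0/1)")
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(contig=c.chrom, start=c.pos, stop=c.pos + 1,
                                 alleles=(c.ref_allele, c.mosaic_allele))
            rec.info["SCORE"] = float(c.score)
            rec.info["MAF"] = float(c.maf)
            rec.info["DP"] = int(c.depth)
            rec.info["DISC"] = int(c.discordant_count)
            rec.info["HAP"] = c.haplotype or "unassigned"
            if c.filters_failed:
                for f in sorted(c.filters_failed):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            rec.samples[sample_name]["GT"] = (0, 1)
            out.write(rec)
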