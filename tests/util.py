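"""Shared builders for synthetic reads and pileups used across the tests."""
from __future__ import annotations

import itertools

import numpy as np

from samovar_lr import AlignedRead, PhasedHet

_counter = itertools.count()


def make_read(start, bases, barcode=None, quals=None, name=None, cigar=None,
              chrom="chrT", mapq=60, pair_id=None, **flags):
    n = len(bases)
    read = AlignedRead(
        read_name=name or f"r{next(_counter)}",
        chrom=chrom, start=start,
        cigar=cigar if cigar is not None else [(0, n)],
        bases=bases,
        base_quals=np.full(n, 37, dtype=np.uint8) if quals is None
                   else np.asarray(quals, dtype=np.uint8),
        mapq=mapq, barcode=barcode, pair_id=pair_id,
        **flags)
    return read


def make_het(pos, ref="A", alt="G", h1=None, h2=None, ps=1, chrom="chrT"):
    h1 = h1 or ref
    h2 = h2 or (alt if h1 == ref else ref)
    return PhasedHet(chrom, pos, ref, alt, h1, h2, ps)


def random_reads(rng, ref_seq, n, read_len=20, chrom="chrT", barcodes=None,
                 error=0.0, start_lo=0, start_hi=None):
    """Reads copied from ref_seq with optional barcode pool and iid errors."""
    DNA = "ACGT"
    start_hi = start_hi if start_hi is not None else len(ref_seq) - read_len
    reads = []
    for _ in range(n):
        s = int(rng.integers(start_lo, start_hi + 1))
        seq = list(ref_seq[s:s + read_len])
        for i in range(read_len):
            if rng.random() < error:
                seq[i] = DNA[(DNA.index(seq[i]) + 1 + int(rng.integers(3))) % 4]
        bc = None
        if barcodes:
            bc = barcodes[int(rng.integers(len(barcodes)))]
        reads.append(make_read(s, "".join(seq), barcode=bc, chrom=chrom))
    reads.sort(key=lambda r: r.start)
    return reads
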