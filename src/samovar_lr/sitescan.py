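"""Step 1 of the pipeline: scan a region for candidate sites with
sufficient data for the model.

A candidate site must carry enough depth, enough reads with the candidate
mosaic allele, a mosaic allele fraction in a plausible window, and enough
phased reads; sites already called as germline variants are excluded
because they serve as training negatives.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional

from .phasing import SiteObservation
from .pileup import RegionPileup


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the candidate-site filter.

    Defaults are chosen so that a ~30X linked-read pileup passes
    comfortably; every value is configurable.
    """

    min_depth: int = 16
    min_candidate_reads: int = 2
    min_maf: float = 0.03
    max_maf: float = 0.75
    min_phased_fraction: float = 0.25
    min_mapq: int = 30
    min_bq: int = 20
    exclude_germline: bool = True

    def __post_init__(self):
        if not (0.0 <= self.min_maf <= self.max_maf <= 1.0):
            raise ValueError("need 0 <= min_maf <= max_maf <= 1")
        if min(self.min_depth, self.min_candidate_reads, self.min_mapq, self.min_bq) < 0:
            raise ValueError("count thresholds must be >= 0")
        if not (0.0 <= self.min_phased_fraction <= 1.0):
            raise ValueError("min_phased_fraction must be in [0, 1]")

    def for_mode(self, mode: str) -> "ScanConfig":
        """The phased-fraction floor is vacuous in no_phasing mode (the
        fraction is identically zero there) and is therefore waived."""
        if mode == "no_phasing" and self.min_phased_fraction > 0:
            return dataclasses.replace(self, min_phased_fraction=0.0)
        return self


def passes_site_filter(obs: SiteObservation, germline, cfg: ScanConfig) -> bool:
    """True iff the site has sufficient data to be scored.

    ``germline`` is the GermlineSite at this position, if any (used when
    ``cfg.exclude_germline``: a site Long Ranger already called het or
    hom-alt is a training negative, never a candidate).
    """
    if obs.candidate_allele is None:
        return False
    cand = obs.allele_counts.get(obs.candidate_allele, 0)
    if obs.depth < cfg.min_depth or cand < cfg.min_candidate_reads:
        return False
    if not (cfg.min_maf <= obs.maf <= cfg.max_maf):
        return False
    if obs.phased_fraction < cfg.min_phased_fraction:
        return False
    if cfg.exclude_germline and germline is not None \
            and germline.genotype_class in ("het", "hom_alt"):
        return False
    return True


def scan_candidates(pileup: RegionPileup, germline_sites: Iterable,
                    cfg: ScanConfig, mode: str = "full",
                    region: Optional[tuple] = None) -> list:
    """All (pos, SiteObservation) in the region passing the site filter,
    in coordinate order.  ``region`` optionally restricts to a sub-interval
    (half-open) of the pileup's span."""
    cfg = cfg.for_mode(mode)
    if (pileup.min_bq, pileup.min_mapq) != (cfg.min_bq, cfg.min_mapq):
        raise ValueError("pileup was built with different bq/mapq floors than the scan config")
    germ_at = {g.pos: g for g in germline_sites if g.chrom == pileup.chrom}
    lo = pileup.start if region is None else max(region[0], pileup.start)
    hi = pileup.end if region is None else min(region[1], pileup.end)
    out = []
    for pos, _allele in pileup.candidate_positions(
            cfg.min_depth, cfg.min_candidate_reads, cfg.min_maf, cfg.max_maf):
        if not (lo <= pos < hi):
            continue
        obs = pileup.observation(pos, mode=mode)
        if passes_site_filter(obs, germ_at.get(pos), cfg):
            out.append((pos, obs))
    return out
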