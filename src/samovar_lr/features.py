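"""Fixed-order numeric feature vectors for the random-forest site model.

Three model variants share the site-level features; the *full* and
*short_only* variants add fragment-level (phasing) features on top, the
difference being only how their observations were phased (long fragments
vs read pairs).  The *no_phasing* variant uses the site-level subset alone.

Undefined ratios (empty denominators) are encoded as 0 with a paired 0/1
presence-indicator feature, so all values stay finite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasing import H1, H2, SiteObservation

MODES = ("full", "short_only", "no_phasing")

SITE_FEATURES = (
    "depth",
    "maf",
    "cand_present",            # indicator: >=1 candidate-allele read
    "other_present",           # indicator: >=1 non-candidate read
    "bq_mean_cand",
    "bq_sd_cand",
    "bq_mean_other",
    "bq_sd_other",
    "mapq_mean_cand",
    "mapq_mean_other",
    "frac_cand_reverse",
    "mean_norm_readpos_cand",
    "frac_cand_softclip",
    "mean_mismatch_cand",      # per candidate read, candidate base excluded
)

FRAGMENT_FEATURES = (
    "phased_fraction",
    "cand_h1_count",
    "cand_h2_count",
    "cand_unassigned_count",
    "cand_h1_frac",
    "cand_h2_frac",
    "cand_unassigned_frac",
    "discordant_count",
    "cand_assigned_present",   # indicator: >=1 candidate read on H1/H2
    "hap_concentration",       # majority-haplotype share of assigned candidate reads
    "majority_hap_vaf",        # candidate fraction among all reads on the majority haplotype
    "n_cand_fragments",
    "mean_votes_per_cand_fragment",
)


@dataclass(frozen=True)
class FeatureVector:
    mode: str
    names: tuple
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")


def feature_names(mode: str) -> tuple:
    """Stable, documented feature order for one model variant."""
    if mode in ("full", "short_only"):
        return SITE_FEATURES + FRAGMENT_FEATURES
    if mode == "no_phasing":
        return SITE_FEATURES
    raise ValueError(f"unknown mode {mode!r}")


def _mean(xs) -> float:
    return float(np.mean(xs)) if len(xs) else 0.0


def _sd(xs) -> float:
    return float(np.std(xs)) if len(xs) else 0.0


def extract_features(obs: SiteObservation, mode: str) -> FeatureVector:
    """Feature vector for one site observation.

    The observation must have been produced under the same phasing mode
    (``full`` and ``short_only`` observations differ only in how reads were
    assigned, so the same fragment-level definitions apply to both)."""
    names = feature_names(mode)
    if obs.mode != mode:
        raise ValueError(f"observation was phased in mode {obs.mode!r}, not {mode!r}")
    cand = [r for r in obs.records if r.base == obs.candidate_allele]
    other = [r for r in obs.records if r.base != obs.candidate_allele]
    nc = len(cand)
    vals = {
        "depth": float(obs.depth),
        "maf": obs.maf,
        "cand_present": float(nc > 0),
        "other_present": float(len(other) > 0),
        "bq_mean_cand": _mean([r.qual for r in cand]),
        "bq_sd_cand": _sd([r.qual for r in cand]),
        "bq_mean_other": _mean([r.qual for r in other]),
        "bq_sd_other": _sd([r.qual for r in other]),
        "mapq_mean_cand": _mean([r.mapq for r in cand]),
        "mapq_mean_other": _mean([r.mapq for r in other]),
        "frac_cand_reverse": _mean([float(r.is_reverse) for r in cand]),
        "mean_norm_readpos_cand": _mean([r.norm_pos for r in cand]),
        "frac_cand_softclip": _mean([float(r.softclip > 0) for r in cand]),
        "mean_mismatch_cand": _mean([r.n_mismatch for r in cand]),
    }
    if mode in ("full", "short_only"):
        h1 = sum(1 for r in cand if r.haplotype == H1)
        h2 = sum(1 for r in cand if r.haplotype == H2)
        una = nc - h1 - h2
        assigned = h1 + h2
        maj_hap = H1 if h1 >= h2 else H2
        maj_total = sum(obs.counts_by_haplotype.get(maj_hap, {}).values())
        maj_cand = obs.counts_by_haplotype.get(maj_hap, {}).get(obs.candidate_allele, 0)
        cand_frag_ids = {r.frag_id for r in cand if r.frag_id >= 0}
        votes_by_frag = {r.frag_id: r.frag_votes for r in cand if r.frag_id >= 0}
        vals.update({
            "phased_fraction": obs.phased_fraction,
            "cand_h1_count": float(h1),
            "cand_h2_count": float(h2),
            "cand_unassigned_count": float(una),
            "cand_h1_frac": h1 / nc if nc else 0.0,
            "cand_h2_frac": h2 / nc if nc else 0.0,
            "cand_unassigned_frac": una / nc if nc else 0.0,
            "discordant_count": float(len(obs.discordant_reads)),
            "cand_assigned_present": float(assigned > 0),
            "hap_concentration": max(h1, h2) / assigned if assigned else 0.0,
            "majority_hap_vaf": maj_cand / maj_total if maj_total else 0.0,
            "n_cand_fragments": float(len(cand_frag_ids)),
            "mean_votes_per_cand_fragment": _mean(list(votes_by_frag.values())),
        })
    return FeatureVector(mode=mode, names=names,
                         values=np.array([vals[n] for n in names], dtype=np.float64))


def features_to_frame(vectors):
    """Feature matrix as a pandas DataFrame (inspection/TSV export)."""
    import pandas as pd
    if not vectors:
        return pd.DataFrame()
    return pd.DataFrame(np.vstack([v.values for v in vectors]),
                        columns=list(vectors[0].names))
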