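"""Steps 2–3: sample-specific training by haplotype-aware spike-in.

Positive examples are synthetic mosaic variants introduced *in silico* into
the sample's own pileups: at a hom-ref site, fragments assigned to a chosen
target haplotype are selected with probability min(1, 2·MAF) (unassigned
fragments with probability MAF) and every read of a selected fragment
covering the site has its base replaced by the mosaic allele.  Editing is
fragment-granular because all reads of one molecule derive from one cell
and must agree at the site — this is what makes the haplotype-discordant
signature appear in the training data.  Negative examples are the sample's
real heterozygous and homozygous-alt germline calls, taken unedited.

A random forest of 100 trees is trained on the resulting labelled feature
matrix; its positive-class probability is the mosaic score.
"""
from __future__ import annotations

import dataclasses
import logging
import pickle
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureVector, extract_features, feature_names
from .io_model import DNA, GermlineSite
from .phasing import H1, H2, UNASSIGNED
from .pileup import RegionPileup
from .sitescan import ScanConfig, passes_site_filter

log = logging.getLogger(__name__)

ARTIFACT_VERSION = 1


@dataclass(frozen=True)
class SpikeInSpec:
    chrom: str
    pos: int
    target_maf: float
    target_haplotype: str       # H1 | H2
    mosaic_allele: str
    seed: int

    def __post_init__(self):
        if not (0.0 < self.target_maf <= 0.5):
            raise ValueError("target_maf must be in (0, 0.5]")
        if self.target_haplotype not in (H1, H2):
            raise ValueError("target_haplotype must be H1 or H2")


@dataclass
class TrainingSet:
    vectors: list                   # list[FeatureVector]
    labels: list                    # list[str]: "positive" | "negative"
    provenance: list                # list[(pos, origin)]; origin: spike_in|het|hom_alt
    achieved_maf: dict = field(default_factory=dict)  # pos -> float, positives only
    mode: str = "full"

    def __post_init__(self):
        if not (len(self.vectors) == len(self.labels) == len(self.provenance)):
            raise ValueError("vectors/labels/provenance length mismatch")

    def matrix(self) -> np.ndarray:
        return np.vstack([v.values for v in self.vectors])

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.matrix(), columns=list(self.vectors[0].names))
        df.insert(0, "label", self.labels)
        df.insert(1, "pos", [p for p, _ in self.provenance])
        df.insert(2, "origin", [o for _, o in self.provenance])
        return df


@dataclass
class ModelArtifact:
    forest: RandomForestClassifier
    n_trees: int
    mode: str
    feature_names: tuple
    training_seed: int
    version: int = ARTIFACT_VERSION

    def score(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability (mean of tree leaf probabilities)."""
        pos_col = list(self.forest.classes_).index(1)
        return self.forest.predict_proba(X)[:, pos_col]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh, protocol=4)

    @classmethod
    def load(cls, path) -> "ModelArtifact":
        with open(path, "rb") as fh:
            art = pickle.load(fh)
        if not isinstance(art, cls):
            raise ValueError(f"{path} is not a model artifact")
        if art.version != ARTIFACT_VERSION:
            raise ValueError(f"artifact version {art.version} != {ARTIFACT_VERSION}")
        return art


# ---------------------------------------------------------------------------
# site selection
# ---------------------------------------------------------------------------

def select_training_sites(pileup: RegionPileup, germline: Sequence[GermlineSite],
                          n_pos: int, n_neg: int, seed: int,
                          scan_cfg: Optional[ScanConfig] = None,
                          exclude_positions: Optional[Iterable[int]] = None,
                          min_exclude_dist: int = 1000,
                          max_attempts_factor: int = 200):
    """Choose spike-in positions (hom-ref, data-sufficient pre-edit, away
    from any excluded truth site) and negative germline sites.

    Target MAF ~ U(0.05, 0.5]; target haplotype and mosaic allele uniform.
    Negatives are sampled evenly from het and hom-alt germline calls.
    """
    scan_cfg = scan_cfg or ScanConfig()
    rng = np.random.default_rng(seed)
    germ_pos = {g.pos for g in germline if g.genotype_class != "hom_ref"}
    excl = np.sort(np.array(list(exclude_positions or []), dtype=np.int64))

    def near_excluded(pos: int) -> bool:
        if excl.size == 0:
            return False
        i = int(np.searchsorted(excl, pos))
        for j in (i - 1, i):
            if 0 <= j < excl.size and abs(int(excl[j]) - pos) < min_exclude_dist:
                return True
        return False

    specs: list = []
    chosen: set = set()
    attempts = 0
    max_attempts = max_attempts_factor * max(n_pos, 1)
    while len(specs) < n_pos and attempts < max_attempts:
        attempts += 1
        pos = int(rng.integers(pileup.start, pileup.end))
        if pos in germ_pos or pos in chosen or near_excluded(pos):
            continue
        obs = pileup.observation(pos)
        if obs.depth < scan_cfg.min_depth or obs.phased_fraction < scan_cfg.min_phased_fraction:
            continue
        if obs.ref_allele not in DNA:
            continue
        # require an effectively hom-ref pileup pre-edit
        nonref = obs.depth - obs.allele_counts.get(obs.ref_allele, 0)
        if obs.depth > 0 and nonref / obs.depth > 0.05:
            continue
        target_maf = float(rng.uniform(0.05, 0.5))
        hap = (H1, H2)[int(rng.integers(2))]
        allele = [b for b in DNA if b != obs.ref_allele][int(rng.integers(3))]
        specs.append(SpikeInSpec(pileup.chrom, pos, target_maf, hap, allele,
                                 seed=int(rng.integers(2**31 - 1))))
        chosen.add(pos)
    if len(specs) < n_pos:
        raise RuntimeError(
            f"only {len(specs)} of {n_pos} eligible spike-in sites found "
            f"after {attempts} attempts (region too small or too masked?)")

    hets = [g for g in germline if g.genotype_class == "het"
            and pileup.start <= g.pos < pileup.end and not near_excluded(g.pos)]
    homs = [g for g in germline if g.genotype_class == "hom_alt"
            and pileup.start <= g.pos < pileup.end and not near_excluded(g.pos)]
    n_hom = min(n_neg // 2, len(homs))
    n_het = min(n_neg - n_hom, len(hets))  # hets absorb any hom-alt shortfall
    if n_het + n_hom < n_neg:
        log.warning("only %d of %d negative sites available", n_het + n_hom, n_neg)
    negatives = [hets[i] for i in rng.choice(len(hets), size=n_het, replace=False)] if n_het else []
    negatives += [homs[i] for i in rng.choice(len(homs), size=n_hom, replace=False)] if n_hom else []
    if not negatives:
        raise RuntimeError("no germline sites available as negatives")
    return specs, negatives


# ---------------------------------------------------------------------------
# spike-in
# ---------------------------------------------------------------------------

def spike_in(reads_at_site: Sequence, het_index, spec: SpikeInSpec,
             site_phase_set: Optional[int] = None):
    """Edit the site's reads to carry a synthetic mosaic variant.

    Fragment-granular: a fragment on the target haplotype is selected with
    probability min(1, 2·target_maf); an unassigned fragment with
    probability target_maf; a fragment on the other haplotype never.  Every
    read of a selected fragment covering the site gets the mosaic allele
    (base quality unchanged).  Non-covering reads pass through untouched.

    Returns ``(edited_reads, achieved_maf)`` where edited reads are copies
    (the input pileup is never mutated) and achieved_maf is the edited-read
    share among reads covering the site.
    """
    rng = np.random.default_rng(spec.seed)
    if site_phase_set is None and het_index is not None:
        site_phase_set = het_index.phase_set_at(spec.pos)
    by_frag: dict = {}
    order: list = []
    for r in reads_at_site:
        key = id(r.fragment) if r.fragment is not None else id(r)
        if key not in by_frag:
            by_frag[key] = []
            order.append(key)
        by_frag[key].append(r)
    out: list = []
    n_cover = n_edited = 0
    for key in order:
        group = by_frag[key]
        frag = group[0].fragment
        hap = frag.haplotype_at(site_phase_set) if frag is not None else UNASSIGNED
        if hap == spec.target_haplotype:
            p = min(1.0, 2.0 * spec.target_maf)
        elif hap == UNASSIGNED:
            p = spec.target_maf
        else:
            p = 0.0
        select = rng.random() < p
        for r in group:
            hit = r.base_at(spec.pos)
            if hit is None:
                out.append(r)
                continue
            n_cover += 1
            if select:
                _, _, off = hit
                edited = dataclasses.replace(
                    r, bases=r.bases[:off] + spec.mosaic_allele + r.bases[off + 1:])
                edited.fragment = r.fragment
                out.append(edited)
                n_edited += 1
            else:
                out.append(r)
    if n_cover == 0:
        log.warning("spike-in at %s:%d skipped: no covering reads", spec.chrom, spec.pos)
        return out, 0.0
    return out, n_edited / n_cover


def build_training_set(pileup: RegionPileup, specs: Sequence[SpikeInSpec],
                       negatives: Sequence[GermlineSite], mode: str = "full",
                       scan_cfg: Optional[ScanConfig] = None) -> TrainingSet:
    """Feature vectors for spiked positives (edited pileups, candidate =
    mosaic allele) and germline negatives (unedited pileups, candidate =
    germline alt).  Positives whose post-edit pileup fails the site filter
    are dropped and logged."""
    scan_cfg = (scan_cfg or ScanConfig()).for_mode(mode)
    vectors, labels, prov = [], [], []
    achieved: dict = {}
    n_dropped = 0
    for spec in specs:
        reads = pileup.reads_at(spec.pos)
        edited, amaf = spike_in(reads, pileup.het_index, spec)
        obs = pileup.observation(spec.pos, candidate_allele=spec.mosaic_allele,
                                 mode=mode, read_override=edited)
        if not passes_site_filter(obs, None, dataclasses.replace(scan_cfg, exclude_germline=False)):
            n_dropped += 1
            continue
        vectors.append(extract_features(obs, mode))
        labels.append("positive")
        prov.append((spec.pos, "spike_in"))
        achieved[spec.pos] = amaf
    if n_dropped:
        log.info("dropped %d/%d spike-in positives failing the post-edit site filter",
                 n_dropped, len(specs))
    for g in negatives:
        obs = pileup.observation(g.pos, candidate_allele=g.alt_allele, mode=mode)
        if obs.depth == 0:
            continue
        vectors.append(extract_features(obs, mode))
        labels.append("negative")
        prov.append((g.pos, g.genotype_class))
    return TrainingSet(vectors, labels, prov, achieved, mode=mode)


def train_model(ts: TrainingSet, n_trees: int = 100, seed: int = 0) -> ModelArtifact:
    """Fit the 100-tree random forest on a labelled training set.

    The mosaic score of a site is the forest's positive-class probability,
    i.e. its resemblance to the synthetic-mosaic training sites."""
    classes = set(ts.labels)
    if classes != {"positive", "negative"}:
        raise ValueError(f"training set must contain both classes, got {sorted(classes)}")
    X = ts.matrix()
    y = np.array([1 if l == "positive" else 0 for l in ts.labels])
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return ModelArtifact(forest=forest, n_trees=n_trees, mode=ts.mode,
                         feature_names=feature_names(ts.mode), training_seed=seed)
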