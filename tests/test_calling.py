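"""Scoring, region masks, the alignment-error heuristic, and the end-to-end
calling contracts (filter provenance, threshold monotonicity)."""
import dataclasses

import numpy as np
import pytest

from samovar_lr import (CallConfig, MosaicCall, RegionMask, ScanConfig,
                        alignment_error_filter, apply_region_filters,
                        call_variants, score_sites)
from samovar_lr.calling import homopolymer_run
from samovar_lr.features import FeatureVector, feature_names
from samovar_lr.phasing import H1, H2, UNASSIGNED, SiteObservation, ReadAtSite
from util import make_read


class TestScoreSites:
    def test_scoring_is_pure_and_order_preserving(self, small_model):
        rng = np.random.default_rng(4)
        vecs = [FeatureVector("full", feature_names("full"),
                              rng.random(len(feature_names("full"))))
                for _ in range(10)]
        s1 = score_sites(small_model, vecs)
        s2 = score_sites(small_model, vecs)
        assert np.array_equal(s1, s2)
        assert len(s1) == 10

    def test_permuted_feature_names_fatal(self, small_model):
        names = list(feature_names("full"))
        names[0], names[1] = names[1], names[0]
        v = FeatureVector("full", tuple(names), np.zeros(len(names)))
        with pytest.raises(ValueError, match="match the model"):
            score_sites(small_model, [v])

    def test_mode_mismatch_fatal(self, small_model):
        v = FeatureVector("no_phasing", feature_names("no_phasing"),
                          np.zeros(len(feature_names("no_phasing"))))
        with pytest.raises(ValueError):
            score_sites(small_model, [v])

    def test_training_positive_duplicate_scores_high(self):
        from samovar_lr.training import TrainingSet, train_model
        names = feature_names("full")
        i = names.index("hap_concentration")
        vectors, labels, prov = [], [], []
        for k in range(40):
            x = np.full(len(names), 0.05)
            pos = k % 2 == 0
            x[i] = 1.0 if pos else 0.5
            vectors.append(FeatureVector("full", names, x))
            labels.append("positive" if pos else "negative")
            prov.append((k, "spike_in" if pos else "het"))
        art = train_model(TrainingSet(vectors, labels, prov, mode="full"), seed=1)
        assert score_sites(art, [vectors[0]])[0] > 0.5


def _call(pos, chrom="chrT", **kw):
    base = dict(ref_allele="A", mosaic_allele="G", score=0.9, maf=0.2,
                depth=30, discordant_count=5, haplotype=H2)
    base.update(kw)
    return MosaicCall(chrom=chrom, pos=pos, **base)


class TestRegionFilters:
    def test_overlap_gains_label(self):
        c = _call(100)
        apply_region_filters([c], [RegionMask([("chrT", 50, 150)], label="repeats")])
        assert c.filters_failed == {"region_repeat"}

    def test_empty_mask_list_no_change(self):
        c = _call(100)
        apply_region_filters([c], [])
        assert c.filters_failed == set()

    def test_fuzzed_membership_matches_interval_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            ivs = []
            for _ in range(int(rng.integers(1, 10))):
                s = int(rng.integers(0, 900))
                ivs.append(("chrT", s, s + int(rng.integers(1, 120))))
            mask = RegionMask(ivs, label="cnv")
            calls = [_call(int(rng.integers(0, 1100))) for _ in range(10)]
            apply_region_filters(calls, [mask])
            for c in calls:
                inside = any(s <= c.pos < e for _, s, e in ivs)
                assert ("region_cnv" in c.filters_failed) == inside

    def test_no_calls_deleted(self):
        calls = [_call(p) for p in (10, 20, 30)]
        out = apply_region_filters(calls, [RegionMask([("chrT", 0, 100)], "repeats")])
        assert len(out) == 3 and all("region_repeat" in c.filters_failed for c in out)


def obs_from_records(records, pos=50, ref="A" * 200, cand="G"):
    from collections import Counter
    counts = Counter(r.base for r in records)
    return SiteObservation(
        chrom="chrT", pos=pos, ref_allele="A", allele_counts=dict(counts),
        depth=len(records), candidate_allele=cand,
        maf=counts.get(cand, 0) / len(records) if records else 0.0,
        counts_by_haplotype={H1: {}, H2: {}, UNASSIGNED: dict(counts)},
        discordant_reads=[], phased_fraction=0.0, records=records, mode="full")


def rand_record(rng, base="G"):
    return ReadAtSite(read=None, base=base, qual=37, mapq=60,
                      is_reverse=bool(rng.integers(2)),
                      is_proper_pair=rng.random() < 0.8,
                      norm_pos=float(rng.random()),
                      softclip=int(rng.integers(0, 12)),
                      n_mismatch=int(rng.integers(0, 6)),
                      haplotype=UNASSIGNED, frag_id=-1, frag_votes=0)


class TestAlignmentErrorFilter:
    def test_clean_candidate_reads_pass(self):
        rng = np.random.default_rng(0)
        recs = []
        for _ in range(4):
            r = rand_record(rng)
            r.softclip, r.n_mismatch, r.is_proper_pair = 0, 1, True
            recs.append(r)
        ok, diag = alignment_error_filter(obs_from_records(recs), "ACGT" * 50)
        assert ok

    def test_heavily_clipped_reads_fail(self):
        rng = np.random.default_rng(1)
        recs = []
        for _ in range(4):
            r = rand_record(rng)
            r.softclip, r.n_mismatch, r.is_proper_pair = 20, 0, True
            recs.append(r)
        ok, diag = alignment_error_filter(obs_from_records(recs), "ACGT" * 50)
        assert not ok and diag["softclip_frac"] == 1.0

    def test_homopolymer_site_fails(self):
        ref = "ACGT" * 10 + "A" * 12 + "CGT" * 10
        obs = obs_from_records([], pos=45)
        assert homopolymer_run(ref, 45) == 12
        ok, diag = alignment_error_filter(obs, ref)
        assert not ok and diag["homopolymer_run"] >= 10

    def test_fuzzed_decisions_match_predicate_oracle(self):
        rng = np.random.default_rng(12)
        cfg = CallConfig()
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            recs = [rand_record(rng) for _ in range(n)]
            # random reference with occasional homopolymer at the site
            if rng.random() < 0.3:
                run = int(rng.integers(5, 15))
                ref = "ACGT" * 10 + "T" * run + "ACGT" * 10
                pos = 40 + int(rng.integers(run))
            else:
                ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
                pos = int(rng.integers(0, 100))
            obs = obs_from_records(recs, pos=pos)
            ok, _ = alignment_error_filter(obs, ref, cfg=cfg)
            # independently coded predicate
            clip = np.mean([r.softclip >= 5 for r in recs])
            mm = np.mean([r.n_mismatch for r in recs])
            imp = np.mean([not r.is_proper_pair for r in recs])
            b = ref[pos]
            lo = pos
            while lo > 0 and ref[lo - 1] == b:
                lo -= 1
            hi = pos
            while hi + 1 < len(ref) and ref[hi + 1] == b:
                hi += 1
            hp = hi - lo + 1
            expect = not (clip > 0.5 or mm > 3 or imp > 0.5 or hp >= 10)
            assert ok == expect


class TestCallVariants:
    def test_low_discordant_site_is_filtered(self, small_sim, small_model):
        ctx = small_sim
        calls, _ = call_variants(ctx["pileup"], ctx["germ"], small_model,
                                 ctx["scan_cfg"])
        for c in calls:
            if c.discordant_count < 4:
                assert "min_discordant" in c.filters_failed

    def test_relaxing_min_discordant_only_adds_pass_calls(self, small_sim, small_model):
        ctx = small_sim
        p4 = {c.pos for c in call_variants(ctx["pileup"], ctx["germ"], small_model,
                                           ctx["scan_cfg"],
                                           CallConfig(min_discordant=4))[0] if c.passes}
        p3 = {c.pos for c in call_variants(ctx["pileup"], ctx["germ"], small_model,
                                           ctx["scan_cfg"],
                                           CallConfig(min_discordant=3))[0] if c.passes}
        assert p4 <= p3

    def test_score_threshold_sweep_monotone_recall(self, small_sim, small_model):
        ctx = small_sim
        truth = ctx["truth_pos"]
        recalls = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            calls, _ = call_variants(ctx["pileup"], ctx["germ"], small_model,
                                     ctx["scan_cfg"], CallConfig(score_threshold=thr))
            passed = {c.pos for c in calls if c.passes}
            recalls.append(len(passed & truth))
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_filter_provenance_conservation(self, small_sim, small_model):
        from samovar_lr.sitescan import scan_candidates
        ctx = small_sim
        mask = RegionMask([(ctx["cfg"].chrom, 0, 50_000)], label="repeats")
        calls, rep = call_variants(ctx["pileup"], ctx["germ"], small_model,
                                   ctx["scan_cfg"], masks=[mask])
        cands = scan_candidates(ctx["pileup"], ctx["germ"], ctx["scan_cfg"])
        assert len(calls) == len(cands) == rep["n_scored"]
        assert len({c.pos for c in calls}) == len(calls)
        for c in calls:
            assert c.passes == (not c.filters_failed)

    def test_mode_mismatch_with_artifact_fatal(self, small_sim, small_model):
        ctx = small_sim
        with pytest.raises(ValueError, match="mode"):
            call_variants(ctx["pileup"], ctx["germ"], small_model,
                          ctx["scan_cfg"], mode="no_phasing")

    def test_output_vcf_round_trips(self, small_sim, small_model, tmp_path):
        from samovar_lr.calling import read_calls_vcf
        ctx = small_sim
        out = tmp_path / "calls.vcf"
        calls, _ = call_variants(ctx["pileup"], ctx["germ"], small_model,
                                 ctx["scan_cfg"], vcf_path=out)
        back = read_calls_vcf(out)
        assert [(c.chrom, c.pos, c.mosaic_allele) for c in back] == \
               [(c.chrom, c.pos, c.mosaic_allele) for c in calls]
        assert [c.passes for c in back] == [c.passes for c in calls]
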