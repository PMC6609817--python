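from __future__ import annotations

import pytest

from samovar_lr import (ScanConfig, SimConfig, read_phased_vcf, simulate_dataset)
from samovar_lr.phasing import HetIndex
from samovar_lr.pileup import RegionPileup
from samovar_lr.training import (build_training_set, select_training_sites,
                                 train_model)


def build_ctx(res):
    """Load a simulated dataset into the in-memory pipeline context."""
    genome = res["genome"]
    cfg = res["config"]
    scan_cfg = ScanConfig()
    hets, germ = read_phased_vcf(res["vcf"])
    het_index = HetIndex(hets, chrom=cfg.chrom)
    pileup = RegionPileup.from_bam(
        res["bam"], het_index, genome.reference, cfg.chrom, 0, cfg.region_length,
        min_bq=scan_cfg.min_bq, min_mapq=scan_cfg.min_mapq)
    return {"genome": genome, "cfg": cfg, "paths": res, "scan_cfg": scan_cfg,
            "hets": hets, "germ": germ, "het_index": het_index, "pileup": pileup,
            "truth_pos": {m.pos for m in genome.truth.mosaic},
            "support": genome.truth.support}


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """300 kb / 30X with sequencing error and 30 mosaic sites."""
    cfg = SimConfig(region_length=300_000, n_mosaic=30, seed=7)
    res = simulate_dataset(cfg, tmp_path_factory.mktemp("sim_small"))
    return build_ctx(res)


@pytest.fixture(scope="session")
def errorfree_sim(tmp_path_factory):
    """300 kb / 30X, error-free: the idealized haplotype-signature regime."""
    cfg = SimConfig(region_length=300_000, n_mosaic=25, base_error_rate=0.0, seed=13)
    res = simulate_dataset(cfg, tmp_path_factory.mktemp("sim_ef"))
    return build_ctx(res)


@pytest.fixture(scope="session")
def small_model(small_sim):
    """Full-mode forest trained on the small simulation (spike-ins disjoint
    from the mosaic truth sites)."""
    ctx = small_sim
    specs, negs = select_training_sites(
        ctx["pileup"], ctx["germ"], 150, 150, seed=11, scan_cfg=ctx["scan_cfg"],
        exclude_positions=ctx["truth_pos"])
    ts = build_training_set(ctx["pileup"], specs, negs, mode="full",
                            scan_cfg=ctx["scan_cfg"])
    return train_model(ts, seed=3)
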