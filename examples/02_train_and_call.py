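"""The full pipeline from Python: simulate, spike-in training, random
forest, calling, and MAF-binned evaluation.

Printed metrics use the support-aware recall denominator: only truth
sites the sequencer covered with >= 4 alt reads count, because a caller
requiring 4 discordant reads cannot recover the rest.
"""
import tempfile

from samovar_lr import (CallConfig, call_variants, precision_recall)
from samovar_lr import SimConfig, simulate_dataset
from samovar_lr.benchmark import load_pipeline_context
from samovar_lr.training import (build_training_set, select_training_sites,
                                 train_model)

cfg = SimConfig(region_length=400_000, n_mosaic=40, seed=21)
dataset = simulate_dataset(cfg, tempfile.mkdtemp(prefix="svlr_ex2_"))
ctx = load_pipeline_context(dataset)
truth_pos = {m.pos for m in ctx["truth"]}

# training sites must stay away from the evaluation truth
specs, negatives = select_training_sites(
    ctx["pileup"], ctx["germ"], n_pos=200, n_neg=200, seed=3,
    scan_cfg=ctx["scan_cfg"], exclude_positions=truth_pos)
ts = build_training_set(ctx["pileup"], specs, negatives, mode="full",
                        scan_cfg=ctx["scan_cfg"])
model = train_model(ts, seed=4)
print(f"trained {model.n_trees}-tree forest on "
      f"{ts.labels.count('positive')} spiked positives / "
      f"{ts.labels.count('negative')} germline negatives")

calls, report = call_variants(ctx["pileup"], ctx["germ"], model,
                              ctx["scan_cfg"], CallConfig())
passed = [c for c in calls if c.passes]
print(f"candidates {report['n_candidates']} -> PASS {report['n_pass']} "
      f"(min_discordant removed {report['n_fail_min_discordant']})")

res = precision_recall(passed, ctx["truth"], support=ctx["support"], min_support=4)
print(f"\nprecision {res.precision:.3f}  recall {res.recall:.3f}  F {res.f_score:.3f} "
      f"(TP {res.tp}, FP {res.fp}, FN {res.fn}; denominator {res.denominator_rule})")
print("per-MAF-bin recall (truth MAF, right-closed bins):")
for b in res.bins:
    if b.tp + b.fn:
        print(f"  ({b.lo:.2f}, {b.hi:.2f}]  recall {b.recall:.2f}  "
              f"({b.tp}/{b.tp + b.fn} sites)")
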