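"""Benchmark-convention splits, the split-shift diagnostic, and the
batch-count-proportional sampling schedule with global loss weights.

Reproduces the published 13-task sampling table from the dataset sizes
alone, then contrasts the molecular-weight shift of random vs scaffold
test splits on a two-chemotype fixture.
"""

from molfuse import (BENCHMARK_TASKS, FixtureSpec, build_schedule,
                     gen_molecule_dataset, random_split, scaffold_split,
                     split_shift_report, stratified_split)

# -- the 13-benchmark sampling schedule --------------------------------
sched = build_schedule(BENCHMARK_TASKS, batch_size=32)
print(f"{'task':9s} {'pi %':>7s} {'beta':>6s}")
for name, pct, beta in sched.as_table():
    print(f"{name:9s} {pct:7.2f} {beta:6.2f}")
print("sum of probabilities:", float(sum(sched.probabilities)))
# pi is each task's chance of being drawn per training step; beta =
# sqrt(max pi / pi) is the loss weight compensating rare sampling.

# -- split strategies on a synthetic table ------------------------------
recs, _ = gen_molecule_dataset(FixtureSpec(n=300, n_endpoints=1,
                                           positive_rates=(0.3,), seed=1))
strat = stratified_split(recs, seed=0)
labels = [r.labels[0] for r in recs]
tr_rate = sum(labels[i] for i in strat.train) / len(strat.train)
te_rate = sum(labels[i] for i in strat.test) / len(strat.test)
print(f"\nstratified 80/20: positive rate train {tr_rate:.3f} vs test {te_rate:.3f}")

for split in (random_split(recs, seed=0), scaffold_split(recs)):
    rep = split_shift_report(recs, split)
    print(f"{split.method:9s} split: train MW {rep['train']['mean']:7.1f}, "
          f"test MW {rep['test']['mean']:7.1f}, KS distance {rep['ks_statistic']:.3f}")
# the scaffold split isolates whole chemotypes in the test set, so its
# weight distribution shifts more than a random split's (larger KS).
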