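"""Differential methylation calling with the dual FDR/effect filter.

Builds the coverage-filtered matrix (>=10X in every animal after merging
seasons), runs the quasi-binomial LRT per cytosine, adjusts with
Benjamini-Hochberg, and applies the dual filter q <= 0.05 AND
|difference| >= 10%.  DMCs are classed <30%, 30-70%, >70%.
"""

from methclash import SimulationConfig, call_dmcs, simulate_dataset
from methclash.coverage_matrix import build_matrix, merge_seasons

config = SimulationConfig(n_cpg_sites=3000, n_true_dmc=200, seed=42)
ds = simulate_dataset(config)

base = build_matrix(ds.calls, ds.samples, min_cov=0)
matrix = merge_seasons(base, min_cov=10)
records, summary = call_dmcs(matrix, fdr=0.05, min_diff=0.10)

print(f"sites tested (>=10X in all {matrix.n_samples} animals): {summary.n_tested}")
print(f"DMCs called: {summary.n_dmc} ({summary.dmc_percent:.2f}%), "
      f"MCs: {summary.n_mc}")
print(f"effect classes: {summary.class_counts}")
true = ds.truth.true_dmc_sites()
called = {(r.chrom, r.pos) for r in records if r.is_dmc}
tested = {(r.chrom, r.pos) for r in records}
sens = len(true & called) / max(len(true & tested), 1)
print(f"sensitivity vs planted truth: {sens:.2f}")
# The dual filter keeps statistically solid sites with a biologically
# meaningful difference; weak-effect planted sites (<30% class near the
# 10% floor) are the ones that escape.
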