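"""Knockdown-vs-control differential of normalized Alu siRNA abundance.

Simulates a control library and a matched pair in which Alu siRNA production
is halved (emulating knockdown of the DICER-stimulating cofactor), then
prints the per-length difference of exclusion-normalized read numbers:
Alu siRNA reads / (total - miRNA - Alu siRNA) x 1e6, treated minus control.
"""

from alusirna import (
    SimConfig,
    differential_profile,
    make_synthetic_references,
    preprocess_reads,
    run_cascade,
    simulate_paired_libraries,
)

refs = make_synthetic_references(seed=3)
config = SimConfig(seed=3, n_reads=100_000)
control_reads, _, treated_reads, _ = simulate_paired_libraries(
    config, refs, alu_scale=0.5
)

summaries = {}
for name, reads in (("control", control_reads), ("treated", treated_reads)):
    passed, _ = preprocess_reads(reads, config.adaptor)
    summaries[name] = run_cascade(passed, refs.ref_sets)

dp = differential_profile(summaries["treated"], summaries["control"])
print("length  norm_treated  norm_control  delta")
for n, t, c, d in zip(dp.lengths, dp.norm_treated, dp.norm_control, dp.delta):
    print(f"{n:>6}  {t:>12.1f}  {c:>12.1f}  {d:>8.1f}")
print(
    "Negative deltas mean fewer normalized Alu siRNA reads after the "
    "knockdown; with production halved, every observed length drops by "
    "roughly half its control value."
)
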