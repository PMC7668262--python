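"""Map in vitro dicing products back onto their inverted-Alu hairpin.

Builds a hairpin with two ~300 nt Alu arms joined by a 533 nt loop, samples
5,000 dicer fragments (21-24 nt, both strands, independent cleavage sites),
wraps them in 5'/3' cloning adaptors, and maps them back with zero
mismatches.
"""

from alusirna import (
    SmallRead,
    make_hairpin,
    make_synthetic_references,
    map_dicing_products,
    simulate_dicer_products,
)
from alusirna.profiling import DICING_ADAPTOR_3P, DICING_ADAPTOR_5P

refs = make_synthetic_references(seed=4)
hairpin = make_hairpin(
    "inverted_alu", refs.alu_consensi[0], refs.alu_consensi[1], loop_len=533, seed=4
)
frags = simulate_dicer_products(hairpin, 5_000, seed=5)
reads = [
    SmallRead(f"d{i}", DICING_ADAPTOR_5P + seq + DICING_ADAPTOR_3P)
    for i, (seq, _, _) in enumerate(frags)
]

cov = map_dicing_products(reads, hairpin)
(l0, l1), (r0, r1) = hairpin.arms
print(f"mapped {cov.n_mapped}, unmapped {cov.n_unmapped}")
print(f"left arm  mean coverage: +{cov.plus[l0:l1].mean():.1f}  -{cov.minus[l0:l1].mean():.1f}")
print(f"loop      total coverage: {cov.loop_coverage(hairpin):.0f}")
print(f"right arm mean coverage: +{cov.plus[r0:r1].mean():.1f}  -{cov.minus[r0:r1].mean():.1f}")
print(
    "Every fragment places exactly (zero mismatches) and both strands of "
    "both stems are covered, while the single-stranded loop stays at zero - "
    "the signature of dicer acting on the paired stems only."
)
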