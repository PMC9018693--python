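"""Simulate bisulfite amplicon reads from a known epiallele mixture.

Builds a 7-CpG, 388-bp promoter amplicon, draws molecules from a two-
epiallele mixture, converts them with 99% bisulfite efficiency and emits
overlapping 251-nt read pairs.
"""

from collections import Counter

from epiamplicon import MixtureSpec, make_amplicon_spec, simulate_sample_reads

spec = make_amplicon_spec(
    n_cpgs=7, length=388, labels=[-118, -91, -47, -3, 92, 112, 131], seed=1
)
print(f"amplicon: {spec.name}, {len(spec)} bp, CpGs at offsets {spec.cpg_offsets}")
print(f"non-CpG cytosines for conversion QC: {len(spec.non_cpg_c_offsets)}")

mix = MixtureSpec(
    epiallele_probs={"1000000": 0.5, "0000001": 0.5},
    n_molecules=2000,
    conversion_rate=0.99,
    seq_error_rate=0.001,
    seed=7,
)
molecules, pairs = simulate_sample_reads(spec, mix)
print(f"\nsimulated {len(pairs)} read pairs of {len(pairs[0][0])} nt each")
print("ground-truth epiallele counts:", dict(Counter(molecules)))
# Each molecule's binary string records which CpGs were methylated ('1');
# the reads carry that pattern as C (methylated) vs T (converted) bases.
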