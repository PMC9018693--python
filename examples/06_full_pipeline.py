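"""Run the complete pipeline on the default two-tissue demo design.

Two amplicons (7 and 8 CpGs), brain and heart at postnatal stages
P1/P15/P60 with 3 replicates each. Scaled to 2000 reads/sample to finish
in seconds; the defaults use 10,000.
"""

from epiamplicon import RunConfig, run_pipeline

cfg = RunConfig(n_reads_per_sample=2000, seed=123)
result = run_pipeline(cfg, outdir="scratch/demo_run")

for name, amp in result.amplicons.items():
    print(f"\n== {name} ({amp.spec.n_cpgs} CpGs, {len(amp.spec)} bp) ==")
    meta = amp.count_table.meta
    mm = amp.mean_meth * 100
    for tissue in ("brain", "heart"):
        traj = [
            mm.loc[meta.index[(meta.tissue == tissue)
                              & (meta.stage == s)]].mean()
            for s in ("P1", "P15", "P60")
        ]
        print(f"  {tissue} mean methylation P1->P15->P60: "
              + " -> ".join(f"{v:.1f}%" for v in traj))
    print(f"  rarefied to {amp.rarefied.rarefied_depth} reads/sample")
    print("  methylation-expression correlation:")
    for row in amp.correlation.itertuples():
        print(f"    {row.tissue}: r = {row.r:.3f} (p = {row.p:.2g})")
    pe = amp.ordination.proportion_explained
    print(f"  ordination PC1+PC2 variance: {pe.sum():.1%}")

conv = result.conversion
print(f"\nspike-in conversion efficiency: {conv.efficiency:.4f} "
      f"[{conv.ci_low:.4f}, {conv.ci_high:.4f}]")
print("tables written under scratch/demo_run/")
# Methylation rises with age in brain and falls in heart, and expression
# tracks it inversely in both tissues - the built-in demo ground truth.
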