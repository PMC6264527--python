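"""Generate the synthetic embryo-transcriptome bundle.

Builds a two-chromosome toy genome carrying reference protein-coding
genes, annotated lncRNAs, and candidate transcript models in which
every artifact class of the discovery cascade is planted with known
ground truth, then prints the planted composition.
"""

from collections import Counter

from lncdiscover import SimConfig, generate_bundle

bundle = generate_bundle(SimConfig(seed=1))

print(f"reference genes : {len(bundle.reference)}")
print(f"candidate genes : {len(bundle.candidates)}")

counts = Counter()
for labels in bundle.truth.labels.values():
    for lab in labels:
        if lab in {"planted_novel_lncRNA", "dna_contamination",
                   "pre_mRNA_leftover", "repeat_decoy", "coding_orf",
                   "readthrough"}:
            counts[lab] += 1
print("\nplanted candidate classes:")
for lab, n in sorted(counts.items()):
    print(f"  {lab:22s} {n}")

# Each class is constructed to violate exactly one filter of the
# cascade (or, for the clean lncRNAs, none), so downstream recovery can
# be scored against this truth table.
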