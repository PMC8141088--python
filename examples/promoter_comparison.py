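"""Promoter-capture evidence: compare the candidate ORF's upstream region
with the promoter of a reference gene.

The synthetic CMS insert places the chimeric ORF downstream of a captured
copy of the rpl5 promoter (~99% identity, a couple of substitutions) —
promoter capture is how novel mitochondrial ORFs acquire expression.
"""

from mitoscreen import SimConfig, compare_flanking, simulate

bundle = simulate(SimConfig(seed=5))
truth = bundle.manifest["promoter"]
insert = bundle.derivation.insert_seq

lo, hi = truth["insert_start"] - 1, truth["insert_end"]
query = insert[lo:hi + 3]                       # captured promoter + ATG
gene = bundle.reference.gene(truth["source_gene"])
ref = bundle.reference.promoter(truth["source_gene"]) \
    + bundle.reference.seq[gene.start - 1:gene.start + 2]

cmp = compare_flanking(query, ref, query_anchor=truth["length"] + 1)
print(f"candidate upstream region vs {truth['source_gene']} promoter: "
      f"{cmp.identity_pct}% identity")
for diff in cmp.differences:
    print(f"  {diff.kind} at position {diff.position} from the start codon: "
          f"{diff.ref_base} -> {diff.query_base}")
print("\nNear-identity of the upstream regions means the candidate is "
      f"transcribed from a captured {truth['source_gene']} promoter.")
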