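"""Classify candidate proteins into the five gene families.

Builds one record per family plus its tail annotation and genomic
context, runs the rule table, and prints the label with the rule-by-rule
evidence for one ambiguous case.
"""

from slc_evo.classifier import classify
from slc_evo.features import delineate_tail
from slc_evo.synthetic import (DEFAULT_FAMILY_SPECS, NeighborhoodSpec,
                               balanced_tree, family_reference, family_seed,
                               make_family, make_neighborhood)

CONTEXTS = {
    "VpreB1": (("MIF", "+"), ("CANDIDATE", "-"), ("IGLL1", "-"),
               ("TOP3B", "+")),
    "VpreB2": (("SLC5A1", "+"), ("SLC5A4", "+"), ("CANDIDATE", "-"),
               ("IGL", "+")),
}

references = {
    label: family_reference(spec, family_seed(label, 7))
    for label, spec in DEFAULT_FAMILY_SPECS.items()}

for label, spec in DEFAULT_FAMILY_SPECS.items():
    records, _ = make_family(spec, balanced_tree(4, 0.1),
                             family_seed(label, 7))
    rec = records[0]
    ann = delineate_tail(rec, references[label])
    context = None
    if label in CONTEXTS:
        genes = CONTEXTS[label]
        _, context, _ = make_neighborhood(
            NeighborhoodSpec(gene_order=genes,
                             anchors=(genes[0][0], genes[-1][0])), 0)
    res = classify(rec, tail=ann, context=context, references=references,
                   subject_gene="CANDIDATE")
    print(f"true={label:7s} assigned={res.label:8s} "
          f"passed_rules={res.score}")

print()
print("Evidence trail for one record (VpreB2):")
records, _ = make_family(DEFAULT_FAMILY_SPECS["VpreB2"],
                         balanced_tree(4, 0.1), family_seed("VpreB2", 7))
ann = delineate_tail(records[0], references["VpreB2"])
res = classify(records[0], tail=ann)
for rule, status, detail in res.evidence:
    print(f"  {rule:28s} {status:13s} {detail}")
print(f"-> label without genomic context: {res.label}")
print("This tail's charged count sits strictly inside the VpreB2 range "
      "and only within the\nsoft margin of the VpreB1 range, so the "
      "strict candidate wins without context.\nCounts inside both ranges "
      "(11-12) stay 'unknown' until the gene neighborhood\n(TOP3B vs "
      "SLC5A4/IGL proximity) breaks the tie.")
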