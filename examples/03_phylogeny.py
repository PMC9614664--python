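"""Pairwise identity, neighbor joining and bootstrap support.

Recreates the glires-style situation: a recently duplicated VpreB1 pair
(nearly identical) inside the VpreB1 ortholog clade, far from VpreB2.
The duplicated pair should form a 100%-supported cherry.
"""

import numpy as np

from slc_evo.phylo import (bootstrap_support, clade_support,
                           percent_identity_matrix)
from slc_evo.synthetic import make_duplicate_pair_scenario

records, pair, clade1 = make_duplicate_pair_scenario(seed=2)
ident, ids = percent_identity_matrix(records)

short = [i.replace("VpreB1_", "") for i in ids]
print("pairwise identity (fraction of shared residues, column convention):")
header = "          " + " ".join(f"{s:>10s}" for s in short)
print(header)
for name, row in zip(short, ident):
    print(f"{name:>10s} " + " ".join(f"{v:10.2f}" for v in row))

res = bootstrap_support([r.sequence for r in records], ids,
                        n_replicates=200, seed=0)
print()
print("NJ tree (Newick):", res.newick()[:90], "...")
print(f"bootstrap support, duplicated pair cherry : "
      f"{clade_support(res, pair):.0f}%")
print(f"bootstrap support, full VpreB1-like clade : "
      f"{clade_support(res, clade1):.0f}%")
print()
print("The near-identical duplicate pair (~97% identity) groups inside "
      "the VpreB1 clade\nwith maximal support, while true VpreB2 "
      "sequences (<62% identity) branch separately —\nthe signature of a "
      "recent within-locus duplication rather than an old ortholog.")
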