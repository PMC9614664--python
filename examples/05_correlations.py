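"""CDR H3 extraction and the Spearman correlation battery.

Plants per-species CDR H3 lengths in synthetic junction reads, recovers
them by IMGT-style anchor delimitation, then runs a Spearman test with an
exact small-n p-value and a copula-based rank-structure recovery.
"""

from scipy import stats as sps

from slc_evo.stats import spearman, species_cdrh3_summary
from slc_evo.synthetic import CopulaSpec, make_correlated_table, \
    make_repertoire

lengths = {"human": [8, 10, 12, 14, 16], "mouse": [9, 11, 13],
           "cattle": [12, 45, 58, 61]}
reads, _ = make_repertoire(lengths, seed=6)
summary = species_cdrh3_summary(reads)
print("per-species CDR H3 summary (anchors: 2nd-CYS .. [WF]-G-x-G):")
print(summary.to_string())

x = [6, 9, 13, 18, 22, 35]   # e.g. VpreB2 tail lengths, residues
y = [24, 30, 37, 40, 55, 148]  # e.g. maximum germline DH length, nt
r = spearman(x, y, x_name="vpreb2_tail_len", y_name="dh_max")
print(f"\nspearman({r.x_name}, {r.y_name}): rho={r.rho:.2f} "
      f"p={r.p_value:.4f} (n={r.n}, {r.method})")
print("With n = 6 untied pairs the p-value is exact: every one of the "
      "720 rank\npermutations is enumerated, not approximated.")

df = make_correlated_table(CopulaSpec(n_species=1000, target_rho=0.8,
                                      seed=3))
got = sps.spearmanr(df.x, df.y).statistic
print(f"\ncopula generator: target rho = 0.80, "
      f"recovered rho = {got:.3f} (n = 1000)")
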