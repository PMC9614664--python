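# Methods

`slc_evo` mechanises a comparative analysis of surrogate-light-chain (SLC)
genes — VpreB1, VpreB2, VpreB3, IGLL1 (λ5) and PTCRA — across tetrapod
species: delineating their unique-region "tails", classifying candidate
sequences by motif, charge and genomic context, comparing loci by gene-order
synteny, building pairwise-distance phylogenies, and correlating tail
features with heavy-chain CDR H3 and germline DH lengths. This note records
the models, conventions and numerical choices, and what the synthetic data
do and do not establish.

## Tail delineation

VpreB1/VpreB2 carry a C-terminal unique region; IGLL1 carries an N-terminal
one. No algorithmic definition of the boundary exists in the literature this
package follows, so the boundary is an *annotation*, not an inference: a
curated reference per family stores the boundary index, and a query's
boundary is obtained by globally aligning reference and query (BLOSUM62,
affine gaps, open 11 / extend 1) and mapping the reference boundary column
to the query coordinate. Alignments whose column identity falls below a
configurable floor (default 0.20) are refused rather than projected.
Boundaries are 0-based half-open internally and 1-based inclusive in all
emitted tables; a C-terminal boundary is the index of the first tail
residue, an N-terminal boundary is one past the last.

Because no real curated references ship with the package (the sequences
behind the published per-species tables are external supplementary data),
`slc_evo.synthetic.synthetic_references` provides generator-derived
stand-ins: the exact root sequences the family simulator evolves from,
labelled synthetic. Users with curated proteins supply their own reference
TSV in the same format.

## Charge and isoelectric point

Basic residues are R, K, H; acidic are D, E (the convention used when
highlighting charged tail residues in alignment figures). X counts toward
length but never toward charge.

The isoelectric point is the root of the Henderson–Hasselbalch net charge

    Q(pH) = Σ_basic 1/(1 + 10^(pH − pKa)) − Σ_acidic 1/(1 + 10^(pKa − pH)),

with ionizable side chains D, E, C, Y (acidic) and H, K, R (basic) plus
both free termini (tails are treated as free peptides with termini
included — an explicit, testable convention). Q is strictly decreasing in
pH for any peptide with an ionizable group, so the root is unique;
bisection on [0, 14] converges on interval width 1e−4. Convergence is on
the bracket width rather than |Q| because the charge curve can be nearly
flat when the root lies far from every pKa, making a charge-based stopping
rule less accurate than the bracket itself. Two pKa scales ship:
Bjellqvist (default) and EMBOSS. Point values depend on the scale — which
is why it is recorded in every output row — but all downstream statistics
are rank-based and therefore scale-invariant.

## Family classification

The rule table encodes the curation criteria for each family: VpreB1 — an
elongated C-terminal tail (≥ 10 residues) with 11–15 charged residues and,
where genomic context exists, TOP3B within 5 genes; VpreB2 — a tail with
7–12 charged residues near SLC5A4 or the lambda locus; IGLL1 — the GPRC
motif inside the N-terminal tail window; VpreB3 — the VFPGQ motif within
the first 40 residues and *no* elongated tail; PTCRA — two cysteines with
an intervening tryptophan at positions projected from the curated PTCRA
reference (± 3 columns). Motif matching is exact by default (the motifs are
only 4–5 residues); one mismatch can be allowed by configuration.

Charged-count ranges are soft: a count missing its range by ≤ 2 downgrades
the rule to a warning instead of a failure, since real tails "often", not
always, carry the stated counts. The decision procedure keeps this from
destroying discrimination: sequence-only rules rank each family as a strict
candidate (all rules pass), a soft candidate (pass with warnings) or a
non-candidate, and a unique best-tier candidate is the provisional label.
Genomic context then acts purely as a veto — it can resolve a strict tie
(the VpreB1/VpreB2 charged-count overlap at 11–12) or overturn the
provisional label to "unknown", but never substitutes another family. This
gives the invariant that removing context moves labels only to or from
"unknown". Every evaluated rule leaves an evidence record, and borderline
outcomes surface as warnings rather than silent decisions.

## Synteny

Neighborhoods are ordered, stranded gene lists on one scaffold, with
names normalised through an editable alias table whose defaults encode
known misannotations (Ig Iota → VPREB1, Om / Ig Omega → VPREB2, IGLL3/5/7
→ IGLL1 candidates). Comparisons are anchored: the interval between MIF
(5') and TOP3B (3') inclusive, re-oriented 5'→3' with strand labels
flipped when the scaffold is stored in reverse.

Block calling is greedy maximal-run extension over the order permutation of
shared genes — not a chaining DP — because anchored loci here span tens of
genes and runs suffice. A run extends while matched genes are adjacent on
both sides with consistent strand relation: equal strands in ascending
query order ("same") or flipped strands in descending order ("inverted").
Runs of ≥ `min_block` (default 2) genes are blocks; shorter runs are
singletons; one-sided genes are unplaced; copy-count differences are
duplications. Distances are ordinal gene counts, never base pairs.

Whole-gene edit inference (used to verify planted rearrangements) reads
inversions off inverted runs, duplications and deletions off copy counts,
and translocations as blocks whose removal restores monotone query order.
Moving block X past block Y is mathematically indistinguishable from moving
Y past X, so the smallest removable block is called the moved one; the
benchmark generator therefore plants moves whose jumped-over segment is
strictly larger than the moved span, making recovery exact.

## Pairwise alignment and trees

Global alignment uses the Needleman–Wunsch/Gotoh affine-gap optimum
(BLOSUM62, gap open 11, gap extend 1 by default; a gap of length k costs
open + k·extend). Because "percent of shared residues" is ambiguous, both
conventions are computed per alignment: identical columns over columns
with residues in both rows (primary), and identical columns over the
shorter sequence length.

Trees are neighbor joining on distance matrices, with negative branch
lengths clamped to zero and the clamped deficit logged. NJ is a documented
stand-in for GUI tree builders whose method is unspecified; only
topology-level claims (clade membership, support) are made, never
branch-length claims. Bootstrap support resamples alignment columns with
replacement, rebuilds a p-distance NJ tree per replicate, and reports for
each internal bipartition of the point estimate the percentage of
replicates containing it. Leaves are canonically ordered before
resampling, so support is invariant to input order at a fixed seed. The
pipeline's multiple-row input is produced by pivot ("star") alignment onto
the longest reference — adequate for the closely related, indel-free
synthetic inputs; it is deliberately not a progressive MSA, which is out of
scope.

## CDR H3 and the correlation battery

CDR H3 is delimited IMGT-style: the residues strictly between the conserved
2nd-CYS and the J-region Trp/Phe of the [WF]-G-x-G motif. Full IMGT unique
numbering is out of scope, so the anchors are located lexically: the first
[WF]-G-x-G match downstream of a cysteine, with the last cysteine before
that match taken as the 2nd-CYS. This convention is exact on the synthetic
repertoire (whose CDR segments exclude C/W/F) but can misplace the anchor
on natural cysteine-rich CDR H3 such as bovine ultralong knobs — a known
limitation; anchorless reads are skipped and logged, never guessed.

Spearman's rho is Pearson correlation on tie-corrected average ranks.
Two-sided p-values are exact — full enumeration of the n! rank
permutations, via the cached distribution of Σd² per n — when n ≤ 9 and
the data are untied; ties or larger n route to the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df. Enumeration at n = 9 is 362,880
permutations, done once and cached. Missing values are deleted pairwise,
with n reported per analysis. The battery runs a fixed list of twelve
analyses (tail length vs DH and CDR H3 lengths; tail and whole-protein pI
vs tail length; IGLL1 tail pI vs maximum CDR H3), including first-class
drop-cattle variants, since the ultralong-antibody species dominates two of
the relationships; analyses with < 3 complete pairs are emitted as
"skipped" and constant columns as "degenerate" rather than dropped.
Germline DH lengths default to nucleotides (the unit is recorded); ranks,
hence rho, are unit-invariant when consistent.

## Synthetic data: what it emulates, and what passing tests show

The generator produces (i) protein families — an immunoglobulin-like core
with optional diagnostic motif and conserved sites, plus a charged tail —
evolved along a Newick tree by per-site substitutions with probability
1 − exp(−rate·t) per branch; (ii) gene neighborhoods with planted
inversions, translocations, duplications and deletions plus an edit log;
(iii) junction reads with planted CDR H3 lengths; (iv) two-column tables
with a prescribed Spearman correlation through a Gaussian copula (latent
Pearson r = 2·sin(πρ/6), the exact inverse of the normal-copula Spearman
map; |ρ| = 1 short-circuits to a co-/anti-monotone transform).

Hard constraints, by construction rather than expectation: motif and
conserved-site positions are never substituted unless `motif_decay` is set,
and tail substitutions stay within charge class (basic↔basic,
acidic↔acidic, neutral↔neutral), so generated tails always satisfy their
spec's charged-count range. Identical (spec, seed) inputs give identical
outputs.

Default family parameters are the study conditions: VpreB1 tails 16–38
residues with 11–15 charged; VpreB2 tails with 7–12 charged; VpreB3 with
VFPGQ near the N-terminus and essentially no tail; IGLL1 with GPRC inside a
basic-biased N-terminal tail; PTCRA with the Cys/Trp/Cys scaffold as
conserved sites. Tail charge bias defaults to 0.4 basic for VpreB (most
VpreB1 tails are acidic) and 0.7 for IGLL1 (its N-terminal tail is
positively charged); core length ~115 residues approximates an Ig V
domain. Where a quantitative value was not dictated by the study
conditions (core lengths, IGLL1 charged range, neighborhood gene sizes),
one realistic value was chosen and fixed.

What the generator does *not* emulate: indels (tail length is fixed along
one family's tree, so per-species tail-length variation must come from
separate family draws or the copula generator — in the bundled demo the
tail-length correlation analyses are honestly reported "degenerate");
rate heterogeneity across sites; nucleotide-level evolution; real
immunoglobulin domain architecture. Passing tests therefore establish the
*mechanics* — boundary projection, rule logic, block calling, statistic
computation — under controlled conditions, not performance on real genomes
with fragmented assemblies, misannotations beyond the alias table, or
borderline sequences that required expert judgment in the original
curation.

## Benchmark and test problem sizes

Chosen to make each check decisive while keeping the whole suite fast: pI
solver vs an exhaustive 0.0005-pH-step grid on 1,000 random 30-mers
(agreement within 0.001 pH); aligner vs enumeration of every global
alignment on 300 random pairs of length ≤ 6 over a 4-letter alphabet
(score-identical); Spearman exact-vs-t calibration over 500 untied draws
at n = 9 (≤ 0.02) and exact type-I error by full enumeration for n ≤ 7
(≤ nominal); classifier on 5 families × 20 leaves at substitution rate 0.1
(macro accuracy ≥ 0.95, confusion confined to the charged-count overlap);
synteny recovery on 100 seeded single-edit draws (exact); bootstrap with
200 replicates on the duplicated-pair scenario (cherry support ≥ 90);
copula recovery at n = 1,000 for ρ ∈ {−0.3, 0.6, 0.8} (± 0.05, about 1.6
standard errors at this n). `scripts/acceptance.py` recomputes all of
these from a caller-supplied seed.

## Known limitations

* Tail boundaries are only as good as the curated reference and the
  pairwise alignment; highly diverged tails near the identity floor can
  project a boundary a few residues off (the synthetic benchmark allows
  ± 1).
* The pivot alignment used for bootstrap columns discards insertions
  relative to the pivot; with gappy, distantly related inputs a real MSA
  should be supplied instead.
* The CDR H3 anchor heuristic assumes a cysteine-free CDR (see above).
* Printed pI values depend on the pKa scale; cross-study point comparisons
  must match scales, though rank statistics do not.
* The classifier mechanises criteria that were originally applied with
  expert judgment; borderline genomic cases (fragmented scaffolds, aliased
  annotations) yield warnings and "unknown", not forced calls.
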