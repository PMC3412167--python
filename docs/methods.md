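# Methods

`gelpkit` re-implements, as one tested pipeline, the multi-stage genome
survey used to characterize large plant hydrolase families of the GDSL
esterase/lipase (SGNH) kind: profile-based family identification,
genomic-organization analysis, ZOOPS motif discovery, a conserved-block
neighbour-joining phylogeny with bootstrap, subclade-specific motif
classification with structural loop mapping, and ddCT expression
quantification. Every stage is exercised against a synthetic family
generator with machine-readable ground truth, so each claim the pipeline
makes has a recovery test with a known answer.

## The synthetic family generator

The generator emulates the salient statistical structure of a divergent
SGNH-type family:

* **True phylogeny.** A Yule (pure-birth) tree with unit speciation rate
  and the requested number of tips (default 24). Branch lengths are
  exponential waiting times; leaf labels are `fam001..famN`.
* **Proteins.** Each protein is an alternation of conserved blocks and
  divergent linkers. Blocks (default 4 blocks of 10 residues) evolve with
  a fixed per-branch per-site substitution probability (`block_sub_prob`,
  default 0.02) under uniform replacement over the 19 alternative
  residues; this "per-edge" clock makes every branch equally visible to
  distance methods regardless of its length. Catalytic residues — Ser in
  block I, Gly in II, Asn in III, and the DxxH Asp/His pair in block V —
  are planted at fixed offsets and held invariant, emulating their strict
  conservation in the real family.
* **Linkers.** Inter-block linkers (default 20–30 residues) substitute at
  0.5 per site per branch with occasional geometric-length indels clamped
  to the configured range. The high rate is deliberate: the real family's
  inter-block regions are effectively unalignable across the family, and
  lower rates leave family-wide linker conservation that shows up as
  extra universal motifs.
* **Planted clade motifs.** Leaf sets are partitioned into clades by
  greedy balanced edge-cuts of the unrooted true topology (see below);
  each planted motif's exact consensus is inserted mid-linker into every
  leaf of its target clade only. Consensus strings are repeat-free and
  drawn from pairwise-disjoint residue sets (defaults WYHKQFM, CRGPLIV,
  ATSNED): two deterministic signals sharing even a couple of aligned
  residues give a zero-or-one-per-sequence search a foothold to merge
  them into one bimodal mixture PWM, which would make the planted
  signals unidentifiable by construction rather than by any failure of
  the method.
* **Genome layout.** Family genes and single-exon decoy genes are placed
  on chromosomes so that planted clusters have exactly the configured
  intervening decoy counts, tandem arrays are adjacent placements of the
  most recently diverged subtrees (so member similarity follows from the
  tree, as in real tandem duplicates), and segmental pairs sit on
  distinct chromosomes within 50 kb of decoy anchor genes recorded in the
  collinear-anchor table. Planted features are isolated by six decoys so
  no spurious clusters arise; cluster specs use at least two intervening
  genes so planted clusters are not also trivially tandem.
* **Expression.** For each gene with a planted fold f, the treated target
  CT sits log2(f) cycles below the control CT; reference CT is constant.
  Gaussian CT noise (default sd 0.1 cycles) and three replicates per
  condition mirror ordinary qPCR practice. At zero noise the ddCT
  quantification inverts the model exactly.

One master seed drives everything; each stage derives a child seed by
hashing its stage name, so stages are independently reproducible.

What the generator does **not** emulate: realistic amino-acid exchange
matrices or rate heterogeneity, codon-level evolution, gene
conversion between tandem copies, genuine repeat-element sequence, or
amplification-efficiency artifacts in qPCR. Passing recovery tests
therefore demonstrate the pipeline's correctness on data satisfying its
model assumptions, not robustness to every artifact of real surveys.

## Family identification

Each conserved block of a seed alignment becomes a position weight
matrix ((count + 0.01)/(n + 0.2) per column); the background is the seed
residue composition interpolated 3:1 with uniform, because a small seed
otherwise assigns unseen residues near-zero frequency and mismatches to
them would score *positively*.

A candidate protein is scanned by dynamic programming for the best
chained placement of all blocks in canonical order (I < II < III < V)
without overlap. The reported bit score is, for each placed block, the
log2 *marginal* likelihood ratio within the window range compatible with
the chain under a uniform placement prior — a forward-style score — and
the total is their exact sum. This choice matters: a max-placement score
concentrates random proteins near zero (best-of-L selection bias), while
the marginal score charges the placement entropy, putting uniform-random
decoys near −110 bits and true members near +130, so the family's
literature gathering cutoff (−69.0, applied to our bit score) genuinely
separates members from non-members. Empirical E-values come from
composition-preserving shuffles, E = (exceedances + 1)/(n + 1), and are
uniform on null proteins by construction (verified by a calibration
test); they are not comparable to database HMM E-values. Acceptance
requires E < 0.1, score > −69.0 and length > 100 residues, with an
explicit exclusion list; the rejection ledger records the first failing
rule in that order. Catalytic Ser/Gly/Asn/His and the DxxH pattern (Asp
exactly three positions before the His) are verified at the profile's
offsets. Accepted genes are named `<prefix>1..N` by chromosome, then
start coordinate, ties by gene id.

## Genomic organization

Clusters are maximal runs of two or more family genes separated by at
most 4 unrelated annotated genes (TE-related genes count as intervening).
Tandem groups are within-cluster runs with at most one intervening gene
and block p-distance ≤ 0.6 — a reconstruction of the usual
database-curated criterion, with both thresholds exposed. Segmental
pairs are family genes lying within 500 kb of the two sides of one
collinear anchor block; synteny itself is consumed, not inferred.
Exon/intron statistics treat introns as the gaps between sorted exons
(lengths always summing, with exons, to the genomic span); repeats
(BED, converted to 1-based closed on read) count in any of
exon/intron/5'UTR/3'UTR they overlap by ≥ 1 bp, with junction-spanning
repeats counted in both regions and exonic regions excluding the UTR
portions so the four classes are disjoint.

## ZOOPS motif discovery

The occurrence model is zero-or-one-per-sequence: with prior γ a
sequence carries the motif at a uniformly chosen position. EM alternates
occurrence posteriors with PWM/γ re-estimation (pseudocount 0.01);
convergence is declared when the MAP objective (log-likelihood plus the
Dirichlet pseudocount prior) improves by less than 1e-6, capped at 200
iterations, and any decrease of that objective raises immediately — the
EM guarantee is a hard assertion in production code, not only in tests.

Discovery seeds EM from every distinct data k-mer (deterministically
subsampled to 400 when more exist), one iteration each, then runs the
best seed to convergence; this is done for every width 6–15. Each
width's converged model receives an empirical E-value from a
within-sequence shuffle null in which the same seeding effort is spent
on the shuffled data (an asymmetric search would systematically favour
the observed fit) and residues are permuted among unmasked positions
only, preserving the window structure of erased sequences. The accepted
width minimizes (E-value, then −LLR, then −width); since acceptance at
the 0.05 raw-exceedance threshold requires zero null exceedances with 20
shuffles, widths are evaluated in descending-LLR order and a width's
null loop stops at its first exceedance — an exact shortcut for the
same argmin. The reported E-value carries a Bonferroni factor for the
ten widths tried.

Accepted motifs are trimmed: edge columns with under 2 bits of
information are dropped (never below width 6) and the trimmed model
re-converged. Wide EM fits routinely drag in flanking columns that are
small-sample noise; untrimmed, those columns cause two concrete
failures — erasure bites into neighbouring sequence, clipping motifs
discovered later, and the noisy columns attract spurious occurrences
that contaminate specificity calls and block alignments. Occurrences
(posterior > 0.5, at most one per sequence) are then masked with a
sentinel that scores as background, and discovery repeats up to 45
motifs or until no width achieves zero exceedances. Termini are searched
by default; a `trim_termini` flag can mask them first.

## Conserved-block phylogeny

Motifs covering ≥ 95% of sequences whose pairwise order never flips in
any sequence are selected greedily (coverage, then E-value) and ordered
by mean start; sequences missing any selected block are excluded as
gap-rich, with their missing lists reported. Because blocks are cut at
motif occurrences, the concatenated alignment is ungapped by
construction — the full progressive alignment the original tools used is
deliberately bypassed, since only the conserved regions are informative.
With long blocks (wider than the 15-residue motif cap) a single block is
legitimately represented by several adjacent motifs, as in the original
survey's 13 blocks ↔ 23 motifs.

Distances are mismatch fractions p, optionally Poisson (−ln(1−p)) or the
Kimura protein correction (−ln(1 − p − 0.2p²), the default, with an
explicit error at its divergence pole p ≈ 0.854). Neighbour joining is
the Saitou–Nei Q-criterion agglomeration with ties broken by the
smallest working-matrix index pair and negative branch estimates clamped
to zero and counted; it is exact on additive matrices (topology and
branch lengths), which the tests verify directly and against an
independent implementation. Bootstrap resamples columns with
replacement, re-infers per replicate, and annotates each internal split
of the point tree with its replicate percentage; rows are canonically
ordered first so supports are invariant to caller row order, and the
Newick writer hides supports below 50 as a display convention.

Subclades come in three modes. Curated leaf groups are verified for
(unrooted) monophyly and never silently accepted. The balanced mode cuts
the unrooted topology into k parts by greedily removing the edge that
best splits the largest part (ties by the smaller side's sorted leaf
labels — a criterion depending only on topology and labels); the
generator defines its true clades with the same function, so identical
topologies yield identical partitions. The default automatic mode takes
the outermost clades with support ≥ 50 and ≥ 2 leaves under a midpoint
rooting convention.

## Specificity and loop mapping

A motif is *common* when carried by ≥ 90% of retained proteins,
*specific* when all carriers fall in 1–3 subclades with ≥ 2 carriers in
each (a carrier outside any subclade blocks the call), else
*nonspecific*; precedence is common > specific > nonspecific. Topology
strings over {H, E, C} are parsed into helices, strands and loops
numbered N→C; an occurrence is assigned to every element it overlaps by
one residue, and loops carrying any subclade-specific motif are flagged
— the mapping logic behind "the most divergent loops", with the 3-D
modelling itself out of scope.

## Expression

ddCT averages replicate CT values per condition, differences target
minus reference and treated minus control, and reports 2^(−ddCT) with
the pooled replicate SD of the per-replicate dCT (already a log2-scale
quantity). No efficiency correction is applied. Regulation calls use the
2-fold rule (up if fold > 2, down if < 0.5); concordance between
platforms is agreement of direction calls at the cutoff; the evidence
matrix marks a gene × tissue cell present when ≥ 1 record (EST,
FL-cDNA, MPSS or microarray) supports it, against a fixed tissue
vocabulary.

## Study conditions and problem sizes

Recovery is demonstrated at two generator settings, chosen once:

* **Exact-recovery condition** — 24 members, 4 × 10-residue blocks,
  `block_sub_prob = 0`, 3 planted clade motifs, 50 decoys, CT noise 0.
  Here membership (24/24 accepted, 50/50 decoys rejected), planted-motif
  consensus identity (≥ 90%), selection of exactly the 4 universal
  blocks, clade-specificity of each planted motif against the curated
  clade labels, and exact fold recovery are all asserted.
* **Informative conserved core** — the same family with 4 × 30-residue
  blocks at `block_sub_prob = 0.08`. A perfectly conserved core is a
  constant alignment and carries no phylogenetic signal whatsoever, so
  topology recovery is necessarily tested where substitutions witness
  every internal edge: with ~120 block columns at 0.08 per branch the
  probability that some internal edge of a 24-taxon tree goes unwitnessed
  is below 0.1%. Under this condition a handful of members are excluded
  as gap-rich (missing a selected block piece), exactly as the original
  survey dropped 18 of 114 genes from its tree; the discovery-driven
  pipeline's tree is asserted to equal the true topology restricted to
  the retained leaves (Robinson–Foulds 0, with at least 19 of 24
  members retained).

Unit and property tests use 8–12-taxon families, 100-replicate
bootstraps and 10-seed replicates; these sizes make the full suite and
the acceptance script complete in a few minutes while leaving every
assertion exact.

## Known limitations

* Empirical shuffle E-values have a resolution floor of 1/(n+1) and are
  not comparable to Pfam/MEME analytic E-values; published database
  E-value magnitudes (down to 1e-966) are out of reach by design.
* The ZOOPS search can in principle lock onto mixture optima when two
  planted signals share enough aligned columns; trimming and the
  seeding heuristic mitigate but do not eliminate this.
* Tandem criteria are a reconstruction (adjacency + distance cutoff),
  not the original database's rule.
* The cluster rule reproduces the ≤ 4-intervening-genes definition only;
  published cluster roman-numeral boundaries involve unstated curation.
* With only three clades, the "1–3 subclades" exclusivity rule is weak
  (any non-common motif with ≥ 2 carriers per clade qualifies); it
  becomes discriminative at the original survey's ~12 subclades.
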