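# Methods

This package implements the comparison machinery used to evaluate
protein-coding mitochondrial loci (cytochrome *b*, COI) as species
identification markers: per-site conservation, a pairwise distance
suite, threshold-based species discrimination, and tree-vs-taxonomy
congruence, exercised end to end on synthetic data with known truth.

## Conservation (R_s)

Variation at each aligned site is summarised as
`R_s = 2 − H`, where `H = −Σ_b p_b log2 p_b` over the four bases with
`p_b > 0`. A site where all sequences agree carries the full
log2 4 = 2 bits; a site with all four bases equally frequent carries 0.

Heteroplasmic positions (IUPAC ambiguity codes) count toward the number
of sequences at a site but toward no base, so 99 A plus one A/G out of
100 sequences scores as 99% A and 0% C, G, T. We deliberately do **not**
renormalise the frequencies to sum to one: the worked rule above implies
the unrenormalised form, and renormalising would change R_s at every
heteroplasmic site. Gaps are handled by the same rule; this keeps
Σp ≤ 1 and the frequencies monotone in the counts. A consequence worth
knowing: a column consisting *only* of gaps/ambiguities degenerates to
R_s = 2; such columns do not occur after complete deletion and are
vacuous in practice. No small-sample (Schneider–Stephens style)
correction to H is applied; the statistic is reported raw.

Sliding-window identity over a window of X sites is
`Σ R_s / (2X)` — 1.0 for a fully conserved window. Windows advance one
site at a time and are reported by 1-based start coordinate. The default
sizes 101, 401 and 601 bp reflect typical sequencing fragment sizes for
the two loci. A site is *variable* when at least two distinct
unambiguous bases occur; *singleton-variable* when exactly one sequence
carries the minority base.

## Distances

All distances operate on a complete-deletion alignment: every column
containing a gap or ambiguity in any sequence is removed for all
sequences (the convention of the standard tree packages; pairwise
deletion is available as a non-default option). Column provenance is
retained so codon-position masks can be re-derived on the filtered
coordinates — without this the frame would silently shift at the first
deleted column. For dS/dN a codon-wise variant removes whole codons, so
the reading frame is always preserved.

- **p-distance** — proportion of differing sites over a site subset
  (all, or one codon position).
- **K2P** — with observed transition proportion P and transversion
  proportion Q, `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`. Pairs with
  `1−2P−Q ≤ 0` or `1−2Q ≤ 0` are *saturated*: they raise a flagged
  error in scalar form, are stored as NaN in matrices, and summaries
  report the exclusion count rather than an infinity.
- **Nei–Gojobori dS/dN** — vertebrate mitochondrial code (AGA/AGG/TAA/
  TAG stops, ATA Met, TGA Trp; taken from Biopython's table 2).
  Synonymous site counts per codon are the fractions of the three
  single-base alternatives per position preserving the amino acid;
  changes to stop codons count as non-synonymous in the denominators.
  Differences between codons are averaged over all orderings of the
  single-base steps, excluding pathways through stops; if every pathway
  is blocked the pair is a flagged error. dS = Σsd / mean(S₁,S₂) and
  dN = Σnd / mean(N₁,N₂) are the *p-distance* flavour (no Jukes–Cantor
  correction), so dS can exceed 1 on very short sequences. At matrix
  level, codons that are stops in either sequence are skipped (evolved
  sequences can contain them even when the ancestral sequence did not).

Distances are stored unscaled (substitutions/site); the conventional
×100 presentation is a formatting flag. Bootstrap standard errors
resample alignment columns (codon triplets for dS/dN) with replacement,
recompute the overall mean distance per replicate, and report the
standard deviation across replicates; 1,000 replicates by default, seed
required.

## Discrimination

Pairs are labelled same/different species after collapsing named
subspecies onto their species, so two conspecific subspecies samples
form a same-species pair. A pair is called positive when its K2P (×100)
falls **strictly below** the threshold; a value exactly at the threshold
is negative. The wording "below"/"greater than" leaves equality
undefined, so strictness is a documented, configurable choice; with
continuous distances it almost never matters.

From the 2×2 table (n_AB true positives, n_aB false positives, n_Ab
false negatives, n_ab true negatives): fp rate = n_aB/n_a, fn rate =
n_Ab/n_A, sensitivity = n_AB/n_A, specificity = n_ab/n_a, PPV =
n_AB/n_B, NPV = n_ab/n_b. A zero denominator yields an explicit
undefined marker, not an exception. The candidate thresholds 1.5, 2.0
and 2.5 (K2P ×100) bracket the barcoding gap between intraspecific and
interspecific divergences.

The ROC curve sweeps the threshold over all observed distances with
smaller values indicating a positive; the trapezoid AUC equals the
Mann–Whitney U-statistic with ties counted one half (verified against a
brute-force double loop and scikit-learn), and its standard error uses
the Hanley–McNeil non-parametric formula. Exact duplicate sequences can
be removed before the combined analysis (one representative per
identical sequence, first occurrence kept).

## Neighbor-Joining and congruence

NJ is the classic Saitou–Nei agglomeration with the Studier–Keppler
Q-criterion. Ties in Q break deterministically at the lowest (row,
column) index pair. Negative branch-length estimates are clamped to
zero with the deficit moved to the sibling edge, preserving the joined
pair's summed length. The output is an unrooted binary tree; on any
additive matrix the generating topology and branch lengths are
recovered exactly (property-tested against randomized 4–8 taxon trees
and cross-checked against scikit-bio's implementation).

Congruence at a rank scores each taxonomic group by its largest *pure*
bipartition side: an edge side containing group members and nobody
else, both orientations of every edge considered (unrooted semantics —
equal to rooted clade semantics under any root outside the group). A
group spanning the entire tree is trivially monophyletic; singleton
groups score 100%. Where a group is split into several fragments only
the largest pure fragment counts — alternatives (summing all pure
fragments) exist, but no published formula forces either choice and the
max-fragment rule is the stricter one. Two accounting variants: the
per-sample variant scores every sample; the species-collapsed variant
first prunes the tree to the first-listed sample of each collapsed
species. The overall percentage at a rank is correctly-grouped members
summed over groups divided by total members.

## Synthetic data

The generator emulates the features the analysis relies on, with known
truth:

- a balanced ranked taxonomy realised as an ultrametric species tree.
  Rank-boundary node heights, in units of half the interspecific depth,
  are 1.0 (family node, splitting species within a family), 1.6
  (order), 2.2 (superorder), 2.8 (root); within-species MRCAs sit at
  half the intraspecific depth. Two congeners thus diverge by exactly
  `inter_depth` and conspecifics by `intra_depth`;
- K2P sequence evolution sampled from the exact branch transition
  probabilities (not discrete mutation events), so the expected
  estimated distance between two tips equals their path length — true
  distances are additive on the tree by construction;
- codon-position rate heterogeneity as per-position branch-length
  multipliers (default 0.7 / 0.2 / 2.1, mean 1), a crude but sufficient
  device to reproduce the 3rd > 1st > 2nd ordering without a codon
  model. A `third_position_transitions_only` flag confines change to
  third-position transitions, creating dS ≫ dN structure for the
  synonymous/non-synonymous analyses;
- root sequences uniform over codons excluding in-frame stops
  (subsequent evolution may still create stops — handled leniently
  downstream);
- rare heteroplasmy injected as two-base IUPAC codes at a configurable
  per-cell rate (≤ 1%).

Default study conditions mirror a mammalian mitochondrial gene:
`intra_depth = 0.003` and `inter_depth = 0.12` substitutions/site with
the rank scaling above put intraspecific K2P (×100) around 0.3 with a
maximum well below 1.5, and interspecific values in the ~10–34 band
(mean in the low-to-high twenties), i.e. a clean barcoding gap;
`kappa = 8` reflects the strong mitochondrial transition bias. All
randomness flows from a single seed through named per-operation
generator streams (CRC-tagged `SeedSequence` spawns).

What the generator does *not* emulate: coalescent population structure
within species, indels and alignment error, base-composition bias,
among-site rate variation beyond the three position classes, and
lineage-specific rate differences. Passing tests therefore demonstrate
the correctness of the machinery under the model's assumptions, not the
field behaviour of the loci on real GenBank data.

## Numerical and scale choices

Problem sizes in the tests and the acceptance script are chosen to keep
the full run in the minutes range on one core: the end-to-end study
uses 2 superorders × 2 orders × 2 families × 3 species × 2 samples
(48 sequences, 1,500 bp, intra 0.003 / inter 0.08), which is large
enough that the gap, perfect discrimination at all three thresholds,
AUC = 1 and 100% congruence at every rank are all structurally forced
rather than lucky; parameter-recovery runs use 100 replicates of a
9,999-bp two-sequence simulation at true distance 0.2. The analysis
drivers simulate a 1,140-bp fast locus and a 1,542-bp slower locus
(matching the two real gene lengths) with 1,000 bootstrap replicates.

Known limitations: the NJ implementation is O(n³) pure NumPy and
comfortable to a few hundred taxa, not thousands; saturated K2P pairs
are excluded from summary means rather than imputed; dS/dN at matrix
level silently skips stop-containing codons (counts of skips are not
reported per pair); congruence of very large groups is bounded by the
O(#edges × #leaves) bipartition sweep.
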