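# Methods

This note documents the models and procedures implemented in crystkit, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## Sequence dataset and composition

A crystallin dataset is a list of `SequenceRecord`s (protein or CDS).  The
inclusion filter stands in for the biological criterion of "complete
double-Greek-key domains", for which no algorithm exists: a length window
(default 80–200 residues, covering the single-domain tunicate βγ-crystallin
at 84 residues and the full-length two-domain γ-crystallins at ~174–183)
plus name-pattern exclusions for non-lens homologs such as
absent-in-melanoma-1.  The window is configurable because any fixed
threshold for "truncated" is a judgement call.

Composition counting follows the maturation convention for eukaryotic
proteins: the initiator Met is cleaved post-translationally, so with
`mature=True` position 1 is excluded when counting Met.  Percentage
denominators use the full stored length, and percentages are rounded
half-to-even to one decimal — the combination under which every cell of the
packaged census is internally consistent (count/length reproduces the
printed percentage) and the subfamily averages reproduce exactly.  Group
averages are unweighted arithmetic means of member percentages.  The
packaged census has 42 proteins in four contiguous subfamily blocks
(4 ancestral βγ-like, 11 γS, 16 γD-like, 11 γM); block membership follows
the published table order, which places the shark γS1/γS2 and zebrafish
γS3/γS4 entries in the γD-like block — consistent with the observation that
those sequences cluster with γD-crystallins despite their names.  One cell
of the source table prints a Cys percentage (2.4 for *Xenopus laevis*
γ-crystallin 3) that contradicts its own count and length (6/175 = 3.4);
the fixture stores the arithmetic value and the loader enforces
self-consistency for every row.

## Refractivity

Protein dn/dc is the additive Gladstone–Dale model: the mass-fraction
weighted mean of per-residue refractive index increments, with residue
masses taken as free amino acid minus one water.  The per-residue table is
the standard literature compilation (McMeekin's values as tabulated by
Zhao, Brown & Schuck 2011) and ships as a TSV so it can be swapped; the
model itself only assumes additivity.  Known limitation: additivity ignores
hydration differences and interactions between aromatic pairs, which in
lens crystallins cause the model to underestimate measured refractivity.  A
hook for an additive aromatic-pair term (user-supplied coefficient,
sequence-window pair counting, default off) is provided, but no published
functional form ships with the package.

## Alignment and identity clustering

`nw_align` is Needleman–Wunsch with Gotoh's three-matrix affine-gap
recursion.  A gap of length L costs `gap_open + gap_extend·(L−1)`; defaults
are BLOSUM62 with gap open 10 and extend 0.5 (Clustal-like), configurable
because the original analysis did not publish alignment parameters.
Traceback is deterministic with tie-break diagonal > up > left.  Percent
identity defaults to identities over mutually ungapped columns; two
alternatives (over alignment length, over the shorter sequence) are
selectable since percent-identity conventions differ between tools.
Dissimilarity is 100 − PID, computed all-vs-all.

The progressive multiple aligner follows a UPGMA guide tree built from the
pairwise dissimilarity matrix (scipy average-linkage on the same matrix)
and merges profiles with the same affine-gap recursion, scoring column
pairs by frequency-weighted substitution scores with gaps contributing
zero.  It is a re-implementation of the progressive strategy in spirit, not
a clone of any specific aligner, so cluster-level structure — not exact
column placement — is the reproducible surface.

Conservation logos use information content `log2(20) − H` per column, with
gaps excluded from the frequency normalisation and columns over 50 % gaps
flagged; letter height is frequency × information, with no small-sample
correction.  Note that adding a duplicate of an arbitrary row can *raise* a
column's entropy (duplicating a minority residue flattens nothing); the
monotonicity property that does hold, and that the tests assert, is that
duplicating the column-consensus row never decreases information.

## Hierarchical clustering (ward.D2)

`ward_cluster` applies the Lance–Williams update to squared dissimilarities,

    d(k, i∪j)² = [(nᵢ+nₖ)d(k,i)² + (nⱼ+nₖ)d(k,j)² − nₖ d(i,j)²] / (nᵢ+nⱼ+nₖ),

with merge height the unsquared distance at merge — the ward.D2 criterion
of R's `hclust`, which operates directly on a dissimilarity matrix rather
than on coordinates.  Ties break on the lexicographically smallest pair of
cluster representative labels, making the merge sequence deterministic.
Cutting at k removes the k−1 highest merges.  Correctness is checked two
ways: a from-scratch recursive Lance–Williams oracle with greedy selection,
and scipy's independent ward implementation.

## Codon-level phylogenetics

Coding sequences are aligned by back-threading each CDS through the protein
alignment (one codon per amino-acid column, `---` for gaps), which
guarantees codon integrity without re-aligning nucleotides.  Distances are
p-distance or JC69 (`d = −(3/4)·ln(1 − 4p/3)`), with pairwise deletion of
columns containing a gap or ambiguity in either row of the pair; JC69 is
undefined at p ≥ 0.75 and such pairs are flagged rather than silently
clamped.  The Maximum Composite Likelihood distance used by MEGA in the
original analysis is not re-implemented — its estimation machinery is out
of proportion to its role here — so JC69 (default) and p-distance stand in;
published branch lengths are therefore not expected to reproduce, and
topology-level properties are what the tests assert.

`nj_tree` is Saitou–Nei Neighbor-Joining with the standard Q-criterion and
branch-length formulas, deterministic label-order tie-breaks, and negative
branch-length estimates clamped to zero for output (raw values kept on the
node).  NJ is exact on additive matrices, and the test suite verifies exact
topology and branch-length recovery on random additive matrices.

Bootstrap supports resample alignment units with replacement — codon
triples by default, since the alignment is codon-based; single columns
optionally — rebuild the NJ tree per replicate, and report for each
internal edge of the full-data tree the percentage of replicates containing
the same bipartition.  A seed is mandatory.

## Cysteine solvent exposure

SASA is Shrake–Rupley: each atom's extended sphere (van der Waals radius +
probe) carries a deterministic golden-spiral lattice of test points; points
inside any neighbour's extended sphere are occluded.  Defaults: probe
1.4 Å, 960 points (isolated-sphere error < 0.1 %, two-sphere error < 0.5 %
against the closed-form cap solution), radii C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20, P 1.80 Å, all swappable.  Multi-model (NMR) files use model
1; alternate locations resolve to highest occupancy.  Residue numbering is
the UniProt convention (Met1 counted) throughout.

The exposure statistic sums whole-residue Cys SASA per domain: N-terminal
domain = residue number ≤ boundary, C-terminal > boundary (side-chain-only
summation is selectable).  The boundary is user-supplied per protein, with
the chain midpoint as fallback.  The buried-control baseline is the mean
and sample SD, across the structure set, of the SASA of a designated
conserved buried Cys (C83 of human γS is the canonical choice); structures
without a control are excluded from the baseline and reported.  A domain is
exposed iff its sum is strictly greater than mean + 1·SD (multiplier
configurable), giving classes NTD / CTD / both / neither; the exclusivity
tally flags "both" classifications as exceptions to the
one-exposed-site-per-molecule pattern.

## Motif classification

The γS-diagnostic Asp-Cys repeat is counted as non-overlapping "DC"
occurrences within the N-terminal window (default 90 residues, covering the
NTD of a ~174–183-residue γ-crystallin).  "DCDCDC" counts three pairs.
γS-like requires ≥ 2 pairs (configurable, since the published wording — "at
least two of these DC pairs" — pins the threshold only loosely); below
threshold, sequences of at least 140 residues (long enough for both
domains) call γD-like and shorter ones are left unclassified.

## Synthetic data: what it emulates and what it does not

`gen_family` evolves an ancestor down a random binary tree.  The ancestor
is built with *exact* target Cys/Met counts (then shuffled) rather than
i.i.d. draws, because the family's mean composition tracks the single
ancestor closely and an i.i.d. draw would miss a ±1-percentage-point target
at realistic lengths.  Substitutions are drawn from the target composition
(preserving it in expectation); indels, when enabled, are 3-residue events
placed on 10-residue block boundaries to mimic indels confined to
inter-domain linkers.  Defaults (length 174 ± 5, 4 % Cys, 3 % Met, 2 %
substitutions per site per branch) follow the composition regime of
full-length γ-crystallins; a 10 % Met setting emulates the γM regime.  The
process is deliberately not a named evolutionary model: it supports
alignment/clustering/composition tests, not inference about real
substitution dynamics, and passing tests say nothing about HMM-quality
alignment of remote homologs.

`gen_cds_for` chooses uniformly among synonymous codons of the standard
code.  `gen_additive_matrix` emits a random topology with uniform branch
lengths in [0.01, 1] and its exact path-length matrix.  `gen_structure`
emits single atoms and sphere pairs (analytic SASA), cysteines buried
inside dense carbon shells or left exposed, and an ideal-helix CA trace;
`gen_exposure_cohort` combines buried/exposed cysteines at residues 10 and
110 with an always-buried control at residue 50 (boundary 60), cycling the
four exposure classes.  These are geometric toys, not protein folds.

## Problem sizes and numerical choices

The test suite and the acceptance script use scaled problem sizes chosen as
adequate for the properties they check: 50 random additive matrices
(4–12 leaves) for NJ recovery, 200 random matrices (n ≤ 6) for ward
agreement, 200 short pairs for alignment-vs-enumeration, 50-atom clusters
for the Monte-Carlo SASA cross-check, 8-structure cohorts for exposure
recovery, and 8–20-sequence families for pipeline and calibration checks.
Floating-point comparisons use 1e−9 absolute tolerance where exactness is
mathematically guaranteed (NJ on additive input) and stated percentage
tolerances where the check is numerical (1 % closed-form SASA, 2 %
Monte-Carlo).  All randomness flows through `numpy.random.default_rng`
with explicit seeds; reruns are bit-identical, and the pipeline echoes its
configuration and logs a checksum per output file.

## Known limitations

- Percent-identity clustering reproduces subfamily-level structure, not the
  exact merge heights of any particular aligner's output.
- JC69/p-distance substitute for Maximum Composite Likelihood; branch
  lengths are not comparable to MEGA's.
- The Gladstone–Dale model underestimates crystallin refractivity; the
  aromatic-pair correction is a hook, not a calibrated model.
- Greek-key domain completeness is approximated by sequence length.
- UniProt retrieval is opt-in and network-gated; all shipped analyses run
  offline from the packaged census and generators.
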