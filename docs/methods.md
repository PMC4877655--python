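# Methods

This note documents the models and procedures implemented in `ladderlens`,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic generators do and do not capture about real receptor data. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## LRR module detection

An LRR module's concave face carries the 11-position template
`LxxLxLxxN/CxL`. A window is scored with one unit weight per constrained
position: positions 1, 4, 6 and 11 score when hydrophobic (the set
{L, I, V, F, M}), and position 9 — the ladder position — scores fully for
{N, C} and half for {T, S}, the hydrogen-donating substitutes seen in intact
ladders. `x` positions contribute nothing, so the maximum score is 5.0 and
the default acceptance threshold is 3.0. The ladder residue is *recorded*
but not *required*: TD/TTD ectodomains have substituted ladders, and
demanding N/C would make broken ladders undetectable by construction.

Candidate windows at or above threshold are chained by dynamic programming
into the maximum-total-score set whose consecutive motif starts are spaced
within the module-length window [20, 30] (canonical length 24). Ties are
broken toward more modules, then lexicographically smallest start tuples,
making the scan deterministic. Each module spans from its motif start to one
residue before the next module's start; the last module takes the canonical
length, truncated at the sequence end. Modules longer than 30 residues in
real sequences appear as a module followed by unassigned insert residues.
The DP is verified against exhaustive enumeration of all valid candidate
subsets on sequences with at most 18 candidate windows.

Cysteine caps: a flank of ≥ 10 residues containing ≥ 2 cysteines before the
first (after the last) module is reported as LRRNT (LRRCT).

## Ladder extraction, conservation grading, classification

**Competence.** A ladder position is hydrogen-bond competent iff its residue
is in {N, T, S, C}. Glutamine is deliberately excluded: the competent set is
restricted to asparagine and the three substitutes with documented ladder
participation.

**Segmentation.** Module ordinals are split into contiguous terciles
(N-terminal / central / C-terminal), remainder modules to the center. Fewer
than six modules cannot be segmented and the record is reported AMBIGUOUS.
Subdomain boundaries are not sharply defined in nature; terciles are the
simplest deterministic operationalization and are config-free.

**Break rule.** A segment is broken iff its incompetent positions form a run
of ≥ 2 or exceed a fraction of 0.4. Both thresholds are exposed
(`BreakRule`). The defaults tolerate one isolated substitution in a segment
(observed even in intact ladders) while catching genuine interruptions.
Verdicts: SD = no segment broken; TD = central only; TTD = both terminals
only; anything else AMBIGUOUS, with per-segment diagnostics retained.

**Consensus profiles.** Given an ortholog alignment and an annotated
reference row, each module's ladder column is located by mapping the
reference's ungapped ladder position through the alignment; the modal
non-gap residue, its frequency, and its competence are reported.
Classification from an alignment uses the modal (consensus) residues, not
the reference alone. Modal ties prefer the reference residue, then
alphabetical order.

**Conservation grades.** Column conservation is 1 − H/ln 20, where H is the
Shannon entropy of the residue frequencies; the score is binned into nine
ordinal grades (1 = most variable, 9 = most conserved; an invariant column
is grade 9). This replaces rate-based empirical-Bayes inference
(tree-aware, substitution-matrix-aware) with a tree-free summary: grades are
comparable *ordinally* within an alignment but are not calibrated against
any external scale. Columns with fewer than two non-gap residues are
ungradeable.

**Phenylalanine spine.** A per-module flag (modal residue aromatic at a
configurable offset, default the position just after the 11-mer motif) is
provided but marked EXPERIMENTAL: the spine's exact register varies between
real modules, and the default offset is a modeling convenience.

## Family clustering

Pairwise distances are computed over shared non-gap columns ('X' always
mismatches): p-distance or the Poisson correction −ln(1 − p), capped at 10
near saturation; pairs sharing fewer than 30 columns are an error.
Saitou–Nei neighbor-joining is implemented directly so its determinism is
pinned: Q-matrix ties are resolved by lexicographic order of each cluster's
smallest leaf label, and negative branch lengths are clamped to zero with
the deficit moved to the sister branch. On additive matrices NJ is exact
(topology and branch lengths), which the tests verify over all 4- and
5-taxon topologies and random 8-taxon trees.

Family labels propagate from reference leaves: after midpoint rooting, each
query leaf takes the family of its smallest ancestral clade that contains
references of exactly one family; clades mixing reference families leave the
query UNASSIGNED. NJ on corrected distances is a coarse stand-in for full
maximum-likelihood inference — adequate for deep, well-separated family
clades, but without branch supports; fine topology (e.g. splits at a
family's root) should not be read off these trees.

## dN/dS estimation

Nei–Gojobori (1986) counting with equal pathway weights:

- **Sites.** Per codon position, the synonymous fraction is the share of
  the three single-nucleotide changes that are synonymous among those not
  creating a stop; s sums the fractions, n = 3 − s. Totals are averaged
  over the two sequences of a pair.
- **Differences.** For a codon pair differing at k positions, all k!
  orderings of the changes are enumerated; pathways through stop codons are
  excluded and the survivors averaged (if every pathway is blocked — which
  does not occur between sense codons of the standard code — all pathways
  are used). Implementation and an independent recursive enumeration oracle
  agree exactly over all 61 × 61 codon pairs.
- **Correction.** pN = Nd/N and pS = Sd/S are Jukes–Cantor corrected,
  dN = −(3/4)·ln(1 − (4/3)·pN); proportions at or beyond 3/4 leave the
  distance (and ω) undefined rather than erroring. Note that on degenerate
  inputs (single codons) Sd may exceed S and pS may exceed 1; estimates
  flag this as saturation.
- **Locus summary.** Mean ω over all pairs with defined ω; 95% CI by
  percentile bootstrap over codon columns (columns resampled jointly across
  pairs, mean recomputed; 2.5/97.5 percentiles, clipped to bracket the
  point estimate). Loci with fewer than five sequences are summarized with
  a warning. Gap-, N- and stop-containing codon columns are skipped
  pairwise.

Counting estimators are rank-faithful rather than digit-faithful: they are
meant to separate purifying from relaxed selection across loci, not to
reproduce any particular likelihood-based point estimate.

## Structural comparison

TM-score with the standard constants: d0(L) = 1.24·(L − 15)^⅓ − 1.8 Å,
floored at 0.5 Å (normalization lengths ≤ 15 use the floor, with a warning).
For a fixed residue correspondence the score is maximized over superpositions
by iterating Kabsch superposition on the subset of pairs within d0 and
rescoring all pairs, keeping the best score. Kabsch excludes reflections
(det = +1) and rejects collinear point sets.

`align_structures` seeds the correspondence from a global alignment of the
traces' residue letters (match +1 / mismatch 0 / gap −1), then alternates
superposition with Needleman–Wunsch re-alignment on the similarity matrix
S(i,j) = 1/(1 + (dij/d0)²) (gap penalty −0.6) until the TM-score changes by
less than 1e-4 or 20 iterations, returning the best-scoring state. Both
normalizations (by each trace's length) are reported plus their average.
This is a deliberate simplification of full TM-align — no secondary-structure
or fragment seeding, a single initial alignment — so scores on real
structure pairs can differ from TM-align's by a few hundredths; the
supported use is coarse contrasts (identity ≈ 1, same fold > 0.5,
between-class < within-class), not point-value reproduction.

Class summaries group `tm_avg` by unordered class pair and report
mean ± SEM (SEM 0 with a single-observation flag when n = 1).

## Synthetic generators

All generators take a seed, are fully deterministic given it, and return a
`SyntheticTruth` with everything planted.

**Ectodomains.** 12–25 modules of length 22–26 built on the concave
template, flanked by cysteine-bearing caps (12 and 14 residues). Ladder
residues are N (with 5% T/S/C) where the plan says competent, and drawn from
{A, G, D, E, K, R, Q, H} where broken; SD/TD/TTD plans break nothing, the
central tercile, or both terminal terciles. A noise parameter flips each
module's competence independently (default cohort noise 0.05). Background
('x', inter-motif and cap) residues are drawn uniformly from the
hydrophilic set {A, D, E, G, H, K, N, P, Q, R, S, T} — no L/I/V/F/M, C or
aromatics. This mirrors the hydrophilic character of the convex face and,
by construction, keeps chance windows in caps and module tails below the
scan threshold, so noise-free scans recover the planted modules exactly.
Central TD modules omit the planted phenylalanine spine residue. What is
*not* emulated: indels, atypical oversized central modules, signal peptides,
real amino-acid composition; a perfect noise-free recovery therefore
validates the scanner's chaining logic, not its robustness to real sequence
heterogeneity.

**Ortholog families.** Star-tree evolution: per column and descendant, a
substitution occurs with probability 1 − exp(−rate·t) and replaces the
residue uniformly among the other 19. Gap-free by design. Star trees are
sufficient for consensus and conservation-grade behavior but carry no
phylogenetic correlation structure, so grade values on real (tree-shaped)
families will differ.

**Codon alignments.** A continuous-time codon process: single-nucleotide
neighbor jumps with rate κ for transitions, × ω for nonsynonymous changes,
stops excluded, simulated per site by Gillespie along branches of t/2 from a
random sense-codon ancestor (pairs or star trees). Rates are scaled so t is
expected neutral substitutions per nucleotide site. Defaults: κ = 1 (the
NG86 estimator weights pathways equally, so the default generator matches
the estimator's assumptions and recovery tests exercise the counting
machinery rather than model mismatch; κ is exposed to study mismatch),
300 codons (desk-scale; real receptor CDS are ≥ 600 codons, which would
roughly halve estimator variance). The process has uniform codon usage and
no rate heterogeneity across sites.

**Horseshoes.** CA points on a planar circular arc (radius 40 Å, sweep
280°), grouped per module; the TD-like variant bends the central tercile out
of plane (8 Å sine bump) and shrinks its radius by 0.8, plus optional
isotropic Gaussian noise. By default 3 CA points per module (the ladder
anchor and two flanking backbone points): with one point per module the
normalization length of a 12–25-module trace pushes d0 to its 0.5 Å floor
and even sub-Ångström noise swamps the score, whereas ~3 points per module
puts d0 in the 1.6–3 Å range where the within/between-class contrast is
informative. `ca_per_module=1` reproduces the sparse-skeleton variant.

## Problem sizes and determinism

The shipped tests and the acceptance script use: 300-ectodomain
classification cohorts (100 per architecture at the generator default of 21
modules), 100 scans for module recovery, 50 sequences for the chaining
oracle, all 61 × 61 codon pairs for the counting oracle, 100 seeded
replicates for ω ordering and CI coverage (10 sequences, 300 codons,
t = 0.3, 1000 bootstrap replicates), all 4/5-taxon topologies plus 20 random
8-taxon trees for NJ, and 10 seeded horseshoe pairs per class contrast.
These sizes were chosen so each check is statistically meaningful at desk
scale. All randomness flows through `numpy.random.default_rng` seeds;
reruns are bit-identical.

## Known limitations

- Module boundaries at the termini may differ by ±1 from other LRR
  delimitation tools; module *counts* are the robust output.
- Conservation grades are ordinal stand-ins for rate-based inference.
- NJ trees carry no support values; family assignment quality degrades if
  reference clades are not well separated.
- NG86/JC saturates above ~75% difference proportions and ignores
  transition bias and codon-usage bias.
- The structural aligner is single-seeded; for distant folds it can settle
  in a local optimum that full TM-align would escape.
- TLR15-like cases (TD-adjacent families with intact ladders) are reported
  as what their ladder shows (SD); the classifier encodes no family priors.
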