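# Methods notes

This package re-implements, as a tested library, an attribute-mining
workflow for Na,K-ATPase α-subunit protein families: featurize sequences
into a fixed attribute census, cleanse and weight the attributes, sweep
decision-tree models over the weighted datasets, and corroborate the
composition-level findings with motif scanning and alignment-based site
mapping. This note records the models, the conventions behind every
tunable, and what the synthetic validation does and does not establish.

## Attribute census (featurize)

Inventory `census-1242-v1`, 1,242 attributes in fixed order
(physicochemical block; residue counts/frequencies; dipeptide
counts/frequencies; element counts/frequencies; class counts/frequencies;
ratios; alphabetical within each family):

* **length** counts all letters including ambiguity codes.
* **molecular weight** (Da): sum of average residue masses plus one
  water; B/Z/X/U/O contribute documented average masses.
* **aliphatic index**: X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu), X in
  mole percent of standard residues; permutation invariant by
  construction.
* **isoelectric point**: bisection on the net-charge function over
  pH ∈ [0, 14] to |charge| < 1e-4, EMBOSS pKa set (N-term 8.6, C-term
  3.6; side chains C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1).
  The stopping rule bounds the charge, not the pH, so on very shallow
  charge curves (short peptides) the returned pH can sit a few millipH
  from the exact crossing; the unit tests compare against a 0.001-step
  grid scan with a 0.01 pH tolerance.
* **dipeptides**: overlapping width-2 windows over consecutive standard
  residues; windows touching an ambiguity letter are skipped, so for
  clean sequences the 400 counts sum to length − 1.
* **elements** (C, H, N, O, S): free-amino-acid formulas summed over
  standard residues minus one H₂O per peptide bond between adjacent
  standard residues; frequencies divide by total atoms.
* **classes**: hydrophobic {A,V,L,I,M,F,W,C}, hydrophilic
  {R,K,D,E,N,Q,H,S,T,Y} (Kyte–Doolittle sign), positive {K,R,H},
  negative {D,E}. These sets are conventions, exposed as module
  constants.
* **ratios**: all 380 ordered count ratios; a zero denominator falls
  back to the numerator (equivalently max(denominator, 1)), keeping
  every value finite and monotone in the numerator — necessary because
  downstream trees threshold raw ratio values.
* Frequencies are fractions in [0, 1], not percentages. This interacts
  with the SD ≤ 0.1 cleansing rule: frequency attributes on a 0–1 scale
  are almost all removed there, so the surviving datasets are dominated
  by counts, ratios and the physicochemical block.

The census enumerable from the workflow description totals 1,242; the
original software's census was reported as 1,252 with the remainder
undocumented, so the inventory is versioned rather than padded.

## Cleansing

Sample (n−1) standard deviation throughout. Correlation pruning uses
|Pearson r| > 0.9 with a greedy left-to-right survivor rule (an
attribute is kept iff it is below-threshold against every previously
kept attribute); this is deterministic, order-stable, and idempotent
together with the SD rule.

## Attribute weighting

All ten algorithms emit raw scores that are min–max normalized to
[0, 1]; a zero-range attribute scores raw 0 everywhere.

* **χ² and symmetrical uncertainty** share a 10-bin equal-frequency
  discretization (duplicate quantile edges merged). Note a desk-scale
  caveat: the χ² statistic is compared across attributes with very
  different contingency shapes, so with few rows (n ≈ 40) the
  ~27-degree-of-freedom noise statistics of continuous attributes can
  exceed the n-capped statistic of a perfectly associated binary
  attribute. SU avoids this by normalizing with H(attribute).
* **deviation** = coefficient of variation (SD / |mean|, mean 0 → 0);
  class-blind by definition, as is **PCA** (sum of |loading| × variance
  share over the components covering 95% cumulative variance, after
  z-scoring).
* **Gini / info gain / gain ratio** score the best single binary
  threshold split (midpoints of consecutive distinct sorted values).
* **ReliefF**: every row is a sampling target, k = 10 nearest
  hits/misses (Manhattan distance on z-scored attributes, stable-sorted
  for determinism), diff = |a − b| / range, multi-class miss terms
  weighted by class prior / (1 − prior of the target's class); k is
  truncated for classes smaller than k.
* **rule** = training accuracy of the best one-attribute threshold rule
  with per-side majority prediction.
* **SVM**: one-vs-rest linear SVMs (C = 1) trained by full-batch
  subgradient descent for a fixed 200 epochs on z-scored attributes —
  full-batch rather than stochastic so the weights are row-order
  invariant — scored by the Euclidean norm of each attribute's
  coefficients across the class models.

Selection thresholds per task follow the attribute-evaluation rules:
organism task 0.7 (deviation/PCA 0.8; Gini, info gain, uncertainty 0.6);
isoform task 0.7 (χ², rule, uncertainty 0.6; relief 0.5; deviation
0.26). The eleven analysis datasets are the FCD plus one per algorithm.

## Decision trees

Binary threshold splits only (all attributes numeric). Criteria: info
gain (bits), gain ratio (IG / split-information, 0 when IG ≤ 0), Gini
impurity decrease, accuracy gain over the parent majority. Pre-pruning:
minimal gain 0.01 and max depth 20 by default (both unset → pure
growth, which reaches 100% training accuracy on any consistent table).
Flavors: decision tree; decision stump (depth 1); random tree (random
⌈√p⌉-attribute subset per node); random forest (100 bootstrap random
trees, majority vote). "Performance" is stratified 10-fold
cross-validation accuracy × 100 (folds via scikit-learn, deterministic
under the stage seed).

Determinism conventions: attribute ties at a node go to the earlier
attribute in inventory order, compared with a 1e-12 relative tolerance
because mathematically tied scores differ by ulps (gain ratio is exactly
1.0 for *every* split that cleanly groups classes — a known degeneracy);
threshold ties take the smaller midpoint; vote ties take the earlier
class in sorted order. For reporting, the "best single tree" among
performance-tied sweep cells prefers the information-gain criterion
(the conventional best-model setting for this analysis, and immune to
the gain-ratio tie degeneracy), then earlier datasets with FCD first.

## Motif scanning and site mapping

A width-4 window is an assembly-motif hit if it equals SYGQ or SYGE, or
differs at exactly one position by a substitution with BLOSUM62 score
> 0 ("similar" mismatch — the standard operationalization). Prevalences
are exact rationals × 100 rounded half-up to 2 decimals.

Reference-coordinate mapping uses Needleman–Wunsch global alignment
(Gotoh), BLOSUM62, gap open 10 / extend 1 (a length-k gap costs
10 + (k−1)), end gaps penalized, traceback ties resolved
diagonal > up > left. Ambiguity letters score through documented
stand-ins (U→C, O→K, else X). A site state is the query residues aligned
to the reference columns; any gap yields "gap". Percent identity counts
identical pairs over columns with no gap in either sequence — the
documented convention, since alternatives (alignment-length
denominators) are also in circulation. The DP kernel is numba-compiled
for ~1 kb × 1 kb alignments at dataset scale.

## Synthetic data: the stated world

The generator emits sequences derived from one synthetic reference
(length 1020) so the composition route (counts) and the coordinate
route (alignment) must agree on the same planted truth:

* Site plan: GC at 142/208/702 (vertebrates; invertebrates 142/702
  only), isoform states at 41 (DH = α3, else EH), 431 (FK = α1/α3,
  FL = α2, FQ = α4) and 451 (KC = α1, else KF), plus one marker
  dipeptide per remaining group (fungi HW at 300, Protista WN at 320,
  invertebrate WC at 340). Non-vertebrates draw isoform-site states
  uniformly so those sites carry no group signal.
* Every dipeptide in the site plan is **scrubbed** from the background
  (stray occurrences destroyed by substituting one residue with proline,
  which joins no planted dipeptide and scores non-positively against
  every motif-template residue), so planted counts are exact class
  signals; stray motif windows are scrubbed the same way.
* Per-group substitution divergence from the reference: 0.12 / 0.10 /
  0.08 / 0.06 / 0.03 (prokaryote → vertebrate), giving a plausible
  identity gradient; lengths prokaryote 900 ± 30, others 1020 ± 20,
  reached by segment indels that avoid every planted site ± 2 residues;
  additional small indels at rate 0.005 per residue.
* SYGQ motif planted at position 860 with prevalence 0 / 0.22 / 0.22 /
  0.88 / 1.0 per group.

What a green test establishes: the pipeline recovers *planted, exact*
signals — count_GC roots the best organism tree, the isoform dipeptides
rank highly, site mapping returns the planted states through indels.
What it does not establish: behavior on phylogenetically correlated real
sequences (no tree-structured evolution is simulated; attributes are
i.i.d. noise around the reference), calibrated accuracy values, or the
original study's attribute counts, which depend on its private dataset.

## Known limitations

* The χ²-weighting desk-scale caveat above: with ~10 rows per class,
  single-site dipeptide counts can rank below continuous-attribute
  noise for the χ² scorer specifically (all entropy-, margin- and
  neighborhood-based scorers are robust to this at the same n).
* Percent-identity and motif-similarity conventions are documented
  choices among several in circulation; both are configurable.
* Deduplication of input sequences is left to the user; records are
  never merged or dropped.
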