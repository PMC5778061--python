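# Methods

This note documents the model behind `ecrscan`, the choices made where the
procedure admitted more than one reasonable realisation, and what the
synthetic validation does and does not demonstrate.

## Constraint model

Evolutionary constraint is inferred from the density and rarity of
amino-acid substitutions along a protein alignment, interpreted on a rooted
phylogeny. Sites under purifying selection accumulate fewer and more
conservative exchanges than the protein's average site; a valley in the
smoothed substitution-rate profile is therefore read as an evolutionarily
constrained region (ECR). The method is deliberately rate-based and
length-free: branch lengths are parsed and carried along but never enter
the scoring, which depends on topology only.

## Node substitution scores

The scoring matrix derives from the BLOSUM62 clustered target frequencies
q(a, b) — the joint amino-acid pair frequencies of the blocks database —
shipped with the package in the original lower-triangular text dialect
(`src/ecrscan/data/blosum62.qij`). An off-diagonal entry of that file is
the mass of an *unordered* pair and covers both substitution directions, so
the directional frequency used for an ancestor→child event is q(a, b)/2 off
the diagonal and q(a, a) on it. Each ancestor row of the directional table
is normalised to sum to 1, giving substitution frequencies F_S with the
self entry F_SS, and

    NSS(a, b) = 1 − F_S(a→b) / F_SS(a).

Properties, all verified by tests: the diagonal is exactly 0 (in IEEE
arithmetic, 1 − x/x ≡ 0); every off-diagonal entry lies strictly in (0, 1)
with 1 a theoretical supremum attained only by never-observed exchanges;
within a row, scores order exchanges exactly by descending raw frequency;
and the matrix is ancestor-conditional, hence asymmetric (e.g.
NSS(A→R) ≠ NSS(R→A)).

The ordered-pair conditioning matters: normalising the raw symmetrised rows
instead would make NSS(M→L) negative, because Met–Leu exchanges are more
frequent in the underlying block data than Met–Met conservation
(q(M,L) = 0.0049 > q(M,M) = 0.0040). A negative score would place an
exchange below "no change" and break the parsimony refinement, so the
package treats the split of unordered pair mass as part of the matrix
definition.

Integrity of the shipped table is checked rather than assumed: the full
matrix sums to 1 within its 4-decimal printed precision, its marginals
reproduce the published BLOSUM62 background frequencies, and half-bit
log-odds recomputed from it match the BLOSUM62 matrix for 350+ of the 400
cells with the remainder off by one unit — the jitter expected from the
file's printed precision at rare pairs.

## Ancestral reconstruction

Per column, candidate residue sets are computed bottom-up with Hartigan's
algorithm: the states attaining the maximum support count over a node's
non-missing children, which for a binary node reduces to the classic
intersection-if-nonempty-else-union rule. A leaf with a gap or 'X' is
missing and excluded; a node whose children are all missing is itself
missing, and edges touching a missing endpoint neither contribute score nor
count as changes.

The top-down pass is specified here precisely because its verbal
description ("keep the amino acid with the minimum NSS") leaves the root
and ties open:

* **Root**: every root candidate is tried; the one whose descent yields the
  smallest total score wins, ties broken alphabetically.
* **Descent**: a node keeps its parent's state whenever that state is in
  its candidate set (score 0 is always strictly minimal because
  off-diagonal scores are strictly positive); otherwise it takes the
  candidate minimising NSS(parent→child), ties alphabetical.

Any such choice from Hartigan sets realises the minimum unweighted change
count; the NSS refinement only selects *among* minimum-change histories.
This is verified against exhaustive enumeration of all internal labelings
on small trees. The column substitution score SS is the sum of NSS over
edges; summing over edges (rather than nodes) follows from each score being
defined on an ancestor→child transition.

## Profile and region calling

* Relative score = SS / (number of informative sequences). Columns with
  fewer than two informative sequences cannot express a substitution and
  are set to 0 rather than left undefined; they are rare after the 50% gap
  filter.
* Normalisation divides by the mean relative score, so 1.0 marks the
  protein-average rate. A perfectly invariant alignment has mean 0 and
  raises a degenerate-profile error instead of producing NaNs.
* Smoothing is an 11-column centred moving average followed by two
  7-column passes. Window centring and edge handling are not dictated by
  the procedure's description; centred windows truncated at the array ends
  were chosen because they preserve track length and constant signals
  (a constant profile smooths to itself).
* ECR calling: interior local minima of the smoothed track (equal-value
  plateaus contribute their lower-median column) below a threshold are
  extended on each side to the nearest sign change of the discrete second
  difference d2[i] = s[i−1] − 2s[i] + s[i+1], or to the array end.
  A sign change rather than an exact zero is used because exact floating
  zeros are not robust. Overlapping regions merge, keeping the deepest
  minimum. The threshold defaults to 1.0 — "valley" is read relative to
  the mean-normalised plot — and is exposed as `--ecr-threshold` because it
  is the procedure's largest ambiguity; `min_value` is reported per region
  so users can rank calls by depth.
* Reference coordinates: a region boundary on a reference-gap column moves
  inward to the nearest reference residue; a region wholly inside a
  reference gap is reported in alignment coordinates only.

## Guide tree

When no phylogeny is supplied, a tree is built by neighbor joining on
p-distances (mismatch fraction over columns where both sequences bear a
residue) with midpoint rooting. This substitutes a reproducible, standard
construction for the original web pipeline's unspecified aligner-internal
tree; since scoring uses topology only, the substitution is consequential
only insofar as NJ topology differs from that tree. Negative NJ branch
lengths are clamped to zero before rooting; children are ordered by
smallest descendant leaf label so serialisation is a pure function of the
input; the two-sequence case is rooted directly at the pair's midpoint.

## Synthetic families

The simulator draws an ancestral sequence from the BLOSUM62 marginal
frequencies and evolves it down a Yule topology: per branch, each site
mutates with probability `baseline × multiplier(site)`, the replacement
drawn from the row-normalised BLOSUM62 conditional excluding self.
Defaults — 12 leaves, 300 columns, three 20-column constrained blocks at
multiplier 0.2, baseline 0.08 per branch per site, deletion start
probability 0.01 with geometric length (mean ≈ 5) — define the validation
conditions used throughout the tests: roughly 1.8 expected substitutions
per background site across the tree's 22 branches versus 0.35 in blocks,
which is the rate contrast regime the profile is meant to resolve.

What the simulator does **not** model: insertions (so ancestral coordinates
equal alignment coordinates and the "alignment" is exact by construction),
branch-length-dependent rates, among-site rate variation beyond the block
multipliers, back-substitution-aware distances, or alignment error.
Passing the recovery test therefore shows the pipeline resolves a 5-fold
rate contrast over ≥ 20 columns under ideal alignment, not that it is
robust to misalignment or to saturation on deep trees.

Under these conditions the suite verifies that every simulated block is
overlapped by a called ECR in 20/20 families and that called regions cover
under 60% of background columns (measured: ≈ 23%; the background calls are
shallow minima that users can discard by depth).

## Numerical choices and limitations

* Scores are carried at double precision end to end; tables print at 10
  significant digits, which round-trips the values used.
* All coordinate tracks are 1-based inclusive, matching residue numbering
  conventions.
* Non-standard residues B, Z, U, O are rejected at parse time rather than
  silently remapped; 'X' is accepted and treated as missing for
  reconstruction but as a residue for the gap filter, which the filter's
  definition ties to gap content only.
* The Fisher enrichment uses the two-sided point-probability criterion
  (scipy's convention), with odds ratio (a·d)/(b·c), ∞ when b·c = 0 and
  a·d > 0; Bonferroni adjustment is min(1, m·p). The background is the
  annotated residues supplied, which users should keep in mind when
  annotations are themselves biased toward well-studied regions.
* Determinism is a contract: identical inputs produce byte-identical
  tables, and the simulator is fully seeded.
* Hartigan's procedure guarantees a minimum-change labeling, not all of
  them; the reported ancestral states are one deterministic representative
  of that optimum, and columns whose optimum is degenerate may admit other
  equally parsimonious state assignments with different (higher) NSS sums.
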