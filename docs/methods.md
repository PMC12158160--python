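# Methods

## Model and procedure

The object of analysis is an MS1 annotation table: each annotated ion
(molecular formula + adduct) carries a list of candidate molecular
structures — isomers (identical formula) and isobars (indistinguishable m/z)
— with non-negative sampling weights. Weights default to equal; users may
supply weights reflecting detection frequency, pathway membership, or
MS/MS evidence. Molecule identifiers are opaque case-sensitive strings; any
chemical normalisation is the upstream database's responsibility.

A **bootstrap iteration** resolves the ambiguity by sampling one candidate
per ion, independently across ions, with probability proportional to the
normalized weights. Within one iteration the same molecule may be drawn for
several ions; by default these collisions are collapsed into a molecule
*set* before testing, because overrepresentation is a statement about
distinct molecules — counting one molecule twice would inflate the
intersection. The alternative (counting assignments with multiplicity) is
available via `dedup=off`; in pathological draws it can push the
intersection k above the term's universe count K, which violates the 2x2
table and raises.

**ORA per iteration.** Every term retained in the collection (at least
`min_term_size` = 3 in-universe members; Fisher's test is uninformative
below that) is tested with the one-tailed (greater) exact hypergeometric
tail p = P(X ≥ k), X ~ Hypergeometric(N, K, n). The universe N is the
annotation database the user supplies; if absent, the union of term members
and observed candidates stands in. BH adjustment runs within each iteration
across the terms tested in that iteration — each bootstrap is a complete,
self-contained analysis — and a term is *called* in an iteration when
q ≤ `fdr_cutoff` (default 0.10). Fold enrichment is (k/n)/(K/N), zero for an
empty intersection.

**MSEA per iteration.** Metabolites (= measured ions) are ranked once by a
contrast metric — the ranking does not depend on the draws — and each term's
membership on the list is decided per iteration by the sampled molecule.
The enrichment score is the standard weighted running-sum statistic with
weight exponent α (default 1): hits add |metric|^α normalised over in-set
metric mass, misses subtract 1/(L−|S|); ES is the running-sum value of
maximal magnitude, and the leading edge counts members at or before the
peak (positive ES) or at or after the trough (negative ES). If all in-set
metric values are exactly zero the hit weights fall back to uniform.
Significance uses metabolite-label permutation (ES recomputed on uniformly
random same-size member sets), p = (1 + #{|ES*| ≥ |ES|})/(1 + n_perm) with
n_perm default 1000; label permutation was chosen over phenotype (cell)
permutation for speed at single-cell matrix sizes and because it matches
the exchangeability actually used by the calibration analyses. Terms whose
sampled membership falls below `min_term_size` in an iteration are skipped
for that iteration only.

**Aggregation.** Per term, across the iterations in which it was tested:
median p, median q, median effect (fold or ES) with interquartile range,
median intersection/leading-edge size, the fraction of iterations with
q ≤ `fdr_cutoff`, and `n_effective_bootstraps`. Medians are used throughout
as the robust central statistic. Terms tested in only some iterations are
reported rather than dropped — instability is exactly the signal of
interest.

**Ambiguity score.** For a term: the mean, over ions with ≥ 1 in-term
candidate, of the in-term fraction of the ion's candidate weight mass.
It is 1 iff every supporting ion is fully in-term, and adding an
out-of-term candidate to any supporting ion strictly lowers it. Low scores
(< 0.5) mark terms whose apparent enrichment is spread across ambiguous
candidates and therefore evaporates under bootstrapping; the discordance
table (`compare_standard_vs_bootstrap`) operationalises this by listing
terms with standard-ORA q ≤ cutoff but bootstrap fraction-significant below
0.5. Should a user prefer the opposite orientation (high = ambiguous), the
CLI flag `--ambiguity-orientation inverted` reports 1−x.

## Randomness and reproducibility

A single master seed drives everything. `SeedSequence.spawn` allocates one
independent substream per bootstrap iteration (so results do not depend on
execution order), and the MSEA pipeline first splits the master sequence
into a bootstrap stream and a permutation stream so the two sources of
randomness never interact. Same seed ⇒ byte-identical outputs, including
the CLI result files.

## Synthetic studies

The generator emulates the inputs of a two-condition imaging-MS enrichment
study with known ground truth; defaults: universe 500 molecules, 20
disjoint terms of 10–25 members, 150 ions, 4 candidates per ion, 50+50
cells in conditions "F" vs "U" (a perturbation/steatosis-style contrast vs
control), log-normal intensities with baseline log2 levels uniform on
[8, 14] and Gaussian log-scale noise (sd 0.3). These sizes keep a full
bootstrapped analysis comfortably fast while leaving the hypergeometric
tail far from degeneracy.

Planting: a planted term receives 12 supporting ions. Each such ion's
in-term candidate count is floor(s·c) plus a Bernoulli trial on the
fractional part, so the expected in-term candidate *mass* equals the
enrichment strength s exactly (s = 1 with one candidate per ion gives an
unambiguous plant; s = 0.25 with four candidates reproduces the
minority-candidate regime). In-term candidates tile a shuffled cycle of the
term's members so distinct ions tend to support distinct molecules, as in
real data where each ion is a different molecule's signal; sampling them
independently would collide and quietly halve the planted intersection.
For the intensity matrix, ions of planted terms gain `effect_size` log2
units in condition "F".

What the generator does *not* model: m/z values, adducts or isotope
envelopes; overlapping terms; correlated ion intensities; dropout or
batch structure in the single-cell matrix. Recovery and calibration results
on these fixtures therefore demonstrate the statistical machinery, not
performance on any particular instrument or ontology.

The truth record supports an exact infinite-bootstrap check: the expected
intersection of a term with the sampled set is
Σ_{m∈term} (1 − Π_ions (1 − w_ion(m))), compared against observed
bootstrap means.

## Numerical choices

- Fisher p via `scipy.stats.hypergeom.sf` (exact tail, no normal
  approximation; term sizes are small). Verified exhaustively against an
  integer-combinatorics tail sum for all tables with N ≤ 60 to 1e-12
  relative error.
- BH via `statsmodels` `multipletests(method="fdr_bh")`, verified against
  the textbook step-up recursion on random p-vectors.
- Weight normalisation tolerance 1e-12; the cumulative-weight sampler pins
  the top of the CDF to exactly 1 to guard against round-off.
- Ranking ties break by metabolite ID (stable, deterministic); contrast
  reversal therefore reverses the ranking exactly up to tie order.
- Zero-variance metabolites under t/SNR metrics get metric 0 with a warning
  rather than an error; the log2 fold-change pseudo-count defaults to
  1e-9 × the matrix maximum.
- Candidates outside the universe are dropped with re-normalized weights
  (database mismatches are routine and logged); ions losing every candidate
  are excluded and counted in the validation report.

## Study sizes used by the acceptance analyses

The acceptance script and test suite use: the exhaustive Fisher scan at
N ≤ 60; 1000 random BH vectors of length ≤ 200; 10 000 sampler draws;
50–200 null replicates of the default design with 100 bootstraps each;
10–20 seeds for planted ORA recovery; 5–10 seeds for MSEA recovery with
n_perm = 1000; and 1000–2000 null member-set draws with n_perm = 199 for
permutation calibration (199 puts p = 0.05 exactly on the achievable
lattice, 10/200). These sizes give standard errors comfortably inside the
asserted bands while keeping a full run in minutes on one CPU.

## Known limitations

- The enrichment statistics treat terms independently; no correction for
  term–term overlap or dependence.
- Only two-condition contrasts; no covariates, no multi-group designs, no
  spatial smoothing of pixel matrices.
- Intensity preprocessing (normalisation, log transform) is the caller's
  responsibility.
- No adaptive rule for the number of bootstraps; higher ambiguity needs
  more iterations, and 100 is a floor, not an optimum.
- The MSEA null permutes metabolite labels, not phenotypes; with strongly
  correlated metabolites a phenotype permutation would be more conservative.
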