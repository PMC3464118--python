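# Methods

## Superimposition

All fits are *partial* Procrustes: configurations are translated to a zero
centroid, scaled to unit centroid size, and only a rotation is estimated
(closed form in 2-D).  Reflection is never fitted implicitly; it enters the
analysis only through the explicit matching-symmetry step, where every
right-side configuration is mirrored (x negated) before a single joint GPA
over all sides and replicates.  The GPA iterates rotation onto the running
consensus, re-centering and renormalizing the consensus each round, until
the consensus moves by less than 1e-10 (Frobenius norm; at most 200
iterations, non-convergence flagged rather than raised).  The consensus
orientation is re-anchored to the first input configuration every
iteration; this both fixes the global rotational indeterminacy
deterministically and suppresses a slow rotational drift mode of the naive
iteration.

Tangent coordinates are the orthogonal projection of the aligned
coordinates, relative to the consensus, off the four similarity directions
(x/y translation, rotation, scaling) at the consensus.  Orthogonal rather
than stereographic projection was chosen; at the within-panel scale of
variation (Procrustes distances ~1e-2) the two differ at second order.
Shape space has 2k − 4 dimensions (28 for k = 16 landmarks).

Per individual, the symmetric component is the mean of its two side means
and the asymmetric component the half-difference, so side means are
reconstructed exactly.  Asymmetric components are retained in the result
object but not used by the downstream genetic analyses.

## Procrustes ANOVA

Design: strain / individual(strain) / side / individual×side / error, with
sides and replicates required balanced within individuals (unequal strain
sizes are allowed; incomplete individuals are excluded upstream with a
warning).  Sums of squares are summed over all 2k tangent coordinates;
Procrustes dfs multiply the univariate design dfs (G−1, N−G, 1, N−1,
n_obs − 2N) by 2k − 4, or by 2 for the per-landmark tables.  dfs are always
computed from the data actually present, never assumed from the nominal
design.

Variance components solve the mixed-model expected mean squares (r
replicates, s = 2 sides, n̄ the arithmetic — optionally harmonic — mean of
individuals per strain):

```
MS_error = σ²_m
MS_I×S   = σ²_m + r σ²_FA
MS_ind   = σ²_m + r σ²_FA + r s σ²_ind
MS_strain= MS_ind ladder  + r s n̄ σ²_strain
MS_side  = σ²_m + r σ²_FA + r N s/(s−1) σ²_side
```

Negative solutions are truncated at zero.  The side effect is fixed
(directional asymmetry) but a component is still reported for
quantification; the coefficient r·N·s/(s−1) (= 2Nr for two sides) is chosen
so that the reported component equals the per-observation variance
contributed by the fixed side displacement, putting all five components on
one per-observation scale.  This choice is what makes the synthetic-data
round trip exact in expectation (below).  Goodall-style F ratios follow the
same ladder (strain/individual, individual and side over the interaction,
interaction over error) with the Procrustes dfs.

## MANOVA screening

Each congenic strain is tested against the reference with a two-group
MANOVA on principal components of the tangent coordinates.  By default the
PCA is recomputed on the pooled pair of strains under test (14 components,
capped to keep the within-group covariance nonsingular); a shared global
ordination can be supplied instead.  Wilks' Λ = det(E)/det(E+H) uses the
exact two-group transform F = ((1−Λ)/Λ)(df_den/df_num) with df_num = p and
df_den = n − p − 1.  Bonferroni adjustment is the default
multiple-testing control; the historical raw-scale screening cutoff
p < 0.002 is available as the `historical` preset of `qtl_screen` without being
rationalized here.

## Canonical variates and classification

CVA solves B v = λ W v for the between- and pooled within-group covariance
matrices; axes are scaled to unit pooled within-group variance and capped
at min(groups − 1, p).  The cross-validated classifier is a linear
discriminant with pooled covariance and equal priors — the rule consistent
with CVA geometry — refit for every held-out specimen.  The upstream GPA
and PCA are *not* refit per fold; at panel sample sizes their leverage per
specimen is negligible, but the reported rates are, strictly, conditional
on the full-data ordination.  Mahalanobis ties break to the
lexicographically first strain.  Both specimen-pooled and strain-averaged
correct rates are reported, since the two denominators differ under
unequal strain sizes.

## Modularity and integration

RV coefficients are computed from a single joint superimposition of whole
configurations (blocks are column subsets of the same tangent data, not
separately superimposed sub-shapes).  The enumerated comparison covers all
unordered bipartitions with the a-priori block sizes — C(16,8)/2 = 6435
for the 8|8 mandible split — using the identity ‖S₁₂‖²_F = tr(S₁₂S₂₁) so
the full scan is a single masked matrix product.  The *contiguous* subset
keeps bipartitions in which **both** blocks induce connected subgraphs of
the landmark adjacency graph (the stricter reading of spatial contiguity).
The packaged default graph is the 16-landmark outline cycle, which yields
8 contiguous 8|8 bipartitions; a published count of 94 contiguous
partitions implies a denser (unrecoverable) anatomical graph, so the graph
is always user-overridable.  Left-tail p-values are exact counts:
p = #{RV ≤ RV_observed}/#enumerated, with the observed partition always
included.  The test defaults to strain means (the genetic-variation
reading); specimen-level testing is a flag.

**Calibration caveat.**  The enumerated-partition comparison is a
descriptive left-tail proportion, not a calibrated significance test.
Superimposed data live in the 2k−4-dimensional shape space, and the
similarity-projection covariance is not exchangeable under landmark
relabelling (its rotation and scaling directions depend on the template
geometry).  Under fully isotropic shape-space variation the a-priori
contiguous partition therefore sits systematically left of the middle of
the enumerated RV distribution: in direct simulation from N(0, P) (P the
similarity projector), the mean left-tail proportion is ≈ 0.25 and ~20% of
replicates fall below 0.05.  Small p_full values for spatially coherent
hypotheses are accordingly anticonservative and should be read as strong
only when far below that baseline (the fully modular ρ = 1 regime yields
p_full ~ 2e-4).  This property is intrinsic to the method on Procrustes
data, not an implementation artifact: with exchangeable (unprojected) noise
the proportion is exactly uniform.

Two-block PLS is the SVD of the cross-block covariance S₁₂; per axis the
paired scores, their correlation, and the covariance fraction σᵢ²/Σσ² are
reported.  Permutation tests permute the rows of one block and use
p = (1 + #{statistic ≥ observed})/(n_perm + 1) for the total squared
cross-covariance and the axis-1 score correlation (10,000 permutations by
default, seeded).

## Synthetic-data generator

The generator emulates the panel design: one reference strain plus
congenic strains with the packaged sample sizes (19 strains, 362 mice),
two sides per individual — the right side emitted as the mirrored copy of
its underlying left-form — and two digitization replicates per side, each
observation finally receiving an arbitrary rotation, translation, and mild
(3%) log-scale jitter so superimposition is genuinely exercised.

All effects are drawn in the shape space at the template (directions in
the 2k-coordinate space projected off the similarity subspace), keeping
the variance accounting consistent with tangent-space analysis.  The five
variance shares default to 77.52 / 6.49 / 6.71 / 5.07 / 4.18 % (strain /
individual / side / individual×side / error) of a total per-observation
squared-Procrustes variance of 3e-4 — the scale typical of within-species
craniofacial panels.  Strain effects are sums of per-segment vectors; each
strain's donor Mb is split equally across its segments (no per-segment
sizes are available), and magnitudes are either proportional to an
explicit `additivity_coefficient` (shape units per Mb) or, by default,
calibrated so the weighted fixed-effect variance
Σ n_g‖a_g − ā‖²/((G−1) n̄) equals the strain share — the exact quantity the
strain EMS coefficient estimates, which makes parameter recovery an
unbiased round trip.  Directional asymmetry is one shared displacement of
squared norm equal to the side share; it does not interact with strain.

Modularity is controlled by ρ ∈ [0,1]: each segment direction mixes
√ρ · (a draw from the within-module subspace of a randomly chosen module)
with √(1−ρ) · (an isotropic shape-space draw).  Within-module directions
are built as vectors supported on one module's landmarks *and* orthogonal
to the similarity directions, so at ρ = 1 the between-strain cross-module
covariance vanishes in expectation while effects remain proper shape
changes.  ρ defaults to 0.75 (clearly modular but not surgically
separated, matching the moderate observed RV of real panels); ρ is a
generative knob, not an estimate.

What the generator does **not** emulate: genotypes or linkage (segment
effects are free vectors, not mapped loci), epistasis and dominance,
strain-specific asymmetry, allometry (size and shape are independent), and
digitizer-specific error structure (error is isotropic in shape space).
Passing tests therefore validate the statistical machinery and its
calibration under the stated model, not the biological conclusions one
would draw from real mandibles.

## Numerical choices and conventions

* Landmark indices are 1-based in every file and report, 0-based
  internally; TPS IDs encode metadata as
  `<specimen>_<strain>_<side>_<replicate>`, with a sidecar table override.
* Coordinates are unitless; centroid-size standardization removes units.
* GPA tolerance 1e-10, max 200 iterations; PCA rank is cut at 1e-10 of the
  leading singular value; variance components truncate at 0; Mahalanobis
  ties break lexicographically; permutation p-values use the +1 correction
  so they are never zero.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); the pipeline splits one root seed into
  per-stage seeds with `SeedSequence`, so reruns are byte-identical.

## Problem sizes used by the test suite

The unit suite runs the 19-strain design with per-strain sample sizes
capped at 2–6 mice; the parameter-recovery check runs the full 362-mouse
design over 20 seeds, the modularity power/null checks 50 and 200 full
simulations, and brute-force oracles use 4–16 observation fixtures.  The
acceptance script reports the design dfs from a 3-mice-per-strain
simulation, since those dfs depend only on the landmark and strain counts.

## Known limitations

* The enumerated-partition RV test is anticonservative on Procrustes data
  (see the calibration caveat above).
* The EMS ladder assumes balanced sides/replicates; unbalanced strain
  sizes enter only through n̄, the standard approximation.
* Per-test pooled-pair PCA means different strains are compared in
  slightly different reduced spaces; the global-ordination mode trades
  this for a shared but reference-dominated basis.
* Leave-one-out refits the discriminant only, not the superimposition.
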