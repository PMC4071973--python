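# Methods

## Data model

The unit of analysis is a binary band matrix: *n* strains scored over *m*
bands, each band assigned to exactly one primer combination. Scores are
strictly 0/1; a missing score is rejected at validation rather than
imputed, because band selection in dominant-marker studies already filters
to well-separated bands that can be called in every lane. The CSV dialect
encodes the primer grouping in the band header token
(`<primer>:<band>[:<size_bp>]`) so the matrix and its grouping travel in a
single flat file.

## Polymorphism statistics

**Band PIC.** A dominant band has two observable states, so its
polymorphism information content is the two-state gene diversity
PIC = 1 − p² − (1 − p)² = 2p(1 − p), where p is the presence frequency
across the panel. This is bounded by 0.5 (p = 0.5) and symmetric in
p ↔ 1 − p. The generic pattern-frequency form of PIC is ambiguous for
multi-band fingerprints (per band vs. per multilocus pattern); the per-band
two-state reading is adopted because published per-primer PIC values in
this literature respect the 0.5 ceiling and reach it even for primers with
few polymorphic bands — which also implies the per-primer value averages
over *polymorphic* bands only. A primer with no polymorphic band reports
PIC = 0 with a logged warning.

**Polymorphism criterion.** A band is polymorphic when both states are
observed; no minor-frequency threshold is applied.

**Marker index.** Two conventions exist for MI: the formula usually quoted,
MI = PIC·η·β (η = band count, β = polymorphic proportion), and the variant
actually followed by most printed tables, MI = PIC·η. Both are exposed via
the `mode` argument of `marker_index` (`"formula"` / `"table"`); the
default is `"table"` because, on the packaged reference panel, PIC·η
reproduces the printed MI column within half-ulp rounding of the 2-dp PIC
for 27 of 28 rows, while PIC·η·β reproduces almost none. The one
inconsistent row (JN00L1-EM16) fits neither convention and is treated as a
typographical anomaly; it is excluded from the consistency invariant but
kept verbatim in the fixture. All statistics are computed at full precision
and rounded to 2 dp only at serialization.

**Reference panel fixture.** The packaged 28-row table stores a published
per-primer summary verbatim (totals 288 bands / 202 polymorphic). Its
running text quotes a grand total of 287 fragments, one less than the
column sum; the 287 figure is kept as a metadata constant and never
asserted against the rows.

## Similarity and clustering

Jaccard similarity a/(a+b+c) is used, excluding joint absences — for
dominant markers a shared absent band carries no evidence of shared state.
Two all-zero profiles get similarity 0 with a warning (degenerate but
representable). Clustering and ordination operate on the complement
distance d = 1 − s.

UPGMA merges the closest pair of clusters, maintaining inter-cluster
distances as leaf-count-weighted averages
(n_A·d_AX + n_B·d_BX)/(n_A + n_B), which equals the unweighted mean over
all cross leaf pairs. Merge heights are recorded on the distance scale and
are provably non-decreasing. **Tie-break:** among pairs at the minimum
distance, the pair whose clusters contain the smallest original leaf
indices (lexicographically) merges first; this makes the tree a pure
function of the input, which the tests rely on. Whether the historical
NTSYS workflow clustered similarities (merging maxima) or complement
distances is not observable from published trees — both give identical
topologies with mirrored heights — so the distance-scale convention is
simply documented here.

Cluster cuts are specified on the similarity scale, as published trees
annotate them: cutting at similarity s keeps every merge with height
strictly below 1 − s. Thus s = 1 yields singletons (merges at height 0 are
also undone) and s = 0 yields one cluster (all merges kept, including any
at distance exactly 1 — the strict rule is relaxed at s = 0 so the
whole-panel cluster is always reachable). `cut_into_k` undoes the last
k − 1 merges instead, reporting the similarity at which the partition would
coarsen. Newick export uses node depths of half the merge height, so
root-to-leaf paths are uniform and leaf-pair path lengths equal cophenetic
distances. The cophenetic correlation (Pearson, over the n(n−1)/2 pairs)
is the standard goodness-of-fit diagnostic; it requires n ≥ 3 and
non-constant distances.

## Ordination

PCoA Gower-centers the squared distances, B = −½ J D² J, and
eigendecomposes the symmetrized B. Coordinates are eigenvectors scaled by
√λ for eigenvalues above 1e−9; axes at or below that carry zero
coordinates. Variance shares are percentages of the *positive* eigenvalue
sum. Jaccard distances are not guaranteed Euclidean-embeddable, so negative
eigenvalues occur routinely; they are flagged
(`negative_eigenvalue_flag`) but deliberately not corrected
(no Lingoes/Cailliez adjustment) — variance percentages are then relative
to the positive part of the spectrum, which is the convention most
band-matrix studies implicitly use. Eigenvector sign is fixed by making
each axis's largest-magnitude loading positive, for reproducibility.

## Synthetic data generator

The generator emulates the *structure* of a dominant-marker study, not its
biology: no coalescent, no mutation clock, no gel artifacts (co-migration,
intensity ambiguity and band-calling error are out of scope).

Defaults encode the emulated study conditions: 20 strains; the packaged
28-primer architecture (band counts 4–17, 288 bands total); two ancestors
weighted 18/20 and 2/20; the larger ancestor split into nested subgroups of
2, 14 and 2 strains; monomorphic fraction 0.30 (so 202 of 288 bands are
designed polymorphic, the panel's ≈70% level); ancestral presence
probability 0.5 per polymorphic band, redrawn per ancestor; per-strain,
per-band flip probability 0.05. Band sizes are drawn uniformly on
100–2100 bp in 10-bp steps, sorted within primer as on a gel. All draws
come from one seeded generator; identical configs give bit-identical
output.

Noise placement: flips and subgroup perturbations touch designed-polymorphic
bands only. Monomorphic bands model invariant species-diagnostic fragments,
and keeping them noise-free preserves the limit behaviours the generator is
specified by (monomorphic fraction 1 ⇒ all PIC = 0; flip probability 0 ⇒
clustermates identical). Each non-largest subgroup of an ancestor flips a
private block of 15 polymorphic bands of the ancestral profile — enough to
separate subgroups at intermediate tree heights (above the ≈10-band noise
scale between clustermates, well below the ≈100-band ancestor divergence)
without creating new top-level clusters. The value is a design choice, not
an emulated quantity.

A consequence worth noting: the *realized* polymorphic fraction is lower
than the designed 70%, because a designed-polymorphic band can end up fixed
across the panel (both ancestors drawing the same state and no strain
flipping: probability ≈ 0.5·0.95²⁰ ≈ 0.18 per band). Exact enumeration over
ancestor states and subgroup-flip membership gives an expected realized
fraction of ≈59%, and the test suite checks the simulation against that
enumeration rather than against the designed level. Passing tests on these
panels therefore show the pipeline recovers planted structure under
idealized symmetric noise; they do not certify behaviour under real-data
pathologies such as correlated scoring error.

## Numerical conventions and degenerate inputs

- Tolerances: 1e−9 for eigenvalue noise and oracle comparisons; 1e−12 slack
  on symmetry/monotonicity checks against round-off.
- Validation errors (`ValidationError`) for non-binary cells, duplicate
  ids, single-strain matrices, asymmetric or negative distance matrices,
  out-of-range thresholds/axes; CLI maps them to exit code 1 (I/O errors
  to 2).
- Degenerate cases defined rather than raised: all-zero strain pairs
  (similarity 0 + warning), primers with no polymorphic band (PIC 0 +
  warning).
- Problem sizes in the test suite — 6–8-leaf matrices for clustering
  oracles (200 random instances), 100 seeded 20×288 panels for cluster
  recovery, 50 seeds for the polymorphism-level check — were chosen as the
  smallest sizes at which the checked properties are non-trivial, and keep
  the whole suite around a few seconds.

## Known limitations

- Per-band PIC assumes dominance; codominant PIC and heterozygosity-based
  indices (Nei's H, Shannon) are out of scope.
- Only Jaccard association is implemented (no simple-matching or Dice),
  and only UPGMA linkage (no NJ/Ward), matching the emulated workflow.
- The published study's strain-level results (specific memberships at the
  0.718/0.575/0.435 cuts, the 35.48% three-axis PCoA variance) depend on a
  raw band matrix that was never deposited and are therefore not
  reproduction targets; the pipeline reproduces the *procedure* and is
  validated on simulated panels with known truth.
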