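# Methods

This note documents the statistical machinery, the modelling choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Pedigree data model and integrity checking

Pedigrees follow the LINKAGE pre-MAKEPED dialect (sex 1=male/2=female,
affection 2/1/0, allele 0 = missing).  A genotype with exactly one typed
allele is set fully missing, the LINKAGE convention.  Mendelian integrity is
checked jointly per nuclear family by an existence search over parental
genotype candidates: an untyped parent ranges over unordered pairs drawn
from the alleles observed in that nuclear family plus one wildcard standing
for "any unobserved allele" (a wildcard can never match an observed child
allele, which is the correct feasibility relaxation).  This detects
everything a trio-level check detects plus sibship-level impossibilities
with untyped parents; inconsistencies that only emerge *across* nuclear
families through an untyped connector are not detected.  Flagged genotypes
can be masked to missing (the default resolution; removing individuals is
deliberately not offered because masking is reversible and preserves family
structure).

"Unrelated individuals" — the set used for allele-frequency estimation, the
HWE filter and the PCA screen — are all individuals without parents on
record (founders and marry-in parents).  Within a pedigree these are
mutually unrelated by construction, and counting their alleles is the
founder-based frequency estimator; no EM refinement is attempted.

### Hardy–Weinberg filter

Genotype counts are tested against HWE expectations with a chi-square
goodness of fit on all k(k+1)/2 genotype cells, df = k(k−1)/2 (allele
frequencies estimated from the same sample).  When any expected cell count
falls below 5 the test switches to a Monte Carlo exact test: the 2n alleles
are permuted into pairs 10⁴ times (seeded) and the P-value uses the add-one
estimator.  Note a structural consequence: the smallest attainable Monte
Carlo P is 1/(10⁴+1) ≈ 10⁻⁴, which is *larger* than the default exclusion
threshold 9.5×10⁻⁵ — markers routed to the exact test are therefore
effectively never excluded at the default threshold.  With ~10² unrelated
individuals and 9–14 alleles most microsatellites take the Monte Carlo
path, so the default filter is intentionally conservative; the chi-square
path governs large-sample/biallelic situations and is the one whose null
calibration is verified in the tests.  Markers with fewer than 10 typed
unrelated unaffecteds are retained with a warning.

### Inbreeding loops

`add_inbreeding_loop` rewrites a founder couple as relatives by inserting
the minimal *valid* untyped ancestor scaffold (every inserted non-founder
has both parents present): e.g. a first-cousin loop inserts the shared
grandparental couple, two linking sibs and their two marry-in spouses.  The
catalogue covers full sib, half sib, avuncular, half-avuncular, first
cousin, half first cousin, second cousin, double first cousin and the
compound "half sibs plus first cousin" (P0 = 0.375).  Each construction is
verified against its exact (P0, P1, P2) by enumeration.

## Linkage engine

### Inheritance vectors and likelihoods

Per family, the segregation state at a position is a bit vector over scored
meioses (2 per non-founder on autosomes; on X only meioses with a choice
are scored — males are hemizygous, carrying one maternal slot, and must be
coded homozygous in the genotype file).  Marker likelihoods P(G | v) sum
ordered founder-allele assignments: a typed founder ranges over its two
phase orderings; an untyped founder ranges over the alleles observed in its
typed descendants plus one pooled pseudo-allele carrying the remaining
frequency mass — an exact marginalization, since any allele not seen in a
founder's typed descendants is interchangeable with any other.  Consistency
of every typed non-founder is evaluated vectorized over all 2^b inheritance
vectors through precomputed founder-slot arrays.  A signature-grouped
recursive solver is kept as fallback for pathologically unconstrained
founder sets, and the two paths are cross-checked in the tests, along with
a brute-force transmission-path oracle on small families.

The meiosis budget defaults to 16 bits (65 536 vectors) and raising it is
the caller's explicit choice; larger pedigrees should be split.  No
founder-couple symmetry reduction is applied — correctness and clarity
first; the vectorized path keeps a 12-bit family ~1 ms per marker.

### Multipoint HMM

Between adjacent markers each meiosis bit flips independently with the
Haldane recombination fraction θ = (1 − e^(−2d/100))/2.  The transition
kernel is diagonal in the Walsh–Hadamard basis with eigenvalue (1−2θ) per
set bit, so each forward–backward step costs two fast Walsh–Hadamard
transforms.  θ = 0.5 exactly decouples markers and θ = 0 copies
information, both verified as invariants.  Posteriors are evaluated at
marker positions only; off-marker grids are not needed because all reported
quantities are per marker.

### S_pairs, weighting and the Kong & Cox LOD

S_pairs sums, over all pairs of affected members, the Whittemore–Halpern
cross-count of IBD-shared alleles (0/1/2 for outbred pairs; inbred pairs
can exceed 2; male–male X pairs max at 1).  Unaffected members contribute
genotype information only.  Null moments (μ₀, σ₀) come from exact
enumeration under the uniform prior, and Z = (E[S_pairs | G] − μ₀)/σ₀.
Affected pairs with no common ancestor (e.g. two affected marry-ins)
contribute a constant 0 and are harmless.

Families are weighted w_f ∝ k_f^(power−1)·σ₀ with k_f the number of
affected pairs, normalized to Σw² = 1.  Because w_f·Z_f =
k_f^(power−1)·(S_obs − μ₀), power=1 counts each affected pair's raw excess
sharing once (pair weighting) and power=0 weights each family's per-pair
average equally (family weighting); the default 0.5 is the standard
compromise for unequal pedigree sizes.

The combined statistic maximizes ℓ(δ) = Σ log(1 + δ w_f Z_f).  δ is
restricted so that 1 + δ w_f Z_f(v) > 0 for *every attainable* vector v of
every family (bounds from each family's extreme standardized scores), which
keeps the one-parameter model a genuine likelihood on both sides of 0; the
concave objective is maximized by bounded 1-D search at tolerance 1e-10.
LOD = ℓ(δ̂)/ln 10 ≥ 0 and the track reports sign(δ̂)·LOD.  Nominal
one-sided P uses P = 1 − Φ(√(2 ln10·LOD)) evaluated at max(signed LOD, 0);
deficit positions therefore read P = 0.5 rather than P > 0.5.
Information content is 1 − H(posterior)/b bits per family, combined across
families weighted by meiosis count.

Null calibration at the full 58-pedigree design is verified by simulation:
P(signed LOD ≥ 0.59) = 0.045 over 10³ unlinked single-marker replicates
(binomial 3 SE band around 0.05).  With incomplete marker information the
statistic is expected to sit slightly below nominal, because σ₀ is the
perfect-data null SD while E[S_pairs | G] shrinks toward μ₀; the measured
calibration shows this conservatism is mild at the study's information
levels (~0.4–0.6 single-marker IC).

### Regions

Linkage regions are maximal runs of ≥ 2 consecutive markers with signed
LOD ≥ 0.59 (nominal P ≤ 0.05); peaks break ties leftmost.

## Relatedness

Expected (P0, P1, P2) for a relationship come from exact enumeration of the
inheritance vectors of the canonical pedigree's ancestor closure — the same
engine as linkage, so the catalogue and the loop builders cannot drift
apart — and are cross-checked by vectorized gene-drop Monte Carlo.

Genotype-based estimation treats the marker-wise genotype pairs as a
three-component mixture over the latent IBD state, with closed-form
component likelihoods P(g₁, g₂ | IBD = j) given the allele frequencies (the
classical conditional-kinship formulas, each verified to marginalize back
to the HWE genotype probability).  The mixing proportions are fitted by EM,
which respects the probability simplex by construction; a final Euclidean
simplex projection guards against floating drift.  This likelihood-weighted
estimator was chosen over IBS-count moments because moments on "how many
alleles match" discard "which allele matches": at heterozygosity 0.7 the
usable IBS moment equations collapse to an IBS=0 ratio whose sampling SD at
515 markers is ≈ 0.09 — too noisy to respect the ±0.02 accuracy the
binning needs near P0 = 1.  Measured bias of the mixture estimator is
≤ 0.014 across the catalogue at 515 markers.  Markers are treated as
independent (reasonable at ~10 cM spacing; residual linkage slightly
understates the estimator's SE but does not bias it).

Classification assigns the nearest catalogue bin, with one override: any
P0 ≥ 0.95 is "unrelated" — the consanguinity flag dominates nearest-bin
distance, so 0.96 reads unrelated even though 0.9375 is the nearer center.
Summaries report per-bin counts, one-decimal percentages, and the overall
whole-percent related (P0 < 0.95).

## Substructure screen

Each microsatellite with n observed alleles among the unrelated set becomes
n−1 columns counting copies of each allele, omitting the most frequent;
count ties are broken on column *content*, which makes the recoding — and
hence the PCA — exactly invariant under allele relabeling.  Markers with
more than 20% missingness are dropped; remaining missing entries are
mean-imputed.  Columns are centered and scaled to unit variance before PCA
(for multi-allelic indicator columns there is no canonical binomial
normalization, so plain unit variance is used and documented).  Eigenvalue
sums equal the processed matrix's total variance; structure/no-structure
behaviour is exercised by simulation (two Balding–Nichols-style diverged
subpopulations separate on PC1 at divergence 0.05; panmictic data with
random religion labels give AUC ≈ 0.5 on PC1–PC3).  Bayesian admixture
modelling is out of scope; the PCA path is the substructure screen.

## Geographic heterogeneity

### UTM

Coordinates convert to UTM (WGS84, scale 0.9996, false easting 500 000 m,
zone 45 default) with the Karney/Krüger series to n⁴ — sub-millimeter
within a zone; the inverse solves the conformal latitude by Newton.  Tests
compare against an independently coded Snyder-series oracle (< 1 m) and
require < 1 m round trips.  Latitudes outside [−80, 84] are rejected.

### Per-family LOD decomposition

Family f's contribution at a marker is sign(δ̂)·log₁₀(1 + δ̂ w_f Z_f) at
the *combined* δ̂, so contributions sum to the combined signed LOD exactly
(verified to 1e-9).  Re-maximizing δ per family would break this
conservation and is deliberately not the default.

### CART

The regression tree minimizes within-node sum of squared deviations of the
per-family LOD contributions — the regression analogue of the
classification criteria usually cited for recursive partitioning.  Numeric
rules read "var < cut" with the true branch on the left; candidate cuts are
midpoints of sorted unique values with ties toward the smaller cut, and the
religion factor is split optimally by ordering its levels on mean response.
Defaults: minimum leaf 5 families, minimum split 10, depth cap 10.  The
grown tree is pruned by weakest-link cost-complexity with 10-fold
cross-validation (seeded fold assignment); the selected size is the
smallest tree whose CV error ties the CV minimum — the operational reading
of "the first distinct minimum" of the CV error curve.  Node bookkeeping
(n, mean, summed contribution) is conserved through every split.  An
independent off-the-shelf CART implementation is used in the tests as an
oracle for the first split; it is never the implementation.

### IDW surfaces

Cell values are Σ w_i LOD_i / Σ w_i with w_i = d_i^(−power), power 1
(first-order: a point 2 km from a centroid contributes exactly 8× more
than one 16 km away), all points contributing with no search radius, 0.5 km
cells, bounds = family bounding box padded 1 km.  A point within 1 m of a
centroid takes the cell exactly.  Output is an ESRI ASCII grid;
cartographic rendering is out of scope.

## Synthetic studies

The generator reproduces the primary study design *exactly* at the
structure level: 58 pedigrees / 74 nuclear families / 353 individuals
(31 Hindu, 27 Muslim), sibship classes of (1,2,3,4,5) affected sibs =
(16,47,8,2,1), 147 affected offspring, and 25 affected (historical-case)
parents modelled as affected founder mothers.  The 16 single-affected
nuclear families are attached to larger pedigrees through an unaffected
linking son, giving two- and three-nuclear-family pedigrees whose meiosis
counts stay within the engine cap.  Published totals do not pin down every
degree of freedom — the split of unaffected sibs across families and the
attachment topology are chosen once, deterministically, to match the
published row totals.

Marker panels default to 9–14 alleles cycling across markers; frequencies
are a Dirichlet draw blended toward uniform (or a point mass) so each
marker's heterozygosity hits the 0.7 target exactly.  Gene drop draws
founder alleles from those frequencies and walks each meiosis as a
two-state Markov chain with the Haldane flip probability per interval.
A planted biallelic risk locus (penetrances f0 ≤ f1 ≤ f2) is inserted at
its map position; ascertainment conditions on the *designed* affection
pattern by rejection sampling at the locus alone and then extends the
accepted state outward along the chromosome — exact, because the
inheritance chain is reversible and founder alleles at other positions are
independent.  Genotype missingness (default 9%) is applied uniformly at the
end.  True inheritance vectors are recorded per family and marker in the
engine's meiosis order, enabling exact oracle tests of the scoring path.
All generators are driven by a single integer seed and are byte-for-byte
reproducible.

Geography scatters families around village-style cluster centers inside a
58 km × 31 km frame (largest pairwise distance ≈ 55 km), religion is
carried from the design, and a risk locus can be restricted to one cluster
(families elsewhere are drawn under the null).  Consanguinity loops can be
installed per founder couple at configured per-bin rates
(`table2_rates()` matches the observed 22/47 related parental pairs); the
primary preset installs none by default because loop correction is an
analysis-stage option, not part of the base design.

What the generator does **not** emulate: realistic founder haplotype
structure (founders are in linkage equilibrium), marker mutation,
genotyping-error mechanisms beyond uniform missingness, informative
missingness, or religion-correlated geography.  Passing tests therefore
demonstrate correctness of the machinery under the stated design, not
robustness to those real-data features.

### Power and recovery experiments (problem sizes used)

- Null calibration: 10³ unlinked single-marker replicates of the full
  58-pedigree design.
- Planted-locus recovery: 20 replicates of a 6-marker, 10 cM panel with a
  dominant near-fully-penetrant locus (q=0.05, f=(0.01,0.9,0.9)) at a
  marker; the genome-wide peak sits at the planted marker in ≥ 90%.
- Power: the same dominant preset reaches the LOD 2.07 threshold in
  essentially every replicate; the power helper reports the binomial SE
  alongside the estimate, and no attempt is made to match any particular
  published power figure (the major-gene model behind those figures is not
  fully specified anywhere).
- Cluster isolation: a *recessive* fully penetrant locus
  (q=0.3, f=(0.002,0.02,0.95)) restricted to one of three clusters, typed
  at three markers 2 cM apart.  Recessive was chosen because affected sib
  pairs under a dominant locus share only E[S_pairs]=1.5 (a 0.7 SD step,
  unrecoverable from 58 noisy points by any partitioner), whereas a
  recessive locus forces IBD=2.  Success means the majority of the
  max-summed-LOD leaf's families belong to the planted cluster; the pruned
  tree succeeds in ≥ 80% of 50 replicates, and a 5σ step response has its
  boundary recovered within one inter-family gap in ≥ 90% of replicates.

## Known limitations

- The meiosis cap (16 bits) excludes very large uncollapsed pedigrees and
  deep loop scaffolds (a second-cousin loop adds 12 bits); split pedigrees
  or raise the cap explicitly.
- X-linked analysis uses the documented hemizygote simplification; the
  autosomal engine is the reference path.
- The HWE Monte Carlo exact test cannot reach the default exclusion
  threshold (see above) — by construction, not by accident.
- Nominal P-values are uncorrected for multiple testing throughout, by
  design.
- CV pruning makes tree size mildly seed-dependent on weak signals; the
  fold assignment is seeded for reproducibility.
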