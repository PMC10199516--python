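# Methods

## The analysis model

The package operates on the post-binning layer of a fermented-food
metagenomics study. Its units are:

- **MAG** — a genome bin with a fermentation-type (habitat) label and
  CheckM-style completeness/contamination estimates. Bins below medium
  quality (completeness < 50% or contamination > 10%, both bounds
  inclusive on the retained side) are discarded before any clustering.
- **Genotype / species** — clusters of MAGs at 99% and 95% ANI. Clustering
  is greedy and centroid-based, as in dRep: the unassigned MAG with the
  highest quality score (completeness − 5 × contamination; ties broken by
  lexicographically smallest id) seeds a cluster and absorbs every
  unassigned MAG whose symmetrized ANI reaches the threshold *and* whose
  genome overlap is ≥ 0.25. Greedy assignment deliberately differs from
  single-linkage closure: it cannot chain distant genomes through
  intermediates. On ANI distributions whose within/between ranges are
  separated from the threshold the two coincide, which is asserted against
  a brute-force union-find oracle in the tests.
- **ANI symmetrization** — directed pairs may disagree (fragmented
  genomes); ANI is averaged across directions, overlap takes the minimum.
  The conservative minimum means a fragmented genome cannot join a cluster
  on the strength of its own small denominator. Absent pairs are treated as
  below any threshold, matching fastANI's reporting floor.
- **GCF** — gene cluster families are connected components of the BGC
  similarity network. The distance between two BGCs with ordered domain
  lists is `1 − ½·J − ½·A`: `J` the Jaccard index of domain sets (defined
  as 1 for two empty lists), `A` the Jaccard index of unordered adjacent
  domain pairs (falling back to `J` when either list has < 2 domains).
  Edges require strict `d < c` with `c = 0.3`, so `c = 0` yields no edges.
  The metric is symmetric, bounded in [0, 1] and zero exactly on identical
  ordered lists; the triangle inequality is not claimed and not needed,
  since family extraction is purely component-based. This is a simplified,
  fully specified surrogate for the class-weighted BiG-SCAPE score; the
  cutoff semantics match, the numerical values do not. Reference (MIBiG-
  like) records participate in clustering exactly like food BGCs, and a
  family containing one is *known*.
- **Habitat specificity** — a family whose non-reference members all come
  from one fermentation type is habitat-specific, and every member BGC
  inherits the label (a singleton family is therefore always specific).
  Reference members carry no habitat and cannot break specificity.
  Habitat-specific BGCs are attributed by origin with the species rule
  taking precedence: habitat-specific species → `habitat_specific_species`;
  otherwise habitat-specific genotype → `habitat_specific_genotype`;
  otherwise the residual `multi_habitat_genotype`. The residual class is
  reported, never merged: real data can populate it (noisy clustering) and
  so can the simulator (a genotype whose MAGs genuinely span habitats).
- **Novelty** — BGCs are featurized as domain-count vectors (counts capped
  at 255, mirroring byte-ranged features); each reference ecosystem is
  summarized by the arithmetic-mean vectors of its families; novelty is the
  Euclidean distance to the nearest centroid (ties broken by smallest
  centroid id). Classification is inclusive: `d ≥ t` is novel, `d ≥
  t_extreme` extremely divergent (`t_extreme ≥ t`; extreme counts nest
  inside novel counts). Against three ecosystems, far from all is
  *unique*, close to all is *shared*, anything else *other*. The interface
  retains the conventional absolute thresholds 900/1800 as CLI defaults,
  but these belong to the sub-Pfam feature space of the original pipeline;
  this package's feature space has no comparable scale, so the library
  default calibrates `t` per run (below).

## Threshold calibration

`calibrate_threshold` places the novelty cutoff at the split maximizing the
between-class variance of the observed nearest-centroid distances (Otsu's
criterion), at the midpoint between the boundary values of the two classes.
On a zero-noise synthetic community the distance distribution is exactly
bimodal — shared-family BGCs at 0, everything else at ≥ 1 (see prototype
margins below) — and the calibrated threshold classifies with zero error.
Under mutation noise the populations widen but stay separated at the
default rates. The calibration assumes bimodality: on a unimodal
distribution it degrades to an arbitrary central split and should be
replaced by an explicit `novelty_t`.

## PCA

The BGC × ecosystem distance matrix is column-centered and decomposed by
SVD. Axis signs are fixed by making each axis's largest-magnitude loading
positive, so coordinates are reproducible across runs; component variances
are non-increasing and sum to the total variance of the centered matrix. A
constant matrix yields all-zero coordinates with a warning rather than an
error.

## Statistics

- **Chi-squared**: Pearson statistic from row/column margins, no continuity
  correction, df = (r−1)(c−1), p from the chi-squared survival function. A
  zero margin raises an error naming the offending margin.
- **One-way ANOVA + Tukey HSD**: the usual sum-of-squares decomposition;
  each pair's studentized-range statistic uses the pooled within-group
  variance with Tukey–Kramer scaling for unequal group sizes, and adjusted
  p-values come from the studentized-range distribution. Zero within-group
  variance is an error (degenerate F), not a silent infinity.
- **Wilcoxon rank-sum**: two-sided, average ranks for ties. Exact p by
  enumeration of rank assignments when n ≤ 12 and there are no ties;
  otherwise a normal approximation with tie correction *and* a continuity
  correction. The continuity correction follows R's `wilcox.test` default
  and keeps the approximation within 0.02 of the exact tail over the whole
  6-vs-6 statistic range; without it the discrepancy reaches 0.07.
- **Fractions**: percentages are rounded half-up to two decimals (0.125 →
  0.13), matching the conventional printed style; zero denominators yield
  entries marked undefined rather than being dropped.

## The synthetic community generator

The generator emulates the four input kinds (MAG table, ANI table, BGC
catalogs, reference sets) with planted truth. What it models, and what it
deliberately does not:

- **Taxonomic structure.** Species are habitat-specific with probability
  `p_habitat_specific_species` (default 0.82, a realistic specificity rate
  for fermentation communities); multi-habitat species draw a uniform
  habitat subset of size ≥ 2. Habitats use real fermentation-type names
  (cheese, kimchi, bean paste, …; default 5 types, 40 species, 1–3
  genotypes per species, 1–2 MAGs per genotype — a desk-scale community of
  ~130 MAGs). Every planted habitat of a species is materialised on at
  least one member MAG, so the invariant *species habitat set = union of
  member habitats* holds by construction; a species with fewer MAGs than
  planted habitats has its habitat set shrunk and re-recorded before any
  specificity flag is derived.
- **ANI.** Values are drawn per unordered pair from ranges keyed by the
  planted relation — same genotype (99.2–100), same species (95.5–98.5),
  different species (80–94) — plus optional Gaussian jitter (default SD
  0.1) truncated into (0, 100]. Within-species overlap fractions stay above
  the 0.25 dereplication floor. No nucleotide sequences exist; ANI is
  synthesized directly, which is the point: the clustering contract is
  exercised without an assembler in the loop.
- **BGC content tracks taxonomy.** Family prototypes are random domain
  strings (length 5–15 over a synthetic vocabulary of 400 labels),
  rejection-sampled so every prototype pair is farther apart than
  `prototype_margin = 0.6 = 2c`; since a margin above 0.5 forces distinct
  domain-count vectors, planted families are separable both in the GCF
  network and in feature space at zero noise. Each species draws a family
  repertoire shared by its genotypes (a small common pool of widespread
  families covers ~25% of draws; the rest are dedicated lineage-specific
  prototypes), and genotypes may add private families — the concrete
  mechanism behind habitat-specific BGCs inside multi-habitat species.
  Members are mutated copies of their prototype (per-position substitution,
  default rate 0.05).
- **Novelty.** A reserved fifth of the vocabulary never appears in
  ecosystem references; BGCs planted as novel (default 15%) draw from it,
  forcing large nearest-centroid distances without any tuning. Each
  ecosystem reference covers a configurable fraction (default 0.85) of the
  food families plus its own families; the per-ecosystem planted novelty
  flag is simply "family not covered by that ecosystem".
- **Known families.** A fraction (default 0.03) of food families is seeded
  with a MIBiG-like reference record carrying the prototype itself, so
  known-family flagging emerges from co-clustering rather than lookup.
- **Determinism.** One integer seed feeds per-component substreams
  (structure, quality, prototypes, BGCs, ANI, references), so regenerating
  one component never perturbs another and identical config + seed
  reproduces the bundle byte-identically.

What passing recovery tests on this generator shows: the pipeline's
thresholding, clustering, labelling and attribution logic is correct under
the stated noise models. What it does not show: robustness to real-world
failure modes the generator omits — chimeric bins, fragmented BGCs at
contig edges, realistic Pfam nomenclature, phylogenetically correlated gene
content, or the true BiG-SCAPE/BiG-SLiCE numerical scales.

## Problem sizes and numerical choices

The default community (~130 MAGs, ~300 BGCs, ~900 reference BGCs) keeps a
full end-to-end run around two seconds and the entire test suite under half
a minute; all-pairs distance computation is quadratic and dominates, so
scale community size, not thresholds, for larger experiments. Boundary
semantics throughout: quality and ANI thresholds inclusive, GCF cutoff
strictly exclusive, novelty thresholds inclusive. Cluster and family ids
are deterministic (quality-ranked representatives; smallest member BGC id),
so repeated runs produce identical tables.

## Known limitations

- Greedy centroid clustering depends on the quality ranking; on ANI
  distributions straddling a threshold its output differs from
  single-linkage and from the original per-type dereplication workflow
  (this package clusters globally across habitats, which the definition of
  habitat-specific genotypes requires).
- The BGC distance is a domain-content surrogate; absolute family counts
  are not comparable to BiG-SCAPE's, only the cutoff semantics are.
- Novelty distances are not comparable to BiG-FAM distances; only the
  ordering and the calibrated classification carry meaning here.
- The per-class GCF mode (`per_class=True`) restricts edges to same-class
  pairs without claiming fidelity to BiG-SCAPE's class-stratified networks.
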