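# fermbgc

Habitat specificity and novelty of biosynthetic gene clusters (BGCs) in
fermented-food microbial communities.

Fermented foods — cheese, kimchi, bean paste, kombucha and their relatives —
host bacterial communities whose secondary-metabolite repertoires are
largely uncharted. Given metagenome-assembled genomes (MAGs) with habitat
labels and quality estimates, a pairwise average-nucleotide-identity (ANI)
table, and BGC annotations, this package answers three questions a
fermentation microbiologist would ask:

1. **Which species and strains are habitat-specific?** MAGs are quality
   filtered (completeness ≥ 50%, contamination ≤ 10%) and clustered at two
   ANI levels — genotypes at 99% ANI with ≥ 25% genome overlap, species at
   95% ANI. A cluster occurring in exactly one fermentation type is
   habitat-specific.
2. **Which BGCs are habitat-specific, and why?** BGCs are grouped into gene
   cluster families (GCFs): the distance between two BGCs is
   `d(a, b) = 1 − ½·J(a, b) − ½·A(a, b)` where `J` is the Jaccard index of
   their domain sets and `A` the Jaccard index of their unordered adjacent
   domain pairs; pairs with `d < 0.3` are edges, GCFs are connected
   components, and families co-clustering with MIBiG-like reference records
   are *known*. A BGC whose family comes from a single fermentation type is
   habitat-specific, and each one is attributed to a habitat-specific
   species, a habitat-specific genotype inside a multi-habitat species, or a
   residual class.
3. **Which BGCs are novel or unique?** Each BGC becomes a byte-capped
   domain-count vector; reference ecosystems (human-gut / ocean / soil
   surrogates) are summarized by GCF centroids, and the Euclidean distance
   to the nearest centroid measures novelty. Distances ≥ t are *novel*
   (≥ 2t *extremely divergent*); far from all three ecosystems is *unique*,
   close to all three is *shared*. The BGC × ecosystem distance matrix is
   projected with PCA.

Because real communities come without ground truth, the package includes a
first-class synthetic community generator that plants species structure,
GCF structure, habitat occupancy and novelty labels, and records them — so
every stage is validated by exact recovery at zero noise. The supporting
statistics (chi-squared association, one-way ANOVA with Tukey HSD, Wilcoxon
rank-sum) are implemented from their textbook definitions and cross-checked
against independent implementations in the tests.

## Worked example

```python
from fermbgc import CommunityConfig, generate_community, run_bundle, origin_fractions

bundle = generate_community(CommunityConfig(seed=1))
result = run_bundle(bundle)
n_specific = sum(1 for l in result.bgc_labels if l.is_habitat_specific)
print(f"{n_specific} of {len(result.bgc_labels)} BGCs are habitat-specific")
for origin, (count, pct) in origin_fractions(result.attributions).items():
    print(f"  {origin}: {count} ({pct}%)")
```

prints

```
240 of 306 BGCs are habitat-specific
  habitat_specific_species: 213 (88.75%)
  habitat_specific_genotype: 16 (6.67%)
  multi_habitat_genotype: 11 (4.58%)
```

i.e. 78% of this community's BGCs occur in one fermentation type only, and
most of those sit on species that are themselves confined to one habitat;
a smaller share is carried by single-habitat genotypes of species that
span habitats. The `examples/` directory holds one short script per
capability (simulation, dereplication, GCF clustering, specificity
decomposition, novelty queries, statistics); each prints the numbers it
computes and says what they mean. A thin CLI wraps the same stages:

```sh
fermbgc all --seed 1 --outdir out/         # simulate + full analysis
fermbgc derep --mags mags.tsv --ani ani.tsv --outdir out/
```

All interchange formats are plain TSV/JSON; the ANI reader also accepts
headerless fastANI output, and an antiSMASH-style GenBank subset reader is
provided for BGC domain annotations.

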