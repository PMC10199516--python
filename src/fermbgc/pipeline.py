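"""End-to-end orchestration: quality filter -> ANI clustering -> GCFs ->
habitat specificity -> novelty queries -> summary fractions.

`run_pipeline` executes the full analysis on a community (real tables or a
synthetic bundle); `evaluate_recovery` scores the result of a synthetic run
against its planted truth, which is how the pipeline is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import catalog, gcf, novelty, specificity
from .catalog import AniTable, GenomeCluster, HabitatPartition
from .gcf import GeneClusterFamily
from .novelty import EcosystemReference, NoveltyResult
from .records import BgcRecord, MagRecord
from .simulate import CommunityBundle
from .specificity import (
    ORIGIN_GENOTYPE,
    ORIGIN_RESIDUAL,
    ORIGIN_SPECIES,
    OriginAttribution,
    SpecificityLabel,
)
from .stats import FractionEntry, round_half_up, summary_fractions



@dataclass
class PipelineResult:
    mags_retained: list[MagRecord]
    genotype_clusters: list[GenomeCluster]
    species_clusters: list[GenomeCluster]
    species_partition: HabitatPartition
    genotype_partition: HabitatPartition
    families: list[GeneClusterFamily]
    gcf_labels: list[SpecificityLabel]
    bgc_labels: list[SpecificityLabel]
    attributions: list[OriginAttribution]
    habitat_rows: list
    novelty_results: list[NoveltyResult]
    fractions: list[FractionEntry]

    def fraction(self, label: str) -> FractionEntry:
        for f in self.fractions:
            if f.label == label:
                return f
        raise KeyError(label)


def run_pipeline(
    mags: Sequence[MagRecord],
    ani: AniTable,
    bgcs: Sequence[BgcRecord],
    reference_bgcs: Sequence[BgcRecord] = (),
    ecosystem_bgcs: Mapping[str, Sequence[BgcRecord]] | None = None,
    genotype_ani: float = catalog.GENOTYPE_ANI,
    species_ani: float = catalog.SPECIES_ANI,
    min_overlap: float = catalog.MIN_OVERLAP,
    gcf_cutoff: float = gcf.GCF_CUTOFF,
    novelty_t: float | None = None,
    novelty_t_extreme: float | None = None,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> PipelineResult:
    """Run the whole analysis; returns every intermediate product.

    ``novelty_t=None`` calibrates the novelty threshold from the widest gap
    of the observed nearest-centroid distance distribution (the surrogate
    feature space carries no absolute scale); pass an explicit value to pin
    it.
    """
    retained = catalog.filter_by_quality(mags, min_completeness, max_contamination)
    kept_ids = {m.mag_id for m in retained}
    genotypes = catalog.cluster_genomes(retained, ani, genotype_ani, min_overlap, "genotype")
    species = catalog.cluster_genomes(retained, ani, species_ani, min_overlap, "species")
    sp_part = catalog.habitat_specific_clusters(species)
    gt_part = catalog.habitat_specific_clusters(genotypes)

    food = [b for b in bgcs if b.mag_id in kept_ids]
    mag_habitats = {m.mag_id: m.habitat for m in retained}
    families = gcf.cluster_bgcs(list(food) + list(reference_bgcs), gcf_cutoff, mag_habitats)

    bgc_habitats = {b.bgc_id: mag_habitats[b.mag_id] for b in food}
    gcf_labels = [specificity.classify_gcf_habitat(f, bgc_habitats) for f in families]
    bgc_labels = specificity.classify_bgc_specificity(food, families, bgc_habitats)
    specific_ids = {l.subject_id for l in bgc_labels if l.is_habitat_specific}
    specific_bgcs = [b for b in food if b.bgc_id in specific_ids]
    attributions = specificity.attribute_origin(specific_bgcs, species, genotypes)
    habitat_rows = specificity.per_habitat_summary(
        bgc_labels, attributions, {b.bgc_id: b.bgc_class for b in food}
    )

    novelty_results: list[NoveltyResult] = []
    if ecosystem_bgcs:
        vocab = novelty.build_vocabulary(food, *ecosystem_bgcs.values())
        references: list[EcosystemReference] = []
        for name in sorted(ecosystem_bgcs):
            eco_records = list(ecosystem_bgcs[name])
            eco_fams = gcf.cluster_bgcs(eco_records, gcf_cutoff)
            references.append(
                novelty.gcf_centroids(
                    name, eco_fams, {b.bgc_id: b for b in eco_records}, vocab
                )
            )
        if novelty_t is None:
            probe = novelty.query_catalog(food, references, vocab, t=0.0, t_extreme=0.0)
            novelty_t = novelty.calibrate_threshold(
                d for r in probe for d in r.distances.values()
            )
        if novelty_t_extreme is None:
            novelty_t_extreme = 2.0 * novelty_t
        novelty_results = novelty.query_catalog(
            food, references, vocab, novelty_t, novelty_t_extreme
        )

    counts: list[tuple[str, int, int]] = []
    n_bgcs = len(food)
    n_specific = len(specific_ids)
    counts.append(("habitat_specific_bgcs", n_specific, n_bgcs))
    origin = specificity.origin_fractions(attributions)
    counts.append(("origin_habitat_specific_species", origin[ORIGIN_SPECIES][0], n_specific))
    counts.append(("origin_habitat_specific_genotype", origin[ORIGIN_GENOTYPE][0], n_specific))
    counts.append(("origin_multi_habitat_genotype", origin[ORIGIN_RESIDUAL][0], n_specific))
    counts.append(
        ("habitat_specific_species", len(sp_part.habitat_specific), len(species))
    )
    counts.append(
        ("habitat_specific_genotypes", len(gt_part.habitat_specific), len(genotypes))
    )
    if novelty_results:
        first_eco = sorted(novelty_results[0].distances)[0] if novelty_results else None
        n_novel_any = sum(
            1
            for r in novelty_results
            if all(c != "known" for c in r.novelty_class.values())
        )
        counts.append(("novel_bgcs_all_ecosystems", n_novel_any, n_bgcs))
        n_unique = sum(1 for r in novelty_results if r.uniqueness_class == "unique")
        counts.append(("unique_bgcs", n_unique, n_bgcs))
    fractions = summary_fractions(counts)

    return PipelineResult(
        mags_retained=retained,
        genotype_clusters=genotypes,
        species_clusters=species,
        species_partition=sp_part,
        genotype_partition=gt_part,
        families=families,
        gcf_labels=gcf_labels,
        bgc_labels=bgc_labels,
        attributions=attributions,
        habitat_rows=habitat_rows,
        novelty_results=novelty_results,
        fractions=fractions,
    )


def run_bundle(bundle: CommunityBundle, **kwargs) -> PipelineResult:
    """Run the pipeline on a synthetic community bundle."""
    return run_pipeline(
        bundle.mags,
        bundle.ani,
        bundle.bgcs,
        bundle.reference_bgcs,
        bundle.ecosystem_bgcs,
        **kwargs,
    )


def _partition(clusters: Sequence[GenomeCluster]) -> set[frozenset[str]]:
    return {frozenset(c.member_mag_ids) for c in clusters}


def evaluate_recovery(bundle: CommunityBundle, result: PipelineResult) -> dict[str, float]:
    """Score a synthetic run against its planted truth.

    Partition comparisons are exact (1.0 iff identical); label comparisons
    are per-item agreement fractions. All values are in [0, 1].
    """
    truth = bundle.truth
    out: dict[str, float] = {}
    out["genotype_partition_exact"] = float(
        _partition(result.genotype_clusters) == truth.genotype_partition()
    )
    out["species_partition_exact"] = float(
        _partition(result.species_clusters) == truth.species_partition()
    )
    food_and_ref = [b.bgc_id for b in bundle.bgcs] + [b.bgc_id for b in bundle.reference_bgcs]
    recovered_fams = {
        frozenset(m for m in f.member_bgc_ids) for f in result.families
    }
    out["family_partition_exact"] = float(
        recovered_fams == truth.family_partition(food_and_ref)
    )

    # habitat-specificity of species clusters
    sp_truth = {
        sp: len(h) == 1 for sp, h in truth.species_habitats.items()
    }
    match = total = 0
    for c in result.species_clusters:
        rep_sp = truth.genotype_to_species[truth.mag_to_genotype[c.representative_mag_id]]
        match += c.is_habitat_specific == sp_truth[rep_sp]
        total += 1
    out["species_specificity_accuracy"] = match / total if total else 1.0

    # BGC habitat-specificity labels vs truth family habitat sets
    truth_specific = {
        bid: len(truth.family_habitats[truth.bgc_to_family[bid]]) == 1
        for bid in truth.bgc_mag
    }
    labels = {l.subject_id: l.is_habitat_specific for l in result.bgc_labels}
    agree = [labels[b] == truth_specific[b] for b in labels if b in truth_specific]
    out["bgc_specificity_accuracy"] = sum(agree) / len(agree) if agree else 1.0

    # origin classes
    origin = {a.bgc_id: a.origin_class for a in result.attributions}
    truth_origin = {
        bid: truth.origin_class(bid) for bid, spec in truth_specific.items() if spec
    }
    agree = [origin.get(b) == cls for b, cls in truth_origin.items()]
    out["origin_accuracy"] = sum(agree) / len(agree) if agree else 1.0

    # known-family flags: recovered family is known iff it holds a reference record
    match = total = 0
    for fam in result.families:
        truth_known = any(
            truth.family_known.get(truth.bgc_to_family.get(m, ""), False)
            for m in fam.member_bgc_ids
        )
        match += fam.is_known == truth_known
        total += 1
    out["known_family_accuracy"] = match / total if total else 1.0

    # per-ecosystem novelty flags (novel = not shared with that ecosystem)
    agree_n = total_n = 0
    for r in result.novelty_results:
        for eco, cls in r.novelty_class.items():
            predicted_novel = cls != "known"
            agree_n += predicted_novel == truth.bgc_novel_vs[eco][r.bgc_id]
            total_n += 1
    out["novelty_flag_accuracy"] = agree_n / total_n if total_n else 1.0

    # uniqueness classes
    if result.novelty_results:
        agree = []
        for r in result.novelty_results:
            flags = truth.bgc_novel_vs
            far = [flags[e][r.bgc_id] for e in sorted(flags)]
            truth_cls = "unique" if all(far) else ("shared" if not any(far) else "other")
            agree.append(r.uniqueness_class == truth_cls)
        out["uniqueness_accuracy"] = sum(agree) / len(agree)
    return out
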