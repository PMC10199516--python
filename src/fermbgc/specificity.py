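"""Habitat specificity of gene cluster families and its taxonomic origin.

A GCF whose (non-reference) members all come from one fermentation type is
habitat-specific, and every member BGC inherits that label. Habitat-specific
BGCs are then decomposed by origin: those carried by habitat-specific
species, those carried by habitat-specific genotypes within multi-habitat
species, and a residual class of BGCs on genotypes that themselves span
habitats. The species rule takes precedence, which is what makes the
two-way percentage split well-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .catalog import GenomeCluster
from .gcf import GeneClusterFamily
from .records import BgcRecord
from .stats import round_half_up

logger = logging.getLogger(__name__)

ORIGIN_SPECIES = "habitat_specific_species"
ORIGIN_GENOTYPE = "habitat_specific_genotype"
ORIGIN_RESIDUAL = "multi_habitat_genotype"


@dataclass(frozen=True)
class SpecificityLabel:
    subject_id: str
    scope: str  # "gcf" | "bgc"
    is_habitat_specific: bool
    habitat: str | None = None  # set only when specific
    applicable: bool = True  # False for reference-only families


@dataclass(frozen=True)
class OriginAttribution:
    bgc_id: str
    origin_class: str
    species_cluster_id: str
    genotype_cluster_id: str


def classify_gcf_habitat(
    gcf: GeneClusterFamily, bgc_habitats: Mapping[str, str]
) -> SpecificityLabel:
    """Label one family: habitat-specific iff all non-reference members share a habitat.

    Reference members (MIBiG-like) are excluded from the habitat set; a
    family with only reference members is not applicable and excluded from
    counts. Singleton families are habitat-specific by construction.
    """
    habitats = set()
    n_nonref = 0
    for member in gcf.member_bgc_ids:
        if member in bgc_habitats:
            habitats.add(bgc_habitats[member])
            n_nonref += 1
    if n_nonref == 0:
        return SpecificityLabel(gcf.gcf_id, "gcf", False, None, applicable=False)
    if len(habitats) == 1:
        return SpecificityLabel(gcf.gcf_id, "gcf", True, next(iter(habitats)))
    return SpecificityLabel(gcf.gcf_id, "gcf", False, None)


def classify_bgc_specificity(
    bgcs: Sequence[BgcRecord],
    gcfs: Sequence[GeneClusterFamily],
    bgc_habitats: Mapping[str, str],
) -> list[SpecificityLabel]:
    """Each non-reference BGC inherits its family's habitat-specificity label."""
    gcf_labels = {g.gcf_id: classify_gcf_habitat(g, bgc_habitats) for g in gcfs}
    member_to_gcf: dict[str, str] = {}
    for g in gcfs:
        for m in g.member_bgc_ids:
            member_to_gcf[m] = g.gcf_id
    labels: list[SpecificityLabel] = []
    for b in bgcs:
        if b.is_reference:
            continue
        if b.bgc_id not in member_to_gcf:
            raise ValueError(f"BGC {b.bgc_id} is not assigned to any GCF")
        fam = gcf_labels[member_to_gcf[b.bgc_id]]
        labels.append(
            SpecificityLabel(b.bgc_id, "bgc", fam.is_habitat_specific, fam.habitat)
        )
    return labels


def attribute_origin(
    specific_bgcs: Sequence[BgcRecord],
    species_clusters: Sequence[GenomeCluster],
    genotype_clusters: Sequence[GenomeCluster],
) -> list[OriginAttribution]:
    """Attribute each habitat-specific BGC to its clustering-level origin.

    habitat_specific_species if the source MAG's species cluster occupies one
    habitat; else habitat_specific_genotype if its genotype cluster does;
    else the residual multi_habitat_genotype class.
    """
    mag_species = {m: c for c in species_clusters for m in c.member_mag_ids}
    mag_genotype = {m: c for c in genotype_clusters for m in c.member_mag_ids}
    out: list[OriginAttribution] = []
    n_residual = 0
    for b in specific_bgcs:
        sp = mag_species.get(b.mag_id)
        gt = mag_genotype.get(b.mag_id)
        if sp is None or gt is None:
            raise ValueError(f"MAG {b.mag_id} (BGC {b.bgc_id}) missing from clustering output")
        if sp.is_habitat_specific:
            origin = ORIGIN_SPECIES
        elif gt.is_habitat_specific:
            origin = ORIGIN_GENOTYPE
        else:
            origin = ORIGIN_RESIDUAL
            n_residual += 1
        out.append(OriginAttribution(b.bgc_id, origin, sp.cluster_id, gt.cluster_id))
    if n_residual:
        logger.warning(
            "%d habitat-specific BGCs sit on genotypes that span habitats", n_residual
        )
    return out


def origin_fractions(attributions: Sequence[OriginAttribution]) -> dict[str, tuple[int, float]]:
    """Counts and 2-decimal percentages of the three origin classes."""
    total = len(attributions)
    out: dict[str, tuple[int, float]] = {}
    for cls in (ORIGIN_SPECIES, ORIGIN_GENOTYPE, ORIGIN_RESIDUAL):
        n = sum(1 for a in attributions if a.origin_class == cls)
        pct = round_half_up(100.0 * n / total, 2) if total else float("nan")
        out[cls] = (n, pct)
    return out


@dataclass
class HabitatRow:
    habitat: str
    n_specific_bgcs: int
    frac_from_specific_species: float  # 2-decimal percent; NaN when no specific BGCs
    class_composition: dict[str, int]


def per_habitat_summary(
    labels: Sequence[SpecificityLabel],
    attributions: Sequence[OriginAttribution],
    bgc_classes: Mapping[str, str],
) -> list[HabitatRow]:
    """Per-habitat table of habitat-specific BGC counts and origin ratios.

    Grand totals across rows equal the catalog-level habitat-specific count.
    """
    origin_by_bgc = {a.bgc_id: a.origin_class for a in attributions}
    by_habitat: dict[str, list[SpecificityLabel]] = {}
    for lab in labels:
        if lab.scope == "bgc" and lab.is_habitat_specific:
            by_habitat.setdefault(lab.habitat, []).append(lab)
    rows: list[HabitatRow] = []
    for habitat in sorted(by_habitat):
        habs = by_habitat[habitat]
        n = len(habs)
        n_species = sum(
            1 for lab in habs if origin_by_bgc.get(lab.subject_id) == ORIGIN_SPECIES
        )
        comp: dict[str, int] = {}
        for lab in habs:
            cls = bgc_classes.get(lab.subject_id, "other")
            comp[cls] = comp.get(cls, 0) + 1
        rows.append(
            HabitatRow(
                habitat=habitat,
                n_specific_bgcs=n,
                frac_from_specific_species=round_half_up(100.0 * n_species / n, 2)
                if n
                else float("nan"),
                class_composition=comp,
            )
        )
    return rows
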