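"""MAG quality filtering and two-level ANI clustering (genotypes / species).

Mirrors the dRep-style dereplication workflow: bins are filtered on
CheckM-style completeness/contamination, then clustered greedily around the
highest-quality unassigned genome at 99% average nucleotide identity
(genotype/strain level, with a 25% genome-overlap requirement) and at 95%
ANI (species level). A cluster whose members occur in exactly one
fermentation type is habitat-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import MagRecord

logger = logging.getLogger(__name__)

GENOTYPE_ANI = 99.0
SPECIES_ANI = 95.0
MIN_OVERLAP = 0.25


class AniTable:
    """Sparse directed pairwise ANI/overlap values, symmetrized on access.

    Absent pairs mean "below any threshold" (fastANI and friends do not
    report pairs under their reporting floor). Symmetrization: ANI is the
    mean of the two directed values when both are present, otherwise the one
    present; overlap is the minimum of the directed overlaps, which is
    conservative for fragmented genomes.
    """

    def __init__(self) -> None:
        self._directed: dict[tuple[str, str], tuple[float, float]] = {}
        self._partners: dict[str, set[str]] = {}

    def add(self, query: str, reference: str, ani: float, overlap: float = 1.0) -> None:
        if query == reference:
            return
        if not 0.0 < ani <= 100.0:
            raise ValueError(f"ANI {ani} for ({query}, {reference}) not in (0, 100]")
        if not 0.0 <= overlap <= 1.0:
            raise ValueError(f"overlap {overlap} for ({query}, {reference}) not in [0, 1]")
        self._directed[(query, reference)] = (ani, overlap)
        self._partners.setdefault(query, set()).add(reference)
        self._partners.setdefault(reference, set()).add(query)

    def get(self, a: str, b: str) -> tuple[float, float] | None:
        """Symmetrized (ani, overlap) for an unordered pair, or None."""
        fwd = self._directed.get((a, b))
        rev = self._directed.get((b, a))
        if fwd is None and rev is None:
            return None
        if fwd is None:
            return rev
        if rev is None:
            return fwd
        return (fwd[0] + rev[0]) / 2.0, min(fwd[1], rev[1])

    def partners(self, a: str) -> Iterable[str]:
        return self._partners.get(a, ())

    def ids(self) -> set[str]:
        return set(self._partners)

    def __len__(self) -> int:
        return len(self._directed)

    def directed_items(self):
        return self._directed.items()


@dataclass
class GenomeCluster:
    """One genotype- or species-level cluster of MAGs."""

    cluster_id: str
    level: str  # "genotype" | "species"
    representative_mag_id: str
    member_mag_ids: tuple[str, ...]
    habitat_set: frozenset[str]
    is_unknown: bool | None = None

    @property
    def is_habitat_specific(self) -> bool:
        return len(self.habitat_set) == 1

    def __post_init__(self) -> None:
        if self.representative_mag_id not in self.member_mag_ids:
            raise ValueError(
                f"cluster {self.cluster_id}: representative not among members"
            )


def quality_score(mag: MagRecord) -> float:
    """Bin quality used to pick cluster representatives: completeness - 5 x contamination."""
    return mag.completeness - 5.0 * mag.contamination


def filter_by_quality(
    mags: Sequence[MagRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list[MagRecord]:
    """Retain medium/high-quality bins: completeness >= min AND contamination <= max.

    Both comparisons are inclusive; input order is preserved.
    """
    kept = [
        m
        for m in mags
        if m.completeness >= min_completeness and m.contamination <= max_contamination
    ]
    removed = len(mags) - len(kept)
    if removed:
        logger.info(
            "quality filter removed %d of %d MAGs (completeness >= %g, contamination <= %g)",
            removed, len(mags), min_completeness, max_contamination,
        )
    return kept


def cluster_genomes(
    mags: Sequence[MagRecord],
    ani: AniTable,
    ani_threshold: float,
    min_overlap: float = MIN_OVERLAP,
    level: str = "genotype",
) -> list[GenomeCluster]:
    """Greedy centroid clustering of MAGs at an ANI threshold.

    Repeatedly takes the unassigned MAG with the highest ``quality_score``
    (ties broken by lexicographically smallest id) as a representative and
    assigns every unassigned MAG whose symmetrized ANI to it is
    >= ``ani_threshold`` and whose overlap is >= ``min_overlap``. Greedy
    centroid assignment (rather than transitive closure) avoids chaining
    clusters through intermediate genomes.
    """
    if not 0.0 < ani_threshold <= 100.0:
        raise ValueError(f"ani_threshold {ani_threshold} not in (0, 100]")
    ids = [m.mag_id for m in mags]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate MAG ids: {dupes}")
    known = set(ids)
    stray = ani.ids() - known
    if stray:
        logger.warning(
            "ANI table references %d MAG ids absent from the catalog; their pairs are ignored",
            len(stray),
        )

    by_id = {m.mag_id: m for m in mags}
    order = sorted(mags, key=lambda m: (-quality_score(m), m.mag_id))
    unassigned = set(ids)
    clusters: list[GenomeCluster] = []
    for rep in order:
        if rep.mag_id not in unassigned:
            continue
        unassigned.discard(rep.mag_id)
        members = [rep.mag_id]
        for other in sorted(unassigned):
            pair = ani.get(rep.mag_id, other)
            if pair is None:
                continue
            pair_ani, pair_overlap = pair
            if pair_ani >= ani_threshold and pair_overlap >= min_overlap:
                members.append(other)
        unassigned.difference_update(members)
        habitats = frozenset(by_id[m].habitat for m in members)
        clusters.append(
            GenomeCluster(
                cluster_id=f"{level}_{len(clusters):04d}",
                level=level,
                representative_mag_id=rep.mag_id,
                member_mag_ids=tuple(members),
                habitat_set=habitats,
            )
        )
    return clusters


@dataclass
class HabitatPartition:
    """Habitat-specific vs multi-habitat clusters, with per-habitat counts."""

    habitat_specific: list[GenomeCluster]
    multi_habitat: list[GenomeCluster]
    per_habitat_counts: dict[str, int]
    ratio_percent: float  # habitat-specific / total, 2-decimal percent


def habitat_specific_clusters(clusters: Sequence[GenomeCluster]) -> HabitatPartition:
    """Split clusters into habitat-specific (single habitat) and multi-habitat."""
    from .stats import round_half_up

    specific = [c for c in clusters if c.is_habitat_specific]
    multi = [c for c in clusters if not c.is_habitat_specific]
    counts: dict[str, int] = {}
    for c in specific:
        (habitat,) = c.habitat_set
        counts[habitat] = counts.get(habitat, 0) + 1
    ratio = (
        round_half_up(100.0 * len(specific) / len(clusters), 2) if clusters else float("nan")
    )
    return HabitatPartition(specific, multi, counts, ratio)


def flag_unknown_species(
    clusters: Sequence[GenomeCluster],
    reference_ani: AniTable | None,
    ani_threshold: float = SPECIES_ANI,
) -> list[GenomeCluster]:
    """Flag clusters with no member matching any reference genome at >= 95% ANI.

    ``reference_ani`` maps MAG ids to named reference-genome ids. A missing
    or empty table flags every cluster unknown (with a warning), mirroring a
    failed taxonomy lookup.
    """
    if reference_ani is None or len(reference_ani) == 0:
        logger.warning("no reference ANI table: flagging all clusters as unknown")
        reference_ani = AniTable()
    flagged: list[GenomeCluster] = []
    for c in clusters:
        known = False
        for member in c.member_mag_ids:
            for ref in reference_ani.partners(member):
                pair = reference_ani.get(member, ref)
                if pair is not None and pair[0] >= ani_threshold:
                    known = True
                    break
            if known:
                break
        flagged.append(
            GenomeCluster(
                cluster_id=c.cluster_id,
                level=c.level,
                representative_mag_id=c.representative_mag_id,
                member_mag_ids=c.member_mag_ids,
                habitat_set=c.habitat_set,
                is_unknown=not known,
            )
        )
    return flagged
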