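"""Synthetic fermentation-community generator with fully recorded planted truth.

Everything downstream of assembly/binning is emulated here: a set of MAGs
with habitat labels and quality metrics, a fastANI-like pairwise table whose
values are drawn from relation-dependent ranges (same genotype / same
species / different species), BGC catalogs built from family prototypes
under per-position domain mutation, a MIBiG-like known-BGC reference set,
and per-ecosystem reference collections with a configurable fraction of
families shared with the food community. The planted structure (who belongs
to which genotype, species, family; which families are known; which BGCs
are novel or shared with each ecosystem) is recorded so that every pipeline
stage can be tested by exact recovery at zero noise.

All randomness flows from one integer seed; each component draws from its
own deterministically derived substream, so e.g. regenerating BGCs does not
perturb the ANI draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .catalog import GENOTYPE_ANI, SPECIES_ANI, AniTable
from .gcf import bgc_distance
from .records import BGC_CLASSES, BgcRecord, MagRecord

#: The fermentation types of the study system, used as habitat labels.
FERMENTATION_TYPES = (
    "cheese", "milk_kefir", "nunu", "yoghurt", "koumiss",
    "kimchi", "kombucha", "wine", "chinese_liquor", "chilli_paste",
    "coffee", "soy_sauce", "bean_paste", "cocoa", "sourdough",
)

#: Rough class frequencies of food-fermentation BGC catalogs.
_CLASS_WEIGHTS = {
    "RiPP": 0.10, "NRPS": 0.17, "PKS": 0.17, "terpene": 0.12,
    "siderophore": 0.02, "arylpolyene": 0.08, "betalactone": 0.08,
    "ectoine": 0.02, "other": 0.24,
}

# substream codes (mixed with the root seed)
_S_STRUCTURE, _S_QUALITY, _S_PROTO, _S_BGC, _S_ANI, _S_REF = range(6)

IntSampler = int | tuple[int, int]


def _as_range(spec: IntSampler, name: str, minimum: int = 0) -> tuple[int, int]:
    if isinstance(spec, int):
        spec = (spec, spec)
    low, high = int(spec[0]), int(spec[1])
    if low > high:
        raise ValueError(f"{name}: low {low} > high {high}")
    if low < minimum:
        raise ValueError(f"{name}: low {low} < {minimum}")
    return low, high


def _sample_int(spec: tuple[int, int], rng: np.random.Generator) -> int:
    return int(rng.integers(spec[0], spec[1] + 1))


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _check_range(rng_: tuple[float, float], name: str) -> None:
    if rng_[0] > rng_[1]:
        raise ValueError(f"{name}: low {rng_[0]} > high {rng_[1]}")


@dataclass
class CommunityConfig:
    """Study conditions of the simulated fermentation community.

    Defaults describe a desk-scale community: 5 fermentation habitats,
    40 species most of which (p = 0.82) occupy a single habitat, one to
    three 99%-ANI genotypes per species and one or two MAGs per genotype,
    with ANI ranges placed inside/outside the 99/95 thresholds.

    BGC content tracks taxonomy: each species draws a family repertoire
    (``bgcs_per_genotype`` families, shared by all its genotypes) and each
    genotype may additionally carry private families
    (``private_bgcs_per_genotype``) — the mechanism that yields
    habitat-specific BGCs on habitat-specific genotypes within
    multi-habitat species.
    """

    n_habitats: int = 5
    n_species: int = 40
    p_habitat_specific_species: float = 0.82
    genotypes_per_species: IntSampler = (1, 3)
    mags_per_genotype: IntSampler = (1, 2)
    bgcs_per_genotype: IntSampler = (1, 4)
    private_bgcs_per_genotype: IntSampler = (0, 2)
    n_family_prototypes: int = 160
    n_common_families: int = 30  # widespread families any species may draw
    frac_shared_repertoire: float = 0.25  # repertoire slots drawn from the common pool
    vocabulary_size: int = 400
    prototype_length: tuple[int, int] = (5, 15)
    within_family_mutation_rate: float = 0.05
    frac_reference_families: float = 0.03
    frac_novel_bgcs: float = 0.15
    ani_intra_genotype_range: tuple[float, float] = (99.2, 100.0)
    ani_intra_species_range: tuple[float, float] = (95.5, 98.5)
    ani_inter_species_range: tuple[float, float] = (80.0, 94.0)
    ani_jitter_sd: float = 0.1
    completeness_range: tuple[float, float] = (50.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 10.0)
    seed: int = 0
    # plumbing knobs behind the headline parameters
    prototype_margin: float = 0.6  # min pairwise prototype distance (2 x GCF cutoff)
    n_ecosystem_families: int = 20  # ecosystem families NOT shared with food
    ecosystem_overlap: float = 0.85  # fraction of food families covered by each ecosystem
    ecosystem_members_per_family: IntSampler = (1, 3)
    ecosystems: tuple[str, ...] = ("gut", "ocean", "soil")
    overlap_within_range: tuple[float, float] = (0.3, 1.0)
    overlap_between_range: tuple[float, float] = (0.05, 1.0)

    def validate(self) -> None:
        if self.n_habitats < 1 or self.n_species < 1:
            raise ValueError("n_habitats and n_species must be positive")
        if self.n_habitats < 2 and self.p_habitat_specific_species < 1.0:
            raise ValueError(
                "n_habitats < 2 with p_habitat_specific_species < 1: "
                "multi-habitat species cannot be placed"
            )
        if self.vocabulary_size < 1:
            raise ValueError("vocabulary must be non-empty")
        if self.n_family_prototypes < 1:
            raise ValueError("n_family_prototypes must be positive")
        for p, name in (
            (self.p_habitat_specific_species, "p_habitat_specific_species"),
            (self.within_family_mutation_rate, "within_family_mutation_rate"),
            (self.frac_reference_families, "frac_reference_families"),
            (self.frac_novel_bgcs, "frac_novel_bgcs"),
            (self.frac_shared_repertoire, "frac_shared_repertoire"),
            (self.ecosystem_overlap, "ecosystem_overlap"),
        ):
            _check_prob(p, name)
        for r, name in (
            (self.ani_intra_genotype_range, "ani_intra_genotype_range"),
            (self.ani_intra_species_range, "ani_intra_species_range"),
            (self.ani_inter_species_range, "ani_inter_species_range"),
            (self.completeness_range, "completeness_range"),
            (self.contamination_range, "contamination_range"),
            (self.overlap_within_range, "overlap_within_range"),
            (self.overlap_between_range, "overlap_between_range"),
        ):
            _check_range(r, name)
        _as_range(self.genotypes_per_species, "genotypes_per_species", 1)
        _as_range(self.mags_per_genotype, "mags_per_genotype", 1)
        _as_range(self.bgcs_per_genotype, "bgcs_per_genotype", 0)
        _as_range(self.private_bgcs_per_genotype, "private_bgcs_per_genotype", 0)
        _as_range(self.prototype_length, "prototype_length", 1)
        if not 0 <= self.n_common_families <= self.n_family_prototypes:
            raise ValueError("n_common_families must be in [0, n_family_prototypes]")
        if self.frac_shared_repertoire > 0 and self.n_common_families < 1:
            raise ValueError("frac_shared_repertoire > 0 needs a non-empty common pool")
        if self.ani_jitter_sd < 0:
            raise ValueError("ani_jitter_sd must be non-negative")
        if self.ani_intra_genotype_range[0] < GENOTYPE_ANI:
            raise ValueError("intra-genotype ANI low bound must be >= the genotype threshold")
        if not (SPECIES_ANI < self.ani_intra_species_range[0]
                and self.ani_intra_species_range[1] < GENOTYPE_ANI):
            raise ValueError("intra-species ANI range must lie strictly between the thresholds")
        if self.ani_jitter_sd == 0 and self.ani_inter_species_range[1] >= SPECIES_ANI:
            raise ValueError("inter-species ANI high bound must be below the species threshold")

    def habitats(self) -> list[str]:
        base = list(FERMENTATION_TYPES[: self.n_habitats])
        for i in range(len(base), self.n_habitats):
            base.append(f"habitat_{i + 1:02d}")
        return base


@dataclass
class PlantedTruth:
    """Ground truth of one generated community."""

    mag_to_genotype: dict[str, str]
    genotype_to_species: dict[str, str]
    mag_habitat: dict[str, str]
    species_habitats: dict[str, frozenset[str]]
    genotype_habitats: dict[str, frozenset[str]]
    bgc_to_family: dict[str, str]  # food, MIBiG-like and ecosystem records
    bgc_mag: dict[str, str]  # food BGCs only
    family_known: dict[str, bool]
    family_habitats: dict[str, frozenset[str]]  # food members only
    family_prototypes: dict[str, tuple[str, ...]]
    family_class: dict[str, str]
    novel_families: frozenset[str]  # reserved-vocabulary families
    bgc_novel: dict[str, bool]  # food BGCs: planted far from every ecosystem
    ecosystem_shared_families: dict[str, frozenset[str]]
    bgc_novel_vs: dict[str, dict[str, bool]]  # ecosystem -> food bgc -> not shared

    def species_partition(self) -> set[frozenset[str]]:
        by_sp: dict[str, set[str]] = {}
        for mag, gt in self.mag_to_genotype.items():
            by_sp.setdefault(self.genotype_to_species[gt], set()).add(mag)
        return {frozenset(v) for v in by_sp.values()}

    def genotype_partition(self) -> set[frozenset[str]]:
        by_gt: dict[str, set[str]] = {}
        for mag, gt in self.mag_to_genotype.items():
            by_gt.setdefault(gt, set()).add(mag)
        return {frozenset(v) for v in by_gt.values()}

    def family_partition(self, bgc_ids) -> set[frozenset[str]]:
        keep = set(bgc_ids)
        by_fam: dict[str, set[str]] = {}
        for bgc, fam in self.bgc_to_family.items():
            if bgc in keep:
                by_fam.setdefault(fam, set()).add(bgc)
        return {frozenset(v) for v in by_fam.values()}

    def origin_class(self, bgc_id: str) -> str:
        from .specificity import ORIGIN_GENOTYPE, ORIGIN_RESIDUAL, ORIGIN_SPECIES

        gt = self.mag_to_genotype[self.bgc_mag[bgc_id]]
        sp = self.genotype_to_species[gt]
        if len(self.species_habitats[sp]) == 1:
            return ORIGIN_SPECIES
        if len(self.genotype_habitats[gt]) == 1:
            return ORIGIN_GENOTYPE
        return ORIGIN_RESIDUAL

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, frozenset):
                return sorted(v)
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return list(v)
            return v

        return json.dumps({k: enc(v) for k, v in asdict(self).items()}, indent=1, sort_keys=True)


@dataclass
class CommunityBundle:
    config: CommunityConfig
    mags: list[MagRecord]
    ani: AniTable
    bgcs: list[BgcRecord]  # food BGCs
    reference_bgcs: list[BgcRecord]  # MIBiG-like known set
    ecosystem_bgcs: dict[str, list[BgcRecord]]
    truth: PlantedTruth


def mutate_domain_string(
    prototype: Sequence[str],
    rate: float,
    rng: np.random.Generator,
    vocabulary: Sequence[str],
) -> tuple[str, ...]:
    """Independently substitute each position with a random vocabulary label
    with probability ``rate``; length is preserved."""
    if not len(prototype):
        raise ValueError("prototype must be non-empty")
    _check_prob(rate, "rate")
    if not len(vocabulary):
        raise ValueError("vocabulary must be non-empty")
    out = list(prototype)
    if rate > 0:
        hits = rng.random(len(out)) < rate
        for i in np.flatnonzero(hits):
            out[i] = vocabulary[int(rng.integers(len(vocabulary)))]
    return tuple(out)


def _component_rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, component]))


def _draw_prototype(
    rng: np.random.Generator,
    vocab: Sequence[str],
    length_range: tuple[int, int],
    existing: list[tuple[str, ...]],
    margin: float,
    max_tries: int = 5000,
) -> tuple[str, ...]:
    """Rejection-sample a prototype whose distance to every existing prototype
    exceeds ``margin`` (guarantees planted family separability at zero noise)."""

    def _rec(domains):
        return BgcRecord(bgc_id="_p", mag_id="_", bgc_class="other", domains=domains)

    for _ in range(max_tries):
        length = _sample_int(length_range, rng)
        cand = tuple(vocab[int(i)] for i in rng.integers(len(vocab), size=length))
        if all(bgc_distance(_rec(cand), _rec(p)) > margin for p in existing):
            return cand
    raise RuntimeError(
        "could not draw a sufficiently separated family prototype; "
        "increase vocabulary_size or lower prototype_margin"
    )


def _pick_class(rng: np.random.Generator) -> str:
    labels = list(_CLASS_WEIGHTS)
    w = np.array([_CLASS_WEIGHTS[c] for c in labels])
    return labels[int(rng.choice(len(labels), p=w / w.sum()))]


def generate_community(config: CommunityConfig) -> CommunityBundle:
    """Generate MAGs, ANI table, BGC catalogs and reference sets with truth.

    Identical config + seed reproduces the bundle byte-identically.
    """
    config.validate()
    habitats = config.habitats()
    rng_struct = _component_rng(config.seed, _S_STRUCTURE)
    rng_quality = _component_rng(config.seed, _S_QUALITY)
    rng_proto = _component_rng(config.seed, _S_PROTO)
    rng_bgc = _component_rng(config.seed, _S_BGC)
    rng_ref = _component_rng(config.seed, _S_REF)

    gt_range = _as_range(config.genotypes_per_species, "genotypes_per_species", 1)
    mag_range = _as_range(config.mags_per_genotype, "mags_per_genotype", 1)
    bgc_range = _as_range(config.bgcs_per_genotype, "bgcs_per_genotype", 0)

    # --- species / genotype / MAG structure --------------------------------
    mag_to_genotype: dict[str, str] = {}
    genotype_to_species: dict[str, str] = {}
    mag_habitat: dict[str, str] = {}
    species_habitats: dict[str, frozenset[str]] = {}
    genotype_members: dict[str, list[str]] = {}
    n_mags = 0
    for s in range(config.n_species):
        sp_id = f"sp_{s:04d}"
        if rng_struct.random() < config.p_habitat_specific_species:
            planted = [habitats[int(rng_struct.integers(len(habitats)))]]
        else:
            size = int(rng_struct.integers(2, config.n_habitats + 1))
            planted = [str(h) for h in rng_struct.choice(habitats, size=size, replace=False)]
        species_mags: list[str] = []
        for g in range(_sample_int(gt_range, rng_struct)):
            gt_id = f"gt_{s:04d}_{g:02d}"
            genotype_to_species[gt_id] = sp_id
            genotype_members[gt_id] = []
            for _ in range(_sample_int(mag_range, rng_struct)):
                mag_id = f"MAG_{n_mags:05d}"
                n_mags += 1
                mag_to_genotype[mag_id] = gt_id
                genotype_members[gt_id].append(mag_id)
                species_mags.append(mag_id)
        # materialise the habitat set on the MAGs: each planted habitat goes
        # to at least one member; shrink the set when the species is smaller
        # than its planted habitat list so the union invariant always holds
        order = list(species_mags)
        rng_struct.shuffle(order)
        realized = planted[: len(order)]
        for i, mag in enumerate(order):
            if i < len(realized):
                mag_habitat[mag] = realized[i]
            else:
                mag_habitat[mag] = realized[int(rng_struct.integers(len(realized)))]
        species_habitats[sp_id] = frozenset(realized)
    genotype_habitats = {
        gt: frozenset(mag_habitat[m] for m in members)
        for gt, members in genotype_members.items()
    }

    mags = [
        MagRecord(
            mag_id=mag_id,
            habitat=mag_habitat[mag_id],
            completeness=float(rng_quality.uniform(*config.completeness_range)),
            contamination=float(rng_quality.uniform(*config.contamination_range)),
        )
        for mag_id in sorted(mag_to_genotype)
    ]

    # --- domain vocabulary and family prototypes ---------------------------
    n_reserved = max(1, math.ceil(config.vocabulary_size / 5)) if config.frac_novel_bgcs > 0 else 0
    if config.vocabulary_size - n_reserved < 1:
        raise ValueError("vocabulary too small to reserve a novel partition")
    vocab_all = [f"D{i:04d}" for i in range(config.vocabulary_size)]
    vocab_main = vocab_all[: config.vocabulary_size - n_reserved]
    vocab_reserved = vocab_all[config.vocabulary_size - n_reserved:]

    family_prototypes: dict[str, tuple[str, ...]] = {}
    family_class: dict[str, str] = {}
    protos: list[tuple[str, ...]] = []
    normal_families: list[str] = []
    novel_families: list[str] = []
    for i in range(config.n_family_prototypes):
        fam = f"fam_{i:04d}"
        proto = _draw_prototype(
            rng_proto, vocab_main, config.prototype_length, protos, config.prototype_margin
        )
        protos.append(proto)
        family_prototypes[fam] = proto
        family_class[fam] = _pick_class(rng_proto)
        normal_families.append(fam)
    n_novel_fams = (
        max(1, round(config.n_family_prototypes * config.frac_novel_bgcs))
        if config.frac_novel_bgcs > 0
        else 0
    )
    for i in range(n_novel_fams):
        fam = f"famnov_{i:04d}"
        proto = _draw_prototype(
            rng_proto, vocab_reserved, config.prototype_length, protos, config.prototype_margin
        )
        protos.append(proto)
        family_prototypes[fam] = proto
        family_class[fam] = _pick_class(rng_proto)
        novel_families.append(fam)

    # --- MIBiG-like reference seeds ----------------------------------------
    n_known = round(config.frac_reference_families * len(normal_families))
    known_fams = sorted(
        str(f) for f in rng_ref.choice(normal_families, size=n_known, replace=False)
    ) if n_known else []
    reference_bgcs: list[BgcRecord] = []
    bgc_to_family: dict[str, str] = {}
    for i, fam in enumerate(known_fams):
        rid = f"MIBIG_{i:04d}"
        reference_bgcs.append(
            BgcRecord(
                bgc_id=rid,
                mag_id="mibig",
                bgc_class=family_class[fam],
                domains=family_prototypes[fam],
                is_reference=True,
                ecosystem="mibig",
            )
        )
        bgc_to_family[rid] = fam
    family_known = {fam: fam in set(known_fams) for fam in family_prototypes}

    # --- food BGCs ---------------------------------------------------------
    # gene content tracks taxonomy: every genotype of a species carries the
    # species' family repertoire; genotypes may add private families, which
    # is what plants habitat-specific BGCs inside multi-habitat species
    private_range = _as_range(
        config.private_bgcs_per_genotype, "private_bgcs_per_genotype", 0
    )

    common_pool = normal_families[: config.n_common_families]
    dedicated_stock = iter(normal_families[config.n_common_families:])
    novel_stock = iter(novel_families)

    def _fresh(stock, fallback: list[str]) -> str:
        fam = next(stock, None)
        if fam is None:  # stock exhausted: reuse the pool
            fam = fallback[int(rng_bgc.integers(len(fallback)))]
        return fam

    def _draw_family() -> tuple[str, bool]:
        if bool(novel_families) and rng_bgc.random() < config.frac_novel_bgcs:
            return _fresh(novel_stock, novel_families), True
        if common_pool and rng_bgc.random() < config.frac_shared_repertoire:
            return common_pool[int(rng_bgc.integers(len(common_pool)))], False
        return _fresh(dedicated_stock, normal_families), False

    bgcs: list[BgcRecord] = []
    bgc_mag: dict[str, str] = {}
    bgc_novel: dict[str, bool] = {}
    n_bgc = 0
    species_genotypes: dict[str, list[str]] = {}
    for gt in sorted(genotype_members):
        species_genotypes.setdefault(genotype_to_species[gt], []).append(gt)
    for sp in sorted(species_genotypes):
        repertoire = [_draw_family() for _ in range(_sample_int(bgc_range, rng_bgc))]
        for gt in species_genotypes[sp]:
            carried = repertoire + [
                _draw_family() for _ in range(_sample_int(private_range, rng_bgc))
            ]
            carrier = genotype_members[gt]
            for fam, is_novel in carried:
                mag_id = carrier[int(rng_bgc.integers(len(carrier)))]
                domains = mutate_domain_string(
                    family_prototypes[fam],
                    config.within_family_mutation_rate,
                    rng_bgc,
                    vocab_reserved if is_novel else vocab_main,
                )
                bid = f"BGC_{n_bgc:05d}"
                n_bgc += 1
                bgcs.append(
                    BgcRecord(
                        bgc_id=bid, mag_id=mag_id, bgc_class=family_class[fam], domains=domains
                    )
                )
                bgc_to_family[bid] = fam
                bgc_mag[bid] = mag_id
                bgc_novel[bid] = is_novel

    family_habitats_acc: dict[str, set[str]] = {}
    for bid, fam in bgc_to_family.items():
        if bid in bgc_mag:
            family_habitats_acc.setdefault(fam, set()).add(mag_habitat[bgc_mag[bid]])
    family_habitats = {f: frozenset(h) for f, h in family_habitats_acc.items()}

    # --- ecosystem reference collections -----------------------------------
    eco_members = _as_range(config.ecosystem_members_per_family, "ecosystem_members_per_family", 1)
    ecosystem_bgcs: dict[str, list[BgcRecord]] = {}
    ecosystem_shared: dict[str, frozenset[str]] = {}
    for eco in config.ecosystems:
        n_shared = min(
            round(config.ecosystem_overlap * len(normal_families)),
            len(normal_families),
        )
        shared = sorted(
            str(f) for f in rng_ref.choice(normal_families, size=n_shared, replace=False)
        ) if n_shared else []
        fams: list[tuple[str, tuple[str, ...], str]] = [
            (f, family_prototypes[f], family_class[f]) for f in shared
        ]
        for j in range(config.n_ecosystem_families):
            fam = f"fam_{eco}_{j:04d}"
            proto = _draw_prototype(
                rng_ref, vocab_main, config.prototype_length, protos, config.prototype_margin
            )
            protos.append(proto)
            family_prototypes[fam] = proto
            family_class[fam] = _pick_class(rng_ref)
            family_known.setdefault(fam, False)
            fams.append((fam, proto, family_class[fam]))
        records: list[BgcRecord] = []
        for fam, proto, cls in fams:
            for m in range(_sample_int(eco_members, rng_ref)):
                rid = f"{eco.upper()}_{fam}_{m:02d}"
                records.append(
                    BgcRecord(
                        bgc_id=rid,
                        mag_id=f"{eco}_ref",
                        bgc_class=cls,
                        domains=mutate_domain_string(
                            proto, config.within_family_mutation_rate, rng_ref, vocab_main
                            if not fam.startswith("famnov_") else vocab_reserved
                        ),
                        is_reference=True,
                        ecosystem=eco,
                    )
                )
                bgc_to_family[rid] = fam
        ecosystem_bgcs[eco] = records
        ecosystem_shared[eco] = frozenset(shared)

    bgc_novel_vs = {
        eco: {bid: bgc_to_family[bid] not in ecosystem_shared[eco] for bid in bgc_mag}
        for eco in config.ecosystems
    }

    truth = PlantedTruth(
        mag_to_genotype=mag_to_genotype,
        genotype_to_species=genotype_to_species,
        mag_habitat=mag_habitat,
        species_habitats=species_habitats,
        genotype_habitats=genotype_habitats,
        bgc_to_family=bgc_to_family,
        bgc_mag=bgc_mag,
        family_known=family_known,
        family_habitats=family_habitats,
        family_prototypes=family_prototypes,
        family_class=family_class,
        novel_families=frozenset(novel_families),
        bgc_novel=bgc_novel,
        ecosystem_shared_families=ecosystem_shared,
        bgc_novel_vs=bgc_novel_vs,
    )
    ani = synthesize_ani_table(truth, config)
    return CommunityBundle(config, mags, ani, bgcs, reference_bgcs, ecosystem_bgcs, truth)


def synthesize_ani_table(truth: PlantedTruth, config: CommunityConfig) -> AniTable:
    """Draw a symmetric pairwise ANI table from the planted relations.

    Each unordered pair draws its ANI from the range matching the relation
    (same genotype / same species / different species) plus Gaussian jitter
    truncated into (0, 100]; overlap fractions are drawn per direction, with
    within-species overlaps kept above the dereplication floor by default.
    Uses its own substream of the config seed, so the table is reproducible
    independently of the other components.
    """
    rng = _component_rng(config.seed, _S_ANI)
    table = AniTable()
    mag_ids = sorted(truth.mag_to_genotype)
    for i, a in enumerate(mag_ids):
        for b in mag_ids[i + 1:]:
            gt_a, gt_b = truth.mag_to_genotype[a], truth.mag_to_genotype[b]
            sp_a = truth.genotype_to_species[gt_a]
            sp_b = truth.genotype_to_species[gt_b]
            if gt_a == gt_b:
                lo, hi = config.ani_intra_genotype_range
                within_species = True
            elif sp_a == sp_b:
                lo, hi = config.ani_intra_species_range
                within_species = True
            else:
                lo, hi = config.ani_inter_species_range
                within_species = False
            ani = float(rng.uniform(lo, hi))
            if config.ani_jitter_sd > 0:
                ani += float(rng.normal(0.0, config.ani_jitter_sd))
            ani = min(100.0, max(1e-6, ani))
            ov_range = (
                config.overlap_within_range if within_species else config.overlap_between_range
            )
            ov_ab = float(rng.uniform(*ov_range))
            ov_ba = float(rng.uniform(*ov_range))
            table.add(a, b, ani, ov_ab)
            table.add(b, a, ani, ov_ba)
    return table
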