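"""Shared fixtures: synthetic communities at zero noise and default noise."""

from __future__ import annotations

import pytest

from fermbgc import CommunityConfig, generate_community
from fermbgc.records import BgcRecord


def zero_noise_config(seed: int = 1) -> CommunityConfig:
    """Default community with every noise source switched off."""
    return CommunityConfig(
        seed=seed, ani_jitter_sd=0.0, within_family_mutation_rate=0.0
    )


def small_config(seed: int = 0, **overrides) -> CommunityConfig:
    """A fast, small community for per-seed loops."""
    base = dict(
        n_habitats=4,
        n_species=8,
        genotypes_per_species=(1, 2),
        mags_per_genotype=(1, 2),
        bgcs_per_genotype=(0, 2),
        private_bgcs_per_genotype=(0, 1),
        n_family_prototypes=12,
        n_common_families=4,
        vocabulary_size=80,
        n_ecosystem_families=3,
        ani_jitter_sd=0.0,
        within_family_mutation_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return CommunityConfig(**base)


@pytest.fixture(scope="session")
def zero_noise_bundle():
    return generate_community(zero_noise_config(seed=1))


@pytest.fixture(scope="session")
def noisy_bundle():
    return generate_community(CommunityConfig(seed=7))


def mk_bgc(bgc_id: str, domains, mag_id: str = "M1", bgc_class: str = "other",
           is_reference: bool = False, ecosystem: str | None = None) -> BgcRecord:
    return BgcRecord(
        bgc_id=bgc_id,
        mag_id=mag_id,
        bgc_class=bgc_class,
        domains=tuple(domains),
        is_reference=is_reference,
        ecosystem=ecosystem,
    )
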