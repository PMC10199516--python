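"""Generator behaviour: determinism, planted structure, noise models."""

from __future__ import annotations

import math

import numpy as np
import pytest

from fermbgc import CommunityConfig, generate_community, mutate_domain_string
from fermbgc.simulate import synthesize_ani_table

from conftest import small_config, zero_noise_config


class TestConfigValidation:
    def test_single_habitat_with_multi_habitat_species_rejected(self):
        cfg = CommunityConfig(n_habitats=1, p_habitat_specific_species=0.5)
        with pytest.raises(ValueError, match="multi-habitat"):
            cfg.validate()

    def test_single_habitat_all_specific_allowed(self):
        small_config(n_habitats=1, p_habitat_specific_species=1.0).validate()

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            CommunityConfig(vocabulary_size=0).validate()

    def test_intra_species_range_must_sit_between_thresholds(self):
        with pytest.raises(ValueError, match="between the thresholds"):
            CommunityConfig(ani_intra_species_range=(94.0, 98.0)).validate()

    def test_inter_species_must_stay_below_species_threshold_at_zero_jitter(self):
        with pytest.raises(ValueError, match="species threshold"):
            CommunityConfig(
                ani_jitter_sd=0.0, ani_inter_species_range=(80.0, 96.0)
            ).validate()

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            CommunityConfig(frac_novel_bgcs=1.2).validate()


class TestDeterminism:
    def test_same_seed_reproduces_bundle_byte_identically(self, tmp_path):
        from fermbgc import io

        dirs = []
        for run in ("a", "b"):
            bundle = generate_community(small_config(seed=5))
            d = tmp_path / run
            d.mkdir()
            io.write_mags(bundle.mags, d / "mags.tsv")
            io.write_ani(bundle.ani, d / "ani.tsv")
            io.write_bgcs(bundle.bgcs, d / "bgcs.tsv")
            io.write_bgcs(bundle.reference_bgcs, d / "mibig.tsv")
            (d / "truth.json").write_text(bundle.truth.to_json())
            dirs.append(d)
        for name in ("mags.tsv", "ani.tsv", "bgcs.tsv", "mibig.tsv", "truth.json"):
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_community(small_config(seed=1))
        b = generate_community(small_config(seed=2))
        assert a.truth.to_json() != b.truth.to_json()

    def test_ani_substream_independent_of_bgc_generation(self):
        # regenerating the ANI table from truth reproduces the bundle's table
        bundle = generate_community(small_config(seed=3))
        again = synthesize_ani_table(bundle.truth, bundle.config)
        assert dict(bundle.ani.directed_items()) == dict(again.directed_items())


class TestPlantedStructure:
    def test_degenerate_single_everything_community(self):
        cfg = small_config(
            n_habitats=1,
            n_species=1,
            p_habitat_specific_species=1.0,
            genotypes_per_species=1,
            mags_per_genotype=1,
            bgcs_per_genotype=1,
            private_bgcs_per_genotype=0,
            frac_novel_bgcs=0.0,
        )
        bundle = generate_community(cfg)
        assert len(bundle.mags) == 1
        assert len(bundle.bgcs) == 1
        truth = bundle.truth
        (sp,) = truth.species_habitats
        assert len(truth.species_habitats[sp]) == 1  # habitat-specific species
        fam = truth.bgc_to_family[bundle.bgcs[0].bgc_id]
        assert truth.family_habitats[fam] == truth.species_habitats[sp]

    def test_every_mag_in_one_genotype_and_each_genotype_in_one_species(self, zero_noise_bundle):
        truth = zero_noise_bundle.truth
        assert set(truth.mag_to_genotype) == {m.mag_id for m in zero_noise_bundle.mags}
        assert set(truth.mag_to_genotype.values()) == set(truth.genotype_to_species)

    def test_species_habitat_set_is_union_of_member_mag_habitats(self, zero_noise_bundle):
        truth = zero_noise_bundle.truth
        union: dict[str, set[str]] = {}
        for mag, gt in truth.mag_to_genotype.items():
            union.setdefault(truth.genotype_to_species[gt], set()).add(truth.mag_habitat[mag])
        for sp, habs in truth.species_habitats.items():
            assert habs == union[sp]

    def test_genotype_habitats_union_to_species_habitats(self, zero_noise_bundle):
        truth = zero_noise_bundle.truth
        union: dict[str, set[str]] = {}
        for gt, sp in truth.genotype_to_species.items():
            union.setdefault(sp, set()).update(truth.genotype_habitats[gt])
        for sp, habs in truth.species_habitats.items():
            assert habs == union[sp]

    def test_quality_metrics_within_configured_ranges(self, zero_noise_bundle):
        cfg = zero_noise_bundle.config
        for m in zero_noise_bundle.mags:
            assert cfg.completeness_range[0] <= m.completeness <= cfg.completeness_range[1]
            assert cfg.contamination_range[0] <= m.contamination <= cfg.contamination_range[1]

    def test_planted_specific_species_count_matches_binomial_oracle(self):
        # binomial oracle: n = 10 species at p = 0.8 -> mean 8, SE sqrt(10*0.8*0.2)
        n_species, p, n_seeds = 10, 0.8, 200
        counts = []
        for seed in range(n_seeds):
            cfg = small_config(
                seed=seed,
                n_habitats=5,
                n_species=n_species,
                p_habitat_specific_species=p,
                genotypes_per_species=1,
                mags_per_genotype=5,  # >= n_habitats: planted sets never shrink
                bgcs_per_genotype=0,
                private_bgcs_per_genotype=0,
                n_ecosystem_families=1,
            )
            truth = generate_community(cfg).truth
            counts.append(sum(1 for h in truth.species_habitats.values() if len(h) == 1))
        mean = np.mean(counts)
        se = math.sqrt(n_species * p * (1 - p) / n_seeds)
        assert abs(mean - n_species * p) < 3 * se


class TestAniSynthesis:
    def test_ani_values_fall_in_relation_ranges_at_zero_jitter(self, zero_noise_bundle):
        cfg = zero_noise_bundle.config
        truth = zero_noise_bundle.truth
        mags = sorted(truth.mag_to_genotype)
        for a in mags[:40]:
            for b in mags[:40]:
                if a >= b:
                    continue
                ani, _ = zero_noise_bundle.ani.get(a, b)
                gt_a, gt_b = truth.mag_to_genotype[a], truth.mag_to_genotype[b]
                if gt_a == gt_b:
                    lo, hi = cfg.ani_intra_genotype_range
                elif truth.genotype_to_species[gt_a] == truth.genotype_to_species[gt_b]:
                    lo, hi = cfg.ani_intra_species_range
                else:
                    lo, hi = cfg.ani_inter_species_range
                assert lo <= ani <= hi

    def test_within_species_overlap_stays_above_derep_floor(self, zero_noise_bundle):
        truth = zero_noise_bundle.truth
        mags = sorted(truth.mag_to_genotype)
        for a in mags[:40]:
            for b in mags[:40]:
                if a >= b:
                    continue
                gt_a, gt_b = truth.mag_to_genotype[a], truth.mag_to_genotype[b]
                if truth.genotype_to_species[gt_a] == truth.genotype_to_species[gt_b]:
                    _, overlap = zero_noise_bundle.ani.get(a, b)
                    assert overlap >= 0.25


class TestMutateDomainString:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        proto = ("a", "b", "c")
        assert mutate_domain_string(proto, 0.0, rng, ["a", "b", "c", "d"]) == proto

    def test_rate_one_single_label_vocabulary_forces_identity(self):
        rng = np.random.default_rng(0)
        proto = ("a",) * 5
        assert mutate_domain_string(proto, 1.0, rng, ["a"]) == proto

    def test_length_preserved(self):
        rng = np.random.default_rng(1)
        out = mutate_domain_string(("a",) * 17, 0.5, rng, ["a", "b"])
        assert len(out) == 17

    def test_empty_prototype_rejected(self):
        with pytest.raises(ValueError):
            mutate_domain_string((), 0.1, np.random.default_rng(0), ["a"])

    def test_rate_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            mutate_domain_string(("a",), 1.5, np.random.default_rng(0), ["a"])

    def test_mean_hamming_distance_matches_binomial_oracle(self):
        # expected distance = L * rate * (1 - 1/V): substitutions may redraw
        # the same label
        L, rate, V, reps = 20, 0.1, 20, 1000
        vocab = [f"x{i}" for i in range(V)]
        proto = tuple(vocab[i % V] for i in range(L))
        rng = np.random.default_rng(42)
        dists = [
            sum(a != b for a, b in zip(proto, mutate_domain_string(proto, rate, rng, vocab)))
            for _ in range(reps)
        ]
        expected = L * rate * (1 - 1 / V)
        p_eff = rate * (1 - 1 / V)
        se = math.sqrt(L * p_eff * (1 - p_eff) / reps)
        assert abs(np.mean(dists) - expected) < 3 * se
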