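"""Generate a synthetic fermentation community with planted ground truth.

The generator emulates everything downstream of assembly/binning: MAGs with
habitat labels and CheckM-style quality values, a fastANI-like pairwise
table, BGC catalogs drawn from family prototypes, and reference sets. The
planted structure is recorded so the analysis can be validated by recovery.
"""

from fermbgc import CommunityConfig, generate_community

config = CommunityConfig(seed=1)
bundle = generate_community(config)
truth = bundle.truth

n_species = len(truth.species_habitats)
n_specific = sum(1 for h in truth.species_habitats.values() if len(h) == 1)
print(f"MAGs: {len(bundle.mags)} across {config.n_habitats} fermentation habitats")
print(f"species planted: {n_species} ({n_specific} habitat-specific)")
print(f"genotypes planted: {len(truth.genotype_to_species)}")
print(f"food BGCs: {len(bundle.bgcs)} in {len(set(truth.bgc_to_family[b.bgc_id] for b in bundle.bgcs))} families")
print(f"MIBiG-like reference BGCs: {len(bundle.reference_bgcs)}")
for eco, records in bundle.ecosystem_bgcs.items():
    print(f"ecosystem reference '{eco}': {len(records)} BGCs")
# A habitat-specific species occupies exactly one fermentation type; the
# planted fraction is governed by p_habitat_specific_species (default 0.82).
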