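"""Estimate total market species richness with all twelve models.

Abundance models run on the packaged survey counts; incidence models on
a simulated survey's (event, vendor) sampling units.
"""

from finsurvey import (
    MarketSimConfig,
    abundance_frequencies,
    default_species_pool,
    estimate_table,
    incidence_frequencies,
    load_market_table,
    simulate_market,
)

table, _ = load_market_table("guangzhou")
freq_a = abundance_frequencies(table, ("species", "complex"))

ledger, _ = simulate_market(MarketSimConfig(species_pool=default_species_pool(), seed=3))
freq_i = incidence_frequencies(ledger)

out = estimate_table(freq_a, freq_i)
out["estimate"] = out["estimate"].round(3)
out["se"] = out["se"].round(3)
print(out.to_string(index=False))
print(
    f"\nAbundance models start from {freq_a.s_obs} observed categories, "
    f"incidence models from {freq_i.s_obs} (in the simulated survey's "
    f"{freq_i.t} vendor visits); every estimate sits at or above its "
    "observed richness because the rare-category frequencies imply species "
    "present in the market but missed by the sample."
)
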