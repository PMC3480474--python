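"""Generate the synthetic at-risk population and its areal-unit systems.

Builds a Tennessee-sized planar region holding a 122,500-point pool of
candidate background cases (a mixture of Gaussian "city" blobs and a
uniform rural background, with a January-peaked seasonal month
distribution), then partitions it into 617 ZIP-like and 95 county-like
Voronoi units.
"""

from stpscan import RegionConfig, build_study_region

config = RegionConfig(seed=1)
pop, zips, counties = build_study_region(config)

print(f"pool: {pop.n} points on a {config.width_km:.0f} x "
      f"{config.height_km:.0f} km region over {config.months} months")
print(f"month distribution peaks in month {pop.month_marginal.argmax()} "
      f"(January) at {pop.month_marginal.max():.4f} per month")
print(f"zip-like units: {zips.n_units}, mean membership "
      f"{zips.member_count.mean():.0f} points "
      f"(sd {zips.member_count.std():.0f})")
print(f"county-like units: {counties.n_units}, mean membership "
      f"{counties.member_count.mean():.0f} points")

# The membership spread reflects population concentration: urban units
# hold far more of the at-risk pool than rural ones, as real ZIP codes do.
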