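"""Inject one artificial space-time cluster into a 1000-case dataset.

Draws a random square cluster (inscribed-circle radius 1.6-48 km),
relative risk 1-10 and a 3-month onset window; computes the at-risk
share C inside the square; converts (C, RR) into the excess probability
p = C(RR-1)/(1-C); and assembles N_t ~ Binomial(1000, p) treatment cases
inside the square with N_c = 1000 - N_t controls drawn from the pool.
"""

from stpscan import RegionConfig, build_study_region, inject_dataset

pop, zips, counties = build_study_region(RegionConfig(seed=1))
ds = inject_dataset(pop, zips, counties, seed=11)

t = ds.truth
print(f"cluster center {t.center[0]:.1f}, {t.center[1]:.1f} km, "
      f"radius {t.r_km:.1f} km (square side {2 * t.r_km:.1f} km)")
print(f"RR = {t.rr}, onset months {t.window[0]}-{t.window[1]}")
print(f"C = {t.C:.5f} of the at-risk pool lies inside the square")
print(f"p = {t.p:.5f} -> N_t = {t.n_t} treatment cases, "
      f"N_c = {t.n_c} controls")
print(ds.records.head())

# Treatment cases sit inside the square during the window; controls keep
# their true pool coordinates but carry re-randomized months, so the
# dataset contains exactly one space-time interaction cluster.
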