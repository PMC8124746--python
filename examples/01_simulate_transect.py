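"""Generate a synthetic shrub-encroached grassland transect and summarise it.

Builds the default 381 m / 128-quadrat scene (three seasons, five replicate
spectra per quadrat, ten pure-shrub endmember spectra per season), then
compares line-intercept shrub cover with the mean visual quadrat estimate.
"""

from shrubspec import TransectConfig, compare_lit_quadrat, generate_scene, simulate_lit

config = TransectConfig(seed=1)
scene = generate_scene(config)
lit = simulate_lit(scene)

print(f"quadrats: {config.n_quadrats}, replicate spectra: {len(scene.library)}")
print(f"LIT shrub cover: {lit.cover_pct:.1f}% from {lit.n_patches} canopy patches "
      f"({lit.density_per_m:.2f} shrubs/m)")

comparison = compare_lit_quadrat(lit.cover_pct, scene.quadrats, "spring")
row = comparison.iloc[0]
print(f"visual quadrat mean (spring): {row.quadrat_mean_cover_pct:.1f}% "
      f"-> LIT minus visual = {row.difference_pct:+.1f} points")

# Seasonal shrub cover course: spring highest, declining with leaf loss.
by_season = scene.quadrats.groupby("season")["cover_pct_shrub"].mean()
for season in ("spring", "summer", "fall"):
    print(f"mean visual shrub cover, {season:6s}: {by_season[season]:.1f}%")
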