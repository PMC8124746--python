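"""Wavelength-by-wavelength Spearman correlation against shrub cover.

Scans every valid wavelength of a full transect scene for a monotonic
relationship with visually estimated shrub cover (n = 128), using the
two-tailed critical value of Spearman's r at alpha = 0.05.
"""


from shrubspec import (TransectConfig, generate_scene, library_matrix,
                       significant_regions, spearman_critical, spearman_profile)
from shrubspec.spectra import average_replicates, mask_library

print(f"critical |r| at n=128, alpha=0.05: {spearman_critical(128):.4f} "
      f"(displayed as {round(spearman_critical(128), 2)})")

scene = generate_scene(TransectConfig(seed=1))
lib = mask_library(average_replicates(scene.library))

season = "summer"
X, wavelengths, keys = library_matrix(lib.subset(season=season))
q = scene.quadrats[scene.quadrats.season == season]
cover = q.set_index("quadrat_id").loc[[k[0] for k in keys], "cover_pct_shrub"]

profile = spearman_profile(X, cover.to_numpy(), wavelengths)
regions = significant_regions(profile)

print(f"{season}: {profile['significant'].mean():.0%} of wavelengths significant")
for _, r in regions.iterrows():
    print(f"  {r.sign} {r.low_nm:6.0f}-{r.high_nm:6.0f} nm, "
          f"peak |r|={r.peak_abs_r:.2f} at {r.peak_wavelength_nm:.0f} nm")
# Expect a negative visible region (pigment absorption rises with shrub
# cover) and a positive NIR region (leaf-structure scattering).
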