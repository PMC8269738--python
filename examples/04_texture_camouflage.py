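"""Texture-signature camouflage scores for matched vs conspicuous eggs.

Scores two extremes: eggs carrying the background's own texture (perfect
background matching) and uniform bright eggs on dark clutter.
"""

import eggshade as eg

bank = eg.build_filter_bank(scales=(8.0, 16.0, 32.0, 64.0), scale_factor=0.125)
common = dict(image_size=(384, 384), px_per_cm=8.0, n_eggs=5,
              egg_axes_cm=(8.0, 6.0), spot_fraction=0.0, noise_sd=0.004)

matched = eg.render_scene(eg.SceneParams(rng_seed=11, **common),
                          paint_eggs=False)
s_matched = eg.camouflage_distance(matched.image[..., :3], matched.regions,
                                   seed=0, bank=bank)

conspicuous = eg.render_scene(eg.SceneParams(
    rng_seed=12, band_reflectance_egg_ground=(0.9,) * 4,
    band_reflectance_background_base=(0.08,) * 4, **common))
s_consp = eg.camouflage_distance(conspicuous.image[..., :3],
                                 conspicuous.regions, seed=0, bank=bank)

print(f"background-matching eggs: chi2 = {s_matched.value:.4f}")
print(f"bright eggs on dark clutter: chi2 = {s_consp.value:.4f}")
# The chi-square texture distance is ~0 when egg and microhabitat share a
# texture distribution and approaches 1 when their texture labels are
# disjoint; lower means better camouflage.
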