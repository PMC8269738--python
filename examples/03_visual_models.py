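"""Cone-catch mapping for the four predator visual models.

Maps a flat grey stimulus (the von Kries anchor) and a UV-only patch into
each observer's receptor space.
"""

import numpy as np

import eggshade as eg

grey = np.full((1, 1, 4), 0.25)
uv_patch = np.zeros((1, 1, 4))
uv_patch[0, 0, 3] = 1.0          # reflective only below 400 nm

for name, model in eg.BUILTIN_MODELS.items():
    g = eg.map_to_visual_model(grey, model)[0, 0]
    u = eg.map_to_visual_model(uv_patch, model)[0, 0]
    peaks = ", ".join(f"{p:.0f}" for p in model.lambda_max)
    print(f"{name:>8s} (peaks {peaks} nm)")
    print(f"          grey 25%: {np.round(g, 3)}   UV patch: {np.round(u, 3)}")
# Grey maps to 1.0 in every channel by construction.  The UV patch drives
# the blue tit's 371-nm receptor far harder than any other channel of any
# model: only the UV-sensitive tetrachromat sees it as a strong signal.
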