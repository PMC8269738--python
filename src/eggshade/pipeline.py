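"""End-to-end desk-scale replications of the two field experiments.

Experiment 1 (radiation / fading): ten spotted eggs per shading treatment
photographed on days 0, 3 and 7 through the full synthetic imaging chain
(render -> camera encode -> linearize -> grey-standard normalize), with the
per-treatment radiation logs summarized as daily maxima averaged over the
recording days, and the reflectance changes correlated against them.

Experiment 2 (camouflage): clutches of three eggs in nests under direct
sun, photographed on several days, mapped to the four predator visual
models, and scored with the egg-vs-microhabitat chi-square texture
distance.  The desk-scale profile runs the filter bank at a reduced
scale_factor on small scenes; geometry is kept similar via the pixel scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .camera import CameraResponseParams, encode_camera, linearize
from .radiometry import (extract_egg_reflectances, normalize_to_reflectance,
                         summarize_radiation)
from .scene import (TREATMENTS, FadingParams, SceneParams, normalized_dose,
                    render_scene, simulate_radiation)
from .stats import Exp1Report, Exp2Report, exp1_summary, exp2_summary
from .texture import build_filter_bank, camouflage_distance
from .vision import BUILTIN_MODELS, map_to_visual_model

__all__ = ["Exp1Run", "Exp2Run", "run_experiment1", "run_experiment2",
           "calibrate_scene"]

#: Recording days of the radiation logger in experiment 1.
EXP1_RECORDING_DAYS = (0, 3, 7)

DEFAULT_CAMERA = CameraResponseParams(gamma=2.2, black_level=512,
                                      bit_depth=16, shot_noise_sd=2.0)

EXP1_SCENE = SceneParams(image_size=(288, 288), px_per_cm=10.0, n_eggs=10)

#: Desk-scale experiment-2 scene: 3 eggs per nest, pixel scale chosen so the
#: 45-cm microhabitat circle fits a 416x416 frame.
EXP2_SCENE = SceneParams(image_size=(416, 416), px_per_cm=6.0, n_eggs=3)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def calibrate_scene(raw: np.ndarray, standard_polygon: np.ndarray,
                    crp: CameraResponseParams) -> np.ndarray:
    """Linearize an encoded image and normalize it to the grey standard."""
    lin, sat = linearize(raw, crp)
    return normalize_to_reflectance(lin, standard_polygon, saturated=sat)


@dataclass
class Exp1Run:
    reflectance_table: pd.DataFrame
    radiation_records: pd.DataFrame
    radiation_summaries: pd.DataFrame
    report: Exp1Report


def run_experiment1(seed: int = 0, days=(0, 3, 7),
                    scene: SceneParams = EXP1_SCENE,
                    fading: FadingParams | None = None,
                    camera: CameraResponseParams = DEFAULT_CAMERA,
                    treatments: dict | None = None) -> Exp1Run:
    """Replicate the radiation experiment on synthetic scenes.

    Each treatment keeps its own clutch (scene seed fixed across days, so the
    same eggs are re-photographed), receives a dose set by its transmittance
    and the elapsed days, and goes through the full imaging chain before the
    per-egg reflectances are extracted.
    """
    fading = fading or FadingParams()
    treatments = treatments or TREATMENTS
    seeds = _child_seeds(seed, 3 * len(treatments))
    tables, records, summaries = [], [], []
    for t_idx, (name, schedule) in enumerate(treatments.items()):
        scene_seed, radiation_seed, camera_seed = seeds[3 * t_idx:3 * t_idx + 3]
        rec = simulate_radiation(schedule, list(EXP1_RECORDING_DAYS),
                                 seed=radiation_seed)
        rec.insert(0, "treatment", name)
        records.append(rec)
        summaries.append(summarize_radiation(rec).rename(name))
        params = replace(scene, rng_seed=scene_seed)
        for d_idx, day in enumerate(days):
            dose = normalized_dose(schedule, day)
            sc = render_scene(params, day=day, dose=dose, fading=fading)
            raw = encode_camera(sc.image, camera, seed=camera_seed + d_idx)
            refl = calibrate_scene(raw, sc.regions.standard_polygon, camera)
            tables.append(extract_egg_reflectances(
                refl, sc.regions, scene_id=f"exp1-{name}", day=day,
                treatment=name))
    table = pd.concat(tables, ignore_index=True)
    summary_df = pd.DataFrame(summaries)
    summary_df.index.name = "treatment"
    report = exp1_summary(table, summary_df.reset_index())
    return Exp1Run(reflectance_table=table,
                   radiation_records=pd.concat(records, ignore_index=True),
                   radiation_summaries=summary_df.reset_index(),
                   report=report)


@dataclass
class Exp2Run:
    scores: pd.DataFrame
    report: Exp2Report


def run_experiment2(seed: int = 0, n_nests: int = 7, days=(0, 7, 14),
                    scene: SceneParams = EXP2_SCENE,
                    fading: FadingParams | None = None,
                    camera: CameraResponseParams = DEFAULT_CAMERA,
                    models=("ferret", "human", "peafowl", "bluetit"),
                    k: int = 20, scale_factor: float = 0.25,
                    max_fit_pixels: int = 8000,
                    fit_mixed_models: bool = False) -> Exp2Run:
    """Replicate the camouflage experiment on synthetic nests.

    Nests sit under direct sun, so the normalized dose at day ``d`` is
    ``d / 7`` in both VIS and UV.  Every nest/day image is calibrated, mapped
    to each requested visual model and scored against its microhabitat.
    """
    fading = fading or FadingParams()
    direct = TREATMENTS["direct"]
    bank = build_filter_bank(scale_factor=scale_factor)
    seeds = _child_seeds(seed, 2 * n_nests)
    rows = []
    for nest in range(n_nests):
        scene_seed, chain_seed = seeds[2 * nest:2 * nest + 2]
        params = replace(scene, rng_seed=scene_seed)
        for d_idx, day in enumerate(days):
            dose = normalized_dose(direct, day)
            sc = render_scene(params, day=day, dose=dose, fading=fading)
            raw = encode_camera(sc.image, camera, seed=chain_seed + d_idx)
            refl = calibrate_scene(raw, sc.regions.standard_polygon, camera)
            for model in models:
                catch = map_to_visual_model(refl, BUILTIN_MODELS[model])
                score = camouflage_distance(
                    catch, sc.regions, k=k, bank=bank,
                    seed=chain_seed + 100 * d_idx, max_fit_pixels=max_fit_pixels,
                    metadata={"nest_id": nest, "day": day,
                              "visual_model": model})
                rows.append({"nest_id": nest, "day": day,
                             "visual_model": model, "chi2": score.value})
    scores = pd.DataFrame(rows)
    report = exp2_summary(scores, fit_mixed_models=fit_mixed_models)
    return Exp2Run(scores=scores, report=report)
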