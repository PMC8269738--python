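"""Predator visual models: cone catches from 4-band reflectance images.

The four camera bands are bridged to continuous spectra by a piecewise-
constant reconstruction over their nominal supports (UV 350-400 nm, blue
400-500, green 500-600, red 600-700).  Receptor sensitivities follow the
Govardovskii A1 alpha-band template at each observer's published peak
wavelengths; the quantum catch of a receptor is the wavelength integral of
reflectance x sensitivity x illuminant, and catches are von-Kries normalized
to the catch of the flat 25% grey standard so a spectrally flat stimulus
maps to 1.0 in every channel.

Built-in observers: dichromatic ferret (430, 538 nm), trichromatic human
(420, 533, 562 nm), violet-sensitive tetrachromatic peafowl (421, 457, 505,
566 nm) and ultraviolet-sensitive tetrachromatic blue tit (371, 448, 503,
563 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError, ShapeError

__all__ = [
    "WAVELENGTH_GRID", "ReceptorSet", "BUILTIN_MODELS",
    "receptor_sensitivity", "reconstruct_spectrum", "cone_catch",
    "illuminant_spectrum", "band_weight_matrix", "map_to_visual_model",
]

#: Fixed wavelength grid of the module: 350-700 nm at 1-nm steps.
WAVELENGTH_GRID = np.arange(350.0, 701.0)

#: Nominal support of each camera band on the grid, image channel order
#: (VIS-R, VIS-G, VIS-B, UV).  Half-open except the last band which closes
#: the grid.
BAND_SUPPORTS = {
    "vis_r": (600.0, 700.0),
    "vis_g": (500.0, 600.0),
    "vis_b": (400.0, 500.0),
    "uv": (350.0, 400.0),
}
_CHANNEL_ORDER = ("vis_r", "vis_g", "vis_b", "uv")


@dataclass(frozen=True)
class ReceptorSet:
    """An observer: a name and its receptor peak wavelengths (nm)."""

    name: str
    lambda_max: tuple[float, ...]

    def __post_init__(self) -> None:
        peaks = self.lambda_max
        if any(not 300 <= p <= 700 for p in peaks):
            raise DomainError("receptor peaks must lie within [300, 700] nm")
        if any(b <= a for a, b in zip(peaks, peaks[1:])):
            raise DomainError("receptor peaks must be strictly increasing")
        if len(peaks) not in (2, 3, 4):
            raise DomainError("supported chromacies are 2, 3 and 4")

    @property
    def chromacy(self) -> int:
        return len(self.lambda_max)


BUILTIN_MODELS: dict[str, ReceptorSet] = {
    "ferret": ReceptorSet("ferret", (430.0, 538.0)),
    "human": ReceptorSet("human", (420.0, 533.0, 562.0)),
    "peafowl": ReceptorSet("peafowl", (421.0, 457.0, 505.0, 566.0)),
    "bluetit": ReceptorSet("bluetit", (371.0, 448.0, 503.0, 563.0)),
}


def receptor_sensitivity(lambda_max: float,
                         grid: np.ndarray | None = None) -> np.ndarray:
    """A1 visual-pigment alpha-band template, peak-normalized to 1.

    Govardovskii template: with x = lambda_max / lambda,

        S(x) = 1 / (exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D)

    A=69.7, B=28, C=-14.9, D=0.674, b=0.922, c=1.104 and
    a = 0.8795 + 0.0459 exp(-(lambda_max - 300)^2 / 11940).
    """
    if not 300 <= lambda_max <= 700:
        raise DomainError(f"lambda_max {lambda_max} nm outside [300, 700]")
    lam = WAVELENGTH_GRID if grid is None else np.asarray(grid, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    s = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
               + np.exp(-14.9 * (1.104 - x)) + 0.674)
    return s / s.max()


def reconstruct_spectrum(band_reflectances,
                         grid: np.ndarray | None = None) -> np.ndarray:
    """Piecewise-constant spectrum from 4 band reflectances (R, G, B, UV)."""
    r = np.asarray(band_reflectances, dtype=float)
    if r.shape != (4,):
        raise ShapeError("band_reflectances must be a 4-vector (R, G, B, UV)")
    if (r < 0).any():
        raise DomainError("band reflectances must be non-negative")
    lam = WAVELENGTH_GRID if grid is None else np.asarray(grid, dtype=float)
    out = np.zeros_like(lam)
    for value, name in zip(r, _CHANNEL_ORDER):
        lo, hi = BAND_SUPPORTS[name]
        sel = (lam >= lo) & (lam < hi) if hi < lam.max() else (lam >= lo)
        out[sel] = value
    return out


def illuminant_spectrum(name: str = "equal_energy",
                        grid: np.ndarray | None = None) -> np.ndarray:
    """Named illuminant on the grid.

    ``equal_energy`` is flat; ``daylight_6500k`` is a Planckian radiator at
    6500 K (a documented approximation of mid-day daylight), peak-normalized.
    """
    lam = WAVELENGTH_GRID if grid is None else np.asarray(grid, dtype=float)
    if name == "equal_energy":
        return np.ones_like(lam)
    if name == "daylight_6500k":
        lam_m = lam * 1e-9
        hc_over_kT = 6.62607015e-34 * 2.99792458e8 / (1.380649e-23 * 6500.0)
        spd = lam_m ** -5 / (np.exp(hc_over_kT / lam_m) - 1.0)
        return spd / spd.max()
    raise ConfigError(f"unknown illuminant {name!r}")


def cone_catch(reflectance_spectrum: np.ndarray, receptor: np.ndarray,
               illuminant: np.ndarray) -> float:
    """Quantum catch: trapezoid integral of R * S * I over the shared grid."""
    r = np.asarray(reflectance_spectrum, dtype=float)
    s = np.asarray(receptor, dtype=float)
    i = np.asarray(illuminant, dtype=float)
    if not (r.shape == s.shape == i.shape == WAVELENGTH_GRID.shape):
        raise ShapeError("spectra must share the module wavelength grid")
    return float(np.trapezoid(r * s * i, WAVELENGTH_GRID))


def band_weight_matrix(model: ReceptorSet,
                       illuminant: str | np.ndarray = "equal_energy"
                       ) -> np.ndarray:
    """(4, chromacy) matrix of catches of the unit indicator of each band.

    Because the reconstructed spectra are piecewise constant over the band
    supports, the catch of any pixel is linear in its band reflectances:
    ``Q = reflectance_vector @ W``.
    """
    illum = (illuminant_spectrum(illuminant)
             if isinstance(illuminant, str) else np.asarray(illuminant, float))
    w = np.empty((4, model.chromacy))
    for b in range(4):
        indicator = reconstruct_spectrum(np.eye(4)[b])
        for i, peak in enumerate(model.lambda_max):
            w[b, i] = cone_catch(indicator, receptor_sensitivity(peak), illum)
    return w


def map_to_visual_model(image: np.ndarray, model: ReceptorSet | str,
                        illuminant: str | np.ndarray = "equal_energy",
                        grey_reflectance: float = 0.25) -> np.ndarray:
    """Map a calibrated (H, W, 4) reflectance image to cone-catch space.

    Each pixel's catches are divided by the catches of the flat grey
    standard under the same illuminant (von Kries), so a uniform
    ``grey_reflectance`` scene maps to 1.0 in every channel.
    """
    if isinstance(model, str):
        if model not in BUILTIN_MODELS:
            raise ConfigError(
                f"unknown visual model {model!r}; built-ins: "
                f"{sorted(BUILTIN_MODELS)}")
        model = BUILTIN_MODELS[model]
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 4:
        raise ShapeError("image must be (H, W, 4) in (R, G, B, UV) order")
    w = band_weight_matrix(model, illuminant)
    grey_catch = grey_reflectance * w.sum(axis=0)
    return (img @ w) / grey_catch
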