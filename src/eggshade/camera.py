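"""Idealized camera response: encode reflectance to digital numbers and back.

The model is a per-channel power law with black-level offset and optional
shot noise:

    DN = clip(black_level + gain * reflectance**(1/gamma) + noise,
              0, 2**bit_depth - 1)

It stands in for a real RAW response only through its contract: linearizing
an encoded image recovers values proportional to scene radiance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = ["CameraResponseParams", "encode_camera", "linearize"]


@dataclass(frozen=True)
class CameraResponseParams:
    """Parameters of the power-law camera model.

    gamma : encoding exponent (> 0); 1.0 is a linear sensor
    gain : digital numbers per unit encoded radiance
    black_level : DN offset at zero light
    bit_depth : output integer width in bits (>= 8)
    shot_noise_sd : additive Gaussian noise, DN
    """

    gamma: float = 2.2
    gain: float | None = None
    black_level: float = 512.0
    bit_depth: int = 16
    shot_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.bit_depth < 8:
            raise ConfigError(f"bit_depth must be >= 8, got {self.bit_depth}")
        if self.gamma <= 0:
            raise ConfigError("gamma must be positive")
        if self.gain is None:
            object.__setattr__(self, "gain", self.full_scale - self.black_level)
        if self.gain <= 0:
            raise ConfigError("gain must be positive")

    @property
    def full_scale(self) -> int:
        return 2 ** self.bit_depth - 1


def encode_camera(image: np.ndarray, crp: CameraResponseParams,
                  seed: int | None = None) -> np.ndarray:
    """Encode a reflectance image (values in [0, 1]) to integer DNs."""
    refl = np.asarray(image, dtype=float)
    if refl.min() < 0 or refl.max() > 1:
        raise ConfigError("encode_camera expects reflectance in [0, 1]")
    dn = crp.black_level + crp.gain * refl ** (1.0 / crp.gamma)
    if crp.shot_noise_sd > 0:
        rng = np.random.default_rng(seed)
        dn = dn + rng.normal(0.0, crp.shot_noise_sd, size=dn.shape)
    dn = np.clip(np.rint(dn), 0, crp.full_scale)
    dtype = np.uint16 if crp.bit_depth <= 16 else np.uint32
    return dn.astype(dtype)


def linearize(raw: np.ndarray, crp: CameraResponseParams
              ) -> tuple[np.ndarray, np.ndarray]:
    """Invert the camera response.

    Returns
    -------
    linear : float array proportional to scene radiance (negatives clipped to 0)
    saturated : boolean mask of pixels at or above full scale, where the
        response is not invertible
    """
    dn = np.asarray(raw, dtype=float)
    saturated = dn >= crp.full_scale
    lin = np.clip((dn - crp.black_level) / crp.gain, 0.0, None) ** crp.gamma
    return lin, saturated
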