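"""Filter-bank texture signatures and the chi-square camouflage score.

The texture of a region is summarized by convolving every image channel with
a 56-kernel filter bank — 14 filters (5 odd- and 5 even-symmetric Gaussian
derivatives at orientations evenly spaced over 0-180 degrees, two Gaussians
and two Laplacians of Gaussian) at each of 4 scales, sigma = {16, 32, 64,
128} px by default — clustering the per-pixel response vectors with K-means
(k = 20), and histogramming the nearest-centre labels inside the region.
Camouflage is the half-normalized chi-square distance between the signature
of the egg region and of the surrounding 45-cm-diameter microhabitat disk:
0 means identical texture distributions (perfect background matching), 1
means disjoint ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft
from sklearn.cluster import KMeans

from .errors import DataError, DomainError, GeometryError, ShapeError
from .regions import RegionSet

__all__ = [
    "FilterKernel", "FilterBank", "TextureModel", "CamouflageScore",
    "oriented_kernel", "build_filter_bank", "apply_filter_bank", "fit_texture_model",
    "assign_labels", "region_signature", "chi_square_distance",
    "camouflage_distance",
]

DEFAULT_SCALES = (16.0, 32.0, 64.0, 128.0)
#: Aspect ratio of the oriented Gaussian envelopes (long : short axis).
ORIENTED_ASPECT = 3.0


@dataclass(frozen=True)
class FilterKernel:
    array: np.ndarray
    scale: float
    kind: str                      # odd | even | gaussian | log
    orientation: float | None      # degrees, None for rotation-invariant


@dataclass
class FilterBank:
    """An ordered list of kernels plus the parameters that built it."""

    kernels: list[FilterKernel]
    scales: tuple[float, ...]
    n_orientations: int
    scale_factor: float
    _fft_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def max_kernel_size(self) -> int:
        return max(k.array.shape[0] for k in self.kernels)

    def per_scale_counts(self) -> dict[float, int]:
        counts: dict[float, int] = {}
        for k in self.kernels:
            counts[k.scale] = counts.get(k.scale, 0) + 1
        return counts


def _rotated_grid(halfwidth: int, theta_deg: float):
    ax = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    xs, ys = np.meshgrid(ax, ax)
    th = math.radians(theta_deg)
    u = np.cos(th) * xs + np.sin(th) * ys      # along the orientation
    v = -np.sin(th) * xs + np.cos(th) * ys     # across it
    return u, v


def _zero_sum_l1(kernel: np.ndarray) -> np.ndarray:
    kernel = kernel - kernel.mean()
    norm = np.abs(kernel).sum()
    return kernel / norm if norm > 0 else kernel


def oriented_kernel(sigma: float, theta_deg: float, kind: str,
                    aspect: float = ORIENTED_ASPECT) -> np.ndarray:
    """One oriented Gaussian-derivative kernel (zero-sum, L1-normalized).

    ``kind`` is ``odd`` (first derivative across the orientation) or ``even``
    (second derivative); the Gaussian envelope has sigma along the
    orientation and sigma/aspect across it, truncated at +/- 3 sigma.
    """
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    if kind not in ("odd", "even"):
        raise DomainError(f"kind must be 'odd' or 'even', got {kind!r}")
    sigma_short = sigma / aspect
    hw = max(int(math.ceil(3.0 * sigma)), 1)
    u, v = _rotated_grid(hw, theta_deg)
    env = np.exp(-(u ** 2 / (2 * sigma ** 2) + v ** 2 / (2 * sigma_short ** 2)))
    if kind == "odd":
        k = -v / sigma_short ** 2 * env
    else:
        k = (v ** 2 / sigma_short ** 4 - 1.0 / sigma_short ** 2) * env
    return _zero_sum_l1(k)


def build_filter_bank(scales=DEFAULT_SCALES, n_orientations: int = 5,
                      scale_factor: float = 1.0) -> FilterBank:
    """Build the 14-filters-per-scale bank.

    Per scale sigma: odd (first) and even (second) derivatives of an
    anisotropic Gaussian (long axis sigma along the orientation, short axis
    sigma/3 across it) at ``n_orientations`` orientations evenly spaced over
    [0, 180) degrees, one Gaussian at sigma and one at sqrt(2) sigma, and one
    Laplacian of Gaussian at each of the same two widths.  Supports are
    truncated at +/- 3 sigma of the largest constituent width.  Derivative
    and LoG kernels are made exactly zero-sum and L1-normalized; Gaussians
    sum to 1.  ``scale_factor`` rescales every sigma, giving a geometrically
    similar bank for small images.
    """
    if n_orientations < 1:
        raise DomainError("n_orientations must be >= 1")
    if scale_factor <= 0:
        raise DomainError("scale_factor must be positive")
    kernels: list[FilterKernel] = []
    orientations = [i * 180.0 / n_orientations for i in range(n_orientations)]
    for nominal in scales:
        if nominal <= 0:
            raise DomainError("scales must be positive")
        sigma = nominal * scale_factor
        for kind in ("odd", "even"):
            for theta in orientations:
                kernels.append(FilterKernel(
                    oriented_kernel(sigma, theta, kind), nominal, kind, theta))
        for width in (sigma, math.sqrt(2.0) * sigma):
            hw = max(int(math.ceil(3.0 * width)), 1)
            ax = np.arange(-hw, hw + 1, dtype=float)
            xs, ys = np.meshgrid(ax, ax)
            r2 = xs ** 2 + ys ** 2
            g = np.exp(-r2 / (2 * width ** 2))
            kernels.append(FilterKernel(g / g.sum(), nominal, "gaussian", None))
        for width in (sigma, math.sqrt(2.0) * sigma):
            hw = max(int(math.ceil(3.0 * width)), 1)
            ax = np.arange(-hw, hw + 1, dtype=float)
            xs, ys = np.meshgrid(ax, ax)
            r2 = xs ** 2 + ys ** 2
            log = (r2 / width ** 4 - 2.0 / width ** 2) * np.exp(-r2 / (2 * width ** 2))
            kernels.append(FilterKernel(_zero_sum_l1(log), nominal, "log", None))
    return FilterBank(kernels=kernels, scales=tuple(scales),
                      n_orientations=n_orientations, scale_factor=scale_factor)


def _kernel_ffts(bank: FilterBank, shape: tuple[int, int]) -> list[np.ndarray]:
    """FFTs of all kernels at a common transform shape (cached on the bank)."""
    cached = bank._fft_cache.get(shape)
    if cached is not None:
        return cached
    ffts = [spfft.rfft2(k.array, s=shape) for k in bank.kernels]
    bank._fft_cache[shape] = ffts
    return ffts


def apply_filter_bank(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Convolve every channel with every kernel (reflect padding).

    Returns an (H, W, C*56) float32 response stack, channel-major then bank
    order (scale, then kernel index within the scale).  True convolution
    (not correlation): a unit impulse reproduces each kernel centred on it.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    if img.ndim != 3:
        raise ShapeError("image must be (H, W) or (H, W, C)")
    h, w, c = img.shape
    kmax = bank.max_kernel_size
    if kmax > min(h, w):
        raise ShapeError(
            f"largest kernel ({kmax} px) exceeds the image "
            f"({h}x{w}); use a smaller scale_factor")
    pad = kmax // 2
    fshape = (spfft.next_fast_len(h + 2 * pad + kmax - 1),
              spfft.next_fast_len(w + 2 * pad + kmax - 1))
    kernel_ffts = _kernel_ffts(bank, fshape)
    out = np.empty((h, w, c * len(bank)), dtype=np.float32)
    for ch in range(c):
        padded = np.pad(img[..., ch], pad, mode="reflect")
        f = spfft.rfft2(padded, s=fshape)
        for ki, (kernel, kf) in enumerate(zip(bank.kernels, kernel_ffts)):
            conv = spfft.irfft2(f * kf, s=fshape)
            off = pad + kernel.array.shape[0] // 2
            out[..., ch * len(bank) + ki] = conv[off:off + h, off:off + w]
    return out


@dataclass
class TextureModel:
    """K-means texture vocabulary in standardized response space."""

    centres: np.ndarray            # (k, d), standardized space
    feature_mean: np.ndarray       # (d,)
    feature_std: np.ndarray        # (d,)
    seed: int
    inertia: float
    n_iter: int

    @property
    def k(self) -> int:
        return self.centres.shape[0]


def fit_texture_model(stack: np.ndarray, mask: np.ndarray, k: int = 20,
                      seed: int = 0, max_fit_pixels: int = 20000
                      ) -> TextureModel:
    """Fit the K-means texture vocabulary on the masked response vectors.

    Features are standardized (zero mean, unit variance over the masked
    pixels) before clustering; k-means++ with 10 restarts at tolerance 1e-6,
    deterministic given ``seed``.  When the region holds more than
    ``max_fit_pixels`` pixels a seeded random subsample of that size is used
    for the fit (labels are still assigned to every pixel afterwards).
    """
    feats = np.asarray(stack)[np.asarray(mask, dtype=bool)]
    if feats.shape[0] < k:
        raise DataError(
            f"{feats.shape[0]} masked pixels < k={k}; cannot fit texture model")
    mean = feats.mean(axis=0, dtype=np.float64)
    std = np.sqrt(np.maximum(
        (feats.astype(np.float64) ** 2).mean(axis=0) - mean ** 2, 0.0))
    std = np.where(std < 1e-12, 1.0, std)
    z = (feats - mean) / std
    if z.shape[0] > max_fit_pixels:
        rng = np.random.default_rng(seed)
        z = z[rng.choice(z.shape[0], size=max_fit_pixels, replace=False)]
    km = KMeans(n_clusters=k, n_init=10, tol=1e-6,
                random_state=int(seed) % (2 ** 31)).fit(z.astype(np.float32))
    return TextureModel(centres=km.cluster_centers_, feature_mean=mean,
                        feature_std=std, seed=int(seed),
                        inertia=float(km.inertia_), n_iter=int(km.n_iter_))


def assign_labels(stack: np.ndarray, model: TextureModel,
                  mask: np.ndarray | None = None,
                  chunk: int = 65536) -> np.ndarray:
    """Label every pixel with its nearest centre (Euclidean, standardized).

    Ties break to the lowest centre index.  Returns an (H, W) int32 map;
    with ``mask`` given, pixels outside it are labelled -1.
    """
    st = np.asarray(stack)
    if st.ndim != 3 or st.shape[2] != model.centres.shape[1]:
        raise ShapeError(
            f"stack feature length {st.shape[-1] if st.ndim == 3 else '?'} "
            f"does not match model dimension {model.centres.shape[1]}")
    h, w, d = st.shape
    labels = np.full((h, w), -1, dtype=np.int32)
    sel = np.ones((h, w), dtype=bool) if mask is None else np.asarray(mask, bool)
    feats = st[sel].astype(np.float64)
    out = np.empty(feats.shape[0], dtype=np.int32)
    c = model.centres
    c_sq = (c ** 2).sum(axis=1)
    for start in range(0, feats.shape[0], chunk):
        z = (feats[start:start + chunk] - model.feature_mean) / model.feature_std
        # argmin over squared distances; np.argmin takes the first minimum,
        # which is the lowest centre index
        d2 = c_sq[None, :] - 2.0 * z @ c.T
        out[start:start + chunk] = np.argmin(d2, axis=1)
    labels[sel] = out
    return labels


def region_signature(labels: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    """Normalized label histogram of a region: length-k, sums to 1."""
    sel = np.asarray(labels)[np.asarray(mask, dtype=bool)]
    if sel.size == 0:
        raise DataError("empty mask: no pixels to histogram")
    if (sel < 0).any():
        raise DataError("mask covers pixels without assigned labels")
    counts = np.bincount(sel, minlength=k)
    if len(counts) > k:
        raise DataError(f"labels exceed k={k}")
    return counts / counts.sum()


def chi_square_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Half-normalized chi-square distance between two texture signatures.

    ``0.5 * sum_t (h1_t - h2_t)^2 / (h1_t + h2_t)`` over bins with non-zero
    total; symmetric, zero iff equal, 1 for disjoint supports.
    """
    a = np.asarray(h1, dtype=float)
    b = np.asarray(h2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("signatures must be 1-D and of equal length")
    for v in (a, b):
        if (v < 0).any() or abs(v.sum() - 1.0) > 1e-6:
            raise DomainError("signatures must be normalized histograms")
    denom = a + b
    nz = denom > 0
    return float(0.5 * np.sum((a[nz] - b[nz]) ** 2 / denom[nz]))


@dataclass(frozen=True)
class CamouflageScore:
    """Chi-square texture distance between eggs and microhabitat."""

    value: float
    metadata: dict = field(default_factory=dict, compare=False)


def camouflage_distance(image: np.ndarray, regions: RegionSet, k: int = 20,
                        seed: int = 0, bank: FilterBank | None = None,
                        microhabitat_diameter_cm: float = 45.0,
                        max_fit_pixels: int = 20000,
                        metadata: dict | None = None) -> CamouflageScore:
    """Egg-vs-microhabitat camouflage score of one (cone-catch) image.

    Pipeline: filter-bank responses -> K-means vocabulary fitted on the
    union of egg and microhabitat pixels -> nearest-centre labels ->
    normalized signatures of (a) the egg region and (b) the 45-cm
    microhabitat disk minus the eggs -> chi-square distance.  Lower is
    better camouflage.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    shape = img.shape[:2]
    egg_mask = regions.egg_mask(shape)
    if not egg_mask.any():
        raise GeometryError("egg polygons rasterize to an empty pixel set")
    micro_mask = regions.microhabitat_mask(
        shape, diameter_cm=microhabitat_diameter_cm, exclude_eggs=True)
    if not micro_mask.any():
        raise GeometryError("microhabitat region is empty")
    bank = bank or build_filter_bank()
    stack = apply_filter_bank(img, bank)
    union = egg_mask | micro_mask
    model = fit_texture_model(stack, union, k=k, seed=seed,
                              max_fit_pixels=max_fit_pixels)
    labels = assign_labels(stack, model, mask=union)
    sig_egg = region_signature(labels, egg_mask, k)
    sig_micro = region_signature(labels, micro_mask, k)
    meta = dict(metadata or {})
    meta.update(n_egg_px=int(egg_mask.sum()), n_micro_px=int(micro_mask.sum()),
                k=k, seed=int(seed))
    return CamouflageScore(value=chi_square_distance(sig_egg, sig_micro),
                           metadata=meta)
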