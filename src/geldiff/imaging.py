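"""Synthetic fluorescence image stacks and radial intensity extraction.

Emulates whole-animal fluorescence imaging of the subcutaneous injection
site: each frame is a circularly symmetric radiant-intensity field around
the injection centre, sampled on a pixel grid, optionally blurred by a
Gaussian PSF, and corrupted by independent multiplicative and additive
Gaussian noise.  Intensities live on the same dimensionless scale as the
model (scaled by the maximum observable intensity); the intensity-to-
concentration mapping is the identity.

Geometry convention: continuous mm coordinates with the origin at the
image's top-left corner; pixel (i, j) has its centre at
((j + 0.5) * pixel_size, (i + 0.5) * pixel_size) — x along columns, y
along rows.  Radial profiles are azimuthal means over thin annuli of
pixel-centre distances to the injection centre.

Stacks round-trip to multi-page 32-bit float TIFF with a JSON sidecar
carrying acquisition times, geometry, seed and (for synthetic data) the
ground-truth parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, DegenerateInputError, GeometryError, ParameterError
from .forward_model import (
    InitialCondition,
    Transport,
    WeibullSource,
    initial_condition_profile,
)
from .hankel import HankelSolver, QuadratureConfig

__all__ = [
    "ImagingConfig",
    "ImageStack",
    "render_frame",
    "add_noise",
    "generate_stack",
    "extract_radial_profile",
    "extract_observations",
    "estimate_center",
    "write_stack",
    "read_stack",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Pixel geometry and noise model of the synthetic camera.

    Defaults give a 128 px x 0.2 mm/px = 25.6 mm field of view, wide
    enough to span the outermost study radius (11.17 mm) around a centred
    injection site, with noise off.
    """

    n_px: int = 128
    pixel_size: float = 0.2          # mm per pixel
    center: tuple[float, float] | None = None  # (x, y) mm; None = midpoint
    psf_sigma: float = 0.0           # Gaussian blur, mm; 0 disables
    noise_rel: float = 0.0           # multiplicative noise s.d. (fraction)
    noise_add: float = 0.0           # additive noise s.d. (intensity)
    background: float = 0.0          # additive offset (intensity)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_px < 32:
            raise ParameterError("n_px must be >= 32")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be > 0")
        for name in ("psf_sigma", "noise_rel", "noise_add", "background"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def extent(self) -> float:
        """Field-of-view side length in mm."""
        return self.n_px * self.pixel_size

    def resolve_center(self) -> tuple[float, float]:
        if self.center is None:
            half = self.extent / 2.0
            return (half, half)
        cx, cy = self.center
        if not (0.0 <= cx <= self.extent and 0.0 <= cy <= self.extent):
            raise ConfigError(
                f"center {self.center} lies outside the {self.extent:g} mm field"
            )
        return (float(cx), float(cy))


@dataclass
class ImageStack:
    """Timed grayscale frames with geometry and optional ground truth."""

    times: np.ndarray                # acquisition days, strictly increasing
    frames: np.ndarray               # (n_t, n_px, n_px), non-negative
    config: ImagingConfig
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames)
        if self.frames.shape[0] != self.times.size:
            raise ParameterError("one frame per acquisition time required")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.frames < 0):
            raise ParameterError("frames must be non-negative")


def _pixel_distances(cfg: ImagingConfig) -> np.ndarray:
    cx, cy = cfg.resolve_center()
    coords = (np.arange(cfg.n_px) + 0.5) * cfg.pixel_size
    return np.hypot(coords[None, :] - cx, coords[:, None] - cy)


def render_frame(src: WeibullSource, ic: InitialCondition, tr: Transport,
                 t: float, cfg: ImagingConfig,
                 solver: HankelSolver | None = None) -> np.ndarray:
    """Noiseless radiant-intensity frame at day ``t``.

    Each pixel carries the model concentration at its centre's distance to
    the injection site.  At t = 0 the initial profile is evaluated exactly;
    at t > 0 the analytic solution is sampled on a fine radial grid
    (pixel_size / 4 spacing) and interpolated, which is far below the
    pixel discretization error.  Deterministic.
    """
    if t < 0:
        raise ParameterError("t must be >= 0")
    dist = _pixel_distances(cfg)
    if t == 0:
        frame = np.asarray(initial_condition_profile(dist, ic), dtype=float)
    else:
        if solver is None:
            solver = HankelSolver(src, ic, tr, QuadratureConfig.fast())
        dr = cfg.pixel_size / 4.0
        r_grid = np.arange(0.0, dist.max() + 2 * dr, dr)
        c_grid = solver.concentration(r_grid, float(t), D=tr.D)[:, 0]
        frame = np.interp(dist, r_grid, c_grid)
    if cfg.psf_sigma > 0:
        frame = gaussian_filter(frame, sigma=cfg.psf_sigma / cfg.pixel_size)
    return frame + cfg.background


def add_noise(image: np.ndarray, cfg: ImagingConfig,
              rng: np.random.Generator) -> np.ndarray:
    """pixel -> max(0, pixel*(1 + e_rel) + e_add), independent Gaussians."""
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ParameterError("input image must be non-negative")
    out = image.copy()
    if cfg.noise_rel > 0:
        out = out * (1.0 + rng.normal(0.0, cfg.noise_rel, size=image.shape))
    if cfg.noise_add > 0:
        out = out + rng.normal(0.0, cfg.noise_add, size=image.shape)
    return np.clip(out, 0.0, None)


def generate_stack(src: WeibullSource, ic: InitialCondition, tr: Transport,
                   times, cfg: ImagingConfig,
                   solver: HankelSolver | None = None) -> ImageStack:
    """Render and noise one frame per acquisition time.

    Noise for each frame is drawn from a per-frame substream spawned from
    ``cfg.seed``, so the stack is bit-reproducible and frames are
    statistically independent.  Ground truth is embedded for downstream
    recovery studies.
    """
    t_arr = np.asarray(times, dtype=float)
    if t_arr.size == 0:
        raise ParameterError("times must be non-empty")
    if solver is None:
        solver = HankelSolver(src, ic, tr, QuadratureConfig.fast())
    streams = np.random.SeedSequence(cfg.seed).spawn(t_arr.size)
    frames = np.empty((t_arr.size, cfg.n_px, cfg.n_px))
    for i, t in enumerate(t_arr):
        clean = render_frame(src, ic, tr, float(t), cfg, solver=solver)
        frames[i] = add_noise(clean, cfg, np.random.default_rng(streams[i]))
    truth = {
        "source": dataclasses.asdict(src),
        "initial": dataclasses.asdict(ic),
        "transport": dataclasses.asdict(tr),
    }
    return ImageStack(times=t_arr, frames=frames, config=cfg, truth=truth)


def extract_radial_profile(image: np.ndarray, center: tuple[float, float],
                           radii, annulus_width: float,
                           pixel_size: float) -> np.ndarray:
    """Azimuthal mean intensity in annuli [r - w/2, r + w/2) around center.

    Distances are measured from pixel centres; annuli are half-open.  An
    annulus containing no pixel centre raises :class:`GeometryError`
    naming the offending radius.
    """
    image = np.asarray(image, dtype=float)
    n_py, n_px = image.shape
    cx, cy = center
    xs = (np.arange(n_px) + 0.5) * pixel_size
    ys = (np.arange(n_py) + 0.5) * pixel_size
    dist = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    out = np.empty(len(radii))
    half = annulus_width / 2.0
    for i, r in enumerate(radii):
        mask = (dist >= r - half) & (dist < r + half)
        if not np.any(mask):
            raise GeometryError(
                f"annulus at r={r:g} mm (width {annulus_width:g} mm) "
                f"contains no pixel centre"
            )
        out[i] = float(image[mask].mean())
    return out


def extract_observations(stack: ImageStack, radii, annulus_width: float = 0.4,
                         center: tuple[float, float] | None = None):
    """Radial intensity time series (radius x time) from an image stack."""
    from .inference import Observations

    ctr = center if center is not None else stack.config.resolve_center()
    radii = np.asarray(radii, dtype=float)
    mat = np.empty((radii.size, stack.times.size))
    for j in range(stack.times.size):
        mat[:, j] = extract_radial_profile(
            stack.frames[j], ctr, radii, annulus_width, stack.config.pixel_size
        )
    return Observations(radii=radii, times=stack.times, intensities=mat)


def estimate_center(image: np.ndarray, pixel_size: float,
                    percentile: float = 0.99) -> tuple[float, float]:
    """Injection-site estimate: intensity-weighted centroid of bright pixels.

    Pixels strictly above the given intensity quantile contribute with
    their intensity as weight.  A flat image has no pixel above its own
    quantile and raises :class:`DegenerateInputError`.
    """
    image = np.asarray(image, dtype=float)
    thresh = np.quantile(image, percentile)
    mask = image > thresh
    if not np.any(mask):
        raise DegenerateInputError(
            "image is flat at the requested percentile; cannot locate centre"
        )
    ii, jj = np.nonzero(mask)
    w = image[mask]
    cx = float(np.sum((jj + 0.5) * pixel_size * w) / np.sum(w))
    cy = float(np.sum((ii + 0.5) * pixel_size * w) / np.sum(w))
    return (cx, cy)


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar round-trip


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path) -> None:
    """Write frames as multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    cfg = dataclasses.asdict(stack.config)
    if cfg["center"] is not None:
        cfg["center"] = list(cfg["center"])
    sidecar = {
        "times": stack.times.tolist(),
        "config": cfg,
        "truth": stack.truth,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_stack(path) -> ImageStack:
    """Load a stack written by :func:`write_stack`."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    sidecar = json.loads(_sidecar_path(path).read_text())
    cfg_dict = dict(sidecar["config"])
    if cfg_dict.get("center") is not None:
        cfg_dict["center"] = tuple(cfg_dict["center"])
    cfg = ImagingConfig(**cfg_dict)
    return ImageStack(times=np.asarray(sidecar["times"], dtype=float),
                      frames=np.asarray(frames, dtype=float),
                      config=cfg, truth=sidecar.get("truth"))
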