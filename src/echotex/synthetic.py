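"""Synthetic speckle ultrasonograms and trait tables for end-to-end testing.

Two generators:

* ``simulate_speckle_image`` — fully developed speckle: the envelope
  ``sqrt(g1^2 + g2^2)`` of two independent zero-mean Gaussian fields of
  scale ``sigma`` is Rayleigh(sigma) per pixel, so the moments are known in
  closed form (mean ``sigma*sqrt(pi/2)``, SD ``sigma*sqrt(2 - pi/2)``).
  Optional anisotropic Gaussian smoothing emulates the elongated, "linear"
  texture of muscle scanned along its fibers; an optional scene frame (black
  scanner mask plus a saturated interface echo) pins the image extrema at 0
  and 255 so byte-scale normalization leaves the parenchyma untouched.

* ``simulate_trait_table`` — per-bird latent multivariate-normal vectors
  over 8 echotexture variables and 29 traits, scaled to the configured
  group means with SD = SEM * sqrt(15), with requested echotexture-trait
  correlations planted in the latent correlation matrix.  Sensory traits
  are snapped to the panel's 1-5 grid in 0.5 steps after planting, so grid
  attenuation is a measured property, not a corrected one.

One master seed drives everything; streams are drawn in a documented fixed
order (traits first, then images bird-major/plane-minor in the pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import defaults
from .image_io import GreyImage, round_half_up

__all__ = [
    "SpeckleParams",
    "TraitModel",
    "simulate_speckle_image",
    "calibrate_sigma",
    "simulate_trait_table",
    "RAYLEIGH_MEAN_FACTOR",
    "RAYLEIGH_SD_FACTOR",
    "PLANE_ANISOTROPY",
]

RAYLEIGH_MEAN_FACTOR = float(np.sqrt(np.pi / 2.0))      # E[X]/sigma ~ 1.2533
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))  # SD[X]/sigma ~ 0.6551

# Stylized per-plane smoothing aspect ratios: fibers run roughly across the
# beam in the longitudinal and second oblique planes, giving a streakier
# texture there than in the transverse plane.
PLANE_ANISOTROPY = {"L": 3.0, "T": 1.0, "O1": 1.5, "O2": 2.5}


@dataclass(frozen=True)
class SpeckleParams:
    """Parameters of one synthetic speckle frame.

    sigma        Rayleigh scale in grey levels (> 0).
    size         (rows, cols), at least 64 x 64.
    smooth_sigma Gaussian kernel scale in px along rows; 0 disables smoothing.
    anisotropy   kernel aspect ratio >= 1 (column scale = smooth_sigma * anisotropy).
    scene        paint a black border and a saturated interface band so the
                 frame spans the full 0-255 range, as scanner exports do.
    log_compress apply display-style log compression to the envelope.
    seed         integer seed; same seed, same image, bit for bit.
    """

    sigma: float
    size: tuple[int, int] = (480, 640)
    smooth_sigma: float = 0.0
    anisotropy: float = 1.0
    scene: bool = False
    log_compress: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.size[0] < 64 or self.size[1] < 64:
            raise ValueError(f"size must be at least 64x64, got {self.size}")
        if self.anisotropy < 1:
            raise ValueError("anisotropy must be >= 1")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")


def simulate_speckle_image(p: SpeckleParams, plane: str | None = None) -> GreyImage:
    """Draw one speckle frame; deterministic under ``p.seed``."""
    rng = np.random.default_rng(p.seed)
    g1 = rng.normal(0.0, p.sigma, p.size)
    g2 = rng.normal(0.0, p.sigma, p.size)
    env = np.hypot(g1, g2)
    if p.log_compress:
        # Display-style compression: rescale ln(1 + x/sigma) back to the
        # envelope's dynamic range so sigma keeps its meaning approximately.
        env = np.log1p(env / p.sigma) * p.sigma * RAYLEIGH_MEAN_FACTOR / np.log(2.0)
    if p.smooth_sigma > 0:
        env = gaussian_filter(env, sigma=(p.smooth_sigma, p.smooth_sigma * p.anisotropy),
                              mode="reflect")
    clipped = np.count_nonzero(env > 255)
    if clipped > 0.01 * env.size:
        warnings.warn(
            f"sigma={p.sigma:g}: {100.0 * clipped / env.size:.1f}% of pixels "
            "clamp at 255; speckle moments will be biased",
            stacklevel=2,
        )
    pixels = round_half_up(np.clip(env, 0.0, 255.0)).astype(np.uint8)
    if p.scene:
        b = max(4, min(p.size) // 20)  # black scanner mask
        pixels[:b, :] = 0
        pixels[-b:, :] = 0
        pixels[:, :b] = 0
        pixels[:, -b:] = 0
        pixels[b + 2:b + 5, b:-b] = 255  # saturated skin/fascia echo
    return GreyImage(pixels=pixels, normalized=False, plane=plane,
                     source_id=f"speckle(sigma={p.sigma:g},seed={p.seed})")


def calibrate_sigma(target_mpi: float) -> float:
    """Rayleigh scale whose envelope mean equals ``target_mpi`` grey levels.

    Inverts E[X] = sigma*sqrt(pi/2).  Targets near the top of the byte range
    clamp heavily (mean + 3 SD beyond 255) and trigger a warning.
    """
    if not 0 < target_mpi < 255:
        raise ValueError(f"target MPI must lie in (0, 255), got {target_mpi}")
    sigma = target_mpi / RAYLEIGH_MEAN_FACTOR
    if sigma * (RAYLEIGH_MEAN_FACTOR + 3 * RAYLEIGH_SD_FACTOR) > 255:
        warnings.warn(
            f"target MPI {target_mpi:g} puts the envelope tail beyond 255; "
            "expect clamping bias",
            stacklevel=2,
        )
    return sigma


@dataclass
class TraitModel:
    """Joint model of echotexture variables and traits for one synthetic study.

    ``echo_stats`` / ``trait_stats`` map variable -> group -> (mean, SEM);
    they default to the shipped turkey-study scenario.  ``target_correlations``
    plants latent correlations (echo variable, trait, r) with |r| < 1.
    ``sd_scale_n`` converts SEM to SD (SD = SEM * sqrt(sd_scale_n)); the
    scenario's group size is 15.
    """

    echo_stats: dict = field(default_factory=lambda: defaults.ECHO_GROUP_STATS)
    trait_stats: dict = field(default_factory=lambda: defaults.TRAIT_GROUP_STATS)
    target_correlations: list[tuple[str, str, float]] = field(default_factory=list)
    sensory_grid: tuple[float, float, float] = (1.0, 5.0, 0.5)
    sd_scale_n: int = defaults.N_PER_GROUP
    seed: int = 0

    @property
    def echo_variables(self) -> tuple[str, ...]:
        return tuple(self.echo_stats)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.trait_stats)

    @property
    def groups(self) -> tuple[str, ...]:
        first = next(iter(self.echo_stats.values()))
        return tuple(first)


def _build_latent_correlation(model: TraitModel) -> np.ndarray:
    """Latent correlation matrix over echo variables + traits; validates PSD."""
    names = list(model.echo_variables) + list(model.traits)
    index = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for x, y, r in model.target_correlations:
        if x not in model.echo_variables:
            raise ValueError(f"unknown echotexture variable {x!r} in target correlation")
        if y not in model.traits:
            raise ValueError(f"unknown trait {y!r} in target correlation")
        if not abs(r) < 1:
            raise ValueError(f"target correlation ({x}, {y}, {r}): |r| must be < 1")
        i, j = index[x], index[y]
        corr[i, j] = corr[j, i] = r
    min_eig = float(np.linalg.eigvalsh(corr).min())
    if min_eig < -1e-10:
        # Name the most likely culprit: the strongest correlation on the
        # variable whose planted row exceeds unit squared mass.
        worst = None
        for x in model.echo_variables:
            mass = sum(r * r for xx, _, r in model.target_correlations if xx == x)
            if mass > 1:
                cands = [t for t in model.target_correlations if t[0] == x]
                worst = max(cands, key=lambda t: abs(t[2]))
                break
        detail = f"; offending triple: {worst}" if worst else ""
        raise ValueError(
            f"requested correlation set is not positive semi-definite "
            f"(min eigenvalue {min_eig:.3g}){detail}"
        )
    return corr


def _snap_to_grid(x: np.ndarray, grid: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = grid
    return np.clip(round_half_up(x / step) * step, lo, hi)


def simulate_trait_table(
    model: TraitModel,
    n_per_group: int = defaults.N_PER_GROUP,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic study: (trait table, echotexture record table).

    The trait table has one row per bird: bird_id, group, then one column
    per trait.  The echotexture table is long format (bird_id, group,
    plane, mpi, mph) matching what image analysis would produce.  Groups
    are drawn in a fixed order from a single generator, so a given seed
    yields bit-identical tables.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3 (the screen needs n >= 3)")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    corr = _build_latent_correlation(model)
    # tiny jitter keeps Cholesky stable when a planted set sits on the PSD edge
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    names = list(model.echo_variables) + list(model.traits)
    sensory = set(defaults.SENSORY_TRAITS) & set(model.traits)
    sd_factor = float(np.sqrt(model.sd_scale_n))
    planes = [p for p in defaults.PLANES
              if f"{p}-MPI" in model.echo_stats and f"{p}-MPH" in model.echo_stats]

    trait_rows: list[dict] = []
    echo_rows: list[dict] = []
    for group in model.groups:
        z = rng.standard_normal((n_per_group, len(names))) @ chol.T
        means = np.array([
            (model.echo_stats.get(n) or model.trait_stats[n])[group][0] for n in names
        ])
        sds = np.array([
            (model.echo_stats.get(n) or model.trait_stats[n])[group][1] * sd_factor
            for n in names
        ])
        values = means + z * sds
        for k in range(n_per_group):
            bird = f"{group}-{k + 1:02d}"
            rec = dict(zip(names, values[k]))
            row = {"bird_id": bird, "group": group}
            for t in model.traits:
                v = rec[t]
                row[t] = float(_snap_to_grid(np.asarray(v), model.sensory_grid)) \
                    if t in sensory else float(v)
            trait_rows.append(row)
            for plane in planes:
                echo_rows.append({
                    "bird_id": bird, "group": group, "plane": plane,
                    "mpi": float(rec[f"{plane}-MPI"]),
                    "mph": float(rec[f"{plane}-MPH"]),
                })
    traits_df = pd.DataFrame(trait_rows)
    echo_df = pd.DataFrame(echo_rows, columns=["bird_id", "group", "plane", "mpi", "mph"])
    return traits_df, echo_df
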