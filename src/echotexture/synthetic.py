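"""Synthetic two-class speckle-image cohorts.

Real echocardiographic B-mode texture is dominated by fully developed
speckle: the envelope of a spatially correlated circular complex Gaussian
scatterer field, whose amplitude is Rayleigh distributed.  The generator
builds each ROI as

    I(x, y) = B(x, y) * E(x, y)  [+ oriented band for the case class]

where ``B`` is a smooth positive echogenicity map (log-normal field with
correlation length ``bg_smoothness``) and ``E`` the unit-mean Rayleigh
envelope of a complex Gaussian field smoothed to correlation length
``speckle_grain``.  The case-vs-control difference is injected as an
additive oriented sinusoidal band — amplitude ``0.5 * effect_size * B``,
wavelength ``2 * effect_scale`` pixels, wave vector along
``effect_orientation`` — so that the discriminative signal is concentrated
in one oriented frequency band, the regime in which Gabor-type features
carry the class information.  Each subject gets one random band phase,
shared by its two cardiac-phase frames ("R" end-diastole, "T" end-systole),
whose speckle realizations are otherwise independent.

With ``effect_size = 0`` the two classes are draws from one distribution;
the generator is bit-deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SpeckleParams",
    "CohortSpec",
    "speckle_envelope",
    "generate_roi",
    "generate_cohort",
]

PHASES = ("R", "T")

#: Upper edge (pre-compression amplitude units, unit-mean speckle) of the
#: fixed display window; amplitudes above it saturate like scanner gain.
_WINDOW_MAX = 6.0


@dataclass(frozen=True)
class SpeckleParams:
    """Physical knobs of one ROI.

    roi_size
        Side of the square ROI in pixels; a power of two >= 64 so that the
        dyadic wavelet decomposition is well defined (256 gives all 8 levels).
    bg_smoothness
        Correlation length (pixels) of the smooth echogenicity map.
    speckle_grain
        Correlation length (pixels) of the complex scatterer field, i.e. the
        speckle cell size.
    log_compress
        Apply logarithmic amplitude compression (as a B-mode scan converter
        would) before the final rescale.
    bit_depth
        Output bit depth; pixels are rescaled to [0, 2**bit_depth - 1].
    """

    roi_size: int = 256
    bg_smoothness: float = 32.0
    speckle_grain: float = 2.0
    log_compress: bool = False
    bit_depth: int = 8

    def __post_init__(self) -> None:
        n = self.roi_size
        if n < 64 or (n & (n - 1)) != 0:
            raise ValueError(
                f"roi_size must be a power of two >= 64, got {n}"
            )
        if self.bg_smoothness < 1 or self.speckle_grain < 1:
            raise ValueError("correlation lengths must be >= 1 pixel")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and class effect.

    The default 64 cases / 46 controls matches a two-class echocardiographic
    study cohort of pacemaker patients and healthy controls.  The effect is
    an oriented band (see module docstring): ``effect_size`` scales its
    amplitude (0 = null cohort), ``effect_orientation`` is the wave-vector
    angle in degrees and ``effect_scale`` the Gabor-envelope size (pixels)
    the band is matched to (wavelength = 2 * effect_scale).
    """

    n_cases: int = 64
    n_controls: int = 46
    effect_size: float = 1.0
    effect_orientation: int = 90
    effect_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.effect_orientation not in (0, 45, 90, 135):
            raise ValueError("effect_orientation must be one of 0, 45, 90, 135")


def speckle_envelope(n: int, grain: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean Rayleigh envelope of a correlated circular complex
    Gaussian field on an n x n grid."""
    re = gaussian_filter(rng.standard_normal((n, n)), grain / 2.0, mode="wrap")
    im = gaussian_filter(rng.standard_normal((n, n)), grain / 2.0, mode="wrap")
    env = np.hypot(re, im)
    return env / env.mean()


def _echogenicity_map(n: int, smoothness: float, rng: np.random.Generator) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((n, n)), smoothness, mode="wrap")
    sd = f.std()
    # standardized log-echogenicity: zero mean, unit variance per ROI
    f = (f - f.mean()) / sd if sd > 0 else f - f.mean()
    return np.exp(0.4 * f)


def generate_roi(
    params: SpeckleParams,
    class_label: int,
    spec: CohortSpec,
    rng: np.random.Generator,
    band_phase: float | None = None,
) -> np.ndarray:
    """One speckle ROI; ``class_label`` 1 = case (band effect added), 0 =
    control.  ``band_phase`` fixes the band's spatial phase (radians); when
    None it is drawn from ``rng`` (consumed for both classes so the two
    classes share one random stream layout)."""
    n = params.roi_size
    b = _echogenicity_map(n, params.bg_smoothness, rng)
    env = speckle_envelope(n, params.speckle_grain, rng)
    phase = float(rng.uniform(0.0, 2.0 * math.pi)) if band_phase is None else band_phase
    if class_label and spec.effect_size > 0:
        theta = math.radians(spec.effect_orientation)
        y, x = np.mgrid[0:n, 0:n].astype(np.float64)
        u = x * math.cos(theta) + y * math.sin(theta)
        band = np.cos(2.0 * np.pi * u / (2.0 * spec.effect_scale) + phase)
        # the band modulates echogenicity *under* the multiplicative
        # speckle (amplitude tied to the ROI-mean echogenicity), so the
        # class difference lives in oriented texture, not in the
        # dark-pixel floor of the histogram
        b = np.maximum(b + 0.5 * spec.effect_size * b.mean() * band, 0.0)
    img = b * env
    # fixed display window (fixed scanner gain): amplitudes in [0, 6]
    # pre-compression units map onto the full bit range, brighter saturates
    top = (1 << params.bit_depth) - 1
    if params.log_compress:
        img = np.log1p(img / _WINDOW_MAX * 1000.0) / math.log1p(1000.0)
        img = np.clip(img, 0.0, 1.0) * top
    else:
        img = np.clip(img, 0.0, _WINDOW_MAX) * (top / _WINDOW_MAX)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return np.rint(img).astype(dtype)


def generate_cohort(
    spec: CohortSpec,
    params: SpeckleParams | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Generate the full two-class cohort: two frames (phases R and T, with
    independent speckle but a shared subject-level band phase) per subject.

    Returns ``(manifest, images)``; the manifest has one row per image with
    columns ``subject_id, class, phase, path, seed`` and ``images`` maps
    ``(subject_id, phase)`` to the raster.  When ``out_dir`` is given the
    rasters are additionally written there as 8/16-bit grayscale PNG and the
    manifest as ``manifest.csv``.
    """
    params = params or SpeckleParams()
    rng = np.random.default_rng(spec.seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    rows = []
    images: dict[tuple[str, str], np.ndarray] = {}
    subjects = [("case", i, 1) for i in range(spec.n_cases)] + [
        ("ctrl", i, 0) for i in range(spec.n_controls)
    ]
    for prefix, i, label in subjects:
        sid = f"{prefix}_{i + 1:03d}"
        band_phase = float(rng.uniform(0.0, 2.0 * math.pi))
        for phase in PHASES:
            img = generate_roi(params, label, spec, rng, band_phase=band_phase)
            images[(sid, phase)] = img
            fname = f"{sid}_{phase}.png"
            if out_path is not None:
                Image.fromarray(img).save(out_path / fname)
            rows.append(
                {
                    "subject_id": sid,
                    "class": label,
                    "phase": phase,
                    "path": str(out_path / fname) if out_path is not None else fname,
                    "seed": spec.seed,
                }
            )
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return manifest, images
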