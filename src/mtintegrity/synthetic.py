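"""Synthetic confocal micrographs of cortical microtubule arrays.

Renders single cells of a GFP-tubulin marker line as seen in spinning-disc
confocal sections: numerous, mostly parallel microtubule bundles (bright
lines with a Gaussian cross-section) over a low diffuse background in the
intact state.  A single *disintegration* parameter ``d`` in [0, 1] moves the
image towards the drug-treated phenotype by transferring filament
fluorescence into a spatially uniform "soluble tubulin" background, so that
the total pre-noise photon budget is conserved.  Optional dark elliptical
voids emulate plastids embedded in the fluorescent cytoplasm (they attenuate
the diffuse background only, not the filaments), and bright punctate
speckles emulate the scarce late-stage puncta seen after prolonged
treatment.

The module also carries the two small coupling models that drive synthetic
experiments: a Hill-type dose → disintegration map and a linear
integrity → mortality coupling with binomial (dye-exclusion) counting noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .scoring import CellImage

__all__ = [
    "SyntheticParams",
    "DoseMap",
    "MortalityCoupling",
    "MortalityRecord",
    "generate_cell_image",
    "render_expected_image",
    "disintegration_from_dose",
    "simulate_mortality",
    "generate_batch",
]

# Attenuation of the diffuse background inside a plastid void and relative
# brightness / width of late-stage speckles.  Fixed rendering constants, not
# experimental knobs.
_PLASTID_TRANSMISSION = 0.08
_PLASTID_EDGE_BLUR = 0.7
_SPECKLE_GAIN = 2.0
_SPECKLE_SIGMA = 1.2


@dataclass
class SyntheticParams:
    """Parameters of one rendered cell.

    Intensities are in expected-photon units; the Poisson branch of the
    noise model draws counts directly from them.  ``disintegration`` is the
    fraction of each filament's photon budget redistributed to the uniform
    soluble-tubulin background.
    """

    image_height: int = 256
    image_width: int = 256
    n_filaments: int = 76
    mean_orientation: float = 90.0  # degrees from +x; 90 = transverse array
    orientation_sd: float = 1.0
    filament_width_sigma: float = 0.6
    filament_peak_intensity: float = 160.0
    baseline_background: float = 4.0
    disintegration: float = 0.0
    n_plastids: int = 600
    plastid_axes: tuple[float, float] = (4.0, 2.0)
    speckle_density: float = 0.0  # speckles per 1000 px^2
    position_jitter: float = 0.05  # bundle-centre jitter, fraction of spacing
    texture_sd: float = 0.5  # granularity of the soluble pool (relative SD)
    texture_scale: float = 0.8  # granularity correlation length, pixels
    noise_model: str = "mixed"  # gaussian | poisson | mixed
    noise_sd: float = 3.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.disintegration <= 1.0:
            raise ValueError(
                f"disintegration must lie in [0, 1], got {self.disintegration}"
            )
        if self.n_filaments < 0 or self.n_plastids < 0:
            raise ValueError("counts must be non-negative")
        if min(self.filament_peak_intensity, self.baseline_background,
               self.noise_sd, self.speckle_density) < 0:
            raise ValueError("intensities, noise and densities must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.noise_model not in ("gaussian", "poisson", "mixed"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def replace(self, **kw) -> "SyntheticParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DoseMap:
    """Hill-type map from applied extract dose to disintegration fraction.

    d(x) = d_max * x**h / (ec50**h + x**h); monotone, d(0) = 0 and
    d(x) -> d_max as x grows.
    """

    d_max: float = 1.0
    ec50: float = 1.0
    hill_coefficient: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_max <= 1.0:
            raise ValueError("d_max must lie in [0, 1]")
        if self.ec50 <= 0 or self.hill_coefficient <= 0:
            raise ValueError("ec50 and hill_coefficient must be positive")


@dataclass(frozen=True)
class MortalityCoupling:
    """Linear coupling of late mortality to the 2-h integrity score.

    Expected mortality fraction at score ``s`` is
    ``intercept + slope * (s - 60)`` (60 = fully intact anchor), perturbed by
    a Gaussian inter-replicate term and realised as a binomial dead-cell
    count over ``n_cells_per_measurement`` scored cells.
    """

    intercept: float = 0.05
    slope: float = -0.059
    residual_sd: float = 0.04
    n_cells_per_measurement: int = 500
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.intercept <= 1.0:
            raise ValueError("intercept is a mortality fraction in [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.n_cells_per_measurement <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")


@dataclass
class MortalityRecord:
    """Dead/total count for one replicate of one condition."""

    condition: tuple
    replicate: int
    dead: int
    total: int = 500

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be positive")
        if not 0 <= self.dead <= self.total:
            raise ValueError("dead must lie in [0, total]")


def _filament_field(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Render the full-intensity filament layer (before disintegration).

    Filaments are straight lines through the frame with Gaussian
    cross-section.  Line centres are a jittered regular grid along the axis
    perpendicular to the mean orientation (cortical arrays are quasi-regular),
    individual orientations are jittered around the mean.
    """
    h, w = params.image_height, params.image_width
    field = np.zeros((h, w), dtype=float)
    n = params.n_filaments
    if n == 0:
        return field

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    diag = float(np.hypot(h, w))
    spacing = diag / n
    base_theta = np.deg2rad(params.mean_orientation)
    # offsets of line centres along the perpendicular of the mean orientation
    offsets = (np.arange(n) + 0.5) * spacing - diag / 2.0
    offsets = offsets + rng.uniform(-1.0, 1.0, size=n) * spacing * params.position_jitter
    thetas = base_theta + np.deg2rad(rng.normal(0.0, params.orientation_sd, size=n))

    perp = np.array([-np.sin(base_theta), np.cos(base_theta)])  # (dx, dy)
    two_sig2 = 2.0 * params.filament_width_sigma ** 2
    for off, th in zip(offsets, thetas):
        px = cx + off * perp[0]
        py = cy + off * perp[1]
        # distance of each pixel to the infinite line through (px, py) at th
        dist = (xx - px) * np.sin(th) - (yy - py) * np.cos(th)
        field += params.filament_peak_intensity * np.exp(-dist * dist / two_sig2)
    return field


def _granularity_field(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative granularity of the soluble cytoplasmic pool.

    The cytoplasm of a living cell is not optically uniform: vesicles,
    strands and organelles modulate the soluble-tubulin fluorescence at a
    few-pixel scale.  Modelled as a smoothed, bounded Gaussian texture
    normalised to an exact mean of one, so the photon budget is unchanged.
    """
    h, w = params.image_height, params.image_width
    if params.texture_sd <= 0:
        return np.ones((h, w), dtype=float)
    g = ndimage.gaussian_filter(rng.standard_normal((h, w)), params.texture_scale)
    sd = float(g.std())
    if sd == 0:
        return np.ones((h, w), dtype=float)
    g *= params.texture_sd / sd
    # bounded modulation: granularity dims and brightens the pool but does
    # not create bright point sources (those are speckles, modelled apart)
    t = np.clip(1.0 + g, 0.0, 1.0 + 1.5 * params.texture_sd)
    return t / float(t.mean())


def _plastid_mask(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative mask (1 outside, strongly attenuating inside voids)."""
    h, w = params.image_height, params.image_width
    mask = np.ones((h, w), dtype=float)
    if params.n_plastids == 0:
        return mask
    a, b = params.plastid_axes
    r = int(np.ceil(max(a, b))) + 1
    for _ in range(params.n_plastids):
        py = rng.uniform(0, h - 1)
        px = rng.uniform(0, w - 1)
        phi = rng.uniform(0, np.pi)
        y0, y1 = max(0, int(py) - r), min(h, int(py) + r + 1)
        x0, x1 = max(0, int(px) - r), min(w, int(px) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        dx, dy = xx - px, yy - py
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        patch = mask[y0:y1, x0:x1]
        patch[inside] = _PLASTID_TRANSMISSION
    # optical blur of the void edges
    return ndimage.gaussian_filter(mask, _PLASTID_EDGE_BLUR)


def _speckle_field(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_height, params.image_width
    field = np.zeros((h, w), dtype=float)
    if params.speckle_density <= 0:
        return field
    n = rng.poisson(params.speckle_density * h * w / 1000.0)
    if n == 0:
        return field
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    amp = _SPECKLE_GAIN * params.filament_peak_intensity
    two_sig2 = 2.0 * _SPECKLE_SIGMA ** 2
    for _ in range(int(n)):
        py = rng.uniform(0, h - 1)
        px = rng.uniform(0, w - 1)
        r2 = (xx - px) ** 2 + (yy - py) ** 2
        field += amp * np.exp(-r2 / two_sig2)
    return field


def _expected_image(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Pre-noise expected-photon image from one rng stream.

    The disintegration exchange is exact: the filament layer contributes
    ``(1-d)*F`` and the soluble pool ``d*mean(F)`` on top of the baseline,
    so the total photon budget of a plastid-free render does not depend on
    ``d`` (the granularity texture is normalised to mean one).
    """
    d = params.disintegration
    filaments = _filament_field(params, rng)
    texture = _granularity_field(params, rng)
    mask = _plastid_mask(params, rng)
    speckles = _speckle_field(params, rng)
    soluble = params.baseline_background + d * float(filaments.mean())
    return soluble * texture * mask + (1.0 - d) * filaments + speckles


def render_expected_image(params: SyntheticParams) -> np.ndarray:
    """Pre-noise, pre-quantisation expected-photon image."""
    return _expected_image(params, np.random.default_rng(params.seed))


def generate_cell_image(params: SyntheticParams, cell_id: str | None = None,
                        metadata: dict | None = None) -> CellImage:
    """Render one synthetic cell and apply the noise model and quantisation.

    Identical ``params`` (including ``seed``) give a bit-identical image.
    """
    rng = np.random.default_rng(params.seed)
    expected = _expected_image(params, rng)

    if params.noise_model == "gaussian":
        noisy = expected + rng.normal(0.0, params.noise_sd, expected.shape)
    elif params.noise_model == "poisson":
        noisy = rng.poisson(expected).astype(float)
    else:  # mixed: shot noise plus Gaussian read noise
        noisy = rng.poisson(expected).astype(float)
        if params.noise_sd > 0:
            noisy += rng.normal(0.0, params.noise_sd, expected.shape)

    vmax = 2 ** params.bit_depth - 1
    quantised = np.clip(np.rint(noisy), 0, vmax)
    pixels = quantised.astype(np.uint8 if params.bit_depth == 8 else np.uint16)
    return CellImage(
        pixels=pixels,
        bit_depth=params.bit_depth,
        id=cell_id or f"synthetic-seed{params.seed}",
        metadata=metadata,
    )


def disintegration_from_dose(dose: float, dose_map: DoseMap) -> float:
    """Hill-type dose response: d = d_max * dose**h / (ec50**h + dose**h)."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose == 0:
        return 0.0
    h = dose_map.hill_coefficient
    xh = float(dose) ** h
    return dose_map.d_max * xh / (dose_map.ec50 ** h + xh)


def simulate_mortality(score: float, coupling: MortalityCoupling, seed: int,
                       condition: tuple = ()) -> list[MortalityRecord]:
    """Simulate one Evans-blue mortality measurement per replicate.

    Each replicate draws its dead-cell count from a binomial over
    ``n_cells_per_measurement`` cells with success probability
    ``clip(intercept + slope*(score - 60) + N(0, residual_sd), 0, 1)``.
    """
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(coupling.n_replicates):
        p = coupling.intercept + coupling.slope * (score - 60.0)
        if coupling.residual_sd > 0:
            p += rng.normal(0.0, coupling.residual_sd)
        p = float(np.clip(p, 0.0, 1.0))
        dead = int(rng.binomial(coupling.n_cells_per_measurement, p))
        records.append(
            MortalityRecord(condition=condition, replicate=rep, dead=dead,
                            total=coupling.n_cells_per_measurement)
        )
    return records


def generate_batch(params: SyntheticParams, n_images: int, seed: int,
                   metadata: dict | None = None,
                   id_prefix: str = "cell") -> list[CellImage]:
    """Render ``n_images`` cells; image ``i`` uses seed ``seed + i``."""
    return [
        generate_cell_image(
            params.replace(seed=seed + i),
            cell_id=f"{id_prefix}-{i:03d}",
            metadata=metadata,
        )
        for i in range(n_images)
    ]
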