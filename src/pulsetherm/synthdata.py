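"""Synthetic pulsed-thermography video generator.

Generates thermal videos with the statistical and physical structure the
downstream analysis assumes: each specimen is a region of hot pixels on a
reflective (cool) stage, heated by a timed lamp pulse and relaxing back toward
ambient afterwards. The per-pixel temperature follows a lumped-capacitance
(Newtonian) model — exponential approach to an equilibrium gain ``g`` above
ambient with time constant ``tau_heat`` while the lamps are on, exponential
relaxation toward ambient with time constant ``tau_cool`` after lamp-off:

    T(t) = T_amb + g * (1 - exp(-t'/tau_heat))            (lamps on)
    T(t) = T_amb + (T_peak - T_amb) * exp(-t''/tau_cool)  (after lamp-off)

The front buffer sits at ambient; the rear buffer continues the cooling decay.
Material classes differ in their gain and time constants (broad thin leaves
heat far more than dense seed coats), in geometry, and in between-specimen
variability, which together reproduce the waveform families and confusion
structure the analysis is designed to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.draw import disk, ellipse

from .videoio import AcquisitionProtocol, ThermalVideo, protocol_frame_indices

STEFAN_BOLTZMANN = 5.670374419e-8  # W m^-2 K^-4

#: The 12 sample classes: cotton lint plus the 11 common contaminant types.
CLASS_NAMES = (
    "bark",
    "bract",
    "brown_leaves",
    "green_leaves",
    "hulls",
    "module_cover",
    "paper",
    "seed_coats",
    "seeds",
    "stems",
    "twine",
    "cotton",
)

#: Classes whose thermal responses overlap strongly (broad, thin botanical
#: tissue with near-identical composition); identification errors are
#: expected to concentrate within this triplet.
CONFUSABLE_TRIPLET = ("bract", "green_leaves", "brown_leaves")

GEOMETRIES = ("broad_leaf", "linear", "blob", "full_window", "rectangle")


@dataclass(frozen=True)
class RadiometricModel:
    """Grey-body radiator: emissivity, Stefan–Boltzmann constant, temperature."""

    emissivity: float
    temperature_k: float
    stefan_boltzmann: float = STEFAN_BOLTZMANN

    def __post_init__(self) -> None:
        if not 0 <= self.emissivity <= 1:
            raise ValueError("emissivity must be in [0, 1]")


def radiant_emission(model: RadiometricModel) -> float:
    """Total emitted radiation (W/m^2) of a grey body: ``eps * sigma * T^4``.

    Raises
    ------
    ValueError
        If the absolute temperature is not positive.
    """
    if model.temperature_k <= 0:
        raise ValueError("absolute temperature must be positive")
    return model.emissivity * model.stefan_boltzmann * model.temperature_k**4


@dataclass(frozen=True)
class MaterialThermalParams:
    """Lumped thermal response of one material class.

    Parameters
    ----------
    ambient_temp : float
        Ambient (resting) temperature, degrees C.
    equilibrium_gain : float
        Asymptotic temperature rise above ambient under the lamps, degrees C.
    tau_heat, tau_cool : float
        Heating and cooling time constants, seconds (> 0).
    pixel_jitter_cv : float
        Coefficient of variation of the per-pixel equilibrium gain within
        one specimen (spatial inhomogeneity).
    edge_cooling_factor : float
        Multiplier (>= 1) on the cooling rate ``1/tau_cool`` at mask-boundary
        pixels, modelling faster heat loss at specimen edges.
    sample_gain_cv, sample_tau_cv : float
        Lognormal coefficients of variation of the gain and the two time
        constants *between* specimens of the class (mass/geometry spread).
    """

    ambient_temp: float = 25.0
    equilibrium_gain: float = 30.0
    tau_heat: float = 2.0
    tau_cool: float = 5.0
    pixel_jitter_cv: float = 0.0
    edge_cooling_factor: float = 1.0
    sample_gain_cv: float = 0.0
    sample_tau_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_heat <= 0 or self.tau_cool <= 0:
            raise ValueError("time constants must be strictly positive")
        if self.equilibrium_gain < 0:
            raise ValueError("equilibrium gain must be non-negative")
        if self.edge_cooling_factor < 1:
            raise ValueError("edge_cooling_factor must be >= 1")
        for name in ("pixel_jitter_cv", "sample_gain_cv", "sample_tau_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ClassSpec:
    """One sample class: a name, a geometry family, a size and its thermal response."""

    class_name: str
    geometry: str
    size_range: tuple[int, int]
    thermal_params: MaterialThermalParams

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        lo, hi = self.size_range
        if lo < 1 or hi < lo:
            raise ValueError("size_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class DatasetConfig:
    """Full synthetic-study configuration."""

    class_specs: tuple[ClassSpec, ...]
    samples_per_class: int = 20
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    frame_height: int = 80
    frame_width: int = 80
    noise_sd: float = 0.045  # camera NETD, degrees C
    background_temp: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        names = [s.class_name for s in self.class_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names in dataset config")


def simulate_trace(
    params: MaterialThermalParams, protocol: AcquisitionProtocol
) -> np.ndarray:
    """Noiseless lumped-capacitance temperature trace over the full protocol.

    Returns one temperature (deg C, float64) per frame. The peak occurs at the
    lamp-off frame (the first cooling frame, at which zero cooling time has
    elapsed); the rear buffer continues the cooling decay.
    """
    lamp_on, lamp_off, _cutoff, total = protocol_frame_indices(protocol)
    t = np.arange(total) / protocol.fps
    trace = np.full(total, params.ambient_temp, dtype=float)

    heating = slice(lamp_on, lamp_off)
    t_heat = t[heating] - protocol.front_buffer_s
    trace[heating] = params.ambient_temp + params.equilibrium_gain * (
        1.0 - np.exp(-t_heat / params.tau_heat)
    )

    peak_rise = params.equilibrium_gain * (
        1.0 - np.exp(-protocol.heat_s / params.tau_heat)
    )
    t_cool = t[lamp_off:] - protocol.front_buffer_s - protocol.heat_s
    trace[lamp_off:] = params.ambient_temp + peak_rise * np.exp(
        -t_cool / params.tau_cool
    )
    return trace


def _geometry_mask(
    geometry: str,
    size_range: tuple[int, int],
    height: int,
    width: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one boolean specimen mask of the requested geometry family."""
    lo, hi = size_range
    if hi > min(height, width):
        raise ValueError(
            f"geometry size up to {hi} px does not fit a {height}x{width} frame"
        )
    mask = np.zeros((height, width), dtype=bool)
    cy, cx = height / 2, width / 2

    if geometry == "full_window":
        mask[:] = True
        return mask

    size = int(rng.integers(lo, hi + 1))
    # small placement jitter keeps the specimen roughly centred on the stage
    jit = max(1, min(height, width) // 16)
    cy += float(rng.integers(-jit, jit + 1))
    cx += float(rng.integers(-jit, jit + 1))

    if geometry == "rectangle":
        h2, w2 = size // 2, max(1, int(size * 0.75)) // 2
        r0 = int(np.clip(cy - h2, 0, height - 1))
        c0 = int(np.clip(cx - w2, 0, width - 1))
        mask[r0 : min(height, r0 + max(1, 2 * h2)), c0 : min(width, c0 + max(1, 2 * w2))] = True
    elif geometry == "blob":
        rr, cc = disk((cy, cx), max(1.5, size / 2), shape=mask.shape)
        mask[rr, cc] = True
    elif geometry == "broad_leaf":
        angle = rng.uniform(0, np.pi)
        rr, cc = ellipse(
            cy, cx, max(2.0, size / 2), max(2.0, size / 3.2),
            shape=mask.shape, rotation=angle,
        )
        mask[rr, cc] = True
    elif geometry == "linear":
        angle = rng.uniform(0, np.pi)
        rr, cc = ellipse(
            cy, cx, max(2.0, size / 2), max(1.0, size / 10),
            shape=mask.shape, rotation=angle,
        )
        mask[rr, cc] = True
    else:  # pragma: no cover - guarded by ClassSpec
        raise ValueError(f"unknown geometry {geometry!r}")

    if not mask.any():
        mask[int(cy) % height, int(cx) % width] = True
    return mask


def _sample_rng(config_seed: int, class_index: int, sample_index: int) -> np.random.Generator:
    """Per-sample RNG stream, stable under class/sample reordering."""
    ss = np.random.SeedSequence(entropy=config_seed, spawn_key=(class_index, sample_index))
    return np.random.Generator(np.random.PCG64(ss))


def _perturbed_params(
    params: MaterialThermalParams, rng: np.random.Generator
) -> MaterialThermalParams:
    """Draw one specimen's thermal parameters (lognormal between-sample spread)."""
    def logn(mean: float, cv: float) -> float:
        if cv <= 0 or mean == 0:
            return mean
        sigma = np.sqrt(np.log1p(cv**2))
        return mean * np.exp(rng.normal(-0.5 * sigma**2, sigma))

    return replace(
        params,
        equilibrium_gain=logn(params.equilibrium_gain, params.sample_gain_cv),
        tau_heat=logn(params.tau_heat, params.sample_tau_cv),
        tau_cool=logn(params.tau_cool, params.sample_tau_cv),
    )


def render_video(
    spec: ClassSpec, config: DatasetConfig, sample_seed: tuple[int, int]
) -> tuple[ThermalVideo, np.ndarray]:
    """Render one specimen video plus its ground-truth pixel mask.

    ``sample_seed`` is the (class_index, sample_index) pair; the RNG stream is
    derived from it and ``config.seed`` so regeneration is bit-identical.
    Sample pixels follow the lumped model with per-pixel gain jitter and
    accelerated cooling at mask-boundary pixels; background pixels sit at
    ``background_temp``. i.i.d. Gaussian camera noise (sd = ``noise_sd``) is
    added everywhere.
    """
    class_index, sample_index = sample_seed
    rng = _sample_rng(config.seed, class_index, sample_index)
    height, width = config.frame_height, config.frame_width
    protocol = config.protocol
    total = protocol.total_frames

    mask = _geometry_mask(spec.geometry, spec.size_range, height, width, rng)
    params = _perturbed_params(spec.thermal_params, rng)

    frames = np.full((total, height, width), config.background_temp, dtype=np.float64)

    # boundary pixels cool faster: scale tau_cool down by the edge factor
    interior = binary_erosion(mask)
    boundary = mask & ~interior
    for region, edge in ((interior, False), (boundary, True)):
        if not region.any():
            continue
        tau_cool = params.tau_cool
        if edge and params.edge_cooling_factor > 1:
            tau_cool = params.tau_cool / params.edge_cooling_factor
        base = simulate_trace(replace(params, tau_cool=tau_cool), protocol)
        n_pix = int(region.sum())
        if params.pixel_jitter_cv > 0:
            gain_scale = 1.0 + params.pixel_jitter_cv * rng.standard_normal(n_pix)
            gain_scale = np.clip(gain_scale, 0.0, None)
        else:
            gain_scale = np.ones(n_pix)
        rise = base - params.ambient_temp  # (F,)
        pix = params.ambient_temp + rise[:, None] * gain_scale[None, :]
        frames[:, region] = pix

    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape)

    metadata = {
        "class": spec.class_name,
        "class_index": class_index,
        "sample_index": sample_index,
        "seed": config.seed,
        "protocol": protocol.to_dict(),
    }
    video = ThermalVideo(frames=frames.astype(np.float32), fps=protocol.fps, metadata=metadata)
    return video, mask


def generate_dataset(config: DatasetConfig):
    """Yield ``(ThermalVideo, mask, class_name)`` for every sample in the study.

    Samples are generated class-by-class; per-sample RNG streams are derived
    deterministically from ``config.seed`` so the full dataset is reproducible
    bit-for-bit.
    """
    for class_index, spec in enumerate(config.class_specs):
        for sample_index in range(config.samples_per_class):
            video, mask = render_video(spec, config, (class_index, sample_index))
            yield video, mask, spec.class_name


# --------------------------------------------------------------------------
# Default study-replica calibration.
#
# Anchors: brown leaves peak near 75 C and seed coats near 35 C above a 25 C
# ambient; bract cools faster than cotton; bract/green-leaf/brown-leaf form a
# thermally overlapping triplet and bark/paper a weakly separated pair. All
# remaining values are free calibration choices of this package, not
# measurements (see docs/methods.md).
# --------------------------------------------------------------------------

_TRIPLET_CV = dict(sample_gain_cv=0.10, sample_tau_cv=0.10)
_DEFAULT_CV = dict(sample_gain_cv=0.08, sample_tau_cv=0.08)

_DEFAULT_THERMAL = {
    #                 gain  tau_h  tau_c  extra
    "bark":         (33.0, 1.9, 4.8, _DEFAULT_CV),
    "bract":        (52.0, 1.9, 3.0, _TRIPLET_CV),
    "brown_leaves": (54.5, 2.0, 4.0, _TRIPLET_CV),
    "green_leaves": (50.0, 2.1, 4.2, _TRIPLET_CV),
    "hulls":        (24.0, 2.2, 6.0, _DEFAULT_CV),
    "module_cover": (40.0, 1.5, 2.5, _DEFAULT_CV),
    "paper":        (34.0, 1.8, 5.0, _DEFAULT_CV),
    "seed_coats":   (11.0, 2.0, 5.0, _DEFAULT_CV),
    "seeds":        (15.0, 3.0, 8.0, _DEFAULT_CV),
    "stems":        (27.0, 2.3, 6.0, _DEFAULT_CV),
    "twine":        (20.0, 2.0, 5.5, _DEFAULT_CV),
    "cotton":       (30.0, 2.5, 9.0, dict(sample_gain_cv=0.05, sample_tau_cv=0.05)),
}

_DEFAULT_GEOMETRY = {
    "bark": ("linear", (24, 40)),
    "bract": ("broad_leaf", (20, 34)),
    "brown_leaves": ("broad_leaf", (20, 34)),
    "green_leaves": ("broad_leaf", (20, 34)),
    "hulls": ("blob", (14, 24)),
    "module_cover": ("rectangle", (18, 30)),
    "paper": ("rectangle", (44, 56)),
    "seed_coats": ("blob", (8, 16)),
    "seeds": ("blob", (8, 14)),
    "stems": ("linear", (24, 40)),
    "twine": ("linear", (24, 40)),
    "cotton": ("full_window", (1, 1)),
}


def default_class_specs(
    frame_size: int = 80, ambient_temp: float = 25.0
) -> tuple[ClassSpec, ...]:
    """The 12-class study-replica calibration, scaled to ``frame_size``."""
    scale = frame_size / 80.0
    specs = []
    for name in CLASS_NAMES:
        gain, tau_h, tau_c, cv = _DEFAULT_THERMAL[name]
        geometry, (lo, hi) = _DEFAULT_GEOMETRY[name]
        if geometry != "full_window":
            lo = max(3, int(round(lo * scale)))
            hi = max(lo, int(round(hi * scale)))
        specs.append(
            ClassSpec(
                class_name=name,
                geometry=geometry,
                size_range=(lo, hi),
                thermal_params=MaterialThermalParams(
                    ambient_temp=ambient_temp,
                    equilibrium_gain=gain,
                    tau_heat=tau_h,
                    tau_cool=tau_c,
                    pixel_jitter_cv=0.05,
                    edge_cooling_factor=1.6,
                    **cv,
                ),
            )
        )
    return tuple(specs)


def default_config(seed: int = 0, frame_size: int = 80) -> DatasetConfig:
    """Study-replica dataset: 12 classes x 20 samples, 1/5/10/1 s at 30 fps."""
    return DatasetConfig(
        class_specs=default_class_specs(frame_size=frame_size),
        samples_per_class=20,
        protocol=AcquisitionProtocol(),
        frame_height=frame_size,
        frame_width=frame_size,
        noise_sd=0.045,
        background_temp=25.0,
        seed=seed,
    )
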