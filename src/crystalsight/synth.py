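"""Synthetic crystallization experiments: backlit suspension frames,
transmission and temperature channels, with ground-truth clear/cloud
events and suspension-density trajectories.

The renderer emulates the imaging geometry of a small-scale crystallizer
camera: a bright, slightly vignetted background with dark elliptical
crystals whose number follows a Poisson law proportional to the suspension
density x_c (mg crystals per mL solvent) and the imaged volume. Kinetics
are a single first-order relaxation of x_c toward the equilibrium implied
by a van't Hoff solubility model; nucleation during cooling triggers at a
configured supersaturation ratio. No optical physics (diffraction,
depth-of-field blur), crystal habit or hydrodynamics are modelled.

The transmission channel saturates by construction: it stays above the
99.9% detection threshold for all densities below a configurable
blind-spot density (default 5 mg/mL), reproducing the late/early
detection failure mode of fixed-threshold transmissivity probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .frames import GrayFrame
from .thermo import SolubilityModel, x_mol_to_gg, DEFAULT_SOLVENT_DENSITY

__all__ = [
    "TemperaturePhase", "ExperimentConfig", "SyntheticExperiment",
    "render_frame", "transmission_model", "simulate_experiment",
    "staircase_profile", "mszw_profile",
]


@dataclass(frozen=True)
class TemperaturePhase:
    """One segment of the reactor temperature program.

    ramp: linear from T_start to T_end at |rate| K/min.
    hold: isothermal at T_start for ``duration`` minutes.
    """

    kind: str                   # {"ramp", "hold"}
    T_start: float              # degC
    T_end: float                # degC
    rate: float = 0.5           # K/min, ramps only
    duration: float = 30.0      # min, holds only

    def __post_init__(self):
        if self.kind not in ("ramp", "hold"):
            raise ValueError("phase kind must be 'ramp' or 'hold'")
        if self.kind == "hold":
            if self.T_start != self.T_end:
                raise ValueError("hold phases must keep T_start == T_end")
            if self.duration <= 0:
                raise ValueError("hold duration must be positive")
        else:
            if self.rate == 0 or not math.isfinite(self.rate):
                raise ValueError("ramp rate must be finite and nonzero")
            if np.sign(self.rate) != np.sign(self.T_end - self.T_start):
                raise ValueError("ramp rate sign must match the temperature change")

    @property
    def minutes(self) -> float:
        if self.kind == "hold":
            return self.duration
        return abs(self.T_end - self.T_start) / abs(self.rate)

    def temperature(self, t_min: float) -> float:
        """Temperature ``t_min`` minutes into the phase."""
        if self.kind == "hold":
            return self.T_start
        return self.T_start + self.rate * min(t_min, self.minutes)


def staircase_profile(T_start: float, T_end: float, step_K: float = 5.0,
                      hold_min: float = 30.0, rate: float = 1.0):
    """Stepwise heating: +step_K ramps with isothermal holds (calibration
    phase design). Starts with a hold at T_start."""
    phases = [TemperaturePhase("hold", T_start, T_start, duration=hold_min)]
    T = T_start
    while T < T_end - 1e-9:
        T_next = min(T + step_K, T_end)
        phases.append(TemperaturePhase("ramp", T, T_next, rate=abs(rate)))
        phases.append(TemperaturePhase("hold", T_next, T_next, duration=hold_min))
        T = T_next
    return phases


def mszw_profile(T_max: float, T_min: float, rate: float = 0.5,
                 hold_min: float = 30.0):
    """Metastable-zone-width design: background hold at T_max (complete
    dissolution), slow cooling to T_min (nucleation), slow re-heating to
    T_max (dissolution / clear point)."""
    return [
        TemperaturePhase("hold", T_max, T_max, duration=hold_min),
        TemperaturePhase("ramp", T_max, T_min, rate=-abs(rate)),
        TemperaturePhase("ramp", T_min, T_max, rate=abs(rate)),
        TemperaturePhase("hold", T_max, T_max, duration=hold_min),
    ]


@dataclass(frozen=True)
class ExperimentConfig:
    """Physical and imaging parameters of one synthetic experiment."""

    solvent_ratio: tuple[float, float] = (0.8, 0.2)   # (DIG, WAT) mass fractions
    solute_load: float = 40.0       # mg solute per g solvent
    profile: tuple = ()             # ordered TemperaturePhase sequence
    fps: float = 0.05               # frames per second (0.05-0.5)
    image_shape: tuple[int, int] = (480, 640)
    px_size: float = 2.8            # um per pixel
    noise_sd: float = 0.1           # additive Gaussian gray-level noise SD
    vignette_amp: float = 0.08      # relative background fall-off at corners
    psd_median: float = 30.0        # lognormal particle diameter median, um
    psd_sigma: float = 0.4          # lognormal shape parameter
    seed: int = 0
    # optics / suspension constants
    background_level: float = 200.0   # mean background gray level
    depth_um: float = 100.0           # imaged optical depth
    crystal_density: float = 1.25     # g/cm^3
    solvent_density: float = DEFAULT_SOLVENT_DENSITY  # g/mL
    # kinetics
    k_diss: float = 2.0             # 1/min, dissolution relaxation
    k_grow: float = 0.5             # 1/min, growth relaxation
    S_nuc: float = 1.5              # supersaturation ratio triggering nucleation
    # transmission channel
    blind_spot_density: float = 5.0   # mg/mL below which T stays > 99.9%
    transmission_noise_sd: float = 0.02  # % transmission noise

    def __post_init__(self):
        dig, wat = self.solvent_ratio
        if abs(dig + wat - 1.0) > 1e-12:
            raise ValueError("solvent mass fractions must sum to 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0 or self.transmission_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.image_shape[0] <= 0 or self.image_shape[1] <= 0:
            raise ValueError("image shape must be positive")

    # ---- derived optics ----
    @property
    def frame_volume_mL(self) -> float:
        rows, cols = self.image_shape
        vol_um3 = rows * self.px_size * cols * self.px_size * self.depth_um
        return vol_um3 * 1e-12  # um^3 -> mL

    @property
    def mean_particle_mass_mg(self) -> float:
        # E[d^3] of a lognormal with median m and shape s: m^3 exp(4.5 s^2)
        e_d3 = self.psd_median**3 * math.exp(4.5 * self.psd_sigma**2)
        vol_um3 = math.pi / 6.0 * e_d3
        return vol_um3 * 1e-12 * self.crystal_density * 1000.0  # mg

    def expected_count(self, x_c: float) -> float:
        """Poisson mean particle count in one frame at density x_c."""
        return x_c * self.frame_volume_mL / self.mean_particle_mass_mg

    def frame_rng(self, frame_index: int) -> np.random.Generator:
        """Per-frame substream so frame k is reproducible in isolation."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, frame_index)))


@dataclass
class SyntheticExperiment:
    """One simulated run: frames plus logs and ground truth."""

    config: ExperimentConfig
    frames: list[GrayFrame]
    transmission: np.ndarray          # % per frame
    x_c_truth: np.ndarray             # mg/mL per frame
    clear_point_truth: tuple | None   # (time_s, temperature_C)
    cloud_point_truth: tuple | None
    solubility_truth: SolubilityModel

    def __post_init__(self):
        n = len(self.frames)
        if not (len(self.transmission) == len(self.x_c_truth) == n):
            raise ValueError("sequences must have equal length")
        if np.any(self.x_c_truth < 0):
            raise ValueError("x_c_truth must be >= 0")
        if np.any((self.transmission < 0) | (self.transmission > 100)):
            raise ValueError("transmission must lie in [0, 100]")

    @property
    def times_s(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])

    @property
    def temperatures_C(self) -> np.ndarray:
        return np.array([f.temperature_C for f in self.frames])


def _background(cfg: ExperimentConfig) -> np.ndarray:
    rows, cols = cfg.image_shape
    r = (np.arange(rows) - (rows - 1) / 2.0) / max(rows / 2.0, 1.0)
    c = (np.arange(cols) - (cols - 1) / 2.0) / max(cols / 2.0, 1.0)
    radial2 = (r[:, None]**2 + c[None, :]**2) / 2.0
    return cfg.background_level * (1.0 - cfg.vignette_amp * radial2)


def render_frame(x_c: float, cfg: ExperimentConfig,
                 rng: np.random.Generator, time_s: float = 0.0,
                 temperature_C: float = float("nan")) -> GrayFrame:
    """Render one backlit suspension frame at density ``x_c`` (mg/mL).

    The particle count is Poisson with mean proportional to x_c and
    inversely proportional to the mean particle mass. Particles are filled
    dark ellipses (aspect ratio U(0.3, 1), random orientation); overlaps
    compose via darkest-wins.
    """
    if x_c < 0:
        raise ValueError("x_c must be >= 0")
    rows, cols = cfg.image_shape
    img = _background(cfg)
    n = int(rng.poisson(cfg.expected_count(x_c)))
    for _ in range(n):
        d_um = rng.lognormal(math.log(cfg.psd_median), cfg.psd_sigma)
        a_px = max(d_um / cfg.px_size / 2.0, 1.0)       # semi-major axis
        aspect = rng.uniform(0.3, 1.0)
        theta = rng.uniform(0.0, math.pi)
        cy = rng.uniform(0, rows - 1)
        cx = rng.uniform(0, cols - 1)
        gray = rng.uniform(0.25, 0.55) * cfg.background_level
        rr, cc = draw_ellipse(cy, cx, a_px, max(a_px * aspect, 0.8),
                              shape=(rows, cols), rotation=theta)
        img[rr, cc] = np.minimum(img[rr, cc], gray)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    px = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayFrame(px, time_s=time_s, temperature_C=temperature_C)


def _k_ext(cfg: ExperimentConfig) -> float:
    # calibrated so transmission is still (just) above 99.9% at the
    # blind-spot density itself: crosses the threshold 1% beyond it
    return math.log(100.0 / 99.9) / (1.01 * cfg.blind_spot_density)


def transmission_model(x_c: float, cfg: ExperimentConfig,
                       rng: np.random.Generator | None = None) -> float:
    """Transmission (%) at density x_c: 100 exp(-k_ext x_c) (+ noise),
    with k_ext set so the signal stays above 99.9% below the blind-spot
    density."""
    if x_c < 0:
        raise ValueError("x_c must be >= 0")
    t = 100.0 * math.exp(-_k_ext(cfg) * x_c)
    if rng is not None and cfg.transmission_noise_sd > 0:
        t += rng.normal(0.0, cfg.transmission_noise_sd)
    return float(min(max(t, 0.0), 100.0))


def _solubility_mg_per_mL(solub: SolubilityModel, T_C: float,
                          cfg: ExperimentConfig) -> float:
    x_gg = x_mol_to_gg(solub.predict_x(T_C), cfg.solvent_ratio)
    return x_gg * cfg.solvent_density * 1000.0


def simulate_experiment(cfg: ExperimentConfig, solub: SolubilityModel,
                        seed: int | None = None,
                        render: bool = True) -> SyntheticExperiment:
    """Integrate the suspension-density trajectory over the temperature
    profile and render the frame sequence.

    Dissolution/growth is a first-order relaxation of x_c toward the
    solubility-implied equilibrium (separate rate constants); nucleation
    during cooling triggers once the supersaturation ratio c/c* reaches
    ``cfg.S_nuc``, defining the cloud-point truth. The clear-point truth
    is the first frame with x_c = 0 during heating (after the last
    nucleation event, when one occurred). ``render=False`` skips the
    imagery (trajectory and transmission only) for trajectory-level tests.
    """
    if not cfg.profile:
        raise ValueError("temperature profile must be nonempty")
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    c_tot = cfg.solute_load * cfg.solvent_density  # mg solute per mL solvent

    phases = list(cfg.profile)
    durations = [p.minutes for p in phases]
    total_min = sum(durations)
    frame_dt_s = 1.0 / cfg.fps
    n_frames = int(total_min * 60.0 / frame_dt_s) + 1

    def temperature_at(t_min: float) -> float:
        rem = t_min
        for p, d in zip(phases, durations):
            if rem <= d or p is phases[-1]:
                return p.temperature(rem)
            rem -= d
        return phases[-1].temperature(durations[-1])

    # integrate with substeps no longer than 6 s
    sub = max(1, int(math.ceil(frame_dt_s / 6.0)))
    dt_min = frame_dt_s / 60.0 / sub

    T0 = temperature_at(0.0)
    c_star0 = _solubility_mg_per_mL(solub, T0, cfg)
    c = min(c_tot, c_star0)          # dissolved, mg/mL
    x_c = c_tot - c                  # suspended, mg/mL
    nucleated = x_c > 0

    times_s = np.arange(n_frames) * frame_dt_s
    temps = np.empty(n_frames)
    xs = np.empty(n_frames)
    clear_truth = None
    cloud_truth = None
    last_cloud = None
    prev_x = x_c
    t_min = 0.0
    for i in range(n_frames):
        T = temperature_at(t_min)
        temps[i] = T
        xs[i] = x_c
        heating = temperature_at(t_min + dt_min) > T + 1e-12
        if prev_x > 0 and x_c == 0 and heating and (clear_truth is None or
                                                    last_cloud is not None):
            clear_truth = (float(times_s[i]), float(T))
            if last_cloud is not None:
                cloud_truth = last_cloud
            last_cloud = None
        prev_x = x_c
        # advance to the next frame
        for _ in range(sub):
            Ts = temperature_at(t_min)
            c_star = _solubility_mg_per_mL(solub, Ts, cfg)
            if not nucleated and x_c == 0 and c_star > 0 and c / c_star >= cfg.S_nuc:
                nucleated = True
                x_c = 1e-6 * c_tot   # seed crystal mass
                c = c_tot - x_c
                if last_cloud is None:
                    last_cloud = (float(t_min * 60.0), float(Ts))
            if x_c > 0 or (nucleated and c > c_star):
                k = cfg.k_diss if c < c_star else cfg.k_grow
                x_new = x_c - k * (c_star - c) * dt_min
                x_c = float(np.clip(x_new, 0.0, c_tot))
                c = c_tot - x_c
                if x_c == 0:
                    nucleated = False
            t_min += dt_min

    if cloud_truth is None and last_cloud is not None:
        cloud_truth = last_cloud

    frames = []
    trans = np.empty(n_frames)
    for i in range(n_frames):
        rng = cfg.frame_rng(i)
        trans[i] = transmission_model(xs[i], cfg, rng)
        if render:
            frames.append(render_frame(xs[i], cfg, rng, time_s=float(times_s[i]),
                                       temperature_C=float(temps[i])))
        else:
            frames.append(GrayFrame(np.zeros((3, 3), dtype=np.uint8),
                                    time_s=float(times_s[i]),
                                    temperature_C=float(temps[i])))
    return SyntheticExperiment(config=cfg, frames=frames, transmission=trans,
                               x_c_truth=xs, clear_point_truth=clear_truth,
                               cloud_point_truth=cloud_truth,
                               solubility_truth=solub)
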