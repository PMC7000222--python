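"""Seeded synthetic scenes with known ground truth.

The generator emulates single-cell sensitized-emission FRET time-lapse
acquisition: an adherent, star-convex cell footprint that deforms over time,
a membrane-proximal angular hotspot of biosensor activity that pulses with a
configurable period, donor quenching with spectral bleed-through, and
photon-counting-like noise.  The defaults mirror typical confocal acquisition
for this class of experiment: 0.2 µm/pixel, 2 frames/min, bleed-through
slopes 0.55 (donor) and 0.028 (acceptor), and a 3.5 min activity pulse
period.

Rendering model (all "true" fields are noise-free, per pixel, per frame):

    E(x, t)                 true FRET fraction in [0, 1)
    donor_true      = D * (1 - E)        quenched donor emission
    sensitized_true = D * E              acceptor emission due to FRET
    acceptor_true   = A                  directly excited acceptor
    Dex-Aem channel = sensitized_true + alpha_d*donor_true + alpha_a*acceptor_true

with D = ``donor_expression`` and A = ``acceptor_expression`` inside the
cell, zero outside.  Noise (Gaussian with variance ``gain``·signal plus
constant read noise, approximating Poisson statistics) is applied last, so a
zero-noise scene round-trips exactly through the bleed-through correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .fret import FRETFrameSet

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "APBPair",
    "BindingData",
    "generate_scene",
    "generate_apb_pair",
    "generate_binding_curve",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic biosensor scene.

    Activity levels are dimensionless FRET fractions; the configuration is
    rejected if the pulsed maximum (baseline + hotspot·amplitude + drift)
    can reach 1.
    """

    image_shape: tuple[int, int] = (96, 96)
    n_frames: int = 50
    pixel_size_um: float = 0.2
    frame_interval_min: float = 0.5           # 2 frames/min
    cell_radius_px: float = 30.0
    shape_harmonics: tuple = ((3, 0.08, 0.0), (5, 0.04, 1.1))
    boundary_motility_amp_px: float = 0.8
    hotspot_angle_deg: float = 45.0
    hotspot_angular_width_deg: float = 80.0
    hotspot_edge_depth_px: float = 8.0
    baseline_activity: float = 0.05
    hotspot_activity: float = 0.30
    pulse_period_min: float = 3.5
    pulse_amplitude: float = 1.0
    pulse_shape: str = "raised-cosine"        # or "sinusoid" / "constant"
    drift_quadratic_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    donor_expression: float = 100.0
    acceptor_expression: float = 120.0
    alpha_d: float = 0.55
    alpha_a: float = 0.028
    gauss_noise_sd: float = 1.0
    poisson_like: bool = True
    detector_gain: float = 1.0
    motility_activity_coupling: float = 0.0   # κ<0: activity suppresses motion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or min(self.image_shape) < 8:
            raise ConfigError("scene must have ≥1 frame and ≥8 px per side")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ConfigError("pixel size and frame interval must be positive")
        if not (0 <= self.baseline_activity < 1 and 0 <= self.hotspot_activity < 1):
            raise ConfigError("activity levels must lie in [0, 1)")
        if self.pulse_period_min <= 2 * self.frame_interval_min:
            raise ConfigError("pulse period must exceed twice the frame interval")
        if self.pulse_shape not in ("raised-cosine", "sinusoid", "constant"):
            raise ConfigError(f"unknown pulse shape {self.pulse_shape!r}")
        if self.donor_expression < 0 or self.acceptor_expression < 0:
            raise ConfigError("expression levels must be non-negative")
        if not (0 <= self.alpha_d < 1 and 0 <= self.alpha_a < 1):
            raise ConfigError("bleed-through slopes must lie in [0, 1)")
        t = np.arange(self.n_frames) * self.frame_interval_min
        c0, c1, c2 = self.drift_quadratic_coeffs
        drift_max = float(np.max(c0 + c1 * t + c2 * t**2, initial=0.0))
        peak = (self.baseline_activity
                + self.hotspot_activity * self.pulse_amplitude + drift_max)
        if peak >= 1:
            raise ConfigError(
                f"pulsed activity peaks at {peak:.3f} ≥ 1; reduce baseline, "
                "hotspot amplitude or drift")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


@dataclass
class SceneTruth:
    """Noise-free ground-truth fields accompanying a generated scene."""

    activity_field: np.ndarray        # T×H×W true FRET fraction E
    mask_truth: np.ndarray            # T×H×W boolean footprint
    sensitized_truth: np.ndarray      # T×H×W donor_expression·E inside mask
    boundary_radius_series: np.ndarray  # T×n_theta radii r(θ, t)
    theta_grid: np.ndarray            # n_theta angles (radians)
    center: tuple[float, float]       # (row, col) of the cell center


@dataclass
class APBPair:
    """Pre/post acceptor-photobleaching frame pair with the bleach map."""

    pre: FRETFrameSet
    post: FRETFrameSet
    bleach_fraction_map: np.ndarray
    dose_label: str = ""
    truth: SceneTruth | None = None


@dataclass
class BindingData:
    """Saturation-binding measurements: ligand concentration vs bound signal."""

    x: np.ndarray                     # concentrations (nM), > 0
    y: np.ndarray                     # bound signal (au), ≥ 0 up to noise
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ConfigError("x and y must have equal length")
        if np.any(self.x <= 0):
            raise ConfigError("concentrations must be positive")


def pulse_waveform(t_min: np.ndarray, period_min: float, shape: str,
                   duty: float = 0.5) -> np.ndarray:
    """Temporal modulation in [0, 1].

    ``raised-cosine``: within each period a half-cosine bump occupying
    ``duty`` of the cycle, zero elsewhere — spectrally richer than a pure
    tone, so spectral tests are non-trivial.  ``sinusoid``:
    0.5·(1 − cos(2πt/P)), exact for on-grid periodogram checks.
    """
    t = np.asarray(t_min, dtype=float)
    if shape == "constant":          # steady hotspot, e.g. for bleaching pairs
        return np.ones_like(t)
    if shape == "sinusoid":
        return 0.5 * (1.0 - np.cos(2 * np.pi * t / period_min))
    phase = np.mod(t, period_min) / period_min
    w = np.where(phase < duty,
                 0.5 * (1.0 - np.cos(2 * np.pi * phase / duty)),
                 0.0)
    return w


def _radius_profile(cfg: SceneConfig, theta: np.ndarray,
                    jitter: np.ndarray) -> np.ndarray:
    """r(θ) = r0·(1 + Σ a_k sin(kθ + φ_k)) + jitter(θ)."""
    r = np.ones_like(theta)
    for order, amp, phase in cfg.shape_harmonics:
        r = r + amp * np.sin(order * theta + phase)
    return cfg.cell_radius_px * r + jitter


def _frame_jitter(cfg: SceneConfig, rng: np.random.Generator,
                  theta: np.ndarray, hot_weight: np.ndarray) -> np.ndarray:
    """Smooth random radial jitter; amplitude modulated by hotspot activity
    when ``motility_activity_coupling`` κ ≠ 0 (κ<0 suppresses motion where
    activity is high)."""
    if cfg.boundary_motility_amp_px == 0:
        return np.zeros_like(theta)
    jit = np.zeros_like(theta)
    for k in range(1, 5):
        a, phi = rng.normal(0.0, 1.0), rng.uniform(0, 2 * np.pi)
        jit += a * np.sin(k * theta + phi)
    jit *= cfg.boundary_motility_amp_px / 2.0
    scale = 1.0 + cfg.motility_activity_coupling * hot_weight
    return jit * np.clip(scale, 0.0, None)


def _angular_weight(cfg: SceneConfig, theta: np.ndarray) -> np.ndarray:
    """1 inside the hotspot's angular window, 0 outside (wrap-aware)."""
    d = np.angle(np.exp(1j * (theta - math.radians(cfg.hotspot_angle_deg))))
    return (np.abs(d) <= math.radians(cfg.hotspot_angular_width_deg) / 2).astype(float)


def generate_scene(config: SceneConfig) -> tuple[FRETFrameSet, SceneTruth]:
    """Render a three-channel time-lapse plus its ground truth.

    Deterministic given ``config.seed``: two calls with the same config are
    bit-identical.  See the module docstring for the rendering model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    rho = np.hypot(rows, cols)
    theta_px = np.arctan2(rows, cols)

    n_theta = 720
    theta_grid = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    t_min = cfg.times_min
    pulse = cfg.pulse_amplitude * pulse_waveform(t_min, cfg.pulse_period_min,
                                                cfg.pulse_shape)
    c0, c1, c2 = cfg.drift_quadratic_coeffs
    drift = c0 + c1 * t_min + c2 * t_min**2
    hot_theta = _angular_weight(cfg, theta_grid)

    T = cfg.n_frames
    activity = np.zeros((T, h, w))
    mask = np.zeros((T, h, w), dtype=bool)
    radii = np.zeros((T, n_theta))
    hot_px_weight = _angular_weight(cfg, theta_px)

    for t in range(T):
        jitter = _frame_jitter(cfg, rng, theta_grid, hot_theta * pulse[t])
        r_theta = _radius_profile(cfg, theta_grid, jitter)
        radii[t] = r_theta
        # star-convex footprint: pixel inside iff rho <= r(θ_pixel)
        r_at_px = np.interp(theta_px.ravel(), theta_grid, r_theta,
                            period=2 * np.pi).reshape(h, w)
        m = rho <= r_at_px
        mask[t] = m
        edge_depth = r_at_px - rho                      # distance inward from edge
        hot = (hot_px_weight > 0) & (edge_depth <= cfg.hotspot_edge_depth_px) & m
        e = np.where(m, cfg.baseline_activity + drift[t], 0.0)
        e = e + np.where(hot, cfg.hotspot_activity * pulse[t], 0.0)
        activity[t] = np.where(m, e, 0.0)

    donor_true = cfg.donor_expression * (1.0 - activity) * mask
    sensitized_true = cfg.donor_expression * activity
    acceptor_true = cfg.acceptor_expression * mask.astype(float)
    fret_chan = (sensitized_true + cfg.alpha_d * donor_true
                 + cfg.alpha_a * acceptor_true)

    donor = _apply_noise(donor_true, cfg, rng)
    fret = _apply_noise(fret_chan, cfg, rng)
    acceptor = _apply_noise(acceptor_true, cfg, rng)

    frames = FRETFrameSet(donor=donor, fret=fret, acceptor=acceptor,
                          pixel_size_um=cfg.pixel_size_um,
                          frame_interval_min=cfg.frame_interval_min)
    truth = SceneTruth(activity_field=activity, mask_truth=mask,
                       sensitized_truth=sensitized_true,
                       boundary_radius_series=radii, theta_grid=theta_grid,
                       center=center)
    return frames, truth


def _apply_noise(signal: np.ndarray, cfg: SceneConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with variance gain·signal (Poisson-like shot noise)
    plus constant read noise ``gauss_noise_sd``; clipped at zero."""
    out = signal.astype(float).copy()
    var = np.zeros_like(out)
    if cfg.poisson_like and cfg.detector_gain > 0:
        var += cfg.detector_gain * np.clip(signal, 0, None)
    if cfg.gauss_noise_sd > 0:
        var += cfg.gauss_noise_sd**2
    if np.any(var > 0):
        out = out + rng.normal(0.0, 1.0, size=out.shape) * np.sqrt(var)
        out = np.clip(out, 0.0, None)
    return out


def noise_free(config: SceneConfig) -> SceneConfig:
    """Copy of ``config`` with all noise sources disabled."""
    return replace(config, gauss_noise_sd=0.0, poisson_like=False)


def generate_apb_pair(
    config: SceneConfig,
    bleach_profile: np.ndarray | float = 1.0,
    dose_label: str = "",
) -> APBPair:
    """Pre/post acceptor-photobleaching single-frame pair.

    Bleaching destroys a fraction ``b`` of acceptor per pixel.  FRET sites
    whose acceptor is gone revert to plain donor emission, so

        post_donor    = donor_true + b · sensitized_true
        post_acceptor = (1 − b) · acceptor_true

    which gives the closed-form per-pixel recovery

        recovery% = 100·(1 − pre/post) = 100·b·E / (1 − E + b·E)

    reducing to 100·E at complete bleaching (b = 1).  Noise, if enabled in
    ``config``, is applied independently to pre and post frames.
    """
    cfg = replace(config, n_frames=1)
    b = np.broadcast_to(np.asarray(bleach_profile, dtype=float),
                        cfg.image_shape).copy()
    if np.any((b < 0) | (b > 1)):
        raise ConfigError("bleach fractions must lie in [0, 1]")

    rng = np.random.default_rng(cfg.seed)
    frames_nf, truth = generate_scene(noise_free(cfg))
    donor_pre = frames_nf.donor[0]
    acceptor_pre = frames_nf.acceptor[0]
    fret_pre = frames_nf.fret[0]
    sensitized = truth.sensitized_truth[0]

    donor_post = donor_pre + b * sensitized
    acceptor_post = (1.0 - b) * acceptor_pre
    # sensitized emission that survives bleaching, with bleed-through re-applied
    sensitized_post = (1.0 - b) * sensitized
    fret_post = (sensitized_post + cfg.alpha_d * donor_post
                 + cfg.alpha_a * acceptor_post)

    def pack(d, f, a):
        return FRETFrameSet(donor=_apply_noise(d, cfg, rng),
                            fret=_apply_noise(f, cfg, rng),
                            acceptor=_apply_noise(a, cfg, rng),
                            pixel_size_um=cfg.pixel_size_um,
                            frame_interval_min=cfg.frame_interval_min)

    return APBPair(pre=pack(donor_pre, fret_pre, acceptor_pre),
                   post=pack(donor_post, fret_post, acceptor_post),
                   bleach_fraction_map=b, dose_label=dose_label, truth=truth)


def generate_binding_curve(
    bmax: float,
    kd: float,
    x: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    relative_noise: bool = False,
) -> BindingData:
    """One-site saturation binding data: Y = Bmax·X/(Kd + X) + noise.

    The default design replicates a typical pulldown titration
    (75, 150, 300, 600, 1250 nM).  With ``relative_noise`` the Gaussian
    noise is multiplicative: sd = noise_sd · Y(x) per point, the usual
    error structure of quantified band intensities.
    """
    if bmax <= 0 or kd <= 0:
        raise ConfigError("bmax and kd must be positive")
    if x is None:
        x = np.array([75.0, 150.0, 300.0, 600.0, 1250.0])
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    xs, ys, reps = [], [], []
    for rep in range(n_replicates):
        y = bmax * x / (kd + x)
        if noise_sd > 0:
            sd = noise_sd * y if relative_noise else noise_sd
            y = y + rng.normal(0.0, 1.0, size=y.shape) * sd
        xs.append(x)
        ys.append(np.clip(y, 0.0, None))
        reps.append(np.full(x.shape, rep))
    return BindingData(x=np.concatenate(xs), y=np.concatenate(ys),
                       replicate=np.concatenate(reps))
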