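"""Sensitized-emission FRET quantification.

The FRET-index ("FRET_T") image is the bleed-through-corrected FRET channel

    FRET_T = I_FRET - alpha_D * I_Donor - alpha_A * I_Acceptor

where ``alpha_D`` is the slope of donor emission leaking into the FRET
detection band and ``alpha_A`` the slope of direct acceptor excitation by the
donor laser, both measured on single-label calibration samples.  This module
implements that correction, the calibration-slope estimators, donor-normalized
FRET, spectral FRET efficiency Fa/(Fa+Fd), and the optional 8-bit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, DataError

__all__ = [
    "FRETFrameSet",
    "BleedThroughCoefficients",
    "SpectralIntensities",
    "estimate_bleedthrough",
    "compute_fret_index",
    "donor_normalized_fret",
    "fret_efficiency",
    "to_8bit",
]


def _as_stack(values: np.ndarray) -> np.ndarray:
    """Coerce 2-D frames to a 1-frame stack; validate finiteness lazily."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError(f"expected a T×H×W stack, got shape {arr.shape}")
    return arr


@dataclass
class FRETFrameSet:
    """Aligned three-channel time-lapse.

    Channels follow the donor-excitation naming convention:
    ``donor`` = Dex-Dem, ``fret`` = Dex-Aem (raw sensitized emission),
    ``acceptor`` = Aex-Aem.  All three share shape (T, H, W).
    """

    donor: np.ndarray
    fret: np.ndarray
    acceptor: np.ndarray
    pixel_size_um: float = 0.2
    frame_interval_min: float = 0.5

    def __post_init__(self) -> None:
        self.donor = _as_stack(self.donor)
        self.fret = _as_stack(self.fret)
        self.acceptor = _as_stack(self.acceptor)
        if not (self.donor.shape == self.fret.shape == self.acceptor.shape):
            raise DataError(
                "channel shapes differ: "
                f"{self.donor.shape}, {self.fret.shape}, {self.acceptor.shape}"
            )
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise DataError("pixel size and frame interval must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.donor.shape

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]


@dataclass(frozen=True)
class BleedThroughCoefficients:
    """Crosstalk slopes: donor emission into the FRET band (``alpha_d``)
    and direct acceptor excitation by the donor laser (``alpha_a``)."""

    alpha_d: float = 0.55
    alpha_a: float = 0.028

    def __post_init__(self) -> None:
        for name, a in (("alpha_d", self.alpha_d), ("alpha_a", self.alpha_a)):
            if not 0.0 <= a < 1.0:
                raise DataError(f"{name} must lie in [0, 1), got {a}")


@dataclass(frozen=True)
class SpectralIntensities:
    """Raw acceptor (Fa) and donor (Fd) emissions for spectral efficiency."""

    fa: float
    fd: float

    def __post_init__(self) -> None:
        if self.fa < 0 or self.fd < 0:
            raise DataError("spectral intensities must be non-negative")


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        raise CalibrationError("zero-variance predictor: cannot fit a slope")
    return float(np.dot(x, y) / sxx)


def estimate_bleedthrough(single_label_set, which: str, mask=None) -> float:
    """Estimate a bleed-through slope from a single-fluorophore sample.

    Parameters
    ----------
    single_label_set:
        ``FRETFrameSet`` from a donor-only or acceptor-only cell, or a list of
        such sets (one per cell); per-cell slopes are averaged.
    which:
        ``"donor"`` regresses Dex-Aem on Dex-Dem (gives ``alpha_d``);
        ``"acceptor"`` regresses Dex-Aem on Aex-Aem (gives ``alpha_a``).
    mask:
        Optional ``CellMaskStack`` (or boolean T×H×W array) restricting the
        regression to cell pixels.  ``None`` pools all pixels.

    Returns the least-squares slope through the origin pooled over mask
    pixels and frames; with several cells, the mean of per-cell slopes.
    """
    if which not in ("donor", "acceptor"):
        raise ValueError("which must be 'donor' or 'acceptor'")
    if isinstance(single_label_set, (list, tuple)):
        slopes = [estimate_bleedthrough(s, which, m)
                  for s, m in zip(single_label_set,
                                  mask if isinstance(mask, (list, tuple))
                                  else [mask] * len(single_label_set))]
        return float(np.mean(slopes))

    frames = single_label_set
    x = frames.donor if which == "donor" else frames.acceptor
    y = frames.fret
    if mask is not None:
        m = np.asarray(getattr(mask, "masks", mask), dtype=bool)
        if m.shape != x.shape:
            raise DataError(f"mask shape {m.shape} != stack shape {x.shape}")
        if not m.any():
            raise CalibrationError("empty mask: no pixels to calibrate on")
        x, y = x[m], y[m]
    return _slope_through_origin(np.ravel(x), np.ravel(y))


def _median_2x2(frame: np.ndarray) -> np.ndarray:
    """Median over the 2×2 block anchored at each pixel's top-left corner.

    Even-sized kernels have no central pixel; the block covers rows r..r+1
    and columns c..c+1 with edge replication on the far border.
    """
    padded = np.pad(frame, ((0, 1), (0, 1)), mode="edge")
    blocks = np.stack([
        padded[:-1, :-1], padded[:-1, 1:], padded[1:, :-1], padded[1:, 1:],
    ])
    return np.median(blocks, axis=0)


def compute_fret_index(
    frames: FRETFrameSet,
    coeffs: BleedThroughCoefficients | None = None,
    median_filter: bool = False,
) -> np.ndarray:
    """Bleed-through-corrected FRET index (FRET_T) stack.

    Pixel-wise ``fret - alpha_d*donor - alpha_a*acceptor``; when
    ``median_filter`` is set, each frame is then median-filtered with a 2×2
    block (top-left anchor, see :func:`_median_2x2`).  Negative values are
    preserved in the float output — over-subtraction is informative — and are
    clipped only on explicit uint8 export via :func:`to_8bit`.
    """
    if coeffs is None:
        coeffs = BleedThroughCoefficients()
    out = frames.fret - coeffs.alpha_d * frames.donor - coeffs.alpha_a * frames.acceptor
    if median_filter:
        out = np.stack([_median_2x2(f) for f in out])
    return out


def donor_normalized_fret(
    fret_index: np.ndarray,
    donor: np.ndarray,
    mask: np.ndarray | None = None,
    floor: float = 1e-6,
) -> np.ndarray:
    """FRET_T divided by donor fluorescence, pixel-wise inside the mask.

    Normalizes activity for sensor expression level.  Pixels outside the mask
    or with donor below ``floor`` are NaN (undefined, excluded from means
    downstream) rather than zero.
    """
    if floor <= 0:
        raise DataError("floor must be positive")
    fret_index = np.asarray(fret_index, dtype=float)
    donor = np.asarray(donor, dtype=float)
    if fret_index.shape != donor.shape:
        raise DataError("fret_index and donor shapes differ")
    valid = donor >= floor
    if mask is not None:
        m = np.asarray(getattr(mask, "masks", mask), dtype=bool)
        valid &= m
    out = np.full(fret_index.shape, np.nan)
    out[valid] = fret_index[valid] / donor[valid]
    return out


def fret_efficiency(s: SpectralIntensities) -> float:
    """Spectral FRET efficiency Fa/(Fa+Fd), in [0, 1]."""
    total = s.fa + s.fd
    if total <= 0:
        raise DataError("Fa + Fd must be positive for a defined efficiency")
    return s.fa / total


def to_8bit(
    stack: np.ndarray,
    mode: str = "global-minmax",
    lo: float | None = None,
    hi: float | None = None,
) -> np.ndarray:
    """Affine conversion to uint8 with round-half-up.

    ``global-minmax`` maps the stack's global [min, max] to [0, 255]; a
    constant stack maps to all zeros (degenerate range).  ``fixed-range``
    maps [lo, hi] to [0, 255], clipping outside.
    """
    arr = np.asarray(stack, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("stack contains non-finite values")
    if mode == "global-minmax":
        lo_, hi_ = float(arr.min()), float(arr.max())
        if hi_ == lo_:
            return np.zeros(arr.shape, dtype=np.uint8)
    elif mode == "fixed-range":
        if lo is None or hi is None or hi <= lo:
            raise DataError("fixed-range mode needs lo < hi")
        lo_, hi_ = float(lo), float(hi)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scaled = (arr - lo_) * (255.0 / (hi_ - lo_))
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
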