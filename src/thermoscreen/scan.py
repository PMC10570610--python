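"""Scan-domain types and signal extraction.

A dynamic-thermography scan heats the tissue with an LED for a fixed time and
records the temperature field with a long-wave infrared camera while the
tissue heats and then relaxes back to baseline.  This module defines the scan
protocol, the camera model, the per-pixel frame stack (:class:`ThermalScan`),
circular regions of interest, and the per-site mean-temperature time series
(:class:`TemperatureCurve`) every downstream stage consumes.  It also
implements flat-field correction and baseline/heating/cooling phase
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GeometryError, ProtocolError, QualityError

PHASE_BASELINE = "baseline"
PHASE_HEATING = "heating"
PHASE_COOLING = "cooling"

SITE_MASS = "mass"
SITE_HEALTHY = "healthy"


@dataclass(frozen=True)
class ScanProtocol:
    """Timing of a heat-cool scan.

    The default mirrors the clinical protocol: a 50 s probe contact with 10 s
    of LED heating followed by 40 s of passive cooling, preceded by a short
    pre-illumination baseline.  Frame rate is a device constant; 10 Hz puts
    frame 100 of the heating phase at the 10 s heating boundary.

    Parameters
    ----------
    heat_duration, cool_duration : float
        Phase lengths in seconds.
    frame_rate : float
        Frames per second.
    baseline_frames : int
        Frames captured before LED onset (>= 1).
    """

    heat_duration: float = 10.0
    cool_duration: float = 40.0
    frame_rate: float = 10.0
    baseline_frames: int = 5

    def __post_init__(self) -> None:
        if self.heat_duration <= 0:
            raise ProtocolError("heat_duration must be > 0")
        if self.cool_duration <= 0:
            raise ProtocolError("cool_duration must be > 0")
        if self.frame_rate <= 0:
            raise ProtocolError("frame_rate must be > 0")
        if self.baseline_frames < 1:
            raise ProtocolError("baseline_frames must be >= 1")

    @property
    def n_heating(self) -> int:
        return int(round(self.frame_rate * self.heat_duration))

    @property
    def n_cooling(self) -> int:
        return int(round(self.frame_rate * self.cool_duration))

    @property
    def n_frames(self) -> int:
        return self.baseline_frames + self.n_heating + self.n_cooling

    def timestamps(self) -> np.ndarray:
        """Frame times in seconds from the first (baseline) frame."""
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def led_onset(self) -> float:
        """Time of the first heating frame (seconds from first frame)."""
        return self.baseline_frames / self.frame_rate

    def phase_labels(self) -> np.ndarray:
        labels = np.empty(self.n_frames, dtype=object)
        labels[: self.baseline_frames] = PHASE_BASELINE
        labels[self.baseline_frames : self.baseline_frames + self.n_heating] = PHASE_HEATING
        labels[self.baseline_frames + self.n_heating :] = PHASE_COOLING
        return labels

    def to_dict(self) -> dict:
        return {
            "heat_duration": self.heat_duration,
            "cool_duration": self.cool_duration,
            "frame_rate": self.frame_rate,
            "baseline_frames": self.baseline_frames,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        return cls(**d)


@dataclass(frozen=True)
class CameraModel:
    """Uncooled LWIR microbolometer model.

    Default geometry is a 160 x 120 focal-plane array (19,200 pixels) with
    noise-equivalent temperature difference below 50 mK, a 6.5 x 4 cm field
    of view, and the FPA stabilised at 35 degC.  ``fixed_pattern`` is the
    per-pixel offset map (kelvin) that flat-field correction removes.
    """

    height: int = 120
    width: int = 160
    noise_sd: float = 0.05
    fixed_pattern: Optional[np.ndarray] = None
    fov_width_cm: float = 6.5
    fov_height_cm: float = 4.0
    fpa_temp: float = 35.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ProtocolError("camera must have positive dimensions")
        if self.noise_sd < 0:
            raise ProtocolError("noise_sd must be >= 0")
        if self.fixed_pattern is not None:
            fp = np.asarray(self.fixed_pattern, dtype=float)
            if fp.shape != (self.height, self.width):
                raise ProtocolError(
                    f"fixed_pattern shape {fp.shape} != ({self.height}, {self.width})"
                )
            object.__setattr__(self, "fixed_pattern", fp)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def pattern(self) -> np.ndarray:
        if self.fixed_pattern is None:
            return np.zeros((self.height, self.width))
        return self.fixed_pattern

    def to_dict(self) -> dict:
        return {
            "height": self.height,
            "width": self.width,
            "noise_sd": self.noise_sd,
            "fov_width_cm": self.fov_width_cm,
            "fov_height_cm": self.fov_height_cm,
            "fpa_temp": self.fpa_temp,
        }


def default_fixed_pattern(camera: CameraModel, sd: float = 0.1, seed: int = 0) -> np.ndarray:
    """Gaussian per-pixel offset map (kelvin), reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sd, size=(camera.height, camera.width))


@dataclass(frozen=True)
class ROI:
    """Circular region of interest in 0-based pixel coordinates.

    A pixel (px, py) belongs to the ROI when its center lies within the
    circle: (px - cx)^2 + (py - cy)^2 <= r^2.  x runs rightward, y downward.
    """

    center_x: float
    center_y: float
    radius: float
    site: str = SITE_MASS

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise GeometryError("ROI radius must be >= 1 pixel")

    def mask(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        return (xx - self.center_x) ** 2 + (yy - self.center_y) ** 2 <= self.radius**2

    def n_pixels(self, height: int, width: int) -> int:
        return int(self.mask(height, width).sum())

    def inside(self, height: int, width: int) -> bool:
        return (
            self.center_x - self.radius >= -0.5
            and self.center_y - self.radius >= -0.5
            and self.center_x + self.radius <= width - 0.5
            and self.center_y + self.radius <= height - 0.5
        )

    def overlaps(self, other: "ROI") -> bool:
        d2 = (self.center_x - other.center_x) ** 2 + (self.center_y - other.center_y) ** 2
        return d2 < (self.radius + other.radius) ** 2

    def to_string(self) -> str:
        return f"{self.center_x:g},{self.center_y:g},{self.radius:g}"

    @classmethod
    def from_string(cls, s: str, site: str = SITE_MASS) -> "ROI":
        cx, cy, r = (float(v) for v in s.split(","))
        return cls(cx, cy, r, site=site)


@dataclass
class TemperatureCurve:
    """Per-site mean temperature time series with phase labels.

    ``values`` are degrees Celsius per frame; ``phase`` labels each frame as
    baseline, heating, or cooling (in that order).  The basal temperature is
    estimated as the median over baseline frames, which is robust to a single
    noisy frame.
    """

    values: np.ndarray
    timestamps: np.ndarray
    phase: np.ndarray
    site: str = SITE_MASS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.values) == len(self.timestamps) == len(self.phase)):
            raise ProtocolError("values, timestamps, phase must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def _select(self, phase: str) -> np.ndarray:
        return self.phase == phase

    def baseline_temp(self) -> float:
        sel = self._select(PHASE_BASELINE)
        if not sel.any():
            raise QualityError("curve has no baseline frames")
        return float(np.median(self.values[sel]))

    def phase_values(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self._select(phase)
        return self.timestamps[sel], self.values[sel]

    def cooling_onset_time(self) -> float:
        """Time of the first cooling frame (= end of heating)."""
        t, _ = self.phase_values(PHASE_COOLING)
        if len(t) == 0:
            raise ProtocolError("curve has no cooling frames")
        return float(t[0])

    def with_site(self, site: str) -> "TemperatureCurve":
        return TemperatureCurve(self.values, self.timestamps, self.phase, site=site)

    def copy(self) -> "TemperatureCurve":
        return TemperatureCurve(
            self.values.copy(), self.timestamps.copy(), self.phase.copy(), site=self.site
        )


@dataclass
class ThermalScan:
    """Time-ordered stack of per-pixel temperature maps (degC)."""

    frames: np.ndarray  # (n_frames, height, width)
    timestamps: np.ndarray
    protocol: ScanProtocol
    camera: CameraModel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ProtocolError("frames must be a (n_frames, height, width) stack")
        if self.frames.shape[0] != self.protocol.n_frames:
            raise ProtocolError(
                f"frame count {self.frames.shape[0]} != protocol {self.protocol.n_frames}"
            )
        if len(self.timestamps) != self.frames.shape[0]:
            raise ProtocolError("timestamps length != frame count")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ProtocolError("timestamps must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def flat_field_correct(scan: ThermalScan, reference: np.ndarray) -> ThermalScan:
    """Remove fixed-pattern offsets using a uniform-scene reference frame.

    Subtracts ``reference - spatial_mean(reference)`` from every frame, so the
    per-frame spatial mean is preserved while per-pixel offsets cancel.  With
    a spatially flat reference this is the identity, and the operation is
    idempotent on noiseless scans.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != scan.frames.shape[1:]:
        raise GeometryError(
            f"reference shape {reference.shape} != frame shape {scan.frames.shape[1:]}"
        )
    offset = reference - reference.mean()
    return ThermalScan(
        frames=scan.frames - offset[None, :, :],
        timestamps=scan.timestamps.copy(),
        protocol=scan.protocol,
        camera=scan.camera,
    )


def extract_curve(scan: ThermalScan, roi: ROI) -> TemperatureCurve:
    """ROI-mean temperature per frame, with phase labels from the protocol."""
    height, width = scan.shape
    if not roi.inside(height, width):
        raise GeometryError(f"ROI {roi.to_string()} not fully inside {width}x{height} frame")
    mask = roi.mask(height, width)
    if not mask.any():
        raise GeometryError("ROI contains no pixel centers")
    values = scan.frames[:, mask].mean(axis=1)
    return TemperatureCurve(
        values=values,
        timestamps=scan.timestamps.copy(),
        phase=scan.protocol.phase_labels(),
        site=roi.site,
    )


def segment_phases(curve: TemperatureCurve, protocol: ScanProtocol) -> TemperatureCurve:
    """Label frames baseline -> heating -> cooling from protocol timing.

    The first ``baseline_frames`` frames are baseline, the next
    ``round(frame_rate * heat_duration)`` heating, and the remainder cooling.
    """
    if len(curve) != protocol.n_frames:
        raise ProtocolError(
            f"curve length {len(curve)} does not match protocol ({protocol.n_frames} frames)"
        )
    if protocol.n_heating == 0:
        raise ProtocolError("heating phase must be non-empty")
    return TemperatureCurve(
        values=curve.values,
        timestamps=curve.timestamps,
        phase=protocol.phase_labels(),
        site=curve.site,
    )


# re-exported for convenience
__all__ = [
    "ScanProtocol",
    "CameraModel",
    "ROI",
    "TemperatureCurve",
    "ThermalScan",
    "flat_field_correct",
    "extract_curve",
    "segment_phases",
    "default_fixed_pattern",
    "PHASE_BASELINE",
    "PHASE_HEATING",
    "PHASE_COOLING",
    "SITE_MASS",
    "SITE_HEALTHY",
]
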