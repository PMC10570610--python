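"""Synthetic heat-cool scans and whole screening cohorts.

The tissue response to LED heating is modelled as lumped two-phase Newton
heating/cooling of the ROI-mean temperature: during illumination the tissue
approaches ``baseline + gain`` with rate ``heat_rate``; after the LED turns
off the accumulated rise relaxes exponentially with rate ``cool_rate``.  The
rates summarise perfusion and tissue composition — malignant tissue, being
highly perfused, sheds heat faster than adjacent healthy skin, while lipomas
(poorly conducting fat) heat up less but cool normally.  These qualitative
signatures drive the default tissue class library.

Cohorts are generated with *exact* class counts (not Bernoulli draws) so that
bookkeeping invariants hold deterministically, and all randomness fans out
from one seed via :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np

from .errors import ConfigurationError, GeometryError, ProtocolError
from .scan import (
    SITE_HEALTHY,
    SITE_MASS,
    CameraModel,
    ROI,
    ScanProtocol,
    TemperatureCurve,
    ThermalScan,
)

BENIGN = "benign"
MALIGNANT = "malignant"
NONDIAGNOSTIC = "nondiagnostic"
ABSENT = "absent"


# ---------------------------------------------------------------------------
# Tissue thermal model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueThermalParams:
    """Lumped thermal parameters of one site.

    baseline_temp : degC resting skin temperature.
    gain : kelvin asymptotic rise under sustained illumination.
    heat_rate : 1/s inverse heating time constant.
    cool_rate : 1/s exponential cooling decay constant.
    """

    baseline_temp: float
    gain: float
    heat_rate: float
    cool_rate: float

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ProtocolError("gain must be >= 0")
        if self.gain > 0 and self.heat_rate <= 0:
            raise ProtocolError("heat_rate must be > 0 when gain > 0")
        if self.cool_rate < 0:
            raise ProtocolError("cool_rate must be >= 0")


def thermal_response(params: TissueThermalParams, protocol: ScanProtocol) -> TemperatureCurve:
    """Noiseless ROI-mean temperature curve for one site.

    T(t) = baseline                                         (pre-LED)
         = baseline + gain*(1 - exp(-heat_rate*t))          (heating, t from onset)
         = baseline + dT_h*exp(-cool_rate*(t - t_heat))     (cooling)

    where dT_h is the rise at the end of heating; the curve is continuous at
    both phase boundaries.
    """
    t = protocol.timestamps()
    t_rel = t - protocol.led_onset  # time since LED onset
    values = np.full(protocol.n_frames, params.baseline_temp, dtype=float)

    labels = protocol.phase_labels()
    heating = labels == "heating"
    cooling = labels == "cooling"
    if params.gain > 0:
        values[heating] += params.gain * (1.0 - np.exp(-params.heat_rate * t_rel[heating]))
        rise_end = params.gain * (1.0 - math.exp(-params.heat_rate * protocol.heat_duration))
        values[cooling] += rise_end * np.exp(
            -params.cool_rate * (t_rel[cooling] - protocol.heat_duration)
        )
    return TemperatureCurve(values=values, timestamps=t, phase=labels)


def render_scan(
    mass_curve: TemperatureCurve,
    healthy_curve: TemperatureCurve,
    camera: CameraModel,
    mass_roi: ROI,
    healthy_roi: ROI,
    seed: int = 0,
) -> ThermalScan:
    """Render two site curves into a full frame stack.

    Pixels inside the mass circle follow ``mass_curve``, inside the healthy
    circle ``healthy_curve``; background pixels sit at the healthy baseline.
    Each pixel gets its fixed-pattern offset plus iid Gaussian noise with
    ``camera.noise_sd`` per frame.  Reproducible given ``seed``.
    """
    if len(mass_curve) != len(healthy_curve):
        raise ProtocolError("mass and healthy curves must share frame count")
    h, w = camera.height, camera.width
    for roi in (mass_roi, healthy_roi):
        if not roi.inside(h, w):
            raise GeometryError(f"ROI {roi.to_string()} out of bounds for {w}x{h} frame")
    if mass_roi.overlaps(healthy_roi):
        raise GeometryError("mass and healthy ROIs overlap")

    n = len(mass_curve)
    background = healthy_curve.baseline_temp()
    frames = np.full((n, h, w), background, dtype=float)
    mmask = mass_roi.mask(h, w)
    hmask = healthy_roi.mask(h, w)
    frames[:, mmask] = mass_curve.values[:, None]
    frames[:, hmask] = healthy_curve.values[:, None]

    frames += camera.pattern()[None, :, :]
    if camera.noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames += rng.normal(0.0, camera.noise_sd, size=frames.shape)
    return ThermalScan(
        frames=frames,
        timestamps=mass_curve.timestamps.copy(),
        protocol=_protocol_from_curve(mass_curve),
        camera=camera,
    )


def _protocol_from_curve(curve: TemperatureCurve) -> ScanProtocol:
    """Reconstruct protocol timing from a labelled curve (frame counts + dt)."""
    dt = float(np.median(np.diff(curve.timestamps)))
    frame_rate = 1.0 / dt
    nb = int((curve.phase == "baseline").sum())
    nh = int((curve.phase == "heating").sum())
    nc = int((curve.phase == "cooling").sum())
    return ScanProtocol(
        heat_duration=nh / frame_rate,
        cool_duration=nc / frame_rate,
        frame_rate=frame_rate,
        baseline_frames=nb,
    )


# ---------------------------------------------------------------------------
# Tissue class library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamPrior:
    """Prior for one thermal parameter: mean plus relative lognormal scatter.

    Draws are ``mean * exp(sigma*z - sigma^2/2)`` with
    ``sigma = sqrt(ln(1 + cv^2))`` so the distribution mean equals ``mean``
    exactly and values stay positive.  ``cv`` is the coefficient of variation
    across patients.
    """

    mean: float
    cv: float = 0.15

    def draw(self, rng: np.random.Generator) -> float:
        if self.mean == 0 or self.cv == 0:
            return self.mean
        sigma = math.sqrt(math.log(1.0 + self.cv**2))
        return self.mean * math.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)


@dataclass(frozen=True)
class SitePriors:
    gain: ParamPrior
    heat_rate: ParamPrior
    cool_rate: ParamPrior

    def draw(self, rng: np.random.Generator, baseline_temp: float) -> TissueThermalParams:
        return TissueThermalParams(
            baseline_temp=baseline_temp,
            gain=self.gain.draw(rng),
            heat_rate=self.heat_rate.draw(rng),
            cool_rate=self.cool_rate.draw(rng),
        )


@dataclass(frozen=True)
class TissueClassEntry:
    """Per tumor-type priors for the mass site and its paired healthy site.

    ``mass_mixture`` optionally replaces the single mass prior with a
    weighted mixture of components, modelling within-type heterogeneity such
    as tumor grade (low-grade mast cell tumors shed heat almost like benign
    tissue).
    """

    mass: SitePriors
    healthy: SitePriors
    malignant: bool
    mass_mixture: Optional[Tuple[Tuple[float, SitePriors], ...]] = None

    def draw_mass(self, rng: np.random.Generator, baseline_temp: float) -> TissueThermalParams:
        if self.mass_mixture:
            weights = np.array([w for w, _ in self.mass_mixture])
            idx = rng.choice(len(weights), p=weights / weights.sum())
            return self.mass_mixture[idx][1].draw(rng, baseline_temp)
        return self.mass.draw(rng, baseline_temp)

    def mean_mass_cool_rate(self) -> float:
        if self.mass_mixture:
            return float(
                sum(w * p.cool_rate.mean for w, p in self.mass_mixture)
                / sum(w for w, _ in self.mass_mixture)
            )
        return self.mass.cool_rate.mean


class TissueClassLibrary:
    """Mapping from tumor-type name to :class:`TissueClassEntry`."""

    def __init__(self, entries: Dict[str, TissueClassEntry]):
        self._entries = dict(entries)

    def __getitem__(self, tumor_type: str) -> TissueClassEntry:
        try:
            return self._entries[tumor_type]
        except KeyError:
            raise ConfigurationError(f"tissue library has no entry for {tumor_type!r}")

    def __contains__(self, tumor_type: str) -> bool:
        return tumor_type in self._entries

    def types(self) -> List[str]:
        return list(self._entries)

    def is_malignant(self, tumor_type: str) -> bool:
        return self[tumor_type].malignant


# Healthy skin archetype: rises ~2.5 K over 10 s (heat_rate 0.35/s reaches
# ~97% of gain by LED-off) and relaxes with rate 0.10/s.
_HEALTHY = SitePriors(
    gain=ParamPrior(2.5), heat_rate=ParamPrior(0.35), cool_rate=ParamPrior(0.10)
)
# Malignant masses: highly perfused, sheds heat markedly faster.
_MALIGNANT_MASS = SitePriors(
    gain=ParamPrior(2.5), heat_rate=ParamPrior(0.35), cool_rate=ParamPrior(0.18)
)
# Generic benign mass: thermally close to healthy skin.
_BENIGN_MASS = SitePriors(
    gain=ParamPrior(2.5), heat_rate=ParamPrior(0.35), cool_rate=ParamPrior(0.10)
)
# Lipoma: fatty, heats up less (60% gain) but cools like healthy tissue.
_LIPOMA_MASS = SitePriors(
    gain=ParamPrior(1.5), heat_rate=ParamPrior(0.35), cool_rate=ParamPrior(0.10)
)
# Cystic / inflamed benign lesions: aberrant heating (lower gain, slower
# heat uptake) with mildly elevated decay — the classic false-positive classes.
_ABERRANT_BENIGN_MASS = SitePriors(
    gain=ParamPrior(1.9), heat_rate=ParamPrior(0.25), cool_rate=ParamPrior(0.11)
)
# Low-grade mast cell tumors: thermally closer to benign tissue; modelled as
# a one-third mixture component of the mast-cell class.
_LOW_GRADE_MCT_MASS = SitePriors(
    gain=ParamPrior(2.5), heat_rate=ParamPrior(0.35), cool_rate=ParamPrior(0.125)
)
_MCT_MIXTURE = ((2.0, _MALIGNANT_MASS), (1.0, _LOW_GRADE_MCT_MASS))

#: Coefficient of variation of the dog-level perfusion factor shared by the
#: mass and healthy sites (scales both cooling rates) — the patient-level
#: effect that differential features exist to cancel.
DOG_PERFUSION_CV = 0.20
#: CV of the dog-level absorption factor shared by both sites (scales gains).
DOG_ABSORPTION_CV = 0.15

_BENIGN_TYPES = {
    "Benign epithelial/adnexal cyst/tumor": _ABERRANT_BENIGN_MASS,
    "Benign melanoma": _BENIGN_MASS,
    "Calcinosis circumscripta": _BENIGN_MASS,
    "Fibroma": _BENIGN_MASS,
    "Hemangioma": _BENIGN_MASS,
    "Histiocytoma": _BENIGN_MASS,
    "Hyperplasia": _BENIGN_MASS,
    "Inflammatory process": _ABERRANT_BENIGN_MASS,
    "Lipoma": _LIPOMA_MASS,
    "Perineal adenoma": _BENIGN_MASS,
    "Scar tissue": _BENIGN_MASS,
    "Sebaceous adenoma": _BENIGN_MASS,
}
_MALIGNANT_TYPES = {
    "Carcinoma": _MALIGNANT_MASS,
    "Malignant melanoma": _MALIGNANT_MASS,
    "Mast cell tumor": _MALIGNANT_MASS,
    "Plasma cell tumor": _MALIGNANT_MASS,
    "Soft tissue sarcoma": _MALIGNANT_MASS,
    "Undifferentiated neoplasia": _MALIGNANT_MASS,
}


def default_library() -> TissueClassLibrary:
    entries: Dict[str, TissueClassEntry] = {}
    for name, mass in _BENIGN_TYPES.items():
        entries[name] = TissueClassEntry(mass=mass, healthy=_HEALTHY, malignant=False)
    for name, mass in _MALIGNANT_TYPES.items():
        mixture = _MCT_MIXTURE if name == "Mast cell tumor" else None
        entries[name] = TissueClassEntry(
            mass=mass, healthy=_HEALTHY, malignant=True, mass_mixture=mixture
        )
    return TissueClassLibrary(entries)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative lognormal factor with the given CV."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return math.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)


def _apply_dog_factors(
    p: TissueThermalParams, perfusion: float, absorption: float
) -> TissueThermalParams:
    return TissueThermalParams(
        baseline_temp=p.baseline_temp,
        gain=p.gain * absorption,
        heat_rate=p.heat_rate,
        cool_rate=p.cool_rate * perfusion,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Composition of a simulated screening cohort.

    ``class_counts`` maps tumor type -> number of masses with a diagnostic
    label; ``nondiagnostic_counts`` maps tumor type -> number of additional
    masses whose cytology is non-diagnostic (they still have an underlying
    tissue class driving the simulation, but no usable label and no
    histopathology).  ``masses_per_dog`` is a distribution over lesions per
    dog used to group masses into dogs; the assignment always sums to
    ``n_masses`` exactly.
    """

    n_dogs: int
    class_counts: Dict[str, int]
    nondiagnostic_counts: Dict[str, int] = field(default_factory=dict)
    masses_per_dog: Dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.2, 3: 0.1, 4: 0.07, 5: 0.02, 6: 0.01}
    )
    histopath_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dogs < 1:
            raise ConfigurationError("n_dogs must be >= 1")
        if any(c < 0 for c in self.class_counts.values()):
            raise ConfigurationError("class counts must be >= 0")
        if any(c < 0 for c in self.nondiagnostic_counts.values()):
            raise ConfigurationError("nondiagnostic counts must be >= 0")
        if not 0 <= self.histopath_fraction <= 1:
            raise ConfigurationError("histopath_fraction must be in [0, 1]")
        if self.n_nondiagnostic >= self.n_masses:
            raise ConfigurationError("n_nondiagnostic must be < n_masses")
        sizes = list(self.masses_per_dog)
        if any(k < 1 for k in sizes) or abs(sum(self.masses_per_dog.values()) - 1) > 1e-9:
            raise ConfigurationError("masses_per_dog must be a distribution over sizes >= 1")

    @property
    def n_diagnostic(self) -> int:
        return sum(self.class_counts.values())

    @property
    def n_nondiagnostic(self) -> int:
        return sum(self.nondiagnostic_counts.values())

    @property
    def n_masses(self) -> int:
        return self.n_diagnostic + self.n_nondiagnostic


@dataclass
class LesionRecord:
    lesion_id: str
    dog_id: str
    tumor_type: str
    cytology_label: str  # benign | malignant | nondiagnostic
    histopath_label: str  # benign | malignant | absent
    mass_roi: ROI
    healthy_roi: ROI
    scan_path: str = ""


@dataclass
class CohortDataset:
    """Generated cohort: per-lesion records plus their site curves.

    ``curves`` maps lesion_id -> (mass_curve, healthy_curve); in
    ``render="scans"`` mode ``scans`` additionally holds the full frame
    stacks.
    """

    records: List[LesionRecord]
    curves: Dict[str, Tuple[TemperatureCurve, TemperatureCurve]]
    scans: Dict[str, ThermalScan] = field(default_factory=dict)
    protocol: ScanProtocol = field(default_factory=ScanProtocol)

    def __len__(self) -> int:
        return len(self.records)


def _dog_sizes(config: CohortConfig, rng: np.random.Generator) -> List[int]:
    """Per-dog lesion counts: exactly n_dogs dogs summing to n_masses."""
    sizes = sorted(config.masses_per_dog)
    probs = np.array([config.masses_per_dog[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    counts = list(rng.choice(sizes, size=config.n_dogs, p=probs))
    counts = [int(c) for c in counts]
    # deterministic repair toward the exact mass total
    target = config.n_masses
    i = 0
    while sum(counts) != target:
        j = i % len(counts)
        if sum(counts) < target and counts[j] < max(sizes):
            counts[j] += 1
        elif sum(counts) > target and counts[j] > 1:
            counts[j] -= 1
        i += 1
        if i > 100 * len(counts) + target:  # pragma: no cover - defensive
            raise ConfigurationError("cannot reconcile masses_per_dog with n_masses")
    return counts


def _default_rois(camera: CameraModel, radius: float = 10.0) -> Tuple[ROI, ROI]:
    cx = camera.width / 2
    cy = camera.height / 2
    return (
        ROI(cx - radius - 15, cy, radius, site=SITE_MASS),
        ROI(cx + radius + 15, cy, radius, site=SITE_HEALTHY),
    )


def generate_cohort(
    config: CohortConfig,
    library: Optional[TissueClassLibrary] = None,
    camera: Optional[CameraModel] = None,
    protocol: Optional[ScanProtocol] = None,
    render: Literal["curves", "scans"] = "curves",
    roi_radius: float = 10.0,
) -> CohortDataset:
    """Simulate a full screening cohort with exact class marginals.

    In the default ``curves`` mode the ROI-mean curves are drawn directly:
    the mean over the N ROI pixels of iid Gaussian pixel noise is Gaussian
    noise with sd ``noise_sd/sqrt(N)``, and the ROI-mean fixed-pattern offset
    is one constant per site — both applied to the noiseless site curve.
    ``scans`` mode renders the full frame stack per lesion instead (identical
    in distribution; far more memory).
    """
    library = library or default_library()
    camera = camera or CameraModel()
    protocol = protocol or ScanProtocol()

    for t in list(config.class_counts) + list(config.nondiagnostic_counts):
        if t not in library:
            raise ConfigurationError(f"tissue library missing class {t!r}")

    root = np.random.SeedSequence(config.seed)
    ss_structure, ss_tissue, ss_noise = root.spawn(3)
    rng_structure = np.random.default_rng(ss_structure)
    rng_tissue = np.random.default_rng(ss_tissue)
    rng_noise = np.random.default_rng(ss_noise)

    # lesion roster with exact counts: diagnostic first, then non-diagnostic
    roster: List[Tuple[str, bool]] = []  # (tumor_type, diagnostic)
    for t in sorted(config.class_counts):
        roster += [(t, True)] * config.class_counts[t]
    for t in sorted(config.nondiagnostic_counts):
        roster += [(t, False)] * config.nondiagnostic_counts[t]
    order = rng_structure.permutation(len(roster))
    roster = [roster[i] for i in order]

    # histopathology flags: exact fraction of diagnostic lesions, rounded
    diag_idx = [i for i, (_, d) in enumerate(roster) if d]
    n_hist = int(round(config.histopath_fraction * len(diag_idx)))
    hist_set = set(rng_structure.choice(diag_idx, size=n_hist, replace=False)) if n_hist else set()

    sizes = _dog_sizes(config, rng_structure)
    dog_of: List[int] = []
    for dog, k in enumerate(sizes):
        dog_of += [dog] * k

    mass_roi, healthy_roi = _default_rois(camera, roi_radius)
    n_roi = mass_roi.n_pixels(camera.height, camera.width)
    fp_sd = 0.1  # kelvin, per-pixel fixed-pattern scatter

    records: List[LesionRecord] = []
    curves: Dict[str, Tuple[TemperatureCurve, TemperatureCurve]] = {}
    scans: Dict[str, ThermalScan] = {}

    # dog-level effects shared by both sites of every lesion on that dog:
    # resting temperature, perfusion (scales cooling rates), LED absorption
    # (scales gains) — the patient effects differential features cancel
    dog_baseline = {}
    dog_perfusion = {}
    dog_absorption = {}
    for dog in range(len(sizes)):
        dog_baseline[dog] = 32.0 + 0.5 * rng_tissue.standard_normal()
        dog_perfusion[dog] = _lognormal_factor(rng_tissue, DOG_PERFUSION_CV)
        dog_absorption[dog] = _lognormal_factor(rng_tissue, DOG_ABSORPTION_CV)

    for i, (tumor_type, diagnostic) in enumerate(roster):
        entry = library[tumor_type]
        dog = dog_of[i]
        lesion_id = f"L{i:04d}"
        base_h = dog_baseline[dog] + 0.2 * rng_tissue.standard_normal()
        base_m = base_h + 0.2 * rng_tissue.standard_normal()
        p_mass = _apply_dog_factors(
            entry.draw_mass(rng_tissue, base_m), dog_perfusion[dog], dog_absorption[dog]
        )
        p_healthy = _apply_dog_factors(
            entry.healthy.draw(rng_tissue, base_h), dog_perfusion[dog], dog_absorption[dog]
        )
        mass_curve = thermal_response(p_mass, protocol).with_site(SITE_MASS)
        healthy_curve = thermal_response(p_healthy, protocol).with_site(SITE_HEALTHY)

        if render == "scans":
            scan_seed = int(rng_noise.integers(0, 2**31 - 1))
            cam = CameraModel(
                height=camera.height,
                width=camera.width,
                noise_sd=camera.noise_sd,
                fixed_pattern=np.random.default_rng(scan_seed ^ 0x5F5F).normal(
                    0.0, fp_sd, size=(camera.height, camera.width)
                ),
                fov_width_cm=camera.fov_width_cm,
                fov_height_cm=camera.fov_height_cm,
                fpa_temp=camera.fpa_temp,
            )
            scan = render_scan(mass_curve, healthy_curve, cam, mass_roi, healthy_roi, scan_seed)
            scans[lesion_id] = scan
            from .scan import extract_curve  # local to avoid cycle at import time

            mc = extract_curve(scan, mass_roi)
            hc = extract_curve(scan, healthy_roi)
        else:
            sd_mean = camera.noise_sd / math.sqrt(n_roi)
            fp_mean_sd = fp_sd / math.sqrt(n_roi)
            mc, hc = mass_curve.copy(), healthy_curve.copy()
            mc.values = (
                mc.values
                + rng_noise.normal(0.0, fp_mean_sd)
                + rng_noise.normal(0.0, sd_mean, size=len(mc))
            )
            hc.values = (
                hc.values
                + rng_noise.normal(0.0, fp_mean_sd)
                + rng_noise.normal(0.0, sd_mean, size=len(hc))
            )

        truth = MALIGNANT if entry.malignant else BENIGN
        if diagnostic:
            cytology = truth
            histopath = truth if i in hist_set else ABSENT
        else:
            cytology = NONDIAGNOSTIC
            histopath = ABSENT

        records.append(
            LesionRecord(
                lesion_id=lesion_id,
                dog_id=f"D{dog:03d}",
                tumor_type=tumor_type,
                cytology_label=cytology,
                histopath_label=histopath,
                mass_roi=mass_roi,
                healthy_roi=healthy_roi,
            )
        )
        curves[lesion_id] = (mc, hc)

    return CohortDataset(records=records, curves=curves, scans=scans, protocol=protocol)


# ---------------------------------------------------------------------------
# Study-mimicking cohort configurations
# ---------------------------------------------------------------------------


def training_cohort_config(seed: int = 0) -> CohortConfig:
    """233 masses from 147 dogs, 186 benign / 47 malignant, all diagnostic."""
    class_counts = {
        "Benign epithelial/adnexal cyst/tumor": 42,
        "Benign melanoma": 3,
        "Fibroma": 2,
        "Hemangioma": 5,
        "Histiocytoma": 3,
        "Inflammatory process": 9,
        "Lipoma": 110,
        "Scar tissue": 1,
        "Sebaceous adenoma": 11,
        "Malignant melanoma": 2,
        "Mast cell tumor": 25,
        "Plasma cell tumor": 1,
        "Carcinoma": 3,
        "Soft tissue sarcoma": 14,
        "Undifferentiated neoplasia": 2,
    }
    return CohortConfig(
        n_dogs=147,
        class_counts=class_counts,
        nondiagnostic_counts={},
        masses_per_dog={1: 0.55, 2: 0.25, 3: 0.12, 4: 0.06, 6: 0.02},
        histopath_fraction=59 / 233,
        seed=seed,
    )


def validation_cohort_config(seed: int = 0) -> CohortConfig:
    """525 masses from 299 dogs; 94 non-diagnostic; 378 benign + 53 malignant diagnostic."""
    class_counts = {
        "Benign epithelial/adnexal cyst/tumor": 94,
        "Benign melanoma": 4,
        "Calcinosis circumscripta": 1,
        "Histiocytoma": 3,
        "Hyperplasia": 3,
        "Inflammatory process": 22,
        "Lipoma": 250,
        "Perineal adenoma": 1,
        "Carcinoma": 2,
        "Mast cell tumor": 38,
        "Soft tissue sarcoma": 13,
    }
    nondiagnostic_counts = {
        "Lipoma": 55,
        "Benign epithelial/adnexal cyst/tumor": 20,
        "Inflammatory process": 10,
        "Mast cell tumor": 5,
        "Soft tissue sarcoma": 2,
        "Carcinoma": 2,
    }
    return CohortConfig(
        n_dogs=299,
        class_counts=class_counts,
        nondiagnostic_counts=nondiagnostic_counts,
        masses_per_dog={1: 181 / 299, 2: 61 / 299, 3: 23 / 299, 4: 21 / 299, 5: 9 / 299, 6: 4 / 299},
        histopath_fraction=41 / 431,
        seed=seed,
    )
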