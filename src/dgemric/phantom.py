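"""Digital cartilage phantoms for sub-regional dGEMRIC analysis.

The phantom is a single sagittal slice through the central femoral condyle:
cartilage is an annular arc of prescribed radial thickness sitting on a
circular subchondral-bone contour.  The arc is divided into a weight-bearing
(WB) and a non-weight-bearing (NWB) segment, each with its own thickness,
depth-dependent pre-contrast T1 and superficial gadolinium concentration.

Ground truth
------------
* pre-contrast T1 varies linearly with normalized depth ``d`` (0 at the
  articular surface, 1 at the bone interface) between a superficial and a
  deep value;
* gadolinium follows a diffusion-from-the-surface profile
  ``gd(d) = A * erfc(d * thickness / diffusion_depth)`` with the amplitude
  ``A`` calibrated so that the continuous mean over the superficial layer
  (``d <= superficial_fraction``) equals the requested superficial
  concentration;
* post-contrast T1 obeys ``1/T1_post = 1/T1_pre + r1 * [Gd]`` with the
  Gd-DTPA2- plasma relaxivity r1 = 4.1 s^-1 mM^-1 by default.

Magnitude inversion-recovery series are simulated from these maps with the
finite-TR signal equation and Rician noise; cohorts of subjects are drawn
from per-group priors whose defaults reproduce the thickness, layer-T1 and
superficial-[Gd] statistics of a sedentary and an exercising (elite runner)
group of healthy volunteers.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import erfc

from .series import IRSeries

__all__ = [
    "SEGMENTS",
    "SEGMENT_CODES",
    "GD_RELAXIVITY_S_PER_MM",
    "AcquisitionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "CompartmentPhantom",
    "SubjectRecord",
    "NormalPrior",
    "UniformPrior",
    "GroupPriors",
    "default_group_priors",
    "build_condyle_geometry",
    "assign_t1_and_gd_fields",
    "simulate_ir_series",
    "build_subject",
    "make_cohort",
]

logger = logging.getLogger(__name__)

SEGMENTS = ("WB", "NWB")
SEGMENT_CODES = {"background": 0, "WB": 1, "NWB": 2}

#: longitudinal relaxivity of Gd-DTPA2- in human plasma at 37 C, s^-1 mM^-1
GD_RELAXIVITY_S_PER_MM = 4.1


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """Magnitude inversion-recovery acquisition parameters.

    Defaults follow a 1.5 T knee protocol: TI = 50..1600 ms, TR = 2000 ms,
    0.47 mm in-plane resolution.  ``noise_sigma`` is the Gaussian channel
    noise as a fraction of the equilibrium signal (0.02 = SNR 50).
    """

    inversion_times_ms: tuple[float, ...] = (50.0, 100.0, 200.0, 400.0, 800.0, 1600.0)
    repetition_time_ms: float = 2000.0
    pixel_size_mm: float = 0.47
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        tis = np.asarray(self.inversion_times_ms, dtype=float)
        if tis.size < 3:
            raise ValueError("at least 3 inversion times are required")
        if np.any(np.diff(tis) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        if np.any(tis <= 0):
            raise ValueError("inversion times must be positive")
        if np.any(tis >= self.repetition_time_ms):
            raise ValueError(
                "all inversion times must be shorter than the repetition time"
            )
        if self.repetition_time_ms <= 0 or self.pixel_size_mm <= 0:
            raise ValueError("repetition time and pixel size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _per_segment(value, name: str) -> dict[str, float]:
    """Broadcast a scalar or {segment: value} mapping to both segments."""
    if isinstance(value, Mapping):
        missing = set(SEGMENTS) - set(value)
        if missing:
            raise ValueError(f"{name} missing segments: {sorted(missing)}")
        return {seg: float(value[seg]) for seg in SEGMENTS}
    return {seg: float(value) for seg in SEGMENTS}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of one condyle phantom.

    Tissue parameters accept either a scalar (same in both segments) or a
    ``{"WB": ..., "NWB": ...}`` mapping.
    """

    condyle_radius_mm: float = 20.0
    thickness_by_segment: Mapping[str, float] | float = 2.0
    t1_superficial_ms: Mapping[str, float] | float = 1100.0
    t1_deep_ms: Mapping[str, float] | float = 650.0
    gd_superficial_mM: Mapping[str, float] | float = 0.35
    diffusion_depth_mm: float = 1.2
    image_shape: tuple[int, int] = (128, 128)
    pixel_size_mm: float = 0.47
    arc_center_deg: float = 90.0
    arc_span_deg: float = 150.0
    superficial_fraction: float = 1.0 / 3.0
    calibration_guard_mm: float | None = None

    def __post_init__(self) -> None:
        for name in ("condyle_radius_mm", "diffusion_depth_mm", "pixel_size_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        thick = _per_segment(self.thickness_by_segment, "thickness_by_segment")
        sup = _per_segment(self.t1_superficial_ms, "t1_superficial_ms")
        deep = _per_segment(self.t1_deep_ms, "t1_deep_ms")
        gd = _per_segment(self.gd_superficial_mM, "gd_superficial_mM")
        for seg in SEGMENTS:
            if not 0.5 < thick[seg] < 5.0:
                raise ValueError(
                    f"{seg} thickness {thick[seg]:.2f} mm outside the plausible "
                    "(0.5, 5.0) mm range"
                )
            if sup[seg] < deep[seg]:
                raise ValueError(
                    f"{seg}: superficial T1 ({sup[seg]:.0f} ms) must not be "
                    f"shorter than deep T1 ({deep[seg]:.0f} ms)"
                )
            if deep[seg] <= 0:
                raise ValueError("T1 values must be positive")
            if gd[seg] < 0:
                raise ValueError("gadolinium concentration must be non-negative")
        if not 0 < self.superficial_fraction <= 0.5:
            raise ValueError("superficial_fraction must lie in (0, 0.5]")
        if self.calibration_guard_mm is not None and self.calibration_guard_mm < 0:
            raise ValueError("calibration_guard_mm must be non-negative")

    @property
    def effective_calibration_guard_mm(self) -> float:
        """Surface margin excluded from the superficial-layer calibration.

        Defaults to half a pixel, matching the partial-volume guard the
        laminar ROI extraction applies, so that the measured superficial
        layer mean reproduces ``gd_superficial_mM``.
        """
        if self.calibration_guard_mm is None:
            return 0.5 * self.pixel_size_mm
        return self.calibration_guard_mm

    def thickness(self, segment: str) -> float:
        return _per_segment(self.thickness_by_segment, "thickness")[segment]

    def t1_superficial(self, segment: str) -> float:
        return _per_segment(self.t1_superficial_ms, "t1_superficial")[segment]

    def t1_deep(self, segment: str) -> float:
        return _per_segment(self.t1_deep_ms, "t1_deep")[segment]

    def gd_superficial(self, segment: str) -> float:
        return _per_segment(self.gd_superficial_mM, "gd_superficial")[segment]


# --------------------------------------------------------------------------
# ground truth container
# --------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground truth for one simulated condyle slice.

    Polylines are (n, 2) arrays of (x, y) millimetre coordinates ordered
    along the arc; ``surfaces``/``interfaces`` hold the per-segment pieces,
    ``articular_surface``/``bone_interface`` their concatenation.
    """

    spec: PhantomSpec
    mask: np.ndarray
    segment_labels: np.ndarray
    thickness_by_segment: dict[str, float]
    articular_surface: np.ndarray
    bone_interface: np.ndarray
    surfaces: dict[str, np.ndarray]
    interfaces: dict[str, np.ndarray]
    center_mm: tuple[float, float]
    radial_depth: np.ndarray  # analytic normalized depth, NaN outside mask
    t1pre_map_ms: np.ndarray | None = None
    gd_map_mM: np.ndarray | None = None
    t1post_map_ms: np.ndarray | None = None

    @property
    def pixel_size_mm(self) -> float:
        return self.spec.pixel_size_mm

    def segment_mask(self, segment: str) -> np.ndarray:
        return self.segment_labels == SEGMENT_CODES[segment]

    def validate(self) -> None:
        """Check the internal-consistency invariants of a populated truth."""
        if not np.array_equal(self.mask, self.segment_labels > 0):
            raise AssertionError("segment labels do not partition the mask")
        if self.gd_map_mM is not None:
            out = ~self.mask
            if np.any(self.gd_map_mM[out] != 0):
                raise AssertionError("gadolinium present outside the mask")
            gd = self.gd_map_mM[self.mask]
            pre = self.t1pre_map_ms[self.mask]
            post = self.t1post_map_ms[self.mask]
            if np.any(post > pre + 1e-9):
                raise AssertionError("post-contrast T1 exceeds pre-contrast T1")
            if np.any((gd > 0) & ~(post < pre)):
                raise AssertionError("T1 not shortened where gadolinium present")


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _pixel_grid(shape: tuple[int, int], pixel_size: float):
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx]
    return x * pixel_size, y * pixel_size


def build_condyle_geometry(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize the condyle arc and build the ground-truth geometry.

    The cartilage occupies radii ``[R, R + t(segment)]`` over an arc of
    ``arc_span_deg`` centred on ``arc_center_deg``; the WB segment is the
    half of the arc below the centre angle, NWB the half above.  Per-segment
    radial thickness equals the spec value exactly by construction.
    """
    ny, nx = spec.image_shape
    pix = spec.pixel_size_mm
    cx, cy = (nx - 1) / 2 * pix, (ny - 1) / 2 * pix
    outer = {seg: spec.condyle_radius_mm + spec.thickness(seg) for seg in SEGMENTS}
    max_outer = max(outer.values())
    half_extent_x = (nx - 1) / 2 * pix
    half_extent_y = (ny - 1) / 2 * pix
    # the arc may not reach the image border in any direction it spans
    if max_outer > half_extent_x:
        raise ValueError(
            f"condyle outer radius {max_outer:.1f} mm exceeds the image "
            f"half-width {half_extent_x:.1f} mm (x dimension too small)"
        )
    if max_outer > half_extent_y:
        raise ValueError(
            f"condyle outer radius {max_outer:.1f} mm exceeds the image "
            f"half-height {half_extent_y:.1f} mm (y dimension too small)"
        )

    x, y = _pixel_grid(spec.image_shape, pix)
    r = np.hypot(x - cx, y - cy)
    theta = np.degrees(np.arctan2(y - cy, x - cx))

    lo = spec.arc_center_deg - spec.arc_span_deg / 2
    hi = spec.arc_center_deg + spec.arc_span_deg / 2
    in_arc = (theta >= lo) & (theta <= hi)
    # WB = lower half of the arc (toward the joint surface), NWB = upper half
    seg_of_angle = np.where(theta < spec.arc_center_deg, "WB", "NWB")

    labels = np.zeros(spec.image_shape, dtype=np.int8)
    depth = np.full(spec.image_shape, np.nan)
    R = spec.condyle_radius_mm
    for seg in SEGMENTS:
        t = spec.thickness(seg)
        inside = in_arc & (seg_of_angle == seg) & (r >= R) & (r <= R + t)
        labels[inside] = SEGMENT_CODES[seg]
        depth[inside] = (R + t - r[inside]) / t
    mask = labels > 0
    if not mask.any():
        raise ValueError("phantom mask is empty; check geometry parameters")

    # polylines sampled at ~0.1 mm chord length
    step_deg = np.degrees(0.1 / max_outer)
    surfaces, interfaces = {}, {}
    seg_bounds = {"WB": (lo, spec.arc_center_deg), "NWB": (spec.arc_center_deg, hi)}
    for seg in SEGMENTS:
        a0, a1 = seg_bounds[seg]
        angles = np.radians(np.linspace(a0, a1, max(int((a1 - a0) / step_deg), 2)))
        ca, sa = np.cos(angles), np.sin(angles)
        surfaces[seg] = np.column_stack([cx + outer[seg] * ca, cy + outer[seg] * sa])
        interfaces[seg] = np.column_stack([cx + R * ca, cy + R * sa])

    return PhantomTruth(
        spec=spec,
        mask=mask,
        segment_labels=labels,
        thickness_by_segment={seg: spec.thickness(seg) for seg in SEGMENTS},
        articular_surface=np.vstack([surfaces["WB"], surfaces["NWB"]]),
        bone_interface=np.vstack([interfaces["WB"], interfaces["NWB"]]),
        surfaces=surfaces,
        interfaces=interfaces,
        center_mm=(cx, cy),
        radial_depth=depth,
    )


# --------------------------------------------------------------------------
# tissue fields
# --------------------------------------------------------------------------

def _erfc_integral(x: np.ndarray | float) -> np.ndarray | float:
    """Closed form of the running integral of erfc from 0 to x."""
    x = np.asarray(x, dtype=float)
    return x * erfc(x) + (1.0 - np.exp(-(x**2))) / np.sqrt(np.pi)


def gd_profile_amplitude(
    gd_superficial: float, thickness_mm: float, diffusion_depth_mm: float,
    superficial_fraction: float = 1.0 / 3.0,
    calibration_guard_mm: float = 0.0,
) -> float:
    """Surface amplitude A such that the continuous mean of
    ``A * erfc(d * thickness / diffusion_depth)`` over the analyzed
    superficial band equals ``gd_superficial``.

    The band runs from ``calibration_guard_mm / thickness`` (the
    partial-volume margin the ROI extraction excludes at the surface) to
    ``superficial_fraction`` in normalized depth.
    """
    if gd_superficial == 0:
        return 0.0
    alpha = thickness_mm / diffusion_depth_mm
    f = superficial_fraction
    d0 = min(calibration_guard_mm / thickness_mm, 0.9 * f)
    layer_mean = (_erfc_integral(alpha * f) - _erfc_integral(alpha * d0)) / (
        alpha * (f - d0)
    )
    return gd_superficial / float(layer_mean)


def assign_t1_and_gd_fields(
    truth: PhantomTruth,
    spec: PhantomSpec | None = None,
    relaxivity_s_per_mM: float = GD_RELAXIVITY_S_PER_MM,
) -> PhantomTruth:
    """Populate the T1-pre, [Gd] and T1-post ground-truth maps in place.

    Pre-contrast T1 interpolates linearly in normalized depth between the
    superficial and deep values; [Gd] follows the calibrated erfc diffusion
    profile; post-contrast T1 is obtained from the relaxivity relation
    ``1/T1_post = 1/T1_pre + r1 * [Gd]`` (T1 in seconds, [Gd] in mM).
    """
    spec = spec or truth.spec
    t1pre = np.full(spec.image_shape, np.nan)
    gd = np.zeros(spec.image_shape)
    for seg in SEGMENTS:
        m = truth.segment_mask(seg)
        d = truth.radial_depth[m]
        sup, deep = spec.t1_superficial(seg), spec.t1_deep(seg)
        t1pre[m] = sup + (deep - sup) * d
        amp = gd_profile_amplitude(
            spec.gd_superficial(seg),
            truth.thickness_by_segment[seg],
            spec.diffusion_depth_mm,
            spec.superficial_fraction,
            spec.effective_calibration_guard_mm,
        )
        gd[m] = amp * erfc(
            d * truth.thickness_by_segment[seg] / spec.diffusion_depth_mm
        )
    # relaxivity relation with T1 in ms and r1 in s^-1 mM^-1
    t1post = np.full(spec.image_shape, np.nan)
    m = truth.mask
    t1post[m] = 1000.0 / (1000.0 / t1pre[m] + relaxivity_s_per_mM * gd[m])
    truth.t1pre_map_ms = t1pre
    truth.gd_map_mM = gd
    truth.t1post_map_ms = t1post
    truth.validate()
    return truth


# --------------------------------------------------------------------------
# signal simulation
# --------------------------------------------------------------------------

def ir_signal(ti_ms, t1_ms, tr_ms):
    """Signed inversion-recovery signal 1 - 2 exp(-TI/T1) + exp(-TR/T1)."""
    ti = np.asarray(ti_ms, dtype=float)
    t1 = np.asarray(t1_ms, dtype=float)
    return 1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr_ms / t1)


def simulate_ir_series(
    t1_map: np.ndarray,
    acquisition: AcquisitionSpec,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> IRSeries:
    """Simulate a magnitude IR series from a T1 map.

    Pixels where ``t1_map`` is NaN (outside tissue) contribute zero signal.
    Rician noise of parameter ``noise_sigma * scale`` is applied by adding
    independent Gaussian noise to two quadrature channels and taking the
    magnitude.  Deterministic for a fixed ``acquisition.seed`` when ``rng``
    is not supplied.
    """
    tis = np.asarray(acquisition.inversion_times_ms, dtype=float)
    tr = acquisition.repetition_time_ms
    t1 = np.asarray(t1_map, dtype=float)
    if np.any(t1[np.isfinite(t1)] <= 0):
        raise ValueError("t1_map must be positive where finite")
    if rng is None:
        rng = np.random.default_rng(acquisition.seed)

    finite = np.isfinite(t1)
    signal = np.zeros((tis.size, *t1.shape))
    for i, ti in enumerate(tis):
        s = np.zeros_like(t1)
        s[finite] = scale * ir_signal(ti, t1[finite], tr)
        signal[i] = s
    sigma = acquisition.noise_sigma * scale
    if sigma > 0:
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        mag = np.hypot(re, im)
    else:
        mag = np.abs(signal)
    return IRSeries(
        images=mag,
        inversion_times_ms=tis,
        repetition_time_ms=tr,
        pixel_size_mm=acquisition.pixel_size_mm,
    )


# --------------------------------------------------------------------------
# cohort priors and subjects
# --------------------------------------------------------------------------

class NormalPrior:
    """Normal prior with optional truncation by redraw (not clipping)."""

    def __init__(self, mean: float, sd: float, low: float | None = None,
                 high: float | None = None):
        self.mean, self.sd = float(mean), float(sd)
        self.low, self.high = low, high

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(10_000):
            x = rng.normal(self.mean, self.sd)
            if (self.low is None or x > self.low) and (
                self.high is None or x < self.high
            ):
                return float(x)
            logger.debug("redrew out-of-range sample %.3g from %r", x, self)
        raise RuntimeError(f"truncated sampling failed for {self!r}")

    def __repr__(self) -> str:
        return f"NormalPrior({self.mean}, {self.sd}, low={self.low}, high={self.high})"


class UniformPrior:
    def __init__(self, low: float, high: float):
        if high < low:
            raise ValueError("high < low")
        self.low, self.high = float(low), float(high)

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))

    def __repr__(self) -> str:
        return f"UniformPrior({self.low}, {self.high})"


@dataclass
class GroupPriors:
    """Per-group sampling distributions for one cohort arm.

    ``thickness`` is indexed by compartment then segment; the layer-T1 and
    superficial-[Gd] priors by segment only (the source tables do not split
    them by compartment).
    """

    thickness: dict[str, dict[str, NormalPrior]]
    t1_superficial: dict[str, NormalPrior]
    t1_deep: dict[str, NormalPrior]
    gd_superficial: dict[str, NormalPrior]
    bmi: UniformPrior | NormalPrior
    diffusion_depth_mm: float = 1.2
    condyle_radius_mm: float = 20.0
    image_shape: tuple[int, int] = (128, 128)


def default_group_priors() -> dict[str, GroupPriors]:
    """Cohort priors reproducing the two study groups.

    Thickness (mm), layer pre-contrast T1 (ms) and superficial [Gd] (mM)
    priors are normal with the published group means and SDs; BMI is uniform
    over each group's published range.  Thickness is truncated to the
    geometric validity range (0.5, 5.0) mm by redraw.
    """
    tlo, thi = 0.5, 5.0

    def tprior(mean, sd):
        return NormalPrior(mean, sd, low=tlo, high=thi)

    exercise = GroupPriors(
        thickness={
            "medial": {"WB": tprior(2.90, 0.30), "NWB": tprior(1.81, 0.19)},
            "lateral": {"WB": tprior(2.87, 0.21), "NWB": tprior(1.73, 0.20)},
        },
        t1_superficial={
            "WB": NormalPrior(1141, 59, low=0),
            "NWB": NormalPrior(1084, 83, low=0),
        },
        t1_deep={
            "WB": NormalPrior(627, 84, low=0),
            "NWB": NormalPrior(737, 83, low=0),
        },
        gd_superficial={
            "WB": NormalPrior(0.29, 0.08, low=0),
            "NWB": NormalPrior(0.37, 0.08, low=0),
        },
        bmi=UniformPrior(20.4, 23.2),
    )
    sedentary = GroupPriors(
        thickness={
            "medial": {"WB": tprior(1.70, 0.50), "NWB": tprior(1.54, 0.20)},
            "lateral": {"WB": tprior(2.54, 0.40), "NWB": tprior(1.56, 0.30)},
        },
        t1_superficial={
            "WB": NormalPrior(1104, 114, low=0),
            "NWB": NormalPrior(1003, 132, low=0),
        },
        t1_deep={
            "WB": NormalPrior(673, 69, low=0),
            "NWB": NormalPrior(703, 91, low=0),
        },
        gd_superficial={
            "WB": NormalPrior(0.35, 0.09, low=0),
            "NWB": NormalPrior(0.39, 0.07, low=0),
        },
        bmi=UniformPrior(17.3, 26.9),
    )
    return {"exercise": exercise, "sedentary": sedentary}


@dataclass
class CompartmentPhantom:
    """One condyle (medial or lateral) of a simulated subject."""

    compartment: str
    truth: PhantomTruth
    series_pre: IRSeries
    series_post: IRSeries


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    bmi: float
    compartments: dict[str, CompartmentPhantom]

    def checksum(self) -> str:
        """SHA-256 over all simulated arrays and metadata (determinism probe)."""
        h = hashlib.sha256()
        h.update(f"{self.subject_id}|{self.group}|{self.bmi!r}".encode())
        for comp in sorted(self.compartments):
            cp = self.compartments[comp]
            for arr in (
                cp.truth.mask,
                cp.truth.segment_labels,
                cp.truth.t1pre_map_ms,
                cp.truth.gd_map_mM,
                cp.truth.t1post_map_ms,
                cp.series_pre.images,
                cp.series_post.images,
            ):
                h.update(np.ascontiguousarray(arr).tobytes())
            for seg in SEGMENTS:
                h.update(repr(cp.truth.thickness_by_segment[seg]).encode())
        return h.hexdigest()


def _draw_spec(priors: GroupPriors, compartment: str,
               rng: np.random.Generator, acquisition: AcquisitionSpec) -> PhantomSpec:
    thickness = {
        seg: priors.thickness[compartment][seg].draw(rng) for seg in SEGMENTS
    }
    sup, deep = {}, {}
    for seg in SEGMENTS:
        for _ in range(10_000):
            s = priors.t1_superficial[seg].draw(rng)
            d = priors.t1_deep[seg].draw(rng)
            if s >= d:
                sup[seg], deep[seg] = s, d
                break
            logger.debug("redrew inverted T1 layer pair (%s)", seg)
        else:  # pragma: no cover - astronomically unlikely with sane priors
            raise RuntimeError("could not draw superficial >= deep T1 pair")
    gd = {seg: priors.gd_superficial[seg].draw(rng) for seg in SEGMENTS}
    return PhantomSpec(
        condyle_radius_mm=priors.condyle_radius_mm,
        thickness_by_segment=thickness,
        t1_superficial_ms=sup,
        t1_deep_ms=deep,
        gd_superficial_mM=gd,
        diffusion_depth_mm=priors.diffusion_depth_mm,
        image_shape=priors.image_shape,
        pixel_size_mm=acquisition.pixel_size_mm,
    )


def build_subject(
    subject_id: str,
    group: str,
    priors: GroupPriors,
    rng: np.random.Generator,
    acquisition: AcquisitionSpec | None = None,
    compartments: tuple[str, ...] = ("medial", "lateral"),
) -> SubjectRecord:
    """Draw one subject from group priors and simulate both IR series."""
    acquisition = acquisition or AcquisitionSpec()
    bmi = priors.bmi.draw(rng)
    comps: dict[str, CompartmentPhantom] = {}
    for comp in compartments:
        spec = _draw_spec(priors, comp, rng, acquisition)
        truth = assign_t1_and_gd_fields(build_condyle_geometry(spec), spec)
        series_pre = simulate_ir_series(truth.t1pre_map_ms, acquisition, rng=rng)
        series_post = simulate_ir_series(truth.t1post_map_ms, acquisition, rng=rng)
        comps[comp] = CompartmentPhantom(comp, truth, series_pre, series_post)
    return SubjectRecord(subject_id, group, bmi, comps)


def make_cohort(
    group_priors: Mapping[str, GroupPriors] | None = None,
    n_per_group: Mapping[str, int] | int = None,
    seed: int = 0,
    acquisition: AcquisitionSpec | None = None,
    compartments: tuple[str, ...] = ("medial", "lateral"),
) -> list[SubjectRecord]:
    """Simulate a full two-group cohort.

    Defaults reproduce the study arms: 8 exercising and 9 sedentary
    subjects drawn from :func:`default_group_priors`.  Each subject receives
    an independent child seed from ``seed`` so cohorts are reproducible and
    subjects are statistically independent.
    """
    group_priors = group_priors or default_group_priors()
    if n_per_group is None:
        n_per_group = {"exercise": 8, "sedentary": 9}
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in group_priors}
    for g, n in n_per_group.items():
        if n < 2:
            raise ValueError(f"group {g!r}: at least 2 subjects per group")
    acquisition = acquisition or AcquisitionSpec()

    ss = np.random.SeedSequence(seed)
    subjects: list[SubjectRecord] = []
    for group in sorted(n_per_group):
        priors = group_priors[group]
        for i in range(n_per_group[group]):
            rng = np.random.default_rng(ss.spawn(1)[0])
            subjects.append(
                build_subject(
                    f"{group}-{i + 1:02d}", group, priors, rng,
                    acquisition, compartments,
                )
            )
    return subjects
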