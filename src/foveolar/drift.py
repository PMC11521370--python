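"""Fixational-drift metrics relative to foveolar landmarks.

Per-trial gaze traces (stimulus position over time, registered to the cone
mosaic) are reduced to scalar drift statistics:

* drift length — concatenated vector sum (sum of magnitudes) of frame-wise
  motion vectors within the 500 ms stimulus window; velocity = length/0.5 s;
* drift direction theta_retina — angle of the onset-to-offset vector;
* theta_landmark — signed angle between the drift vector and the line from
  the onset location to a landmark (CDC, PRL, or PCD);
* tuning ratio — frequency of drifts within +/-45 deg of the landmark
  direction over the mean frequency of the other three quadrants;
* Rayleigh test for circular non-uniformity (implemented natively);
* ISOA — "one-SD isoline area", the area of the kernel-density contour
  enclosing 68.27% of gaze/stimulus-location probability mass;
* convergence ratio and sampling gain.

Angles are in degrees, counterclockwise positive (y is downward in the image
frame, so "up" on the retina is -y), wrapped to (-180, 180].  Trials
containing microsaccades or blinks during the stimulus window are excluded;
detection uses a median-based velocity threshold (Engbert-Kliegl style).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from skimage import measure

__all__ = [
    "GazeTrace",
    "MicrosaccadeEvent",
    "DriftMetrics",
    "DirectionalityStats",
    "ISOAResult",
    "detect_microsaccades",
    "trial_exclusion",
    "drift_length",
    "drift_velocity",
    "drift_direction",
    "angle_to_landmark",
    "tuning_ratio",
    "rayleigh_test",
    "isoa",
    "convergence_ratio",
    "sampling_gain",
    "potential_sampling_gain",
    "trial_drift_metrics",
    "aggregate_directionality",
    "TUNING_RATIO_INF",
]

#: Sentinel returned when every observed drift lands in the landmark quadrant.
TUNING_RATIO_INF = float("inf")

FRAME_RATE_HZ = 30.0


@dataclass(frozen=True)
class GazeTrace:
    """Stimulus trajectory of one trial in the master-image frame.

    ``times_ms``/``xy`` are the recorded samples (30 Hz frame level, or up to
    960 Hz strip level); ``window_ms`` is the stimulus-on interval
    (nominally 500 ms).  Times must be strictly increasing and the window
    must lie within the trace span.
    """

    times_ms: np.ndarray
    xy: np.ndarray
    trial_id: int = 0
    frame_rate_hz: float = FRAME_RATE_HZ
    window_ms: tuple[float, float] | None = None

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace timestamps must be strictly increasing")
        if xy.shape != (len(t), 2):
            raise ValueError("xy must be (n, 2) matching times")
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "xy", xy)
        if self.window_ms is not None:
            a, b = self.window_ms
            if not (t[0] <= a < b <= t[-1]):
                raise ValueError("stimulus window must lie within the trace span")

    def window_samples(self, frame_level: bool = True
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Samples inside the stimulus window, decimated to frame level.

        Drift metrics are defined on frame-wise (30 Hz) motion vectors;
        higher-rate (strip-level) traces are decimated accordingly when
        ``frame_level`` is True.
        """
        t, xy = self.times_ms, self.xy
        if self.window_ms is not None:
            m = (t >= self.window_ms[0]) & (t <= self.window_ms[1])
            t, xy = t[m], xy[m]
        if frame_level and self.frame_rate_hz > FRAME_RATE_HZ + 1e-9:
            step = int(round(self.frame_rate_hz / FRAME_RATE_HZ))
            t, xy = t[::step], xy[::step]
        return t, xy

    @property
    def window_duration_s(self) -> float:
        if self.window_ms is None:
            return (self.times_ms[-1] - self.times_ms[0]) / 1000.0
        return (self.window_ms[1] - self.window_ms[0]) / 1000.0


@dataclass(frozen=True)
class MicrosaccadeEvent:
    """One detected ballistic gaze shift."""

    start_ms: float
    end_ms: float
    peak_velocity: float  # arcmin/s
    amplitude: float      # arcmin, start-to-end displacement

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise ValueError("event end must follow start")


def _ek_velocities(t_s: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Velocity estimate from a 5-sample moving window (Engbert-Kliegl)."""
    n = len(t_s)
    v = np.zeros_like(xy)
    dt = np.median(np.diff(t_s))
    for k in range(2, n - 2):
        v[k] = (xy[k + 2] + xy[k + 1] - xy[k - 1] - xy[k - 2]) / (6.0 * dt)
    v[1] = (xy[2] - xy[0]) / (t_s[2] - t_s[0])
    v[n - 2] = (xy[n - 1] - xy[n - 3]) / (t_s[n - 1] - t_s[n - 3])
    return v


def detect_microsaccades(
    trace: GazeTrace,
    lambda_threshold: float = 6.0,
    min_duration_ms: float = 6.0,
) -> list[MicrosaccadeEvent]:
    """Median-based velocity-threshold microsaccade detection.

    Component-wise velocity thresholds are ``lambda_threshold`` times the
    median-based velocity SD; samples whose normalized velocity exceeds the
    elliptic threshold for at least ``min_duration_ms`` form one event.
    Deterministic for fixed input.  Requires >= 100 ms of samples.
    """
    t = trace.times_ms
    if t[-1] - t[0] < 100.0:
        raise ValueError("need at least 100 ms of samples for detection")
    t_s = t / 1000.0
    v = _ek_velocities(t_s, trace.xy)
    sigma2 = np.median(v ** 2, axis=0) - np.median(v, axis=0) ** 2
    sigma = np.sqrt(np.maximum(sigma2, 1e-12))
    eta = lambda_threshold * sigma
    above = ((v[:, 0] / eta[0]) ** 2 + (v[:, 1] / eta[1]) ** 2) > 1.0

    events: list[MicrosaccadeEvent] = []
    dt_ms = float(np.median(np.diff(t)))
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        # event spans samples i..j; its duration covers (j - i + 1) intervals
        if (t[j] - t[i]) + dt_ms >= min_duration_ms:
            vnorm = np.linalg.norm(v[i:j + 1], axis=1)
            amp = float(np.linalg.norm(trace.xy[j] - trace.xy[i]))
            events.append(MicrosaccadeEvent(
                start_ms=float(t[i]), end_ms=float(t[j] + dt_ms),
                peak_velocity=float(vnorm.max()), amplitude=amp))
        i = j + 1
    return events


def trial_exclusion(trace: GazeTrace, blink_gap_ms: float = 50.0,
                    **detect_kwargs) -> tuple[bool, str]:
    """Whether a trial must be excluded, and why.

    Excluded when a microsaccade overlaps the stimulus window or when a
    sample gap longer than ``blink_gap_ms`` (a blink / tracking loss) falls
    inside it.
    """
    a, b = trace.window_ms if trace.window_ms is not None else (
        trace.times_ms[0], trace.times_ms[-1])
    gaps = np.diff(trace.times_ms)
    if gaps.size:
        gi = np.flatnonzero(gaps > blink_gap_ms)
        for g in gi:
            if trace.times_ms[g] < b and trace.times_ms[g + 1] > a:
                return True, "blink"
    for ev in detect_microsaccades(trace, **detect_kwargs):
        if ev.start_ms < b and ev.end_ms > a:
            return True, "microsaccade"
    return False, ""


def drift_length(trace: GazeTrace) -> float:
    """Concatenated vector sum of frame-wise motion vectors, arcmin.

    Sum of Euclidean norms of successive frame-to-frame displacements inside
    the stimulus window — the full path length, not the net displacement.
    """
    _, xy = trace.window_samples()
    if len(xy) < 2:
        raise ValueError("need at least 2 frames inside the stimulus window")
    return float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())


def drift_velocity(trace: GazeTrace) -> float:
    """Drift length divided by the stimulus window duration, arcmin/s."""
    return drift_length(trace) / trace.window_duration_s


def _vector_angle(dx: float, dy: float) -> float:
    """Angle in degrees, CCW positive, 0 = rightward, +90 = upward.

    The image frame has y pointing downward, hence the sign flip.
    """
    return math.degrees(math.atan2(-dy, dx))


def _wrap_angle(theta: float) -> float:
    """Wrap to (-180, 180]."""
    t = (theta + 180.0) % 360.0 - 180.0
    return 180.0 if t == -180.0 else t


def drift_direction(trace: GazeTrace) -> float:
    """theta_retina: angle of the onset-to-offset drift vector, degrees.

    NaN (flagged-undefined) for zero net displacement.
    """
    _, xy = trace.window_samples()
    d = xy[-1] - xy[0]
    if np.allclose(d, 0.0):
        return float("nan")
    return _vector_angle(d[0], d[1])


def angle_to_landmark(trace: GazeTrace, landmark: tuple[float, float]) -> float:
    """theta_landmark: drift direction relative to the onset->landmark line.

    Signed difference (CCW positive) between the onset-to-offset drift vector
    and the vector from the onset location to the landmark, in (-180, 180].
    NaN when the drift has no net displacement or the onset coincides with
    the landmark.
    """
    _, xy = trace.window_samples()
    d = xy[-1] - xy[0]
    to_lm = np.asarray(landmark, dtype=float) - xy[0]
    if np.allclose(d, 0.0) or np.allclose(to_lm, 0.0):
        return float("nan")
    return _wrap_angle(_vector_angle(d[0], d[1]) - _vector_angle(to_lm[0], to_lm[1]))


def _quadrant_frequencies(angles: np.ndarray) -> np.ndarray:
    """Frequencies in the four half-open quadrants centered on 0/90/180/-90."""
    a = np.asarray([_wrap_angle(x) for x in angles], dtype=float)
    toward = (a >= -45.0) & (a < 45.0)
    ccw = (a >= 45.0) & (a < 135.0)
    away = (a >= 135.0) | (a < -135.0)
    cw = (a >= -135.0) & (a < -45.0)
    n = len(a)
    return np.array([toward.sum(), ccw.sum(), away.sum(), cw.sum()]) / n


def tuning_ratio(angles) -> float:
    """Directionality tuning: landmark-quadrant frequency over the mean of
    the other three quadrants.

    1.0 means drift is equally likely toward all cardinal directions; 2.0
    means drift lands in the landmark quadrant twice as often as in each of
    the others.  Returns +inf (with a warning) when the three far quadrants
    are all empty.  Undefined (NaN) angles are dropped.
    """
    a = np.asarray(list(angles), dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise ValueError("need at least one defined angle")
    freqs = _quadrant_frequencies(a)
    rest = freqs[1:].mean()
    if rest == 0.0:
        warnings.warn("all drifts in the landmark quadrant; tuning ratio is "
                      "infinite", RuntimeWarning, stacklevel=2)
        return TUNING_RATIO_INF
    return float(freqs[0] / rest)


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test for circular non-uniformity.

    Returns (R_bar, p) where R_bar is the mean resultant length of the
    angles (degrees) and p follows the standard approximation
    p = exp(sqrt(1 + 4 n + 4 (n^2 - R^2)) - (1 + 2 n)) with R = n * R_bar.
    Requires n >= 5.
    """
    a = np.deg2rad(np.asarray(list(angles), dtype=float))
    a = a[~np.isnan(a)]
    n = a.size
    if n < 5:
        raise ValueError("Rayleigh test requires at least 5 angles")
    r_bar = float(np.abs(np.exp(1j * a).mean()))
    big_r = n * r_bar
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n ** 2 - big_r ** 2))
                 - (1.0 + 2.0 * n))
    return r_bar, min(p, 1.0)


@dataclass(frozen=True)
class ISOAResult:
    """Kernel-density isoline area of a 2-D point set.

    ``area`` (arcmin^2) is the total area of the region(s) whose KDE density
    exceeds the level enclosing ``mass`` of the probability; ``contours`` are
    the enclosing polygons (arcmin coordinates); ``bandwidth_factor`` is the
    KDE bandwidth factor actually used.
    """

    area: float
    contours: list[np.ndarray] = field(repr=False, default_factory=list)
    bandwidth_factor: float = float("nan")
    mass: float = 0.6827
    level: float = float("nan")


def isoa(points: np.ndarray, mass: float = 0.6827,
         bandwidth: str | float = "silverman",
         grid_step: float = 0.1) -> ISOAResult:
    """One-SD isoline area of gaze or stimulus-location points.

    A Gaussian kernel density estimate (Silverman bandwidth by default) is
    evaluated on a ``grid_step``-arcmin grid; the contour level enclosing
    ``mass`` of the probability (68.27% — the 2-D one-sigma mass — by
    default) is found and the enclosed area returned, summing disjoint
    contours.  Requires >= 10 distinct points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 10:
        raise ValueError("ISOA needs at least 10 points")
    if np.allclose(pts.std(axis=0), 0.0):
        raise ValueError("all points identical; ISOA undefined")
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    bw = float(kde.factor)
    span = 4.0 * bw * pts.std(axis=0).max() + 1.0
    x = np.arange(pts[:, 0].min() - span, pts[:, 0].max() + span, grid_step)
    y = np.arange(pts[:, 1].min() - span, pts[:, 1].max() + span, grid_step)
    gx, gy = np.meshgrid(x, y)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gy.shape)
    cell = grid_step * grid_step
    order = np.argsort(dens.ravel())[::-1]
    cum = np.cumsum(dens.ravel()[order]) * cell
    k = int(np.searchsorted(cum, mass))
    k = min(k, order.size - 1)
    level = float(dens.ravel()[order[k]])
    area = float((dens >= level).sum()) * cell
    contours = []
    for c in measure.find_contours(dens, level):
        poly = np.column_stack([x[0] + c[:, 1] * grid_step,
                                y[0] + c[:, 0] * grid_step])
        contours.append(poly)
    return ISOAResult(area=area, contours=contours, bandwidth_factor=bw,
                      mass=mass, level=level)


def convergence_ratio(trace: GazeTrace, landmark: tuple[float, float]) -> float:
    """Fractional distance convergence toward a landmark over the trial.

    1 - (offset distance / onset distance); positive values mean the drift
    brought the stimulus closer to the landmark.
    """
    _, xy = trace.window_samples()
    lm = np.asarray(landmark, dtype=float)
    d_on = float(np.linalg.norm(xy[0] - lm))
    if d_on == 0.0:
        raise ValueError("onset coincides with the landmark")
    d_off = float(np.linalg.norm(xy[-1] - lm))
    return 1.0 - d_off / d_on


def sampling_gain(series) -> float:
    """Achieved sampling gain: max within-trial density over onset density."""
    onset = series.onset_density
    if not np.isfinite(onset) or onset <= 0:
        raise ValueError("undefined onset frame")
    peak = float(np.nanmax(series.densities[series.defined]))
    return peak / onset


def potential_sampling_gain(landmarks, series) -> float:
    """Potential gain: density at the CDC over the onset sampling density.

    The maximum gain the eye could have achieved by re-centering the
    stimulus on the cone density centroid.
    """
    onset = series.onset_density
    if not np.isfinite(onset) or onset <= 0:
        raise ValueError("undefined onset frame")
    return float(landmarks.cdc_density) / onset


@dataclass(frozen=True)
class DriftMetrics:
    """Scalar drift statistics of one included trial."""

    trial_id: int
    drift_length: float
    drift_velocity: float
    theta_retina: float
    theta_cdc: float
    theta_prl: float
    theta_pcd: float
    onset_distance_cdc: float
    convergence_cdc: float
    convergence_prl: float
    convergence_pcd: float
    sampling_gain: float = float("nan")


def trial_drift_metrics(trace: GazeTrace, landmarks, series=None) -> DriftMetrics:
    """All per-trial drift metrics for one gaze trace.

    ``landmarks`` is a FoveolarLandmarks; PRL-relative entries are NaN when
    no PRL was supplied.  ``series`` (optional SamplingDensitySeries) adds
    the achieved sampling gain.
    """
    _, xy = trace.window_samples()
    cdc = np.asarray(landmarks.cdc_location)

    def _per_landmark(name):
        try:
            lm = landmarks.location(name)
        except ValueError:
            return float("nan"), float("nan")
        return angle_to_landmark(trace, lm), convergence_ratio(trace, lm)

    th_cdc, cv_cdc = _per_landmark("cdc")
    th_prl, cv_prl = _per_landmark("prl")
    th_pcd, cv_pcd = _per_landmark("pcd")
    return DriftMetrics(
        trial_id=trace.trial_id,
        drift_length=drift_length(trace),
        drift_velocity=drift_velocity(trace),
        theta_retina=drift_direction(trace),
        theta_cdc=th_cdc, theta_prl=th_prl, theta_pcd=th_pcd,
        onset_distance_cdc=float(np.linalg.norm(xy[0] - cdc)),
        convergence_cdc=cv_cdc, convergence_prl=cv_prl, convergence_pcd=cv_pcd,
        sampling_gain=(sampling_gain(series) if series is not None
                       else float("nan")),
    )


@dataclass(frozen=True)
class DirectionalityStats:
    """Population directionality summary relative to one landmark."""

    landmark: str
    quadrant_frequencies: np.ndarray  # toward, ccw, away, cw
    tuning_ratio: float
    rayleigh_r: float
    rayleigh_p: float
    n_trials: int


def aggregate_directionality(metrics: list[DriftMetrics], landmarks
                             ) -> dict[str, DirectionalityStats]:
    """Quadrant frequencies, tuning ratio and Rayleigh p per landmark.

    Trials with undefined angles (zero net displacement, onset at the
    landmark, or missing PRL) are dropped from that landmark's statistics.
    """
    out: dict[str, DirectionalityStats] = {}
    for name, attr in (("cdc", "theta_cdc"), ("prl", "theta_prl"),
                       ("pcd", "theta_pcd")):
        a = np.asarray([getattr(m, attr) for m in metrics], dtype=float)
        a = a[~np.isnan(a)]
        if a.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ratio = tuning_ratio(a)
        if a.size >= 5:
            r_bar, p = rayleigh_test(a)
        else:
            r_bar, p = float("nan"), float("nan")
        out[name] = DirectionalityStats(
            landmark=name, quadrant_frequencies=_quadrant_frequencies(a),
            tuning_ratio=ratio, rayleigh_r=r_bar, rayleigh_p=p,
            n_trials=int(a.size))
    return out
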