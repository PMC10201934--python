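"""Run-level statistics: step lengths, photon counts, directionality, timing.

Definitions follow the two-level averaging convention: the electron mean
step length is the average over tracks of the within-track mean step
length, and the mean track length is the average over tracks of the summed
step length per track (track-first averaging, not pooled over all steps).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TrackStats",
    "RunSummary",
    "track_stats",
    "cerenkov_count_stats",
    "xz_angle",
    "order_resolved_angles",
    "backward_fraction",
    "detection_histograms",
    "DetectionHistograms",
]


@dataclass
class TrackStats:
    mean_step_length_um: float
    mean_track_length_um: float
    mean_steps_per_track: float


def _step_lengths_mm(track) -> np.ndarray:
    """Accept an ElectronTrack or a plain sequence of step lengths (mm)."""
    if hasattr(track, "length"):
        return np.asarray(track.length, dtype=float)
    return np.asarray(track, dtype=float)


def track_stats(tracks) -> TrackStats:
    """Two-level electron step statistics, in micrometres.

    mean step length = mean over tracks of (mean step length within track);
    mean track length = mean over tracks of (sum of step lengths).
    """
    if not len(tracks):
        raise ValueError("track list must be nonempty")
    per_track_mean = []
    per_track_sum = []
    per_track_n = []
    for t in tracks:
        lengths = _step_lengths_mm(t)
        if lengths.size == 0:
            continue
        per_track_mean.append(lengths.mean())
        per_track_sum.append(lengths.sum())
        per_track_n.append(lengths.size)
    if not per_track_mean:
        raise ValueError("no track contains any step")
    return TrackStats(
        mean_step_length_um=float(np.mean(per_track_mean)) * 1000.0,
        mean_track_length_um=float(np.mean(per_track_sum)) * 1000.0,
        mean_steps_per_track=float(np.mean(per_track_n)),
    )


def _gauss(x, mu, sigma, a):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def cerenkov_count_stats(event_counts) -> tuple[float, float]:
    """Gaussian-fit mean and sigma of the per-event photon count histogram.

    Least-squares Gaussian fit to the unit-binned count histogram with
    Poisson bin weights; returns the fitted mean (not the sample mean).
    Degenerate all-equal inputs return (value, 0).
    """
    counts = np.asarray(event_counts, dtype=float)
    if counts.size < 50:
        raise ValueError("need at least 50 events for a stable fit")
    if np.all(counts == counts[0]):
        return float(counts[0]), 0.0
    lo, hi = int(counts.min()), int(counts.max())
    edges = np.arange(lo - 0.5, hi + 1.5)
    hist, _ = np.histogram(counts, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (counts.mean(), max(counts.std(), 0.5), hist.max())
    sigma_w = np.sqrt(np.maximum(hist, 1.0))
    try:
        popt, _ = curve_fit(
            _gauss, centers, hist, p0=p0, sigma=sigma_w, absolute_sigma=False, maxfev=20000
        )
        return float(popt[0]), float(abs(popt[1]))
    except RuntimeError:
        return float(counts.mean()), float(counts.std())


def xz_angle(momentum) -> float:
    """Angle (degrees, [0, 360)) of the x-z projection w.r.t. the gamma axis +z."""
    x, _, z = (float(v) for v in momentum)
    if x == 0.0 and z == 0.0:
        raise ValueError("momentum has no x-z projection")
    return math.degrees(math.atan2(x, z)) % 360.0


def _nth_photon_angles(events, order_index: int) -> np.ndarray:
    """x-z angles of the order_index-th Cerenkov photon of each event.

    ``events`` is a sequence of per-event photon lists ordered by emission;
    events with fewer photons (or with no x-z projection) are skipped.
    """
    if order_index < 1:
        raise ValueError("order index starts at 1")
    angles = []
    for photons in events:
        cer = [p for p in photons if getattr(p, "kind", "cerenkov") == "cerenkov"]
        if len(cer) < order_index:
            continue
        p = cer[order_index - 1]
        try:
            angles.append(xz_angle(p.direction))
        except ValueError:
            continue
    return np.asarray(angles)


def order_resolved_angles(events, order_index: int, bins: int = 36) -> np.ndarray:
    """Histogram (normalised to max = 1) of the i-th photon's x-z angle."""
    angles = _nth_photon_angles(events, order_index)
    if angles.size == 0:
        raise ValueError(f"no event has a photon of order {order_index}")
    hist, _ = np.histogram(angles, bins=bins, range=(0.0, 360.0))
    return hist / hist.max()


def backward_fraction(events, order_index: int, bin_width: float = 10.0) -> float:
    """Fraction of events whose i-th photon points within ±bin_width/2 of 180°."""
    angles = _nth_photon_angles(events, order_index)
    if angles.size == 0:
        raise ValueError(f"no event has a photon of order {order_index}")
    half = bin_width / 2.0
    return float(np.mean(np.abs(angles - 180.0) <= half))


@dataclass
class DetectionHistograms:
    path_edges_mm: np.ndarray
    path_hist: np.ndarray
    time_edges_ns: np.ndarray
    time_hist: np.ndarray
    mean_path_mm: float
    mean_detection_time_ns: float
    mean_transit_ns: float


def detection_histograms(detected, n_path_bins: int = 40, n_time_bins: int = 60) -> DetectionHistograms:
    """Path-length (log bins, 0.1-200 mm) and detection-time histograms."""
    if not len(detected):
        raise ValueError("no detected photons")
    paths = np.array([d.path_length for d in detected])
    times = np.array([d.detection_time for d in detected])
    transits = np.array([d.transit_time for d in detected])
    path_edges = np.geomspace(0.1, 200.0, n_path_bins + 1)
    path_hist, _ = np.histogram(paths, bins=path_edges)
    time_edges = np.linspace(0.0, max(float(times.max()) * 1.05, 1e-3), n_time_bins + 1)
    time_hist, _ = np.histogram(times, bins=time_edges)
    return DetectionHistograms(
        path_edges_mm=path_edges,
        path_hist=path_hist,
        time_edges_ns=time_edges,
        time_hist=time_hist,
        mean_path_mm=float(paths.mean()),
        mean_detection_time_ns=float(times.mean()),
        mean_transit_ns=float(transits.mean()),
    )


@dataclass
class RunSummary:
    """Everything the analysis extracts from one simulation run."""

    delta_beta: float | None
    n_events: int
    seed: int
    mean_step_length_um: float
    mean_track_length_um: float
    mean_steps_per_track: float
    cerenkov_fit_mean: float
    cerenkov_fit_sigma: float
    cerenkov_sample_mean: float
    first_step_length_mm: float
    angular_histograms: dict = field(default_factory=dict)  # order -> list
    backward_fractions: dict = field(default_factory=dict)  # order -> float
    n_detected: int = 0
    n_emitted: int = 0
    mean_path_mm: float = float("nan")
    mean_detection_time_ns: float = float("nan")
    mean_transit_ns: float = float("nan")
    loss_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["angular_histograms"] = {
            str(k): list(np.asarray(v, dtype=float)) for k, v in self.angular_histograms.items()
        }
        d["backward_fractions"] = {str(k): float(v) for k, v in self.backward_fractions.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
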