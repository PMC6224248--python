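"""Cross-device harmonization of high-frequency accelerometry.

Wrist-worn research accelerometers record tri-axial acceleration at
~100 Hz, while the reference alphabet of activity states is defined on
per-minute activity counts from a different (hip-worn) device.  The
bridge: split the raw magnitude signal into 1-minute slices, take the
natural log of the summed Welch power spectral density of each slice
(512-point Hann segments, 50% overlap), then choose new bin edges so that
the pooled occupancy fractions of the resulting activity states match a
reference cohort's occupancy fractions (quantile normalization).  Because
the per-minute value is a monotone function of movement intensity and
quantile matching is invariant under monotone transforms, the harmonized
state sequences are device-independent up to sampling noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .markov import DiscretizationScheme, StateSequence, discretize

__all__ = [
    "RawAccelTrack",
    "HarmonizationRef",
    "filter_hardware_errors",
    "downsample_raw",
    "trim_by_mean_activity",
    "occupancy_fractions",
    "fit_quantile_bins",
    "harmonize_values",
]

MAX_HARDWARE_ERRORS = 10
WELCH_NPERSEG = 512
PSD_SUM_EPS = 1e-12
TRIM_FRACTION = 1.0 / 6.0


@dataclass
class RawAccelTrack:
    """High-frequency acceleration-magnitude record for one participant."""

    participant_id: str
    fs: float
    magnitude: np.ndarray
    hardware_error_count: int | None = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if not np.all(np.isfinite(self.magnitude)):
            raise ValueError("magnitude series must be finite")

    @staticmethod
    def magnitude_from_triaxial(ax, ay, az) -> np.ndarray:
        """Euclidean norm of the three axes (the 'absolute acceleration')."""
        return np.sqrt(
            np.asarray(ax, float) ** 2
            + np.asarray(ay, float) ** 2
            + np.asarray(az, float) ** 2
        )


@dataclass
class HarmonizationRef:
    """Reference occupancy fractions and the fitted target bin edges."""

    reference_p: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.reference_p, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("occupancy fractions must be non-negative and sum to 1")
        self.reference_p = p
        e = np.asarray(self.edges, dtype=float)
        if not np.all(np.diff(e) > 0):
            raise ValueError("fitted edges must be strictly increasing")
        self.edges = e

    def scheme(self) -> DiscretizationScheme:
        return DiscretizationScheme(edges=self.edges, require_positive=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"reference_p": self.reference_p.tolist(),
                 "edges": self.edges.tolist()},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "HarmonizationRef":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["reference_p"]), np.asarray(d["edges"]))


def filter_hardware_errors(
    raws: list[RawAccelTrack], max_errors: int = MAX_HARDWARE_ERRORS
) -> tuple[list[RawAccelTrack], list[dict]]:
    """Retain tracks with at most ``max_errors`` hardware errors.

    A missing error count is itself treated as an error condition and the
    track is excluded with a reason.
    """
    retained, excluded = [], []
    for r in raws:
        if r.hardware_error_count is None:
            excluded.append(
                {"participant_id": r.participant_id,
                 "reason": "missing_error_count"}
            )
        elif r.hardware_error_count > max_errors:
            excluded.append(
                {"participant_id": r.participant_id,
                 "reason": "hardware_errors",
                 "count": int(r.hardware_error_count)}
            )
        else:
            retained.append(r)
    return retained, excluded


def downsample_raw(
    raw: RawAccelTrack,
    nperseg: int = WELCH_NPERSEG,
    eps: float = PSD_SUM_EPS,
) -> np.ndarray:
    """Per-minute log-summed Welch PSD of the magnitude signal.

    Each 1-minute slice is reduced to ``ln(sum of its Welch PSD)`` using
    512-point Hann segments with 50% overlap.  A trailing partial minute
    is discarded.  Slices shorter than one Welch segment cannot be
    estimated and come back as NaN (flagged missing).  The PSD sum is
    floored at ``eps`` before the log; by Parseval the value tracks the
    slice variance, so scaling the signal by c shifts it by exactly
    2 ln c.
    """
    n_per_min = int(round(raw.fs * 60.0))
    n_slices = raw.magnitude.size // n_per_min
    if n_slices == 0:
        raise ValueError("track shorter than one minute")
    if n_per_min < nperseg:
        return np.full(n_slices, np.nan)
    sl = raw.magnitude[: n_slices * n_per_min].reshape(n_slices, n_per_min)
    _, psd = scipy.signal.welch(
        sl, fs=raw.fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, axis=-1,
    )
    total = psd.sum(axis=-1)
    return np.log(np.maximum(total, eps))


def trim_by_mean_activity(
    items: list, means: np.ndarray, fraction: float = TRIM_FRACTION
) -> tuple[list, np.ndarray]:
    """Drop the lowest and highest ``fraction`` of items by mean activity.

    Used to build trimmed reference cohorts whose central activity range
    is comparable across devices.  Returns retained items and their
    indices in the original list.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    means = np.asarray(means, dtype=float)
    n = len(items)
    if means.size != n:
        raise ValueError("one mean per item required")
    k = int(n * fraction)
    if fraction > 0 and (k == 0 or n - 2 * k < 1):
        raise ValueError(f"too few items ({n}) to trim fraction {fraction}")
    order = np.argsort(means, kind="stable")
    keep = np.sort(order[k: n - k])
    return [items[i] for i in keep], keep


def occupancy_fractions(
    state_sequences, n_states: int = 8
) -> np.ndarray:
    """Fraction of minutes spent in each state, pooled over all sequences."""
    parts = []
    for s in state_sequences:
        parts.append(s.states if isinstance(s, StateSequence) else np.asarray(s))
    combined = np.concatenate(parts) if parts else np.array([], dtype=int)
    if combined.size == 0:
        raise ValueError("no states supplied")
    return np.bincount(combined, minlength=n_states) / combined.size


def fit_quantile_bins(
    reference_p: np.ndarray, target_values: np.ndarray
) -> HarmonizationRef:
    """Fit target bin edges reproducing the reference occupancy fractions.

    The edges are the empirical quantiles of the pooled target values at
    the cumulative reference fractions; discretizing the target values
    with them reproduces ``reference_p`` up to sampling error.  A zero
    occupancy fraction for an interior state would force two edges to
    coincide and is rejected.
    """
    p = np.asarray(reference_p, dtype=float)
    if np.any(p[1:-1] == 0):
        raise ValueError(
            "zero reference occupancy for an interior state: degenerate edges"
        )
    values = np.asarray(target_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10 * p.size:
        raise ValueError("too few target values relative to the alphabet size")
    cum = np.cumsum(p)[:-1]
    edges = np.quantile(values, cum)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("fitted edges are not strictly increasing")
    return HarmonizationRef(reference_p=p, edges=edges)


def harmonize_values(
    values: np.ndarray, ref: HarmonizationRef
) -> StateSequence:
    """Discretize per-minute harmonized values with the fitted edges."""
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("cannot discretize missing (NaN) per-minute values")
    return discretize(values, ref.scheme())
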