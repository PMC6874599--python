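"""Head rotational-velocity profiles: containers, CSV I/O, resampling, peaks.

A head impact is represented by the 3-DOF angular-velocity time history of the
head, expressed in the anatomical frame: x anterior, y left, z superior (the
mid-sagittal plane therefore has its normal along y).  Profiles are stored as a
3xT array of rad/s sampled at a uniform step ``dt`` (milliseconds).  All
downstream encoding assumes a 200 ms window at 1 ms resolution, so profiles
longer than 200 ms are rejected at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: encoding window length in milliseconds; longer profiles cannot be encoded
MAX_SPAN_MS = 200.0

CSV_COLUMNS = ["impact_id", "time_ms", "wx", "wy", "wz"]


class ProfileError(ValueError):
    """Raised for malformed or out-of-contract velocity profiles."""


@dataclass(frozen=True)
class VelocityProfile:
    """A 3-channel angular-velocity time history in the head anatomical frame.

    Parameters
    ----------
    impact_id : str
        Identifier of the impact (unique within a dataset).
    dt : float
        Sampling interval in milliseconds (> 0).
    samples : ndarray, shape (3, T)
        Angular velocity in rad/s; rows ordered x (anterior), y (left),
        z (superior).
    """

    impact_id: str
    dt: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != 3:
            raise ProfileError(
                f"{self.impact_id}: samples must be 3xT, got shape {arr.shape}"
            )
        if arr.shape[1] < 2:
            raise ProfileError(f"{self.impact_id}: need at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ProfileError(f"{self.impact_id}: non-finite samples")
        if self.dt <= 0:
            raise ProfileError(f"{self.impact_id}: dt must be positive")
        # span counts intervals, not samples: a 201-sample, 1 ms profile
        # covers 0..200 ms and is exactly the encoding window
        if (arr.shape[1] - 1) * self.dt > MAX_SPAN_MS:
            raise ProfileError(
                f"{self.impact_id}: profile exceeds 200 ms window "
                f"({arr.shape[1]} samples at {self.dt} ms)"
            )
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.n_samples) * self.dt

    def with_samples(self, samples: np.ndarray, suffix: str = "") -> "VelocityProfile":
        """Copy with new samples, optionally suffixing the impact id."""
        ident = self.impact_id + suffix if suffix else self.impact_id
        return VelocityProfile(ident, self.dt, samples)


@dataclass(frozen=True)
class PeakInfo:
    """Location and magnitude of the peak resultant angular velocity."""

    peak_index: int
    peak_time: float
    peak_magnitude: float


def resultant(profile: VelocityProfile) -> np.ndarray:
    """Resultant (Euclidean-norm) angular-velocity magnitude, length T."""
    return np.linalg.norm(profile.samples, axis=0)


def peak_resultant(profile: VelocityProfile) -> PeakInfo:
    """Peak of the resultant; ties broken by the earliest sample index."""
    res = resultant(profile)
    idx = int(np.argmax(res))  # argmax returns the first maximal index
    return PeakInfo(idx, idx * profile.dt, float(res[idx]))


def resample(profile: VelocityProfile, dt: float = 1.0) -> VelocityProfile:
    """Resample to a uniform grid of step ``dt`` ms by linear interpolation."""
    if abs(profile.dt - dt) < 1e-12:
        return profile
    t_old = profile.times
    t_new = np.arange(0.0, t_old[-1] + 1e-9, dt)
    samples = np.vstack([np.interp(t_new, t_old, ch) for ch in profile.samples])
    return VelocityProfile(profile.impact_id, dt, samples)


def _profile_from_rows(impact_id: str, time_ms: np.ndarray, w: np.ndarray,
                       dt: float) -> VelocityProfile:
    """Build a uniform-dt profile from (possibly non-uniform) sampled rows."""
    d = np.diff(time_ms)
    if np.any(d <= 0):
        raise ProfileError(f"{impact_id}: time_ms not strictly increasing")
    span = time_ms[-1] - time_ms[0]
    if span > MAX_SPAN_MS:
        raise ProfileError(f"{impact_id}: impact exceeds 200 ms window ({span} ms)")
    t0 = time_ms - time_ms[0]
    if np.allclose(d, dt, rtol=0, atol=1e-9):
        samples = w.T
    else:
        t_new = np.arange(0.0, t0[-1] + 1e-9, dt)
        samples = np.vstack([np.interp(t_new, t0, w[:, j]) for j in range(3)])
    return VelocityProfile(impact_id, dt, samples)


def read_profiles(path, dt: float = 1.0) -> list[VelocityProfile]:
    """Read velocity profiles from a CSV file.

    The CSV must carry columns impact_id, time_ms, wx, wy, wz with one row per
    sample and strictly increasing time within each impact.  Non-uniformly
    sampled impacts are resampled to a uniform ``dt`` (default 1 ms) by linear
    interpolation.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileError(f"{path}: missing columns {missing}")
    profiles = []
    for impact_id, grp in df.groupby("impact_id", sort=False):
        t = grp["time_ms"].to_numpy(dtype=float)
        w = grp[["wx", "wy", "wz"]].to_numpy(dtype=float)
        profiles.append(_profile_from_rows(str(impact_id), t, w, dt))
    return profiles


def write_profiles(profiles: list[VelocityProfile], path) -> None:
    """Write profiles to the same CSV dialect accepted by :func:`read_profiles`."""
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "impact_id": p.impact_id,
            "time_ms": p.times,
            "wx": p.samples[0],
            "wy": p.samples[1],
            "wz": p.samples[2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
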