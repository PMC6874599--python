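"""Fixed-size image-style encoding of velocity profiles for the CNN.

Each profile is reformatted into a 3 x 201 matrix: 201 time points spanning
0-200 ms at 1 ms resolution.  The three components are shifted synchronously
so that the *resultant* peak sits exactly at 100 ms, and both borders are
padded by replicating the first/last recorded sample of each channel, which
keeps the angular acceleration exactly zero inside the padding.  Pinning the
peak removes temporal-alignment variation that the network would otherwise
have to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .kinematics import VelocityProfile, peak_resultant, resample

#: number of time samples in the encoded input (0..200 ms inclusive at 1 ms)
N_TIME = 201
#: index at which the resultant peak is pinned (100 ms)
PEAK_INDEX = 100


class EncodingError(ValueError):
    """Raised when a profile cannot be placed in the 201-sample window."""


@dataclass(frozen=True)
class InputMatrix:
    """A 3 x 201 encoded network input."""

    impact_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3, N_TIME):
            raise EncodingError(
                f"{self.impact_id}: encoded matrix must be 3x{N_TIME}, got {v.shape}")
        object.__setattr__(self, "values", v)


def encode(profile: VelocityProfile) -> InputMatrix:
    """Encode one profile as a peak-centred, border-replicated 3x201 matrix.

    The profile is resampled to 1 ms if needed.  If pinning the peak at
    100 ms would push recorded samples outside the 0-200 ms window the
    profile is rejected (it does not fit the encoding, which is sized to
    accommodate all impacts of interest).
    """
    p = resample(profile, 1.0)
    peak = peak_resultant(p)
    offset = PEAK_INDEX - peak.peak_index
    if offset < 0 or offset + p.n_samples > N_TIME:
        raise EncodingError(
            f"{p.impact_id}: cannot pin peak at 100 ms without truncation "
            f"(peak at {peak.peak_index} ms of {p.n_samples} samples)")
    out = np.empty((3, N_TIME))
    out[:, :offset] = p.samples[:, :1]
    out[:, offset:offset + p.n_samples] = p.samples
    out[:, offset + p.n_samples:] = p.samples[:, -1:]
    return InputMatrix(p.impact_id, out)


def encode_batch(
    profiles: list[VelocityProfile],
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Encode many profiles into a stacked (N, 3, 201) array.

    Returns the stacked array, the impact ids in order, and a list of
    (impact_id, reason) pairs for profiles that failed to encode.  Order of
    successful encodings follows the input order.
    """
    mats, ids, failures = [], [], []
    for p in profiles:
        try:
            m = encode(p)
        except (EncodingError, ValueError) as exc:
            failures.append((p.impact_id, str(exc)))
            continue
        mats.append(m.values)
        ids.append(m.impact_id)
    stacked = np.stack(mats) if mats else np.empty((0, 3, N_TIME))
    return stacked, ids, failures


def save_encoded(path, inputs: np.ndarray, labels: np.ndarray,
                 ids: list[str], measures: list[str]) -> None:
    """Write an encoded dataset to an HDF5 container.

    Layout: datasets ``inputs`` (N x 3 x 201), ``labels`` (N x M, one column
    per strain measure), ``ids`` (N strings); the measure names are stored as
    a ``measures`` attribute on ``labels``.
    """
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if labels.shape[0] != inputs.shape[0]:
        labels = labels.T
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=np.asarray(inputs, dtype=float))
        dl = f.create_dataset("labels", data=labels)
        dl.attrs["measures"] = [str(m) for m in measures]
        f.create_dataset("ids", data=np.array(ids, dtype=h5py.string_dtype()))


def load_encoded(path) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Read back a container written by :func:`save_encoded`."""
    with h5py.File(path, "r") as f:
        inputs = f["inputs"][...]
        labels = f["labels"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][...]]
        measures = [str(m) for m in f["labels"].attrs["measures"]]
    return inputs, labels, ids, measures
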