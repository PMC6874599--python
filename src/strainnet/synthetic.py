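"""Synthetic impact generator and closed-form strain oracle.

Real head-impact recordings and finite-element strain labels are not
distributable with this package, so end-to-end exercise of the pipeline
relies on (a) a generator of impact-like rotational-velocity pulses and
(b) a smooth, closed-form "oracle" that plays the role of the head model:
a deterministic map from a velocity profile to a scalar strain that has the
key structural properties of simulated brain strain — non-negative,
saturating and strongly nonlinear in impact severity, direction dependent,
and exactly symmetric about the mid-sagittal plane (so a mirrored impact has
an identical scalar strain, the property that justifies conjugate-axis
reuse during augmentation).

The oracle is a package construct for testing the learning machinery; its
constants are not physical and it makes no claim of biofidelity.

Generator
---------
Each impact is a raised-sine-squared resultant pulse

    v(t) = A sin^2(pi t / T_d),  t in [0, T_d]

along one random unit direction, optionally followed by a reversed pulse
(direction negated) of amplitude f*A, emulating acceleration, deceleration
and velocity reversal seen in on-field impacts.  Durations are tens of ms
and peak amplitudes span sub-injurious to severe (5-40 rad/s).

Oracle
------
    strain = eps_max * H(p) * D(u) * S (+ optional Gaussian noise, >= 0)

with p the peak resultant, H a Hill-type saturation p^n / (p^n + v50^n),
D a direction factor (1 + a_x u_x^2 + a_y u_y^2 + a_z u_z^2) / (1 + max a)
built from even powers so it is mirror-invariant, and S = 1 + b * min(1,
TV / (2 p)) a waveform-complexity factor driven by the total variation TV of
the resultant (a single clean pulse has TV = 2 p; reversals raise it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationConfig, augment_dataset
from .cnn import StrainMeasure
from .encode import encode_batch, save_encoded
from .kinematics import VelocityProfile, peak_resultant, resultant


@dataclass(frozen=True)
class ProfileGenParams:
    """Synthetic impact-pulse generator parameters (durations in ms,
    amplitudes in rad/s)."""

    n_impacts: int = 110
    duration_range: tuple = (10.0, 60.0)
    peak_range: tuple = (5.0, 40.0)
    reversal_probability: float = 0.3
    reversal_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.duration_range
        plo, phi = self.peak_range
        if not (0 < lo < hi and 0 < plo < phi):
            raise ValueError("ranges must be positive and ordered")
        if not 0 <= self.reversal_probability <= 1:
            raise ValueError("reversal_probability must be in [0, 1]")
        if not 0 < self.reversal_fraction < 1:
            raise ValueError("reversal_fraction must be in (0, 1)")


#: per-measure direction weights (a_x, a_y, a_z): the three regression
#: targets weight the rotation direction differently so they are genuinely
#: distinct tasks
DIRECTION_WEIGHTS = {
    StrainMeasure.MPS_WB_95: (0.2, 0.4, 0.3),
    StrainMeasure.MPS_CC_95: (0.1, 0.6, 0.2),
    StrainMeasure.FS_CC_95: (0.5, 0.3, 0.1),
}

#: per-measure strain ceilings eps_max
EPS_MAX = {
    StrainMeasure.MPS_WB_95: 0.45,
    StrainMeasure.MPS_CC_95: 0.35,
    StrainMeasure.FS_CC_95: 0.25,
}


@dataclass(frozen=True)
class OracleParams:
    """Closed-form strain-oracle parameters (non-physical constants)."""

    eps_max: dict = field(default_factory=lambda: dict(EPS_MAX))
    v50: float = 30.0
    hill_n: float = 3.0
    direction_weights: dict = field(
        default_factory=lambda: dict(DIRECTION_WEIGHTS))
    shape_gain: float = 0.3
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v50 <= 0 or self.hill_n < 1 or self.noise_sd < 0:
            raise ValueError("invalid oracle parameters")
        if any(v <= 0 for v in self.eps_max.values()):
            raise ValueError("eps_max must be positive")


def generate_profiles(params: ProfileGenParams) -> list[VelocityProfile]:
    """Draw ``n_impacts`` synthetic impact profiles, sampled at 1 ms."""
    rng = np.random.default_rng(params.seed)
    profiles = []
    for i in range(params.n_impacts):
        dur = rng.uniform(*params.duration_range)
        amp = rng.uniform(*params.peak_range)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        t = np.arange(0.0, dur + 1e-9, 1.0)
        pulse = amp * np.sin(np.pi * t / dur) ** 2
        if rng.random() < params.reversal_probability:
            t2 = np.arange(1.0, dur + 1e-9, 1.0)
            pulse2 = -params.reversal_fraction * amp * np.sin(np.pi * t2 / dur) ** 2
            scalar = np.concatenate([pulse, pulse2])
        else:
            scalar = pulse
        profiles.append(VelocityProfile(f"syn{i:04d}", 1.0,
                                        u[:, None] * scalar[None, :]))
    return profiles


def oracle_strain(profile: VelocityProfile,
                  measure: StrainMeasure,
                  params: OracleParams | None = None,
                  rng: np.random.Generator | None = None) -> float:
    """Closed-form strain label for one profile (see module docstring).

    Deterministic when ``noise_sd`` is zero; a zero-motion profile maps to
    zero strain.  With noise the result is clamped at zero.
    """
    params = params or OracleParams()
    measure = StrainMeasure(measure)
    peak = peak_resultant(profile)
    p = peak.peak_magnitude
    if p <= 0:
        return 0.0
    n = params.hill_n
    hill = p ** n / (p ** n + params.v50 ** n)
    u = profile.samples[:, peak.peak_index] / p
    ax, ay, az = params.direction_weights[measure]
    direction = (1.0 + ax * u[0] ** 2 + ay * u[1] ** 2 + az * u[2] ** 2) \
        / (1.0 + max(ax, ay, az))
    tv = float(np.sum(np.abs(np.diff(resultant(profile)))))
    shape = 1.0 + params.shape_gain * min(1.0, tv / (2.0 * p))
    eps = params.eps_max[measure] * hill * direction * shape
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        eps += rng.normal(0.0, params.noise_sd)
    return max(0.0, float(eps))


def label_profiles(profiles: list[VelocityProfile],
                   params: OracleParams | None = None,
                   measures: tuple = tuple(StrainMeasure)) -> np.ndarray:
    """Oracle labels for a list of profiles; shape (N, len(measures))."""
    params = params or OracleParams()
    rng = np.random.default_rng(params.seed) if params.noise_sd > 0 else None
    return np.array([[oracle_strain(p, m, params, rng) for m in measures]
                     for p in profiles])


def make_dataset(gen: ProfileGenParams | None = None,
                 oracle: OracleParams | None = None,
                 aug: AugmentationConfig | None = None,
                 out_path=None):
    """generate -> augment -> label -> encode, the full synthetic pipeline.

    Labels are computed *after* augmentation (rotation and rescaling change
    the oracle's inputs, just as each augmented impact would be re-simulated
    by a head model).  Returns (inputs, labels, ids, measures) and, if
    ``out_path`` is given, also writes the HDF5 container.
    """
    gen = gen or ProfileGenParams()
    oracle = oracle or OracleParams()
    aug = aug or AugmentationConfig()
    base = generate_profiles(gen)
    augmented, _ = augment_dataset(base, aug)
    labels = label_profiles(augmented, oracle)
    inputs, ids, failures = encode_batch(augmented)
    if failures:
        raise RuntimeError(f"encoding failed for {failures}")
    measures = [m.value for m in StrainMeasure]
    if out_path is not None:
        save_encoded(out_path, inputs, labels, ids, measures)
    return inputs, labels, ids, measures
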