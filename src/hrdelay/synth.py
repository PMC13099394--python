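"""Synthetic multi-run, multi-session voxel BOLD timeseries generator.

Emulates the statistical structure the analysis assumes: raw scanner-like
intensities with a baseline near 1000 a.u., slow linear drift, Gaussian
noise, and a periodic stimulus-driven sinusoidal response whose amplitude
carries an orientation-tuned spatial pattern and whose delay is uniformly
lengthened for the plaid condition.  Voxels outside the cortical
representation of the stimulus annulus respond with inverted sign
(negative BOLD); a fraction of voxels emulate large draining veins (low
baseline, high amplitude, high variability).

The generated signal for voxel ``v`` at time ``t`` (s) under condition
``c`` is::

    raw(v, t) = baseline_v * (1 + drift_v * t
                                + (A_vc / 100) * sin(2*pi*(t - d_vc) / T))
                + Normal(0, noise_sd_v)

which peaks at ``t = T/4 + d_vc`` within each cycle (mid-ON for zero
delay), matching the phase convention of the sinusoidal GLM.  For grating
conditions ``A_vc = base_amplitude_v * (1 + kappa_v * cos 2(pref_v -
theta_c))``; the plaid uses the untuned base amplitude and adds a uniform
delay shift.  Negative-BOLD voxels use ``-A_vc`` (phase + pi).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .design import StudyDesign

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "VoxelDataset",
    "build_ground_truth",
    "simulate_run",
    "simulate_study",
]

#: orientation (deg) of each grating condition; plaid is untuned
GRATING_ORIENTATIONS = {"-45": -45.0, "+45": +45.0}


@dataclass(frozen=True)
class GeneratorParams:
    """Settings of the synthetic-study generator.

    Fractions, the stimulus annulus and the plaid delay shift follow the
    study conditions this package emulates; amplitude/noise/delay scales
    are realistic choices for 1 mm, TR 1 s gradient-echo EPI at 3 T (see
    the methods note).  All per-voxel quantities are drawn once into a
    :class:`GroundTruth` and then held fixed across runs and sessions.
    """

    annulus_inner_dva: float = 0.75
    annulus_outer_dva: float = 7.0
    field_max_dva: float = 10.0
    negbold_fraction: float = 0.33
    vein_fraction: float = 0.2
    plaid_delay_shift_seconds: float = 0.18
    #: between-participant SD of the plaid delay shift (s)
    plaid_delay_shift_sd: float = 0.08

    baseline_mean: float = 1000.0
    baseline_sd: float = 50.0
    #: voxel thermal+physiological noise SD, scanner units
    noise_sd_mean: float = 15.0
    noise_sd_spread: float = 3.0
    #: stimulus-driven response amplitude, %BOLD (half peak-to-peak)
    base_amplitude_mean: float = 1.2
    base_amplitude_sd: float = 0.3
    #: hemodynamic delay (s): participant mean drawn N(delay_mean, delay_between_sd)
    delay_mean: float = 5.0
    delay_between_sd: float = 0.5
    delay_within_sd: float = 0.3
    #: orientation tuning depth kappa of the amplitude modulation
    tuning_depth_mean: float = 0.3
    tuning_depth_sd: float = 0.1
    #: linear drift slope, fraction of baseline per second
    drift_sd: float = 1e-4

    # vein construction multipliers (relative to the non-vein median)
    vein_baseline_range: tuple[float, float] = (0.5, 0.8)
    vein_noise_range: tuple[float, float] = (2.0, 4.0)
    vein_amplitude_range: tuple[float, float] = (2.0, 4.0)

    # run/session-level hemodynamic state fluctuations
    run_delay_jitter_sd: float = 0.15
    run_amplitude_jitter_sd: float = 0.10
    session_delay_sd: float = 0.10
    session_amplitude_sd: float = 0.05

    #: optional second harmonic (fraction of A) widening the positive lobe
    second_harmonic_ratio: float = 0.0

    def validate(self, design: StudyDesign) -> None:
        for name in ("negbold_fraction", "vein_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.annulus_inner_dva < self.annulus_outer_dva < self.field_max_dva:
            raise ValueError("annulus limits must satisfy 0 < inner < outer < field_max")
        if self.plaid_delay_shift_seconds >= design.cycle_seconds:
            raise ValueError("plaid delay shift must be smaller than the cycle length")

    @classmethod
    def null(cls, **overrides) -> "GeneratorParams":
        """Parameters with zero condition effects (all three conditions share
        identical amplitude and delay parameters); used for calibration."""
        base = dict(
            tuning_depth_mean=0.0,
            tuning_depth_sd=0.0,
            plaid_delay_shift_seconds=0.0,
            plaid_delay_shift_sd=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        for k in ("vein_baseline_range", "vein_noise_range", "vein_amplitude_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-voxel generative parameters plus condition rules for one
    synthetic participant.  Deterministic for a fixed seed."""

    baseline_intensity: np.ndarray
    drift_slope: np.ndarray
    noise_sd: np.ndarray
    orientation_preference: np.ndarray
    tuning_depth: np.ndarray
    base_amplitude: np.ndarray
    base_delay: np.ndarray
    negbold_flag: np.ndarray
    vein_flag: np.ndarray
    plaid_delay_shift: float
    second_harmonic_ratio: float
    rng_seed: int

    @property
    def n_voxels(self) -> int:
        return self.baseline_intensity.size

    def condition_amplitude(self, condition: str) -> np.ndarray:
        """Signed %BOLD amplitude of each voxel under ``condition``."""
        if condition in GRATING_ORIENTATIONS:
            theta = np.deg2rad(GRATING_ORIENTATIONS[condition])
            pref = np.deg2rad(self.orientation_preference)
            amp = self.base_amplitude * (
                1.0 + self.tuning_depth * np.cos(2.0 * (pref - theta))
            )
        elif condition == "plaid":
            amp = self.base_amplitude.copy()
        else:
            raise ValueError(f"unknown condition label: {condition!r}")
        return np.where(self.negbold_flag, -amp, amp)

    def condition_delay(self, condition: str) -> np.ndarray:
        """Response delay (s) of each voxel under ``condition``."""
        if condition == "plaid":
            return self.base_delay + self.plaid_delay_shift
        if condition in GRATING_ORIENTATIONS:
            return self.base_delay.copy()
        raise ValueError(f"unknown condition label: {condition!r}")

    def to_json(self) -> str:
        d = {}
        for k, v in asdict(self).items():
            d[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        for k in (
            "baseline_intensity drift_slope noise_sd orientation_preference "
            "tuning_depth base_amplitude base_delay".split()
        ):
            d[k] = np.asarray(d[k], dtype=float)
        for k in ("negbold_flag", "vein_flag"):
            d[k] = np.asarray(d[k], dtype=bool)
        return cls(**d)


@dataclass
class VoxelDataset:
    """One session of run timeseries plus per-voxel metadata.

    ``runs`` has shape (n_runs, n_volumes, n_voxels) in raw scanner
    units; ``conditions`` gives the stimulus label of each run; ``meta``
    is the voxel table (voxel_id, eccentricity, polar_angle, roi_flag and,
    for synthetic data, the ground-truth flags).
    """

    session_id: int
    runs: np.ndarray
    conditions: list[str]
    meta: pd.DataFrame
    design: StudyDesign
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=float)
        if self.runs.ndim != 3:
            raise ValueError("runs must have shape (n_runs, n_volumes, n_voxels)")
        if self.runs.shape[0] != len(self.conditions):
            raise ValueError("one condition label per run is required")
        if self.runs.shape[2] != len(self.meta):
            raise ValueError("every timeseries column must map to one metadata row")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.runs.shape[2]


# ----------------------------------------------------------------------
def build_ground_truth(
    design: StudyDesign,
    n_voxels: int,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> tuple[GroundTruth, pd.DataFrame]:
    """Draw a synthetic participant: per-voxel generative parameters and
    visual-field metadata.

    Voxels flagged negative-BOLD are placed outside the stimulus annulus
    (eccentricity in [0, inner) or (outer, field_max]); stimulus-driven
    voxels inside it.  Vein voxels are constructed to sit below the
    non-vein median baseline and above the non-vein median noise SD and
    amplitude.

    Returns
    -------
    truth : GroundTruth
    meta : pandas.DataFrame
        Columns voxel_id, eccentricity, polar_angle, roi_flag,
        negbold_flag, vein_flag.
    """
    params = params or GeneratorParams()
    params.validate(design)
    if n_voxels < 10:
        raise ValueError("n_voxels must be >= 10")
    rng = np.random.default_rng(seed)

    inner, outer = params.annulus_inner_dva, params.annulus_outer_dva
    fmax = params.field_max_dva

    n_neg = int(round(params.negbold_fraction * n_voxels))
    negbold = np.zeros(n_voxels, dtype=bool)
    negbold[rng.choice(n_voxels, size=n_neg, replace=False)] = True

    # visual-field coordinates: stimulus-driven voxels inside the annulus,
    # negBOLD voxels in the surround (uniform over the complement's length)
    ecc = np.empty(n_voxels)
    ecc[~negbold] = rng.uniform(inner, outer, size=(~negbold).sum())
    u = rng.uniform(0.0, inner + (fmax - outer), size=n_neg)
    ecc[negbold] = np.where(u < inner, u, outer + (u - inner))
    polar = rng.uniform(0.0, 360.0, size=n_voxels)

    vein = np.zeros(n_voxels, dtype=bool)
    n_vein = int(round(params.vein_fraction * n_voxels))
    vein[rng.choice(n_voxels, size=n_vein, replace=False)] = True

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n_voxels)
    baseline = np.clip(baseline, 0.2 * params.baseline_mean, None)
    noise_sd = np.clip(
        rng.normal(params.noise_sd_mean, params.noise_sd_spread, size=n_voxels),
        0.1 * params.noise_sd_mean,
        None,
    )
    amplitude = np.clip(
        rng.normal(params.base_amplitude_mean, params.base_amplitude_sd, size=n_voxels),
        0.1 * params.base_amplitude_mean,
        None,
    )

    if n_vein and n_vein < n_voxels:
        # veins: low baseline, high variability, large responses — drawn
        # relative to non-vein medians so the construction rule holds exactly
        med_b = np.median(baseline[~vein])
        med_n = np.median(noise_sd[~vein])
        med_a = np.median(amplitude[~vein])
        baseline[vein] = med_b * rng.uniform(*params.vein_baseline_range, size=n_vein)
        noise_sd[vein] = med_n * rng.uniform(*params.vein_noise_range, size=n_vein)
        amplitude[vein] = med_a * rng.uniform(*params.vein_amplitude_range, size=n_vein)

    participant_delay = rng.normal(params.delay_mean, params.delay_between_sd)
    base_delay = rng.normal(participant_delay, params.delay_within_sd, size=n_voxels)
    shift = params.plaid_delay_shift_seconds
    if params.plaid_delay_shift_sd > 0:
        shift = rng.normal(shift, params.plaid_delay_shift_sd)
    if abs(shift) >= design.cycle_seconds:
        raise ValueError("drawn plaid delay shift exceeds the cycle length")

    truth = GroundTruth(
        baseline_intensity=baseline,
        drift_slope=rng.normal(0.0, params.drift_sd, size=n_voxels),
        noise_sd=noise_sd,
        orientation_preference=rng.uniform(0.0, 180.0, size=n_voxels),
        tuning_depth=np.clip(
            rng.normal(params.tuning_depth_mean, params.tuning_depth_sd, size=n_voxels),
            0.0,
            None,
        ),
        base_amplitude=amplitude,
        base_delay=base_delay,
        negbold_flag=negbold,
        vein_flag=vein,
        plaid_delay_shift=float(shift),
        second_harmonic_ratio=params.second_harmonic_ratio,
        rng_seed=int(seed),
    )
    meta = pd.DataFrame(
        {
            "voxel_id": np.arange(n_voxels),
            "eccentricity": ecc,
            "polar_angle": polar,
            "roi_flag": np.ones(n_voxels, dtype=bool),
            "negbold_flag": negbold,
            "vein_flag": vein,
        }
    )
    return truth, meta


def _signal(
    design: StudyDesign,
    truth: GroundTruth,
    condition: str,
    delay_offset: float = 0.0,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Noise-free raw-intensity signal, shape (n_volumes, n_voxels)."""
    t = design.run_times()[:, None]
    T = design.cycle_seconds
    amp = truth.condition_amplitude(condition)[None, :] * amplitude_scale
    delay = truth.condition_delay(condition)[None, :] + delay_offset
    wave = np.sin(2.0 * np.pi * (t - delay) / T)
    if truth.second_harmonic_ratio:
        wave = wave + truth.second_harmonic_ratio * np.sin(
            4.0 * np.pi * (t - delay) / T
        )
    rel = truth.drift_slope[None, :] * t + (amp / 100.0) * wave
    return truth.baseline_intensity[None, :] * (1.0 + rel)


def simulate_run(
    design: StudyDesign,
    truth: GroundTruth,
    condition: str,
    seed: int | np.random.Generator = 0,
    *,
    delay_offset: float = 0.0,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Simulate one run, shape (n_volumes, n_voxels), raw intensity units.

    ``delay_offset`` (s) and ``amplitude_scale`` model run/session-level
    global hemodynamic state; :func:`simulate_study` draws them.
    """
    if condition not in design.conditions:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {design.conditions}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    clean = _signal(design, truth, condition, delay_offset, amplitude_scale)
    noise = rng.normal(0.0, 1.0, size=clean.shape) * truth.noise_sd[None, :]
    return clean + noise


def simulate_study(
    design: StudyDesign,
    truth: GroundTruth,
    seed: int = 0,
    params: GeneratorParams | None = None,
    meta: pd.DataFrame | None = None,
) -> list[VoxelDataset]:
    """Simulate all sessions of one participant.

    Within each triplet of consecutive runs the three condition labels are
    independently randomly ordered.  Both sessions share the same
    :class:`GroundTruth`; session- and run-level global delay/amplitude
    fluctuations are drawn from ``params``.

    Returns one :class:`VoxelDataset` per session.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    if meta is None:
        meta = pd.DataFrame(
            {
                "voxel_id": np.arange(truth.n_voxels),
                "eccentricity": np.zeros(truth.n_voxels),
                "polar_angle": np.zeros(truth.n_voxels),
                "roi_flag": np.ones(truth.n_voxels, dtype=bool),
            }
        )
    sessions = []
    for ses in range(design.n_sessions):
        ses_delay = rng.normal(0.0, params.session_delay_sd)
        ses_scale = max(0.1, rng.normal(1.0, params.session_amplitude_sd))
        conditions: list[str] = []
        runs = np.empty(
            (design.n_runs_per_session, design.n_volumes, truth.n_voxels)
        )
        for trip in range(design.n_triplets_per_session):
            order = rng.permutation(3)
            for k, ci in enumerate(order):
                condition = design.conditions[ci]
                run_delay = ses_delay + rng.normal(0.0, params.run_delay_jitter_sd)
                run_scale = ses_scale * max(
                    0.1, rng.normal(1.0, params.run_amplitude_jitter_sd)
                )
                runs[3 * trip + k] = simulate_run(
                    design,
                    truth,
                    condition,
                    rng,
                    delay_offset=run_delay,
                    amplitude_scale=run_scale,
                )
                conditions.append(condition)
        sessions.append(
            VoxelDataset(
                session_id=ses,
                runs=runs,
                conditions=conditions,
                meta=meta,
                design=design,
                truth=truth,
            )
        )
    return sessions
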