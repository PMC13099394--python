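"""Timing and condition structure of the periodic visual-stimulation experiment.

A study consists of runs of periodic ON/OFF stimulation sampled at a fixed
TR.  Each run presents a single stimulus condition; conditions are grouped
in randomized triplets (one run per condition, order shuffled within each
triplet), several triplets per session, over two sessions.  The
:class:`StudyDesign` is the shared clock for every analysis stage: it fixes
the run length, the stimulus period, and how many initial cycles are
censored before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

__all__ = ["StudyDesign", "DEFAULT_CONDITIONS"]

DEFAULT_CONDITIONS: tuple[str, ...] = ("-45", "+45", "plaid")


@dataclass(frozen=True)
class StudyDesign:
    """Timing/condition structure of the periodic stimulation experiment.

    Defaults reproduce the study layout this package emulates: 120-volume
    runs at TR 1 s, ten 6 s-ON / 6 s-OFF cycles (12 s period), the first
    two cycles censored, three conditions in randomized triplets, two
    sessions.

    Parameters
    ----------
    tr_seconds : float
        Volume sampling interval (s).
    cycle_seconds : float
        Stimulus ON+OFF period (s); must be an integer multiple of
        ``tr_seconds``.
    n_cycles_per_run : int
        Stimulus cycles per run.
    n_censored_cycles : int
        Initial cycles excluded from all model fits (hemodynamic
        transient).
    conditions : tuple of str
        Exactly three condition labels; each triplet contains each label
        once.
    n_triplets_per_session : int
        Number of 3-run repetitions per session.
    n_sessions : int
        Number of repeated sessions (cross-validation folds).
    """

    tr_seconds: float = 1.0
    cycle_seconds: float = 12.0
    n_cycles_per_run: int = 10
    n_censored_cycles: int = 2
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_triplets_per_session: int = 6
    n_sessions: int = 2

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        ratio = self.cycle_seconds / self.tr_seconds
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError(
                "cycle_seconds must be a positive integer multiple of tr_seconds"
            )
        if self.n_cycles_per_run < 1:
            raise ValueError("n_cycles_per_run must be >= 1")
        if not 0 <= self.n_censored_cycles < self.n_cycles_per_run:
            raise ValueError(
                "n_censored_cycles must lie in [0, n_cycles_per_run)"
            )
        if len(self.conditions) != 3:
            raise ValueError("exactly 3 condition labels are required")
        if len(set(self.conditions)) != 3:
            raise ValueError("condition labels must be distinct")
        if self.n_triplets_per_session < 1:
            raise ValueError("n_triplets_per_session must be >= 1")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        # tuple-ify so YAML/JSON round trips compare equal
        object.__setattr__(self, "conditions", tuple(self.conditions))

    # ------------------------------------------------------------------
    # derived quantities
    @property
    def volumes_per_cycle(self) -> int:
        return round(self.cycle_seconds / self.tr_seconds)

    @property
    def n_volumes(self) -> int:
        """Run length in volumes."""
        return self.n_cycles_per_run * self.volumes_per_cycle

    @property
    def n_censored_volumes(self) -> int:
        """Initial volumes excluded from model fits."""
        return self.n_censored_cycles * self.volumes_per_cycle

    @property
    def n_runs_per_session(self) -> int:
        return 3 * self.n_triplets_per_session

    @property
    def peak_reference_seconds(self) -> float:
        """Time subtracted from the fitted peak to express apparent delay.

        Mid-ON of the cycle (cycle/4): a zero-delay sinusoidal response
        peaks there, so delay = (peak time - cycle/4) mod cycle.
        """
        return self.cycle_seconds / 4.0

    def run_times(self) -> "np.ndarray":
        """Volume acquisition times (s), t = 0 at run start."""
        import numpy as np

        return np.arange(self.n_volumes, dtype=float) * self.tr_seconds

    def censor_mask(self) -> "np.ndarray":
        """Boolean mask of retained volumes (False on censored rows)."""
        import numpy as np

        keep = np.ones(self.n_volumes, dtype=bool)
        keep[: self.n_censored_volumes] = False
        return keep

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyDesign":
        d = dict(d)
        d["conditions"] = tuple(d.get("conditions", DEFAULT_CONDITIONS))
        return cls(**d)
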