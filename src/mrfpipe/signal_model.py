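"""Fingerprint signal simulation for an MR-fingerprinting SSFP sequence.

The sequence modelled here is an inversion-prepped, gradient-spoiled
(FISP-style) SSFP train with a linearly ramped flip-angle schedule.  Each
repetition applies an RF pulse, reads out the transverse magnetization at
the echo time, lets the spins relax over the remainder of the TR, and then
ideally crushes residual transverse phase coherence with a one-cycle
gradient spoiler.  The per-timepoint transverse signal traced out by a
(T1, T2) pair under this train is its *fingerprint*.

The simulator uses the extended-phase-graph (EPG) formalism: configuration
states ``F+_k``, ``F-_k``, ``Z_k`` indexed by integer dephasing order ``k``
evolve under RF mixing, relaxation and gradient shifts.  With the RF phase
fixed on the y axis and no off-resonance, all states stay real, so the
fingerprint is a real (signed) sequence.  Off-resonance, B1 error,
magnetization transfer and diffusion are deliberately not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "DEFAULT_FA_START_DEG",
    "DEFAULT_FA_END_DEG",
    "DEFAULT_TR_MS",
    "DEFAULT_TE_MS",
    "DEFAULT_N_TIMEPOINTS",
    "DEFAULT_N_STATES",
    "InvalidScheduleError",
    "InvalidTimingError",
    "SequenceSchedule",
    "Fingerprint",
    "make_schedule",
    "default_schedule",
    "simulate_fingerprint",
    "simulate_fingerprints",
]

# Flip-angle ramp endpoints of the modelled acquisition.
DEFAULT_FA_START_DEG = 0.778
DEFAULT_FA_END_DEG = 70.0
# TR/TE are not dictated by the ramp itself; these are the package defaults
# for a constant-TR FISP-style train (documented in docs/methods.md).
DEFAULT_TR_MS = 10.0
DEFAULT_TE_MS = 2.0
DEFAULT_N_TIMEPOINTS = 500
# EPG configuration orders retained.  Chosen so that truncation error stays
# below 1e-3 relative L2 against a brute-force isochromat simulation for
# all T1, T2 in [10, 5000] ms (long-T2 spins keep high dephasing orders
# alive, so aggressive truncation is visibly wrong there).
DEFAULT_N_STATES = 150


class InvalidScheduleError(ValueError):
    """Raised for malformed schedules (too short, angles out of range)."""


class InvalidTimingError(ValueError):
    """Raised when the TE/TR timing of a schedule is inconsistent."""


def _as_series(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise InvalidScheduleError(
            f"{name} must be scalar or length-{n}, got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class SequenceSchedule:
    """Per-timepoint acquisition parameters of one fingerprint experiment.

    Parameters
    ----------
    flip_angles_deg
        Excitation flip angle per repetition, degrees, each in [0, 180].
    tr_ms, te_ms
        Repetition and echo times in milliseconds; scalars are broadcast.
        Every TR must exceed its TE and TE must be non-negative.
    inversion
        Whether an adiabatic inversion pulse precedes the train.
    inversion_efficiency
        Fraction of longitudinal magnetization inverted, in (0, 1].
    """

    flip_angles_deg: np.ndarray
    tr_ms: np.ndarray
    te_ms: np.ndarray
    inversion: bool = True
    inversion_efficiency: float = 1.0
    schedule_id: str = "custom"

    def __post_init__(self) -> None:
        fa = np.asarray(self.flip_angles_deg, dtype=float)
        if fa.ndim != 1 or fa.size < 2:
            raise InvalidScheduleError(
                "a schedule needs at least 2 timepoints"
            )
        n = fa.size
        tr = _as_series(self.tr_ms, n, "tr_ms")
        te = _as_series(self.te_ms, n, "te_ms")
        if np.any(fa < 0.0) or np.any(fa > 180.0):
            raise InvalidScheduleError("flip angles must lie in [0, 180] deg")
        if np.any(te < 0.0):
            raise InvalidTimingError("TE must be non-negative")
        if np.any(tr <= te):
            raise InvalidTimingError("every TR must exceed its TE")
        if not (0.0 < self.inversion_efficiency <= 1.0):
            raise InvalidScheduleError("inversion_efficiency must be in (0, 1]")
        object.__setattr__(self, "flip_angles_deg", fa)
        object.__setattr__(self, "tr_ms", tr)
        object.__setattr__(self, "te_ms", te)

    @property
    def n_timepoints(self) -> int:
        return self.flip_angles_deg.size

    def to_json(self) -> str:
        return json.dumps(
            {
                "flip_angles_deg": self.flip_angles_deg.tolist(),
                "tr_ms": self.tr_ms.tolist(),
                "te_ms": self.te_ms.tolist(),
                "inversion": self.inversion,
                "inversion_efficiency": self.inversion_efficiency,
                "schedule_id": self.schedule_id,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "SequenceSchedule":
        d = json.loads(payload)
        return cls(
            flip_angles_deg=np.asarray(d["flip_angles_deg"], dtype=float),
            tr_ms=np.asarray(d["tr_ms"], dtype=float),
            te_ms=np.asarray(d["te_ms"], dtype=float),
            inversion=bool(d["inversion"]),
            inversion_efficiency=float(d.get("inversion_efficiency", 1.0)),
            schedule_id=str(d.get("schedule_id", "custom")),
        )


@dataclass(frozen=True)
class Fingerprint:
    """Simulated transverse signal of one (T1, T2) pair.

    ``signal`` is the real (signed) transverse magnetization at each echo
    time, in units of the equilibrium magnetization (so ``|signal| <= 1``).
    """

    signal: np.ndarray
    t1_ms: float
    t2_ms: float
    schedule_id: str = "custom"


def make_schedule(
    n_timepoints: int,
    fa_start_deg: float = DEFAULT_FA_START_DEG,
    fa_end_deg: float = DEFAULT_FA_END_DEG,
    tr_ms: Union[float, np.ndarray] = DEFAULT_TR_MS,
    te_ms: Union[float, np.ndarray] = DEFAULT_TE_MS,
    inversion: bool = True,
    inversion_efficiency: float = 1.0,
    schedule_id: str = "linear-ramp",
) -> SequenceSchedule:
    """Build a linear flip-angle ramp schedule.

    The flip angle rises linearly from ``fa_start_deg`` at the first
    timepoint to ``fa_end_deg`` at the last (inclusive endpoints).
    """
    if n_timepoints < 2:
        raise InvalidScheduleError("n_timepoints must be >= 2")
    fa = np.linspace(float(fa_start_deg), float(fa_end_deg), int(n_timepoints))
    return SequenceSchedule(
        flip_angles_deg=fa,
        tr_ms=tr_ms,
        te_ms=te_ms,
        inversion=inversion,
        inversion_efficiency=inversion_efficiency,
        schedule_id=schedule_id,
    )


def default_schedule(n_timepoints: int = DEFAULT_N_TIMEPOINTS) -> SequenceSchedule:
    """The package-default acquisition: 0.778-70 deg ramp, TR 10 / TE 2 ms,
    adiabatic inversion at t=0."""
    return make_schedule(n_timepoints, schedule_id="default-ramp")


def simulate_fingerprints(
    t1_ms,
    t2_ms,
    schedule: SequenceSchedule,
    n_states: int = DEFAULT_N_STATES,
) -> np.ndarray:
    """Vectorized EPG simulation for arrays of (T1, T2) pairs.

    Parameters
    ----------
    t1_ms, t2_ms
        Broadcastable arrays of relaxation times in ms, all positive.
    n_states
        Number of EPG configuration orders retained (capped at the number
        of timepoints + 1, beyond which orders are unreachable).

    Returns
    -------
    ndarray, shape ``(n_pairs, n_timepoints)``
        One real fingerprint row per pair, in equilibrium-magnetization
        units.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float)).ravel()
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float)).ravel()
    t1, t2 = np.broadcast_arrays(t1, t2)
    if np.any(t1 <= 0.0) or np.any(t2 <= 0.0):
        raise ValueError("relaxation times must be positive")
    n_pairs = t1.size
    n_t = schedule.n_timepoints
    K = int(min(max(1, n_states), n_t + 1))

    fa_rad = np.deg2rad(schedule.flip_angles_deg)
    E1 = np.exp(-schedule.tr_ms[:, None] / t1[None, :])
    E2 = np.exp(-schedule.tr_ms[:, None] / t2[None, :])
    E2te = np.exp(-schedule.te_ms[:, None] / t2[None, :])

    Fp = np.zeros((K, n_pairs))
    Fm = np.zeros((K, n_pairs))
    Z = np.zeros((K, n_pairs))
    Z[0] = -schedule.inversion_efficiency if schedule.inversion else 1.0

    sig = np.empty((n_t, n_pairs))
    for t in range(n_t):
        a = fa_rad[t]
        c2, s2 = np.cos(a / 2.0) ** 2, np.sin(a / 2.0) ** 2
        s, c = np.sin(a), np.cos(a)
        Fp_new = c2 * Fp - s2 * Fm + s * Z
        Fm_new = -s2 * Fp + c2 * Fm + s * Z
        Z = -0.5 * s * (Fp + Fm) + c * Z
        Fp, Fm = Fp_new, Fm_new
        sig[t] = Fp[0] * E2te[t]
        # relaxation over the full TR, then the end-of-TR crusher shift
        Fp *= E2[t]
        Fm *= E2[t]
        Z *= E1[t]
        Z[0] += 1.0 - E1[t]
        Fp[1:] = Fp[:-1]
        Fm[:-1] = Fm[1:]
        Fm[-1] = 0.0
        Fp[0] = Fm[0]
    return np.ascontiguousarray(sig.T)


def simulate_fingerprint(
    t1_ms: float,
    t2_ms: float,
    schedule: SequenceSchedule,
    n_states: int = DEFAULT_N_STATES,
) -> Fingerprint:
    """Simulate the fingerprint of a single (T1, T2) pair."""
    sig = simulate_fingerprints([t1_ms], [t2_ms], schedule, n_states=n_states)
    return Fingerprint(
        signal=sig[0],
        t1_ms=float(t1_ms),
        t2_ms=float(t2_ms),
        schedule_id=schedule.schedule_id,
    )
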