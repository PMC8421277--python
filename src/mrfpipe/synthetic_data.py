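"""Synthetic inputs: a NIST-like relaxometry phantom and a patient cohort.

Two generators produce everything the validation analyses consume:

* a 14-insert digital analog of the NIST/ISMRM system phantom's T1 array —
  discs on a ring, ground-truth T1/T2 log-spaced across the measured
  ranges (T1 20-1980 ms, T2 15-1600 ms), scanned repeatedly at a chosen
  SNR and matched against the dictionary;
* a meningioma cohort with the blocked structure of the modelled study:
  20 patients, 25 tumors (one patient with three, three with two), and one
  record per normal brain structure per patient, each structure's T1/T2
  drawn from its published mean/SD as an independent Gaussian truncated
  at 1 ms.

Ground truth is always carried alongside the rendered data; the certified
per-vial values of the physical phantom are not public in the modelled
study, so the log-spaced values here are an explicit synthetic stand-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import (
    Trajectory,
    make_trajectory,
    reconstruct_series,
    sample_kspace,
    view_share,
)
from .dictionary import Dictionary, ParameterMaps, match_volume
from .signal_model import SequenceSchedule, simulate_fingerprints

__all__ = [
    "STRUCTURES",
    "DEFAULT_STRUCTURE_PARAMS",
    "DEFAULT_MULTI_TUMOR_PLAN",
    "LayoutError",
    "PlanError",
    "PhantomInsert",
    "PhantomSpec",
    "CohortTable",
    "make_phantom_spec",
    "render_phantom",
    "simulate_phantom_session",
    "generate_cohort",
]

STRUCTURES = (
    "meningioma",
    "thalamus",
    "caudate_head",
    "centrum_semiovale",
    "contralateral_white_matter",
)

# Published per-structure relaxometry (t1_mean, t1_sd, t2_mean, t2_sd, n).
DEFAULT_STRUCTURE_PARAMS: Dict[str, Tuple[float, float, float, float, int]] = {
    "meningioma": (1429.0, 202.0, 69.0, 27.0, 25),
    "thalamus": (1054.0, 58.0, 27.0, 3.0, 20),
    "caudate_head": (1223.0, 52.0, 39.0, 5.0, 20),
    "centrum_semiovale": (825.0, 42.0, 29.0, 5.0, 20),
    "contralateral_white_matter": (799.0, 45.0, 35.0, 4.0, 20),
}

# Tumors per patient: one triple-tumor patient, three doubles, the rest
# single -> 25 tumors over 20 patients.
DEFAULT_MULTI_TUMOR_PLAN: Tuple[int, ...] = (3, 2, 2, 2) + (1,) * 16

MIN_RELAXATION_MS = 1.0


class LayoutError(ValueError):
    pass


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomInsert:
    id: int
    center: Tuple[float, float]  # voxel coords
    radius: float  # voxels
    t1_ms: float
    t2_ms: float
    pd: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and ground truth of the synthetic reference phantom."""

    inserts: Tuple[PhantomInsert, ...]
    matrix: int
    background: Optional[Tuple[float, float, float]] = None  # (t1, t2, pd)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix,
                "seed": self.seed,
                "background": self.background,
                "inserts": [
                    {
                        "id": i.id,
                        "center": list(i.center),
                        "radius": i.radius,
                        "t1_ms": i.t1_ms,
                        "t2_ms": i.t2_ms,
                        "pd": i.pd,
                    }
                    for i in self.inserts
                ],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PhantomSpec":
        d = json.loads(payload)
        inserts = tuple(
            PhantomInsert(
                id=i["id"],
                center=tuple(i["center"]),
                radius=i["radius"],
                t1_ms=i["t1_ms"],
                t2_ms=i["t2_ms"],
                pd=i["pd"],
            )
            for i in d["inserts"]
        )
        bg = d.get("background")
        return cls(
            inserts=inserts,
            matrix=d["matrix"],
            background=tuple(bg) if bg else None,
            seed=d.get("seed", 0),
        )


def make_phantom_spec(
    n_inserts: int = 14,
    t1_range_ms: Tuple[float, float] = (20.0, 1980.0),
    t2_range_ms: Tuple[float, float] = (15.0, 1600.0),
    spacing: str = "log",
    matrix: int = 64,
    seed: int = 0,
    insert_radius: Optional[float] = None,
    background: Optional[Tuple[float, float, float]] = None,
) -> PhantomSpec:
    """Lay out ``n_inserts`` discs on a ring with log-spaced ground truth.

    T1 and T2 are paired by insert index (both increase together around the
    ring).  The layout is deterministic given the arguments; ``seed`` is
    recorded for provenance of downstream noisy sessions.
    """
    for lo, hi in (t1_range_ms, t2_range_ms):
        if lo <= 0 or hi <= lo:
            raise ValueError("ranges must be positive with lo < hi")
    if spacing == "log":
        t1s = np.geomspace(*t1_range_ms, n_inserts)
        t2s = np.geomspace(*t2_range_ms, n_inserts)
    elif spacing == "linear":
        t1s = np.linspace(*t1_range_ms, n_inserts)
        t2s = np.linspace(*t2_range_ms, n_inserts)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")

    c = (matrix - 1) / 2.0
    if n_inserts == 1:
        centers = [(c, c)]
        radius = insert_radius if insert_radius is not None else 0.3 * matrix
    else:
        ring_r = 0.36 * matrix
        if insert_radius is None:
            # largest radius leaving a 1-voxel margin between neighbors
            chord = 2.0 * ring_r * np.sin(np.pi / n_inserts)
            radius = min(0.07 * matrix, (chord - 1.0) / 2.0)
        else:
            radius = float(insert_radius)
        angles = 2.0 * np.pi * np.arange(n_inserts) / n_inserts
        centers = [
            (c + ring_r * np.cos(a), c + ring_r * np.sin(a)) for a in angles
        ]
        chord = 2.0 * ring_r * np.sin(np.pi / n_inserts)
        if chord <= 2.0 * radius:
            raise LayoutError(
                f"{n_inserts} inserts of radius {radius:.1f} overlap on the ring"
            )
    if radius < 1.0:
        raise LayoutError("insert radius below one voxel; increase the matrix")
    for cx, cy in centers:
        if cx - radius < 0 or cy - radius < 0 or cx + radius > matrix - 1 or cy + radius > matrix - 1:
            raise LayoutError("insert extends outside the matrix")

    inserts = tuple(
        PhantomInsert(
            id=i + 1,
            center=centers[i],
            radius=float(radius),
            t1_ms=float(t1s[i]),
            t2_ms=float(t2s[i]),
        )
        for i in range(n_inserts)
    )
    return PhantomSpec(inserts=inserts, matrix=int(matrix), background=background, seed=seed)


def render_phantom(spec: PhantomSpec):
    """Voxelize the spec into T1/T2/PD ground-truth images + labels.

    Returns ``(t1, t2, pd, labels)``; label 0 is background, labels 1..n
    follow insert ids.
    """
    m = spec.matrix
    t1 = np.zeros((m, m))
    t2 = np.zeros((m, m))
    pd = np.zeros((m, m))
    labels = np.zeros((m, m), dtype=int)
    if spec.background is not None:
        bt1, bt2, bpd = spec.background
        t1[:], t2[:], pd[:] = bt1, bt2, bpd
    xs, ys = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    for ins in spec.inserts:
        disc = (xs - ins.center[0]) ** 2 + (ys - ins.center[1]) ** 2 <= ins.radius**2
        t1[disc] = ins.t1_ms
        t2[disc] = ins.t2_ms
        pd[disc] = ins.pd
        labels[disc] = ins.id
    return t1, t2, pd, labels


def simulate_phantom_session(
    spec: PhantomSpec,
    schedule: SequenceSchedule,
    dic: Dictionary,
    n_repeats: int = 7,
    snr: Optional[float] = 30.0,
    mode: str = "voxelwise",
    seed: int = 0,
    traj: Optional[Trajectory] = None,
    view_share_window: int = 1,
) -> List[ParameterMaps]:
    """Repeatedly 'scan' the phantom and match each repeat.

    ``mode='voxelwise'`` adds white Gaussian noise directly to the per-voxel
    fingerprints (SNR = mean signal magnitude / noise SD); ``mode=
    'acquisition'`` runs the full undersampled encoding chain (sampling,
    view sharing, gridding).  Per-repeat noise streams derive
    deterministically from the session seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    t1_img, t2_img, pd_img, labels = render_phantom(spec)
    mask = pd_img > 0
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats)

    maps_out: List[ParameterMaps] = []
    if mode == "voxelwise":
        pairs, inv = np.unique(
            np.column_stack([t1_img[mask], t2_img[mask]]), axis=0, return_inverse=True
        )
        fps = simulate_fingerprints(pairs[:, 0], pairs[:, 1], schedule)
        clean = fps[inv] * pd_img[mask][:, None]  # (n_vox, n_t)
        level = float(np.mean(np.abs(clean)))
        for r in range(n_repeats):
            series = clean
            if snr is not None:
                rng = np.random.default_rng(int(child_seeds[r]))
                series = clean + (level / snr) * rng.standard_normal(clean.shape)
            vol = np.zeros(mask.shape + (schedule.n_timepoints,))
            vol[mask] = series
            maps_out.append(match_volume(vol, dic, mask=mask))
    elif mode == "acquisition":
        if traj is None:
            traj = make_trajectory(spec.matrix, schedule.n_timepoints)
        for r in range(n_repeats):
            ks = sample_kspace(
                t1_img, t2_img, pd_img, schedule, traj,
                snr=snr, seed=int(child_seeds[r]),
            )
            if view_share_window > 1:
                ks = view_share(ks, traj, view_share_window)
            series = reconstruct_series(ks, traj)
            series = np.moveaxis(series, 0, -1)
            maps_out.append(match_volume(series, dic, mask=mask))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return maps_out


@dataclass(frozen=True)
class CohortTable:
    """Per-subject, per-structure ROI relaxometry records.

    One row per (patient, structure) for normal structures and one row per
    tumor for meningiomas (``tumor_id`` set only on tumor rows).
    """

    records: pd.DataFrame
    seed: int
    generator_params: Dict[str, Tuple[float, float, float, float, int]]

    @property
    def n_patients(self) -> int:
        return self.records["patient_id"].nunique()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, seed: int = -1) -> "CohortTable":
        df = pd.read_csv(path, dtype={"tumor_id": "string"})
        return cls(records=df, seed=seed, generator_params={})


def _truncated_normal(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (MIN_RELAXATION_MS - mean) / sd
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.rvs(size=size, random_state=rng)


def generate_cohort(
    structure_params: Dict[str, Tuple[float, float, float, float, int]] = DEFAULT_STRUCTURE_PARAMS,
    multi_tumor_plan: Sequence[int] = DEFAULT_MULTI_TUMOR_PLAN,
    seed: int = 0,
    within_patient_corr: float = 0.0,
) -> CohortTable:
    """Draw a synthetic cohort with the study's blocked structure.

    Every structure's T1 and T2 are Gaussians (truncated at 1 ms) with the
    configured mean/SD, independent across structures by default.
    ``within_patient_corr`` adds an equicorrelation between a patient's
    normal-structure values (shared patient-level factor on the standard
    scale; draws are then floored at 1 ms), emulating subjects who run
    globally long or short.  Meningioma rows are distributed over patients
    per ``multi_tumor_plan``; normal-structure rows are one per patient
    and are later shared across that patient's tumor blocks.
    """
    plan = list(multi_tumor_plan)
    if any(c < 1 for c in plan):
        raise PlanError("plan entries must be >= 1 tumors per patient")
    n_patients = len(plan)
    n_tumors = sum(plan)
    for s, (m1, s1, m2, s2, n) in structure_params.items():
        if s1 < 0 or s2 < 0 or n < 1:
            raise PlanError(f"bad parameters for {s}")
    men_n = structure_params["meningioma"][4]
    if men_n != n_tumors:
        raise PlanError(
            f"plan implies {n_tumors} tumors but meningioma n = {men_n}"
        )
    for s in STRUCTURES[1:]:
        if s in structure_params and structure_params[s][4] != n_patients:
            raise PlanError(
                f"{s} n = {structure_params[s][4]} != {n_patients} patients"
            )

    if not (0.0 <= within_patient_corr < 1.0):
        raise PlanError("within_patient_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    m1, s1, m2, s2, _ = structure_params["meningioma"]
    t1_draws = _truncated_normal(rng, m1, s1, n_tumors)
    t2_draws = _truncated_normal(rng, m2, s2, n_tumors)
    rho = within_patient_corr
    if rho > 0.0:
        # shared patient-level factor per value axis (equicorrelation rho)
        g_t1 = rng.standard_normal(n_patients)
        g_t2 = rng.standard_normal(n_patients)
    k = 0
    for p, count in enumerate(plan):
        pid = f"P{p + 1:02d}"
        for t in range(count):
            rows.append(
                {
                    "patient_id": pid,
                    "tumor_id": f"{pid}T{t + 1}",
                    "structure": "meningioma",
                    "t1_ms": t1_draws[k],
                    "t2_ms": t2_draws[k],
                }
            )
            k += 1
    for s in STRUCTURES[1:]:
        m1, s1, m2, s2, n = structure_params[s]
        if rho > 0.0:
            z1 = np.sqrt(rho) * g_t1 + np.sqrt(1 - rho) * rng.standard_normal(n_patients)
            z2 = np.sqrt(rho) * g_t2 + np.sqrt(1 - rho) * rng.standard_normal(n_patients)
            t1_draws = np.maximum(MIN_RELAXATION_MS, m1 + s1 * z1)
            t2_draws = np.maximum(MIN_RELAXATION_MS, m2 + s2 * z2)
        else:
            t1_draws = _truncated_normal(rng, m1, s1, n_patients)
            t2_draws = _truncated_normal(rng, m2, s2, n_patients)
        for p in range(n_patients):
            rows.append(
                {
                    "patient_id": f"P{p + 1:02d}",
                    "tumor_id": pd.NA,
                    "structure": s,
                    "t1_ms": t1_draws[p],
                    "t2_ms": t2_draws[p],
                }
            )
    df = pd.DataFrame(rows)
    return CohortTable(records=df, seed=seed, generator_params=dict(structure_params))
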