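"""Quantitative validation: accuracy regression, repeatability, blocked
rank statistics.

Phantom accuracy is summarized by ordinary least squares of measured
against reference relaxation times (r² as the squared Pearson correlation)
plus the mean absolute percentage error, optionally restricted to a
reference range; repeatability is the per-vial standard deviation across
repeat sessions.

The in-vivo analysis follows the blocked design of the modelled study:
each meningioma forms a block together with its patient's four normal
structures (so multi-tumor patients contribute their normal-structure
values to several blocks), compared with a tie-corrected Friedman rank
ANOVA and Dunn's pairwise post-hoc z tests.  Note the duplicated
normal-structure rows mean blocks from the same patient are not strictly
independent; the study's pairing rule is reproduced as stated rather than
"corrected".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dictionary import ParameterMaps
from .synthetic_data import STRUCTURES, CohortTable

__all__ = [
    "AccuracyReport",
    "RepeatabilityReport",
    "FriedmanResult",
    "DunnResult",
    "BlockError",
    "extract_roi_stats",
    "linear_accuracy",
    "repeatability",
    "build_blocks",
    "friedman_test",
    "dunn_posthoc",
    "table1",
]

ALPHA = 0.05  # study-wide significance threshold


class BlockError(ValueError):
    pass


@dataclass(frozen=True)
class AccuracyReport:
    slope: float
    intercept: float
    r_squared: float
    mape_percent: float
    range_filter: Optional[Tuple[float, float]]
    n_points: int


@dataclass(frozen=True)
class RepeatabilityReport:
    per_vial_sd: np.ndarray
    min_sd: float
    max_sd: float
    n_repeats: int


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    n_blocks: int
    k_conditions: int
    rank_sums: np.ndarray


@dataclass(frozen=True)
class DunnResult:
    comparisons: pd.DataFrame  # condition_a, condition_b, z, p_unadjusted, p_adjusted
    adjustment_method: str

    def p_adjusted(self, a: str, b: str) -> float:
        df = self.comparisons
        sel = ((df.condition_a == a) & (df.condition_b == b)) | (
            (df.condition_a == b) & (df.condition_b == a)
        )
        if not sel.any():
            raise KeyError(f"no comparison {a} vs {b}")
        return float(df.loc[sel, "p_adjusted"].iloc[0])


def extract_roi_stats(maps: ParameterMaps, labels: np.ndarray) -> pd.DataFrame:
    """Per-label mean/SD/voxel-count of the T1 and T2 maps.

    Label 0 is background and ignored; labels present in the volume but
    empty after masking are skipped with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.shape:
        raise ValueError("label volume shape does not match the maps")
    ids = np.unique(labels)
    ids = ids[ids != 0]
    if ids.size == 0:
        raise ValueError("no nonzero labels")
    rows = []
    for lab in ids:
        sel = labels == lab
        n = int(np.count_nonzero(sel))
        if n == 0:  # pragma: no cover - unique() precludes this
            warnings.warn(f"label {lab} is empty; skipping", stacklevel=2)
            continue
        rows.append(
            {
                "label": int(lab),
                "n_voxels": n,
                "t1_mean": float(maps.t1_ms[sel].mean()),
                "t1_sd": float(maps.t1_ms[sel].std(ddof=1)) if n > 1 else 0.0,
                "t2_mean": float(maps.t2_ms[sel].mean()),
                "t2_sd": float(maps.t2_ms[sel].std(ddof=1)) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def linear_accuracy(
    measured,
    reference,
    range_filter: Optional[Tuple[float, float]] = None,
) -> AccuracyReport:
    """OLS of measured on reference + MAPE, optionally range-restricted.

    The filter keeps points whose *reference* value lies in [lo, hi]; r² is
    the squared Pearson correlation of the fit, MAPE is
    mean(|measured - reference| / reference) * 100.
    """
    measured = np.asarray(measured, float)
    reference = np.asarray(reference, float)
    if measured.shape != reference.shape:
        raise ValueError("measured and reference must have equal length")
    if range_filter is not None:
        lo, hi = range_filter
        keep = (reference >= lo) & (reference <= hi)
        measured, reference = measured[keep], reference[keep]
    if reference.size < 2:
        raise ValueError("need at least 2 points after filtering")
    if np.unique(reference).size < 2:
        raise ValueError("reference values must not all coincide")
    fit = stats.linregress(reference, measured)
    mape = float(np.mean(np.abs(measured - reference) / reference) * 100.0)
    return AccuracyReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mape_percent=mape,
        range_filter=range_filter,
        n_points=int(reference.size),
    )


def repeatability(measurements: np.ndarray) -> RepeatabilityReport:
    """Across-repeat sample SD per vial (rows = repeats, cols = vials)."""
    m = np.asarray(measurements, float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a repeats x vials matrix with >= 2 repeats")
    sds = m.std(axis=0, ddof=1)
    return RepeatabilityReport(
        per_vial_sd=sds,
        min_sd=float(sds.min()),
        max_sd=float(sds.max()),
        n_repeats=int(m.shape[0]),
    )


def build_blocks(cohort: CohortTable, value: str = "t1_ms") -> np.ndarray:
    """Blocks-by-conditions matrix: one block per meningioma.

    Block row order follows tumor order in the table; columns follow
    ``STRUCTURES`` (meningioma first).  A multi-tumor patient's
    normal-structure values repeat in each of that patient's blocks.
    """
    df = cohort.records
    tumors = df[df.structure == "meningioma"]
    if tumors.empty:
        raise BlockError("cohort has no meningioma records")
    normals = df[df.structure != "meningioma"]
    blocks = []
    for _, trow in tumors.iterrows():
        row = [trow[value]]
        psel = normals[normals.patient_id == trow.patient_id]
        for s in STRUCTURES[1:]:
            vals = psel.loc[psel.structure == s, value]
            if len(vals) != 1:
                raise BlockError(
                    f"patient {trow.patient_id} lacks a unique {s} record"
                )
            row.append(float(vals.iloc[0]))
        blocks.append(row)
    return np.asarray(blocks, float)


def _midranks(blocks: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, blocks)


def friedman_test(blocks: np.ndarray) -> FriedmanResult:
    """Tie-corrected Friedman rank ANOVA on a blocks x conditions matrix.

    Q = [12 / (n k (k+1))] * sum_j R_j^2 - 3 n (k+1), divided by the tie
    correction 1 - sum(t^3 - t) / (n k (k^2 - 1)); p from chi-square with
    k - 1 degrees of freedom.
    """
    blocks = np.asarray(blocks, float)
    if blocks.ndim != 2 or blocks.shape[0] < 2 or blocks.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 conditions")
    if not np.all(np.isfinite(blocks)):
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = blocks.shape
    ranks = _midranks(blocks)
    rank_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in blocks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    corr = 1.0 - tie_term / (n * k * (k**2 - 1))
    statistic = 0.0 if corr <= 0.0 else q / corr
    p = float(stats.chi2.sf(statistic, k - 1))
    return FriedmanResult(
        statistic=float(statistic),
        df=k - 1,
        p_value=p,
        n_blocks=n,
        k_conditions=k,
        rank_sums=rank_sums,
    )


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_posthoc(
    blocks: np.ndarray,
    adjustment: str = "bonferroni",
    condition_names: Optional[List[str]] = None,
) -> DunnResult:
    """Dunn's pairwise rank comparisons after a Friedman test.

    For conditions i, j: z = (Rbar_i - Rbar_j) / sqrt(k (k+1) / (6 n)) from
    within-block mean ranks, two-sided normal p, adjusted over the k(k-1)/2
    pairs by the selected method (Bonferroni by default).
    """
    blocks = np.asarray(blocks, float)
    if blocks.ndim != 2 or blocks.shape[0] < 2 or blocks.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 conditions")
    if not np.all(np.isfinite(blocks)):
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = blocks.shape
    if condition_names is None:
        condition_names = [f"c{j}" for j in range(k)]
    mean_ranks = _midranks(blocks).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i, j in combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "condition_a": condition_names[i],
                "condition_b": condition_names[j],
                "z": z,
                "p_unadjusted": 2.0 * stats.norm.sf(abs(z)),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _adjust(df["p_unadjusted"].to_numpy(), adjustment)
    return DunnResult(comparisons=df, adjustment_method=adjustment)


def table1(cohort: CohortTable, adjustment: str = "bonferroni") -> pd.DataFrame:
    """Summary table: per-structure mean/SD and Dunn p vs meningioma.

    Reproduces the layout of the study's relaxometry table — for T1 and T2,
    the structure mean, the SD across subjects, and the adjusted Dunn
    p-value of the comparison against meningioma (the reference row).
    """
    df = cohort.records
    rows = []
    dunn = {}
    for value in ("t1_ms", "t2_ms"):
        blocks = build_blocks(cohort, value=value)
        dunn[value] = dunn_posthoc(
            blocks, adjustment=adjustment, condition_names=list(STRUCTURES)
        )
    for s in STRUCTURES:
        sub = df[df.structure == s]
        row = {"structure": s, "n": len(sub)}
        for value, tag in (("t1_ms", "t1"), ("t2_ms", "t2")):
            row[f"{tag}_mean_ms"] = float(sub[value].mean())
            row[f"{tag}_sd_ms"] = float(sub[value].std(ddof=1))
            row[f"{tag}_p_vs_meningioma"] = (
                np.nan
                if s == "meningioma"
                else dunn[value].p_adjusted("meningioma", s)
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("structure")
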