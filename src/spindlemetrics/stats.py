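"""Cohort-level summaries and the statistical test battery.

Covers the half-spindle-ratio distribution summaries (median, fraction
outside the 0.85/1.15 boundaries), per-cell metaphase/anaphase R selection,
anaphase-aligned median-R trajectories with bootstrap confidence bands, and
two-sample / count tests: Welch t, Mann–Whitney U, Fisher exact, exact
binomial, Levene and paired t. All tests are two-sided and p-values are
reported raw (no multiplicity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "TrajectoryRow",
    "ratio_distribution_summary",
    "metaphase_R_selection",
    "anaphase_aligned_trajectories",
    "compare_groups",
    "count_tests",
]

_TWO_SAMPLE_TESTS = ("welch_t", "mann_whitney_u", "levene", "paired_t")


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    alternative: str = "two-sided"
    method: str = ""
    comparison: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class TrajectoryRow:
    time_to_anaphase_s: float
    median_R: float
    ci_lo: float
    ci_hi: float
    n_cells: int


def ratio_distribution_summary(
    r_values: Sequence[float], lo: float = 0.85, hi: float = 1.15
) -> tuple[float, float, float]:
    """(median, fraction strictly outside [lo, hi], fraction strictly above hi).

    Boundary values count as inside: the operational rule is "smaller than
    0.85 or larger than 1.15", strictly.
    """
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    if len(r) == 0:
        raise ValueError("no finite R values")
    median = float(np.median(r))
    frac_outside = float(np.mean((r < lo) | (r > hi)))
    frac_above = float(np.mean(r > hi))
    return median, frac_outside, frac_above


def metaphase_R_selection(
    r_by_frame: Sequence[float],
    anaphase_frame: int | None = None,
    k_first: int = 3,
) -> tuple[float, float | None]:
    """Per-cell (metaphase R, anaphase R).

    Metaphase R is the mean of R over the first ``k_first`` available
    frames (fewer if the recording is shorter) — the earliest-timepoint
    convention, before the plate has had time to move. Anaphase R is R at
    the last frame before the (detected or annotated) onset, or None when
    no onset is known.
    """
    r = np.asarray(r_by_frame, dtype=float)
    finite = np.flatnonzero(np.isfinite(r))
    if finite.size == 0:
        raise ValueError("no finite R values for this cell")
    meta = float(np.mean(r[finite[:k_first]]))
    ana: float | None = None
    if anaphase_frame is not None and anaphase_frame > 0:
        before = finite[finite < anaphase_frame]
        if before.size:
            ana = float(r[before[-1]])
    return meta, ana


def anaphase_aligned_trajectories(
    r_by_cell: Sequence[Sequence[float]],
    anaphase_frames: Sequence[int],
    dt_s: float,
    n_boot: int = 1000,
    seed: int = 0,
    min_cells: int = 3,
) -> list[TrajectoryRow]:
    """Median-R trajectory aligned to anaphase onset (t = 0) with bootstrap CI.

    Each cell's R series is re-indexed to time-to-anaphase (negative before
    onset, multiples of dt); for every bin with at least ``min_cells``
    contributing cells the cross-cell median and a 95% percentile bootstrap
    CI (resampling cells with replacement, seeded) are reported.
    """
    cells = [np.asarray(r, dtype=float) for r in r_by_cell]
    if len(cells) == 0 or len(cells) != len(anaphase_frames):
        raise ValueError("need one anaphase frame per cell")
    if any(a is None for a in anaphase_frames):
        raise ValueError("every cell must have an anaphase frame")
    # bin index = frame - anaphase_frame (so bin 0 is onset)
    offsets: dict[int, list[tuple[int, float]]] = {}
    for ci, (r, af) in enumerate(zip(cells, anaphase_frames)):
        for f in range(len(r)):
            if np.isfinite(r[f]):
                offsets.setdefault(f - int(af), []).append((ci, r[f]))
    rng = np.random.default_rng(seed)
    n_cells = len(cells)
    boot_idx = rng.integers(0, n_cells, size=(n_boot, n_cells))
    rows: list[TrajectoryRow] = []
    for off in sorted(offsets):
        contrib = offsets[off]
        if len(contrib) < min_cells:
            continue
        by_cell = dict(contrib)  # cell index -> R value at this bin
        values = np.array([v for _, v in contrib])
        med = float(np.median(values))
        boot_meds = np.empty(n_boot)
        for b in range(n_boot):
            sample = [by_cell[i] for i in boot_idx[b] if i in by_cell]
            boot_meds[b] = np.median(sample) if sample else np.nan
        ok = np.isfinite(boot_meds)
        lo, hi = np.percentile(boot_meds[ok], [2.5, 97.5])
        rows.append(
            TrajectoryRow(
                time_to_anaphase_s=off * dt_s,
                median_R=med,
                ci_lo=float(min(lo, med)),
                ci_hi=float(max(hi, med)),
                n_cells=len(contrib),
            )
        )
    return rows


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test_name: str,
    paired: bool = False,
) -> TestResult:
    """Two-sided two-sample test by name: welch_t, mann_whitney_u, levene, paired_t.

    Mann–Whitney uses the exact null distribution when both groups have
    n ≤ 20 and no ties, otherwise the normal approximation with tie and
    continuity correction; the choice is recorded in ``method``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test_name not in _TWO_SAMPLE_TESTS:
        raise ValueError(f"unknown test {test_name!r}; expected one of {_TWO_SAMPLE_TESTS}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    method = ""
    if test_name == "paired_t" or paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal group sizes")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            raise ValueError("paired differences have zero variance")
        res = sps.ttest_rel(a, b)
        test_name = "paired_t"
    elif test_name == "welch_t":
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            if np.isclose(a.mean(), b.mean()):
                return TestResult("welch_t", 0.0, 1.0, (len(a), len(b)))
            raise ValueError("both groups have zero variance")
        res = sps.ttest_ind(a, b, equal_var=False)
        method = "welch_df"
    elif test_name == "mann_whitney_u":
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        exact = len(a) <= 20 and len(b) <= 20 and not has_ties
        method = "exact" if exact else "normal_approx_tie_corrected"
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
    elif test_name == "levene":
        res = sps.levene(a, b, center="mean")
        method = "center=mean"
    return TestResult(
        name=test_name,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(len(a), len(b)),
        method=method,
    )


def count_tests(
    table: Sequence[Sequence[int]] | None = None,
    k: int | None = None,
    n: int | None = None,
    p0: float = 0.5,
) -> TestResult:
    """Exact tests on counts.

    With ``table`` (2×2): Fisher's exact test, two-sided p = sum of
    hypergeometric probabilities (margins fixed) of all tables no more
    likely than the observed one. With ``k``/``n``: exact binomial test
    against success probability ``p0``, two-sided p = sum of P(X=i) over
    all i with P(X=i) ≤ P(X=k).
    """
    if table is not None:
        arr = np.asarray(table, dtype=int)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise ValueError("Fisher test needs a 2x2 table of nonnegative counts")
        stat, p = sps.fisher_exact(arr, alternative="two-sided")
        return TestResult("fisher_exact", float(stat), float(p),
                          (int(arr[0].sum()), int(arr[1].sum())))
    if k is None or n is None:
        raise ValueError("provide either a 2x2 table or k and n")
    if k < 0 or n < 0 or k > n:
        raise ValueError("need 0 <= k <= n")
    res = sps.binomtest(k, n, p0, alternative="two-sided")
    return TestResult("exact_binomial", float(k), float(res.pvalue), (n,))
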