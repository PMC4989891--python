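"""Differential-expression engines.

Two callers live here:

* A full two-class unpaired SAM (Significance Analysis of Microarrays):
  moderated d-statistic ``d_i = (mean2_i - mean1_i) / (s_i + s0)`` with a
  permutation-derived expected-order-statistic null, delta-band calling
  and median-FDR estimation.  Used for the miRNA arrays.
* A log2 fold-change caller with pseudocount for FPKM-like mRNA tables
  without replication.

Directions are always treatment (class 2, e.g. KO) versus reference
(class 1, e.g. WT): a positive score means up in the treatment class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ConfigError, ExpressionMatrix


@dataclass
class SamConfig:
    """SAM tuning parameters (two-class unpaired design only)."""

    n_permutations: int = 1000
    delta: float = 2.0
    s0_method: str = "percentile-search"  # or "fixed"
    s0_fixed: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.delta < 0:
            raise ConfigError("delta must be non-negative")
        if self.s0_method not in ("percentile-search", "fixed"):
            raise ConfigError(f"unknown s0_method {self.s0_method!r}")
        if self.s0_method == "fixed" and self.s0_fixed is None:
            raise ConfigError("s0_fixed required when s0_method='fixed'")


@dataclass
class DECall:
    """Per-feature differential-expression record."""

    feature_id: str
    score: float  # SAM d, or log2 fold change
    direction: str  # up | down | none
    q_value: float | None
    called: bool


@dataclass
class SamFit:
    """Everything SAM computed before thresholding.

    ``d_expected`` and each row of ``perm_sorted_d`` are sorted
    non-decreasing; ``pi0`` is the estimated proportion of null
    features, from the fraction of observed d landing inside the
    25th-75th percentile band of all permuted d values.
    """

    feature_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    s0: float
    d_expected: np.ndarray
    perm_sorted_d: np.ndarray  # (n_permutations, n_features)
    pi0: float
    exhaustive: bool


@dataclass
class SamResult:
    calls: list[DECall]
    fdr_median: float | None
    cut_up: float
    cut_down: float
    n_called: int
    median_null_count: float  # median over permutations of d* outside the cuts
    pi0: float


# ---------------------------------------------------------------------------
# Core statistic
# ---------------------------------------------------------------------------

def _class_split(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = matrix.classes
    x1 = matrix.class_values(c1)
    x2 = matrix.class_values(c2)
    if x1.shape[1] < 1 or x2.shape[1] < 1:
        raise ConfigError("each class needs at least one sample")
    return x1, x2


def _d_and_s(x1: np.ndarray, x2: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    dof = n1 + n2 - 2
    if dof <= 0:
        # n=1 per class: no within-class variance is estimable; s = 0 and
        # d degenerates to a scaled mean difference (flagged upstream).
        s = np.zeros(x1.shape[0])
    else:
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m2 - m1) / (s + s0)
    d = np.where(np.isfinite(d), d, 0.0)
    return d, s


def sam_statistic(matrix: ExpressionMatrix, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature SAM statistic d and pooled standard error s.

    ``s_i = sqrt{(1/n1 + 1/n2) * [SS_1 + SS_2] / (n1 + n2 - 2)}`` and
    ``d_i = (mean2_i - mean1_i) / (s_i + s0)``.
    """
    x1, x2 = _class_split(matrix)
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        warnings.warn("a class has fewer than 2 samples; pooled variance is degenerate")
    return _d_and_s(x1, x2, s0)


def choose_s0(matrix: ExpressionMatrix, config: SamConfig | None = None) -> float:
    """Percentile search for the exchangeability (fudge) constant s0.

    Candidates are the percentiles {0, 5, ..., 100} of s.  For each
    candidate, features are binned into up to 100 quantile windows of s,
    the median absolute deviation of d is computed per window, and the
    s0 minimizing the coefficient of variation of the window MADs wins;
    ties break toward the smallest s0.  Deterministic given the matrix.
    """
    config = config or SamConfig()
    if config.s0_method == "fixed":
        return float(config.s0_fixed)  # type: ignore[arg-type]
    x1, x2 = _class_split(matrix)
    _, s = _d_and_s(x1, x2, 0.0)
    if np.all(s == 0):
        warnings.warn("all pooled standard errors are zero; s0 = 0")
        return 0.0
    n = len(s)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_windows = min(100, n)
    # quantile windows of s (equal-count bins by rank)
    order = np.argsort(s, kind="mergesort")
    bins = np.array_split(order, n_windows)
    best_s0, best_cv = None, math.inf
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    num = m2 - m1
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = num / (s + s0)
        d = np.where(np.isfinite(d), d, 0.0)
        mads = np.array([_mad(d[b]) for b in bins if len(b) > 0])
        mean = mads.mean()
        cv = math.inf if mean == 0 else mads.std(ddof=0) / mean
        if best_s0 is None or cv < best_cv - 1e-12 or (abs(cv - best_cv) <= 1e-12 and s0 < best_s0):
            best_cv, best_s0 = cv, float(s0)
    if n < 10:
        warnings.warn("s0 percentile search with <10 features is unreliable")
    return float(best_s0)


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def _label_assignments(labels: np.ndarray, classes: tuple[str, str]) -> int:
    n1 = int((labels == classes[0]).sum())
    return math.comb(len(labels), n1)


def sam_permutation_null(
    matrix: ExpressionMatrix, s0: float, config: SamConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Expected order statistics of d under label permutation.

    Returns ``(d_expected, perm_sorted_d)`` where each row of
    ``perm_sorted_d`` is one permutation's sorted d vector and
    ``d_expected[i]`` is the mean of the i-th order statistic.  When
    ``n_permutations`` is at least the number of distinct two-class
    label assignments, all C(n, n1) assignments are enumerated exactly
    once instead of sampled.
    """
    c1, c2 = matrix.classes
    labels = matrix.condition_labels.to_numpy()
    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[1]
    n1 = int((labels == c1).sum())
    n_assign = math.comb(n, n1)
    rows: list[np.ndarray] = []
    if config.n_permutations >= n_assign:
        for idx1 in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx1)] = True
            d, _ = _d_and_s(X[:, mask], X[:, ~mask], s0)
            rows.append(np.sort(d))
        exhaustive = True
    else:
        rng = np.random.default_rng(config.rng_seed)
        for _ in range(config.n_permutations):
            perm = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[perm[:n1]] = True
            d, _ = _d_and_s(X[:, mask], X[:, ~mask], s0)
            rows.append(np.sort(d))
        exhaustive = False
    perm_sorted = np.vstack(rows)
    d_expected = perm_sorted.mean(axis=0)
    return d_expected, perm_sorted


def sam_fit(matrix: ExpressionMatrix, config: SamConfig | None = None) -> SamFit:
    """Run the full SAM computation (statistic, s0, permutation null, pi0)."""
    config = config or SamConfig()
    s0 = choose_s0(matrix, config)
    d, s = sam_statistic(matrix, s0)
    d_expected, perm_sorted = sam_permutation_null(matrix, s0, config)
    q25, q75 = np.percentile(perm_sorted, [25, 75])
    n_in_band = int(((d >= q25) & (d <= q75)).sum())
    pi0 = min(1.0, n_in_band / (0.5 * len(d)))
    labels = matrix.condition_labels.to_numpy()
    n1 = int((labels == matrix.classes[0]).sum())
    exhaustive = config.n_permutations >= math.comb(len(labels), n1)
    return SamFit(matrix.feature_ids, d, s, s0, d_expected, perm_sorted, pi0, exhaustive)


# ---------------------------------------------------------------------------
# Delta-band calling and median FDR
# ---------------------------------------------------------------------------

def sam_call(fit: SamFit, config: SamConfig | None = None) -> SamResult:
    """Call significant features at the configured delta.

    With observed d sorted ascending and paired with the expected order
    statistics, the walk from the top keeps going while
    ``d(i) - d_expected(i) > delta``; the smallest observed d in that
    run becomes ``cut_up`` and every feature with ``d >= cut_up`` is
    called up (ties included).  The symmetric walk from the bottom fixes
    ``cut_down``.  The median FDR is ``pi0 x median_b #{permuted d
    outside the cuts} / n_called``, capped at 1.
    """
    config = config or SamConfig()
    delta = config.delta
    order = np.argsort(fit.d, kind="mergesort")
    d_sorted = fit.d[order]
    diffs = d_sorted - fit.d_expected
    n = len(d_sorted)

    cut_up = math.inf
    i = n - 1
    while i >= 0 and diffs[i] > delta:
        cut_up = d_sorted[i]
        i -= 1
    cut_down = -math.inf
    i = 0
    while i < n and -diffs[i] > delta:
        cut_down = d_sorted[i]
        i += 1

    up = fit.d >= cut_up
    down = fit.d <= cut_down
    n_called = int(up.sum() + down.sum())

    if n_called == 0:
        fdr = None
        med_null = 0.0
    else:
        null_counts = ((fit.perm_sorted_d >= cut_up) | (fit.perm_sorted_d <= cut_down)).sum(axis=1)
        med_null = float(np.median(null_counts))
        fdr = min(1.0, fit.pi0 * med_null / n_called)

    calls: list[DECall] = []
    for i, fid in enumerate(fit.feature_ids):
        if up[i]:
            direction, called = "up", True
        elif down[i]:
            direction, called = "down", True
        else:
            direction, called = "none", False
        calls.append(DECall(fid, float(fit.d[i]), direction, fdr if called else None, called))
    return SamResult(calls, fdr, float(cut_up), float(cut_down), n_called, med_null, fit.pi0)


def sam_de(matrix: ExpressionMatrix, config: SamConfig | None = None) -> SamResult:
    """Convenience wrapper: fit + call in one step."""
    config = config or SamConfig()
    return sam_call(sam_fit(matrix, config), config)


def tune_delta(
    fit: SamFit,
    target_calls: int,
    config: SamConfig | None = None,
    grid: Sequence[float] | None = None,
) -> float:
    """Pick delta so the number of calls is closest to ``target_calls``.

    Mirrors SAM's interactive thresholding, where the analyst slides
    delta on the observed-vs-expected plot until the call list has the
    desired size.  Ties break toward the larger (more stringent) delta.
    """
    config = config or SamConfig()
    if grid is None:
        spread = float(np.abs(fit.d - fit.d_expected[np.argsort(np.argsort(fit.d))]).max())
        grid = np.linspace(0.05, max(spread, 0.1), 100)
    best_delta, best_gap = float(grid[0]), math.inf
    for delta in grid:
        res = sam_call(fit, SamConfig(config.n_permutations, float(delta), config.s0_method,
                                      config.s0_fixed, config.rng_seed))
        gap = abs(res.n_called - target_calls)
        if gap < best_gap or (gap == best_gap and delta > best_delta):
            best_gap, best_delta = gap, float(delta)
    return best_delta


# ---------------------------------------------------------------------------
# log2 fold-change caller (FPKM tables without replication)
# ---------------------------------------------------------------------------

def log2fc_table(
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
    call_threshold: float = 1.0,
) -> list[DECall]:
    """Per-gene log2((mean_treatment + pc) / (mean_reference + pc)).

    Direction follows the sign; a gene is called iff |score| meets the
    threshold.  q-values are None (no replication assumed).  Negative
    expression values are a domain error.
    """
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("log2fc_table requires a non-negative (FPKM-like) matrix")
    x1, x2 = _class_split(matrix)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    score = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    calls = []
    for fid, sc in zip(matrix.feature_ids, score):
        if sc > 0:
            direction = "up"
        elif sc < 0:
            direction = "down"
        else:
            direction = "none"
        called = bool(abs(sc) >= call_threshold)
        calls.append(DECall(fid, float(sc), direction if sc != 0 else "none", None, called))
    return calls


# ---------------------------------------------------------------------------
# DECall table round-trip
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Sequence[DECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.feature_id, c.score, c.direction, "" if c.q_value is None else c.q_value, c.called) for c in calls],
        columns=["feature_id", "score", "direction", "q_value", "called"],
    )


def write_calls(calls: Sequence[DECall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tscore\tdirection\tq_value\tcalled\n")
        for c in calls:
            q = "" if c.q_value is None else repr(float(c.q_value))
            fh.write(f"{c.feature_id}\t{repr(float(c.score))}\t{c.direction}\t{q}\t{int(c.called)}\n")


def read_calls(path: str | Path) -> list[DECall]:
    calls: list[DECall] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            fid, score, direction, q, called = line.rstrip("\n").split("\t")
            calls.append(
                DECall(fid, float(score), direction, float(q) if q else None, bool(int(called)))
            )
    return calls
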