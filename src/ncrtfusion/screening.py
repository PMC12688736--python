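"""Paired pre/post-treatment screening of the candidate markers.

Continuous markers are compared with a paired t-test, binary markers with
McNemar's chi-square on the discordant pair counts (no continuity
correction), and k>=3 categorical markers with the Stuart-Maxwell marginal-
homogeneity test. Markers with a two-sided p below alpha become the model
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .markers import (
    CATEGORICAL_MARKERS,
    CONTINUOUS_MARKERS,
    MARKER_NAMES,
    MARKERS_BY_NAME,
    feature_index,
)

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class ZeroVarianceError(ValueError):
    """Paired differences have zero variance; the t statistic is undefined."""


class NoDiscordantPairsError(ValueError):
    """A paired 2x2 table has no discordant pairs; McNemar is undefined."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one paired pre/post test."""

    marker: str
    kind: str  # "paired_t" | "mcnemar" | "marginal_homogeneity"
    statistic: float
    df: int
    p_value: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class ScreeningResult:
    """Per-marker test results plus the selected marker set."""

    results: dict[str, TestResult]
    selected: list[str]
    alpha: float
    degenerate: dict[str, str] = field(default_factory=dict)

    @property
    def selected_indices(self) -> list[int]:
        """Model feature numbers (1..7) of the selected markers that carry one,
        in the canonical numbering order."""
        idx = [feature_index(m) for m in self.selected]
        return sorted(i for i in idx if i is not None)


def paired_t_test(pre, post, marker: str = "", alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided paired t-test on d = pre - post with df = n - 1."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError(f"{marker or 'paired_t_test'}: pre/post length mismatch")
    n = len(pre)
    if n < 2:
        raise ValueError(f"{marker or 'paired_t_test'}: need n >= 2 pairs, got {n}")
    if not (np.isfinite(pre).all() and np.isfinite(post).all()):
        raise ValueError(f"{marker or 'paired_t_test'}: non-finite values")
    d = pre - post
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ZeroVarianceError(
            f"{marker or 'paired_t_test'}: zero variance of paired differences"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(marker, "paired_t", float(t), n - 1, float(p), alpha)


def mcnemar_test(b: int, c: int, marker: str = "", alpha: float = DEFAULT_ALPHA) -> TestResult:
    """McNemar chi-square (b - c)^2 / (b + c), df=1, no continuity correction.

    ``b`` and ``c`` are the two discordant cross-counts of the paired 2x2
    table; the statistic is symmetric in (b, c).
    """
    if b < 0 or c < 0:
        raise ValueError(f"{marker or 'mcnemar_test'}: discordant counts must be >= 0")
    if b + c == 0:
        raise NoDiscordantPairsError(f"{marker or 'mcnemar_test'}: no discordant pairs")
    chi2 = (b - c) ** 2 / (b + c)
    p = stats.chi2.sf(chi2, df=1)
    return TestResult(marker, "mcnemar", float(chi2), 1, float(p), alpha)


def _cross_table(pre, post, levels) -> np.ndarray:
    levels = list(levels)
    lut = {lv: i for i, lv in enumerate(levels)}
    tab = np.zeros((len(levels), len(levels)), dtype=float)
    for a, b in zip(pre, post):
        if a not in lut or b not in lut:
            raise ValueError(f"value outside declared level set {levels}: ({a}, {b})")
        tab[lut[a], lut[b]] += 1
    return tab


def marginal_homogeneity_test(
    pre, post, levels, marker: str = "", alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Stuart-Maxwell test of marginal homogeneity on the k x k cross-table.

    For k = 2 the call is routed to :func:`mcnemar_test` (the two tests
    coincide there). The statistic is d' V^- d on the first k-1 categories,
    with V the covariance of the marginal differences; a rank-deficient V is
    handled by the Moore-Penrose inverse with df reduced to rank(V).
    """
    levels = list(levels)
    k = len(levels)
    if len(pre) != len(post):
        raise ValueError(f"{marker or 'marginal_homogeneity'}: pre/post length mismatch")
    tab = _cross_table(pre, post, levels)
    if k < 2:
        raise ValueError("need at least 2 levels")
    if k == 2:
        b, c = int(tab[0, 1]), int(tab[1, 0])
        return mcnemar_test(b, c, marker=marker, alpha=alpha)
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    d = (row - col)[: k - 1]
    V = np.zeros((k - 1, k - 1))
    for i in range(k - 1):
        V[i, i] = row[i] + col[i] - 2.0 * tab[i, i]
        for j in range(i + 1, k - 1):
            V[i, j] = V[j, i] = -(tab[i, j] + tab[j, i])
    if np.allclose(d, 0.0) and np.allclose(V, 0.0):
        # perfect marginal homogeneity with no discordance at all
        return TestResult(marker, "marginal_homogeneity", 0.0, k - 1, 1.0, alpha)
    rank = int(np.linalg.matrix_rank(V))
    if rank < k - 1:
        logger.info(
            "%s: difference covariance is rank-deficient (rank %d of %d); "
            "using generalized inverse", marker or "marginal_homogeneity", rank, k - 1
        )
        stat = float(d @ np.linalg.pinv(V) @ d)
        df = max(rank, 1)
    else:
        stat = float(d @ np.linalg.solve(V, d))
        df = k - 1
    stat = max(stat, 0.0)
    p = stats.chi2.sf(stat, df=df)
    return TestResult(marker, "marginal_homogeneity", stat, df, float(p), alpha)


def screen_features(cohort, alpha: float = DEFAULT_ALPHA) -> ScreeningResult:
    """Run the paired pre/post test for every candidate marker.

    Continuous markers -> paired t; binary -> McNemar on the per-patient
    discordant counts; k>=3 categorical -> Stuart-Maxwell. Markers whose test
    is degenerate (zero-variance differences, no discordant pairs) are logged
    and treated as not selected.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    results: dict[str, TestResult] = {}
    degenerate: dict[str, str] = {}
    for m in MARKER_NAMES:
        pre_col, post_col = f"pre_{m}", f"post_{m}"
        if pre_col not in cohort.columns or post_col not in cohort.columns:
            raise KeyError(f"cohort is missing columns for marker {m!r}")
        pre = cohort[pre_col].to_numpy()
        post = cohort[post_col].to_numpy()
        try:
            if m in CONTINUOUS_MARKERS:
                results[m] = paired_t_test(pre, post, marker=m, alpha=alpha)
            else:
                levels = MARKERS_BY_NAME[m].levels
                results[m] = marginal_homogeneity_test(
                    pre, post, levels, marker=m, alpha=alpha
                )
        except (ZeroVarianceError, NoDiscordantPairsError) as err:
            logger.warning("marker %s not testable: %s", m, err)
            degenerate[m] = str(err)
    selected = [m for m in MARKER_NAMES if m in results and results[m].significant]
    return ScreeningResult(results, selected, alpha, degenerate)
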