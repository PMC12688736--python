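"""Exhaustive feature-subset ablation and top-K proportion analysis.

All 2^m - 1 non-empty subsets of the numbered model features are evaluated
under an identical seed schedule (a paired comparison: subsets differ only by
their features), ranked per metric, and the per-feature share among the top-K
subsets is computed (slot-share by default: a feature's occurrences among the
top-K masks divided by all feature occurrences among those masks, so shares
sum to one; subset-membership rates are available as an alternative).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from .evaluation import METRIC_KEYS, MetricsReport, ModelConfig, repeat_evaluate

logger = logging.getLogger(__name__)

PROPORTION_MODES = ("slot_share", "membership")


def combo_label(mask) -> str:
    """Human-readable subset label, ascending indices joined by ' + '."""
    return " + ".join(str(i) for i in sorted(mask))


@dataclass
class AblationResult:
    """Metrics (or a recorded failure) for one feature subset."""

    mask: tuple[int, ...]
    report: MetricsReport | None = None
    error: str | None = None

    @property
    def label(self) -> str:
        return combo_label(self.mask)


@dataclass
class ProportionTable:
    """Per-feature share among the top-K subsets, one row per ranking metric."""

    k: int
    mode: str
    shares: dict[str, dict[int, float]]  # metric -> feature index -> share


@dataclass
class AblationConfig:
    """Ablation run settings; the seed schedule is shared across subsets."""

    model: ModelConfig = field(default_factory=ModelConfig)
    n_repeats: int = 5
    base_seed: int = 0
    feature_indices: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    cache_dir: str | Path | None = None


def enumerate_subsets(m: int) -> list[tuple[int, ...]]:
    """All 2^m - 1 non-empty subsets of features 1..m, by size then lexicographic."""
    if not 1 <= m <= 20:
        raise ValueError("feature count must be in 1..20")
    out: list[tuple[int, ...]] = []
    for size in range(1, m + 1):
        out.extend(combinations(range(1, m + 1), size))
    return out


def _cache_path(cache_dir: Path, mask: tuple[int, ...]) -> Path:
    return cache_dir / ("mask_" + "-".join(str(i) for i in mask) + ".json")


def run_ablation(cohort, config: AblationConfig | None = None) -> list[AblationResult]:
    """Evaluate every non-empty subset of the configured features.

    Identical (base_seed + r) schedules across subsets; per-mask results are
    cached as JSON under ``cache_dir`` when given, so an interrupted run
    resumes. A failing subset is recorded with its error, never dropped.
    """
    config = config or AblationConfig()
    indices = tuple(sorted(config.feature_indices))
    masks = [
        tuple(indices[i - 1] for i in mask)
        for mask in enumerate_subsets(len(indices))
    ]
    cache_dir = Path(config.cache_dir) if config.cache_dir else None
    if cache_dir:
        cache_dir.mkdir(parents=True, exist_ok=True)
    results: list[AblationResult] = []
    for pos, mask in enumerate(masks, 1):
        if cache_dir:
            path = _cache_path(cache_dir, mask)
            if path.exists():
                payload = json.loads(path.read_text())
                report = MetricsReport(**payload)
                report.feature_subset = tuple(report.feature_subset)
                results.append(AblationResult(mask=mask, report=report))
                continue
        try:
            report = repeat_evaluate(
                cohort, mask, config.model,
                n_repeats=config.n_repeats, base_seed=config.base_seed,
            )
            results.append(AblationResult(mask=mask, report=report))
            if cache_dir:
                _cache_path(cache_dir, mask).write_text(json.dumps(report.to_dict()))
        except Exception as err:  # noqa: BLE001 - recorded, not dropped
            logger.warning("subset %s failed: %s", combo_label(mask), err)
            results.append(AblationResult(mask=mask, error=f"{combo_label(mask)}: {err}"))
        if pos % 16 == 0 or pos == len(masks):
            logger.info("ablation progress: %d/%d subsets", pos, len(masks))
    return results


def rank_topk(results, metric: str, k: int) -> list[AblationResult]:
    """Top-k subsets by a metric's mean, descending.

    Ties break toward the smaller subset, then lexicographic mask; failed
    subsets are excluded. If fewer than k results exist, all are used with a
    logged warning.
    """
    if metric not in METRIC_KEYS:
        raise ValueError(f"unknown metric {metric!r}; valid: {METRIC_KEYS}")
    ok = [r for r in results if r.report is not None]
    if k > len(ok):
        logger.warning("requested top-%d but only %d results; using all", k, len(ok))
        k = len(ok)
    if k < 1:
        raise ValueError("no results to rank")
    ranked = sorted(ok, key=lambda r: (-r.report.mean(metric), len(r.mask), r.mask))
    return ranked[:k]


def feature_proportions(topk, mode: str = "slot_share") -> dict[int, float]:
    """Per-feature share among the top-K masks.

    slot_share: occurrences of the feature across the masks divided by all
    feature occurrences (sums to 1). membership: fraction of masks containing
    the feature.
    """
    if not topk:
        raise ValueError("top-K list is empty")
    if mode not in PROPORTION_MODES:
        raise ValueError(f"unknown proportion mode {mode!r}; valid: {PROPORTION_MODES}")
    features = sorted({i for r in topk for i in r.mask})
    counts = {i: sum(1 for r in topk if i in r.mask) for i in features}
    if mode == "slot_share":
        total = sum(counts.values())
        return {i: counts[i] / total for i in features}
    return {i: counts[i] / len(topk) for i in features}


def proportion_analysis(results, k: int = 50, mode: str = "slot_share",
                        metrics=METRIC_KEYS) -> ProportionTable:
    """Top-K per-feature shares for each ranking metric."""
    all_features = sorted({i for r in results for i in r.mask})
    shares: dict[str, dict[int, float]] = {}
    for metric in metrics:
        topk = rank_topk(results, metric, k)
        s = feature_proportions(topk, mode=mode)
        shares[metric] = {i: s.get(i, 0.0) for i in all_features}
    return ProportionTable(k=k, mode=mode, shares=shares)
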