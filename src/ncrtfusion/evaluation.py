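"""Leave-one-out evaluation of the fusion + SVM pipeline.

Every patient is held out once; standardization, fusion training and the SVM
fit all see only the remaining n-1 rows, so the held-out score is leakage-
free. Pooled held-out scores give the confusion table (threshold 0 on the
signed SVM margin), ACC/SEN/SPE in percent and the rank (Mann-Whitney) AUC.
Repeating over fusion-initialization seeds yields the mean +/- SD report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .fusion import FusionConfig, _train_batch
from .markers import feature_names
from .svm import decision_score, fit_svm

logger = logging.getLogger(__name__)

ENDPOINT_SCHEMES = {
    "good_vs_poor": (0, 1),  # responders: TRG 0-1 vs TRG 2-3
    "pcr_vs_rest": (0,),     # pathological complete response only
}

METRIC_KEYS = ("acc", "auc", "sen", "spe")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN of pooled held-out predictions."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """ACC/SEN/SPE (percent) and AUC as mean +/- SD over repeated runs."""

    acc_mean: float
    acc_sd: float
    auc_mean: float
    auc_sd: float
    sen_mean: float
    sen_sd: float
    spe_mean: float
    spe_sd: float
    n_repeats: int
    endpoint: str
    feature_subset: tuple[int, ...] = ()
    notes: list[str] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return getattr(self, f"{metric}_mean")

    def sd(self, metric: str) -> float:
        return getattr(self, f"{metric}_sd")

    def to_dict(self) -> dict:
        return {
            "feature_subset": list(self.feature_subset),
            "endpoint": self.endpoint,
            "n_repeats": self.n_repeats,
            **{
                f"{m}_{s}": getattr(self, f"{m}_{s}")
                for m in METRIC_KEYS
                for s in ("mean", "sd")
            },
            "notes": self.notes,
        }


@dataclass
class ModelConfig:
    """End-to-end model settings: fusion layer, SVM and endpoint."""

    fusion: FusionConfig = field(default_factory=FusionConfig)
    svm_C: float = 1.0
    svm_gamma: float | str = "scale"
    endpoint: str = "good_vs_poor"

    def validate(self) -> None:
        self.fusion.validate()
        if self.svm_C <= 0:
            raise ValueError("svm_C must be > 0")
        if self.endpoint not in ENDPOINT_SCHEMES:
            raise ValueError(
                f"unknown endpoint scheme {self.endpoint!r}; "
                f"valid: {sorted(ENDPOINT_SCHEMES)}"
            )


@dataclass
class LoocvResult:
    """One leave-one-out pass: pooled confusion, AUC and per-patient scores."""

    confusion: ConfusionCounts
    auc: float
    scores: pd.DataFrame  # patient_id, score, label, prediction

    @property
    def metrics(self) -> tuple[float, float, float]:
        return confusion_metrics(self.confusion)


def binarize_trg(trg, scheme: str = "good_vs_poor"):
    """Map TRG grades to the binary endpoint (1 = responder/positive)."""
    if scheme not in ENDPOINT_SCHEMES:
        raise ValueError(
            f"unknown endpoint scheme {scheme!r}; valid: {sorted(ENDPOINT_SCHEMES)}"
        )
    positive = ENDPOINT_SCHEMES[scheme]
    arr = np.asarray(trg)
    if not np.isin(arr, [0, 1, 2, 3]).all():
        raise ValueError("trg values must be in {0, 1, 2, 3}")
    out = np.isin(arr, positive).astype(int)
    return int(out) if np.isscalar(trg) else out


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(ACC, SEN, SPE) in percent; undefined denominators yield NaN + a log note."""
    if c.total == 0:
        raise ValueError("confusion table is empty")
    acc = 100.0 * (c.tp + c.tn) / c.total
    if c.tp + c.fn > 0:
        sen = 100.0 * c.tp / (c.tp + c.fn)
    else:
        logger.warning("sensitivity undefined: no positive cases (TP+FN=0)")
        sen = float("nan")
    if c.tn + c.fp > 0:
        spe = 100.0 * c.tn / (c.tn + c.fp)
    else:
        logger.warning("specificity undefined: no negative cases (TN+FP=0)")
        spe = float("nan")
    return acc, sen, spe


def auc_rank(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _fold_seed(run_seed: int, patient_id: int) -> np.random.SeedSequence:
    # keyed to patient_id, not row index, so metrics are row-order invariant
    return np.random.SeedSequence([int(run_seed), int(patient_id)])


def loocv_evaluate(cohort, subset, config: ModelConfig | None = None,
                   seed: int = 0) -> LoocvResult:
    """Leave-one-out evaluation of the pipeline on one feature subset.

    ``subset`` lists model feature numbers (1..7); baseline (pre-treatment)
    values of those markers are the inputs. Per fold, standardization
    parameters, fusion parameters and the SVM are fit on the n-1 training
    rows only. Fold fusion seeds derive from (seed, held-out patient_id).
    """
    config = config or ModelConfig()
    config.validate()
    subset = tuple(int(i) for i in subset)
    cohort = cohort.sort_values("patient_id").reset_index(drop=True)
    names = feature_names(subset)
    X = cohort[[f"pre_{m}" for m in names]].to_numpy(dtype=float)
    y = binarize_trg(cohort["trg"].to_numpy(), config.endpoint)
    pids = cohort["patient_id"].to_numpy()
    n, m = X.shape
    if n < 4:
        raise ValueError("leave-one-out needs n >= 4")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        bad = pids[y == counts.argmin()]
        raise ValueError(
            f"training fold would lose a class when holding out patient "
            f"{bad[0]}: each class needs >= 2 members"
        )

    # Per-fold training-set standardization from leave-one-out sums.
    sx = X.sum(axis=0)
    sx2 = (X ** 2).sum(axis=0)
    mu = (sx - X) / (n - 1)                      # (n, m): fold f's train mean
    var = (sx2 - X ** 2 - (n - 1) * mu ** 2) / (n - 2)
    if (var <= 0).any():
        f, j = np.argwhere(var <= 0)[0]
        raise ValueError(
            f"zero-variance feature {subset[j]} in the training fold holding "
            f"out patient {pids[f]}"
        )
    sd = np.sqrt(var)

    keep = ~np.eye(n, dtype=bool)
    Ztr = np.empty((n, n - 1, m))
    Ytr = np.empty((n, n - 1))
    for f in range(n):
        Ztr[f] = (X[keep[f]] - mu[f]) / sd[f]
        Ytr[f] = y[keep[f]]
    seeds = [_fold_seed(seed, pid) for pid in pids]
    P, history = _train_batch(Ztr, Ytr, config.fusion, seeds)

    # Batched fusion of training rows and held-out row for every fold; the
    # per-fold result equals fuse(params_f, z) (asserted by an equivalence
    # test against the public single-fold API).
    s = (P["keys"] @ P["query"][:, :, None])[:, :, 0] / np.sqrt(config.fusion.d_k)
    s = s - s.max(axis=1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=1, keepdims=True)
    Ztest = (X - mu[np.arange(n)]) / sd[np.arange(n)]  # row f standardized by fold f
    if config.fusion.mode == "embed-sum":
        offs = w[:, None, :] @ P["offsets"]  # (n, 1, d_k)
        fused_train = (Ztr * w[:, None, :]) @ P["embeds"] + offs
        fused_test = ((Ztest * w)[:, None, :] @ P["embeds"] + offs)[:, 0, :]
    else:
        fused_train = Ztr * w[:, None, :]
        fused_test = Ztest * w

    scores = np.empty(n)
    for f in range(n):
        model = fit_svm(fused_train[f], Ytr[f], C=config.svm_C, gamma=config.svm_gamma)
        scores[f] = decision_score(model, fused_test[f])

    pred = (scores > 0).astype(int)
    confusion = ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )
    auc = auc_rank(scores, y)
    table = pd.DataFrame(
        {"patient_id": pids, "score": scores, "label": y, "prediction": pred}
    )
    return LoocvResult(confusion=confusion, auc=auc, scores=table)


def repeat_evaluate(cohort, subset, config: ModelConfig | None = None,
                    n_repeats: int = 5, base_seed: int = 0) -> MetricsReport:
    """Run LOOCV with ``n_repeats`` fusion seeds (base_seed + r) -> mean +/- SD.

    The data are fixed; only the fusion initialization varies across repeats,
    so the SD isolates the model's training stochasticity. SD uses ddof=1 and
    is defined as 0 for a single repeat.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    config = config or ModelConfig()
    rows = []
    for r in range(n_repeats):
        res = loocv_evaluate(cohort, subset, config, seed=base_seed + r)
        acc, sen, spe = res.metrics
        rows.append((acc, res.auc, sen, spe))
    arr = np.asarray(rows, dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(4)
    return MetricsReport(
        acc_mean=means[0], acc_sd=sds[0],
        auc_mean=means[1], auc_sd=sds[1],
        sen_mean=means[2], sen_sd=sds[2],
        spe_mean=means[3], spe_sd=sds[3],
        n_repeats=n_repeats,
        endpoint=config.endpoint,
        feature_subset=tuple(int(i) for i in subset),
    )
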