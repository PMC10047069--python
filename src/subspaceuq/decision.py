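"""The decision layer: ArgMax and KS-ratio calls, abstention, and metrics.

Two branches classify each test case's predictive distribution:

* **ArgMax** — the class with the larger mean sampled probability.
* **KS ratio** — the case's ACP-probability samples are compared by
  two-sample Kolmogorov-Smirnov tests against reference distributions
  pooled from held-out calibration patients of each ground-truth class;
  the ratio p_NOTACP / p_ACP above 1 calls NOTACP, below 1 calls ACP.

The final call is the shared class when the branches agree and ABSTAIN when
they disagree. Ties (equal means, ratio exactly 1) resolve to NOTACP, the
non-positive, clinically conservative call. ACP is the positive class
throughout the confusion metrics.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .datasets import ACP, NOTACP
from .ess import PredictiveDistribution

ABSTAIN = "ABSTAIN"

_P_FLOOR = 1e-300


@dataclasses.dataclass
class DecisionRecord:
    case_id: str
    argmax_call: str
    ks_call: str
    final_call: str
    p_acp: float
    p_notacp: float

    @property
    def ks_ratio(self) -> float:
        return self.p_notacp / self.p_acp


@dataclasses.dataclass
class ConfusionMetrics:
    """Counts and rates over non-abstained cases; ACP is positive."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    fnr: float
    fpr: float
    accuracy: float
    abstention_rate: float


def ks_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample KS statistic: sup over pooled points of |ECDF_a - ECDF_b|."""
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.sort(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ecdf_a = np.searchsorted(a, pooled, side="right") / a.size
    ecdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(ecdf_a - ecdf_b)))


def ks_pvalue(D: float, n: int, m: int) -> float:
    """Asymptotic two-sample KS p-value.

    p = Q(lambda) with lambda = D * sqrt(nm/(n+m)) and
    Q(lambda) = 2 * sum_{k>=1} (-1)^{k-1} exp(-2 k^2 lambda^2), the series
    truncated once terms fall below 1e-12; the result is clipped into
    (0, 1] so downstream ratios are always defined.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"KS statistic must lie in [0, 1], got {D}")
    if n < 1 or m < 1:
        raise ValueError("sample sizes must be >= 1")
    lam = D * np.sqrt(n * m / (n + m))
    if lam == 0.0:
        return 1.0
    total = 0.0
    for k in range(1, 1001):
        term = 2.0 * (-1.0) ** (k - 1) * np.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-12:
            break
    return float(np.clip(total, _P_FLOOR, 1.0))


def ks_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic and its asymptotic p-value."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return (d := ks_statistic(a, b)), ks_pvalue(d, a.size, b.size)


def argmax_predict(pred: PredictiveDistribution) -> str:
    """Class with the larger mean sampled probability; exact tie -> NOTACP."""
    return ACP if pred.class_means[0] > pred.class_means[1] else NOTACP


def ks_ratio_predict(
    pred: PredictiveDistribution,
    ref_acp: np.ndarray,
    ref_notacp: np.ndarray,
) -> tuple[str, float, float]:
    """Distribution-shape call from the ratio of KS p-values.

    The case's ACP-probability samples are KS-tested against each class's
    reference distribution; p_NOTACP/p_ACP > 1 calls NOTACP, < 1 calls ACP,
    and a ratio of exactly 1 resolves to NOTACP. Returns (call, p_acp,
    p_notacp).
    """
    _, p_acp = ks_test(pred.acp_samples, ref_acp)
    _, p_notacp = ks_test(pred.acp_samples, ref_notacp)
    ratio = p_notacp / p_acp
    return (ACP if ratio < 1.0 else NOTACP), p_acp, p_notacp


def abstain_predict(argmax_call: str, ks_call: str) -> str:
    """Final call: the shared class on agreement, ABSTAIN on disagreement."""
    return argmax_call if argmax_call == ks_call else ABSTAIN


def decide_cases(
    preds: Iterable[PredictiveDistribution],
    ref_acp: np.ndarray,
    ref_notacp: np.ndarray,
) -> list[DecisionRecord]:
    """Run both branches plus the abstention rule over a list of cases."""
    records = []
    for pred in preds:
        am = argmax_predict(pred)
        ks, p_acp, p_notacp = ks_ratio_predict(pred, ref_acp, ref_notacp)
        records.append(
            DecisionRecord(
                case_id=pred.case_id,
                argmax_call=am,
                ks_call=ks,
                final_call=abstain_predict(am, ks),
                p_acp=p_acp,
                p_notacp=p_notacp,
            )
        )
    return records


def build_references(
    preds: Iterable[PredictiveDistribution],
    truths: Mapping[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Pool calibration cases' ACP-probability samples by ground-truth class."""
    acp_pool, notacp_pool = [], []
    for pred in preds:
        truth = truths[pred.case_id]
        (acp_pool if truth == ACP else notacp_pool).append(pred.acp_samples)
    if not acp_pool or not notacp_pool:
        raise ValueError("references require calibration cases of both classes")
    return np.concatenate(acp_pool), np.concatenate(notacp_pool)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample p-value; identical constant samples give p = 1."""
    if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
        return 1.0
    p = _stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def mean_difference_filter(
    preds: Sequence[PredictiveDistribution],
    truths: Mapping[str, str],
    alphas: Sequence[float] = (0.05, 0.01, 0.005, 0.001),
) -> dict[float, dict]:
    """Sweep of the class-mean-difference abstention filter.

    Per case, a Welch location test compares the ACP- and NOTACP-probability
    sample vectors; at each threshold alpha the cases whose p-value is >=
    alpha (i.e. whose class means are statistically indistinguishable) are
    abstained and the rest are scored by the ArgMax call. ``alpha = 0``
    disables the filter (every p-value is strictly positive, so the
    degenerate threshold retains everything). Returns, per alpha, the
    decision records and the confusion metrics of the retained cases
    (metrics are None when everything abstains).
    """
    pvals = np.array([_welch_p(p.samples[:, 0], p.samples[:, 1]) for p in preds])
    sweep: dict[float, dict] = {}
    for alpha in alphas:
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        records = []
        for pred, p in zip(preds, pvals):
            call = argmax_predict(pred)
            final = ABSTAIN if (alpha > 0.0 and p >= alpha) else call
            records.append(
                DecisionRecord(
                    case_id=pred.case_id,
                    argmax_call=call,
                    ks_call=call,
                    final_call=final,
                    p_acp=float(p),
                    p_notacp=float(p),
                )
            )
        try:
            metrics = confusion_metrics(records, truths)
        except ValueError:
            metrics = None
        sweep[float(alpha)] = {"records": records, "metrics": metrics}
    return sweep


def confusion_metrics(
    records: Sequence[DecisionRecord],
    truths: Mapping[str, str],
) -> ConfusionMetrics:
    """Confusion counts and rates with ACP positive.

    Counts and rates cover non-abstained cases only; the abstention rate is
    taken over all cases. Raises when every case abstained.
    """
    kept = [r for r in records if r.final_call != ABSTAIN]
    if not kept:
        raise ValueError("all cases abstained; confusion metrics are undefined")
    tp = fp = tn = fn = 0
    for r in kept:
        truth = truths[r.case_id]
        if r.final_call == ACP:
            tp += truth == ACP
            fp += truth != ACP
        else:
            tn += truth != ACP
            fn += truth == ACP
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        fnr=1.0 - sens if tp + fn else float("nan"),
        fpr=1.0 - spec if tn + fp else float("nan"),
        accuracy=(tp + tn) / len(kept),
        abstention_rate=1.0 - len(kept) / len(records),
    )
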