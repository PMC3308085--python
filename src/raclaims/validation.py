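"""Validation of the claims algorithm against the clinical gold standard.

Provides the 2x2 cross-classification, PPV/NPV/sensitivity/specificity with
binomial confidence intervals, a misclassification-bias analysis relating
the response rate the algorithm *observes* to the *true* rate implied by
its predictive values, a discordance report, and the comorbidity-exclusion
sensitivity analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from decimal import Decimal, ROUND_HALF_UP

from scipy.stats import beta as beta_dist, norm

from .data_model import (
    AlgorithmResult,
    ConfusionMatrix,
    Flag,
    GoldStandardResult,
    MetricWithCI,
    PerformanceMetrics,
    TreatmentEpisode,
)

CI_METHODS = ("clopper_pearson", "wald", "wald_pooled_n")


def _episode_key(episode: TreatmentEpisode) -> tuple:
    return (episode.patient_id, episode.index_drug.value, episode.index_date)


def confusion_matrix(
    algorithm_results: Sequence[AlgorithmResult],
    gold_results: Sequence[GoldStandardResult],
) -> ConfusionMatrix:
    """Cross-classify algorithm vs gold standard over the same episodes.

    TP counts episodes positive by both; the gold standard is truth.
    Raises if the two result sets do not cover identical episode sets.
    """
    algo = {_episode_key(r.episode): r.effective for r in algorithm_results}
    gold = {_episode_key(r.episode): r.effective for r in gold_results}
    if set(algo) != set(gold):
        only_a = set(algo) - set(gold)
        only_g = set(gold) - set(algo)
        raise ValueError(
            f"episode sets differ: {len(only_a)} only in algorithm results, "
            f"{len(only_g)} only in gold-standard results"
        )
    tp = fp = fn = tn = 0
    for key, a in algo.items():
        g = gold[key]
        if a and g:
            tp += 1
        elif a and not g:
            fp += 1
        elif not a and g:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def binomial_ci(
    k: int, n: int, method: str = "clopper_pearson", alpha: float = 0.05, pooled_n: int | None = None
) -> tuple[float, float]:
    """95% (by default) confidence interval for a binomial proportion k/n.

    ``clopper_pearson`` is the exact interval; ``wald`` the normal
    approximation on n; ``wald_pooled_n`` a normal approximation using a
    pooled denominator (`pooled_n`) for the standard error, matching
    reports that compute every metric's interval on the full sample size.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    p = k / n
    if method == "clopper_pearson":
        lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
        upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
        return lower, upper
    if method in ("wald", "wald_pooled_n"):
        n_se = pooled_n if (method == "wald_pooled_n" and pooled_n) else n
        z = float(norm.ppf(1 - alpha / 2))
        half = z * (p * (1 - p) / n_se) ** 0.5
        return max(0.0, p - half), min(1.0, p + half)
    raise ValueError(f"unknown CI method {method!r}; expected one of {CI_METHODS}")


def _metric(
    k: int, n: int, method: str, alpha: float, pooled_n: int
) -> MetricWithCI | None:
    if n == 0:
        return None
    lo, hi = binomial_ci(k, n, method, alpha, pooled_n)
    p = k / n
    return MetricWithCI(point=p, ci_lower=min(lo, p), ci_upper=max(hi, p))


def performance_metrics(
    cm: ConfusionMatrix, ci_method: str = "clopper_pearson", alpha: float = 0.05
) -> PerformanceMetrics:
    """PPV, NPV, sensitivity and specificity with binomial CIs.

    A metric whose denominator is zero is reported as absent (None).
    """
    return PerformanceMetrics(
        ppv=_metric(cm.tp, cm.tp + cm.fp, ci_method, alpha, cm.n),
        npv=_metric(cm.tn, cm.tn + cm.fn, ci_method, alpha, cm.n),
        se=_metric(cm.tp, cm.tp + cm.fn, ci_method, alpha, cm.n),
        sp=_metric(cm.tn, cm.tn + cm.fp, ci_method, alpha, cm.n),
    )


def percent(value: float) -> int:
    """Proportion -> integer percent, rounded half-up (report convention)."""
    # round first in decimal space so binary float noise cannot push an
    # exact half below the rounding boundary
    return int(
        Decimal(str(round(value * 100, 9))).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class BiasRow:
    """Bias from outcome misclassification at one observed response rate.

    ``true_rate`` inverts the observed rate through the algorithm's
    predictive values: of the observed positives a fraction PPV are truly
    effective, and of the observed negatives a fraction (1 - NPV) are.
    ``relative_bias`` is (observed - true) / true.
    """

    observed_rate: float
    true_rate: float
    relative_bias: float


def bias_analysis(observed_rate: float, ppv: float, npv: float) -> BiasRow:
    """True response rate and relative bias implied by PPV/NPV."""
    for name, v in (("observed_rate", observed_rate), ("ppv", ppv), ("npv", npv)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    true_rate = observed_rate * ppv + (1.0 - observed_rate) * (1.0 - npv)
    if true_rate == 0.0:
        raise ValueError("true rate is zero; relative bias undefined")
    return BiasRow(
        observed_rate=observed_rate,
        true_rate=true_rate,
        relative_bias=(observed_rate - true_rate) / true_rate,
    )


def bias_table(
    ppv: float, npv: float, observed_rates: Iterable[float] = (0.30, 0.40, 0.50, 0.60)
) -> list[BiasRow]:
    return [bias_analysis(r, ppv, npv) for r in observed_rates]


@dataclass(frozen=True)
class DiscordanceReport:
    """Machine-readable discordance summary.

    False negatives (algorithm negative, gold positive) carry the component
    flags that fired; false positives by construction satisfied every
    algorithm condition, so only their identity is listed.
    """

    false_positive_keys: tuple
    false_negative_keys: tuple
    false_negative_flag_counts: dict[Flag, int]


def discordance_report(
    algorithm_results: Sequence[AlgorithmResult],
    gold_results: Sequence[GoldStandardResult],
) -> DiscordanceReport:
    gold = {_episode_key(r.episode): r.effective for r in gold_results}
    fps, fns = [], []
    flag_counts: Counter = Counter()
    for res in algorithm_results:
        key = _episode_key(res.episode)
        if key not in gold:
            raise ValueError(f"episode {key} missing from gold-standard results")
        if res.effective and not gold[key]:
            fps.append(key)
        elif not res.effective and gold[key]:
            fns.append(key)
            flag_counts.update(res.flags)
    return DiscordanceReport(
        false_positive_keys=tuple(sorted(fps)),
        false_negative_keys=tuple(sorted(fns)),
        false_negative_flag_counts=dict(flag_counts),
    )


def comorbidity_exclusion(
    episodes: Sequence[TreatmentEpisode],
    comorbidity_flags: Iterable[tuple[str, str, bool]],
) -> list[TreatmentEpisode]:
    """Drop all episodes of patients carrying any flagged comorbidity.

    Flags arrive as (patient_id, condition, flag) triples, pre-computed
    upstream (e.g. PTSD, low-back pain, fibromyalgia, hepatitis C or
    depression codes that can inflate patient global scores independently
    of RA activity).
    """
    flagged = {pid for pid, _cond, flag in comorbidity_flags if flag}
    return [ep for ep in episodes if ep.patient_id not in flagged]
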