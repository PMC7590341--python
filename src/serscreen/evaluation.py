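"""Screening-performance evaluation against reference HPLC concentrations.

A labeled cohort pairs each sample's summed Z-ratio with its HPLC
benzoic-acid concentration; a sample is a true positive when the
concentration exceeds the regulatory limit (600 ppm by default).  This
module provides the empirical ROC curve with Mann-Whitney pair-count
AUC, confusion statistics at a threshold, the score/concentration
Pearson correlation, and a seeded bootstrap quantifying the triage
risks of a screening rule: how often a truly over-limit sample slips
through (false negative) and what fraction of compliant samples get
referred to confirmatory HPLC anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CohortEntry",
    "LabeledCohort",
    "RocResult",
    "ConfusionResult",
    "MonteCarloResult",
    "DegenerateLabelError",
    "empirical_roc",
    "confusion_at_threshold",
    "pearson_correlation",
    "monte_carlo_triage",
]


class DegenerateLabelError(ValueError):
    """Cohort lacks both a positive and a negative sample."""


@dataclass(frozen=True)
class CohortEntry:
    sample_id: str
    sum_score: float
    hplc_ppm: float


@dataclass
class LabeledCohort:
    """Sample scores paired with reference HPLC concentrations.

    A sample is labeled positive iff its concentration strictly
    exceeds ``regulatory_limit`` (ppm).
    """

    entries: list[CohortEntry]
    regulatory_limit: float = 600.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("cohort is empty")
        for e in self.entries:
            if e.hplc_ppm < 0:
                raise ValueError(f"negative HPLC concentration for {e.sample_id!r}")
            if not (np.isfinite(e.sum_score) and np.isfinite(e.hplc_ppm)):
                raise ValueError(f"non-finite entry for {e.sample_id!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.array([e.sum_score for e in self.entries])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([e.hplc_ppm for e in self.entries])

    @property
    def labels(self) -> np.ndarray:
        """True where the sample exceeds the regulatory limit."""
        return self.concentrations > self.regulatory_limit


@dataclass
class RocResult:
    """Empirical ROC: operating points, pair-count AUC, optimal threshold.

    ``points`` holds one ``(threshold, sensitivity, specificity)``
    triple per candidate threshold (each unique score, plus -inf and
    +inf ends) under inclusive flagging (score >= threshold).
    ``optimal_threshold`` is the largest threshold that still flags
    every positive — i.e. sensitivity exactly 1.0 with maximal
    specificity, the operating rule appropriate for screening where
    false negatives are unacceptable.
    """

    points: list[tuple[float, float, float]]
    auc: float
    optimal_threshold: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ConfusionResult:
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class MonteCarloResult:
    """Bootstrap summary of screening triage risks."""

    n_iter: int
    seed: int
    fn_rate_mean: float
    fp_triage_mean: float
    fn_rate_quantiles: dict = field(default_factory=dict)
    fp_triage_quantiles: dict = field(default_factory=dict)


def _split_scores(c: LabeledCohort) -> tuple[np.ndarray, np.ndarray]:
    scores, labels = c.scores, c.labels
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabelError(
            f"need both classes: {len(pos)} positives, {len(neg)} negatives"
        )
    return pos, neg


def empirical_roc(c: LabeledCohort) -> RocResult:
    """Empirical ROC with Mann-Whitney pair-count AUC (ties count 1/2)."""
    pos, neg = _split_scores(c)
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc = float(wins) / (len(pos) * len(neg))

    thresholds = np.concatenate(([-np.inf], np.unique(c.scores), [np.inf]))
    points = []
    best_t, best_spec = -np.inf, -1.0
    for t in thresholds:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        points.append((float(t), sens, spec))
        if sens == 1.0 and spec > best_spec:
            best_t, best_spec = float(t), spec
    return RocResult(
        points=points,
        auc=auc,
        optimal_threshold=best_t,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def confusion_at_threshold(
    c: LabeledCohort, threshold: float, inclusive: bool = True
) -> ConfusionResult:
    """Sensitivity/specificity of flagging at ``score >= threshold``
    (or strictly ``>`` when ``inclusive`` is False)."""
    scores, labels = c.scores, c.labels
    flagged = scores >= threshold if inclusive else scores > threshold
    tp = int((flagged & labels).sum())
    fn = int((~flagged & labels).sum())
    fp = int((flagged & ~labels).sum())
    tn = int((~flagged & ~labels).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionResult(sens, spec, tp=tp, fp=fp, tn=tn, fn=fn)


def pearson_correlation(c: LabeledCohort) -> float:
    """Product-moment correlation between sum score and HPLC ppm."""
    if len(c) < 3:
        raise ValueError("need at least 3 entries for a correlation")
    scores, conc = c.scores, c.concentrations
    if scores.std() == 0 or conc.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(scores, conc)
    return float(r)


_QUANTS = (0.025, 0.5, 0.975)


def monte_carlo_triage(
    c: LabeledCohort,
    threshold: float,
    n_iter: int = 10_000,
    seed: int = 0,
    inclusive: bool = True,
) -> MonteCarloResult:
    """Bootstrap the cohort to quantify screening triage risk.

    Each iteration resamples the cohort with replacement (same size),
    applies the threshold, and records (a) the false-negative rate
    among resampled over-limit samples and (b) the flagged fraction
    among resampled sub-limit samples.  Iterations whose resample
    contains no sample of the relevant class are skipped for that
    rate.  Means and 2.5/50/97.5% quantiles are reported; results are
    reproducible for a given seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    scores, labels = c.scores, c.labels
    flagged = scores >= threshold if inclusive else scores > threshold
    n = len(c)

    idx = rng.integers(0, n, size=(n_iter, n))
    lab = labels[idx]
    flg = flagged[idx]

    n_pos = lab.sum(axis=1)
    n_neg = n - n_pos
    with np.errstate(invalid="ignore"):
        fn_rates = np.where(n_pos > 0, (lab & ~flg).sum(axis=1) / np.maximum(n_pos, 1), np.nan)
        fp_rates = np.where(n_neg > 0, (~lab & flg).sum(axis=1) / np.maximum(n_neg, 1), np.nan)

    def _summ(x: np.ndarray) -> tuple[float, dict]:
        x = x[np.isfinite(x)]
        if len(x) == 0:
            return float("nan"), {q: float("nan") for q in _QUANTS}
        qs = np.quantile(x, _QUANTS)
        return float(x.mean()), {q: float(v) for q, v in zip(_QUANTS, qs)}

    fn_mean, fn_q = _summ(fn_rates)
    fp_mean, fp_q = _summ(fp_rates)
    return MonteCarloResult(
        n_iter=n_iter,
        seed=seed,
        fn_rate_mean=fn_mean,
        fp_triage_mean=fp_mean,
        fn_rate_quantiles=fn_q,
        fp_triage_quantiles=fp_q,
    )
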