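"""Benchmark metrics against a known ground truth.

Given a fitted result table and the simulation truth, computes the
presence/absence AUC (from the posterior presence probabilities), the
Pearson correlation of estimated vs true abundance on the
log10(x + 1) scale, the empirical coverage of the credible intervals,
the class-wise mean estimated abundance (present vs absent isoforms)
and the mean bias.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .data import ValidationError
from .simulate import SimulationTruth

__all__ = ["EvaluationReport", "auc_mann_whitney", "evaluate_run"]


@dataclass(frozen=True)
class EvaluationReport:
    """One row of benchmark metrics; ``auc`` is None when the truth
    contains a single class."""

    auc: float | None
    log10_corr: float
    ci_coverage: float
    mean_abundance_present: float
    mean_abundance_absent: float
    bias: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Tie-aware AUC via the rank-based Mann-Whitney U statistic.

    Many presence probabilities are exactly 0 or 1, so the tie-corrected
    estimator (ties contribute 1/2) is required; equals the area under
    the ROC curve.  Returns None when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return None
    u1 = stats.mannwhitneyu(
        scores[labels], scores[~labels], alternative="two-sided"
    ).statistic
    return float(u1 / (n1 * n0))


def evaluate_run(
    results: pd.DataFrame, truth: SimulationTruth | pd.DataFrame
) -> EvaluationReport:
    """Score a fitted isoform table against the ground truth.

    ``results`` is the per-isoform table of a fit (needs columns
    ``isoform_id``, ``prob_present``, ``abundance_mean``,
    ``abundance_ci_lo``, ``abundance_ci_hi``); ``truth`` is either a
    :class:`SimulationTruth` or its ``truth_frame()`` with columns
    ``isoform_id``, ``true_abundance``.  Rows are matched by isoform
    id and must index the same isoforms.  Interval coverage uses
    closed endpoints: a true value on the boundary counts as covered.
    """
    truth_df = (
        truth.truth_frame() if isinstance(truth, SimulationTruth) else truth
    )
    merged = results.merge(
        truth_df[["isoform_id", "true_abundance"]],
        on="isoform_id",
        how="inner",
        validate="one_to_one",
    )
    if len(merged) != len(results) or len(merged) != len(truth_df):
        raise ValidationError(
            "results and truth must cover the same isoforms "
            f"(results {len(results)}, truth {len(truth_df)}, "
            f"matched {len(merged)})"
        )
    est = merged["abundance_mean"].to_numpy(dtype=float)
    true = merged["true_abundance"].to_numpy(dtype=float)
    present = true > 0

    auc = auc_mann_whitney(merged["prob_present"].to_numpy(), present)
    if np.std(est) > 0 and np.std(true) > 0:
        log10_corr = float(
            stats.pearsonr(np.log10(est + 1.0), np.log10(true + 1.0)).statistic
        )
    else:
        log10_corr = np.nan
    covered = (merged["abundance_ci_lo"].to_numpy() <= true) & (
        true <= merged["abundance_ci_hi"].to_numpy()
    )
    return EvaluationReport(
        auc=auc,
        log10_corr=log10_corr,
        ci_coverage=float(covered.mean()),
        mean_abundance_present=float(est[present].mean())
        if present.any()
        else float("nan"),
        mean_abundance_absent=float(est[~present].mean())
        if (~present).any()
        else float("nan"),
        bias=float((est - true).mean()),
    )
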