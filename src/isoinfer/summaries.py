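"""Posterior summaries: presence probabilities, abundance estimates,
HPD credible intervals, gene aggregates and protein-vs-transcript
comparisons."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .data import IsoformCatalog, ValidationError
from .mcmc import PosteriorChains
from .preprocess import AnalysisConfig

__all__ = [
    "presence_probability",
    "hpd_interval",
    "log2_fold_change",
    "summarize",
]


def presence_probability(chain: np.ndarray) -> float:
    """Fraction of posterior draws with strictly positive abundance,
    the estimate of Pr(X_p > 0)."""
    chain = np.asarray(chain)
    if chain.size == 0:
        raise ValidationError("empty chain")
    return float((chain > 0).mean())


def hpd_interval(chain: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest interval of sorted draws holding ``level`` posterior mass.

    Empirical estimator: among all windows of ceil(level * K) sorted
    draws, return the narrowest (ties broken by the lowest endpoint).
    """
    chain = np.sort(np.asarray(chain, dtype=float))
    k = chain.size
    if k == 0:
        raise ValidationError("empty chain")
    if not (0.0 < level < 1.0):
        raise ValidationError("level must be in (0, 1)")
    w = math.ceil(level * k)
    if w >= k:
        return float(chain[0]), float(chain[-1])
    widths = chain[w - 1 :] - chain[: k - w + 1]
    j = int(np.argmin(widths))  # argmin returns the first minimum: lowest lo
    return float(chain[j]), float(chain[j + w - 1])


def log2_fold_change(pi_mean: float, pi_t: float, kappa: float) -> float:
    """Stabilized log2 fold change between protein and transcript
    relative abundances, log2((pi + kappa) / (pi^T + kappa))."""
    if pi_mean < 0 or pi_t < 0 or kappa <= 0:
        raise ValidationError("relative abundances must be >= 0, kappa > 0")
    return float(np.log2((pi_mean + kappa) / (pi_t + kappa)))


def summarize(
    chains: PosteriorChains,
    catalog: IsoformCatalog,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Build the per-isoform and per-gene result tables.

    Per isoform: presence probability Pr(X_p > 0), posterior means of
    the overall (X_p) and relative (pi_p) abundance with HPD intervals
    at ``config.ci_level``, and — when transcript data is attached —
    the stabilized log2 fold change of the posterior-mean relative
    abundance against pi^T and the per-draw probability
    Pr(pi_p > pi_p^T).

    Gene aggregates are computed on the per-iteration sums of the
    member isoforms' abundance draws, not on the per-isoform summaries,
    so the gene-level credible interval reflects the joint posterior.
    """
    if chains.kept_iterations < 1:
        raise ValidationError("no kept iterations to summarize")
    if chains.n_isoforms != catalog.n_isoforms:
        raise ValidationError("chain / catalog dimension mismatch")

    ids = catalog.isoform_ids
    x, pi = chains.x_draws, chains.pi_draws
    pi_t = catalog.transcript_array()

    rows = []
    for k, iso in enumerate(ids):
        x_lo, x_hi = hpd_interval(x[:, k], config.ci_level)
        r_lo, r_hi = hpd_interval(pi[:, k], config.ci_level)
        row = {
            "isoform_id": iso,
            "gene_id": catalog.gene_of[iso] if catalog.gene_of else None,
            "prob_present": presence_probability(x[:, k]),
            "abundance_mean": float(x[:, k].mean()),
            "abundance_ci_lo": x_lo,
            "abundance_ci_hi": x_hi,
            "rel_abundance_mean": float(pi[:, k].mean()),
            "rel_ci_lo": r_lo,
            "rel_ci_hi": r_hi,
        }
        if pi_t is not None:
            row["pi_T"] = float(pi_t[k])
            row["log2_fc"] = log2_fold_change(
                row["rel_abundance_mean"], pi_t[k], config.lfc_kappa
            )
            row["prob_protein_higher"] = float((pi[:, k] > pi_t[k]).mean())
        else:
            row["pi_T"] = np.nan
            row["log2_fc"] = np.nan
            row["prob_protein_higher"] = np.nan
        rows.append(row)
    isoform_df = pd.DataFrame(rows)

    gene_df = None
    if catalog.gene_of:
        gene_rows = []
        by_gene: dict[str, list[int]] = {}
        for k, iso in enumerate(ids):
            by_gene.setdefault(catalog.gene_of[iso], []).append(k)
        for gene in sorted(by_gene):
            gene_chain = x[:, by_gene[gene]].sum(axis=1)
            lo, hi = hpd_interval(gene_chain, config.ci_level)
            gene_rows.append(
                {
                    "gene_id": gene,
                    "n_isoforms": len(by_gene[gene]),
                    "prob_present": presence_probability(gene_chain),
                    "abundance_mean": float(gene_chain.mean()),
                    "abundance_ci_lo": lo,
                    "abundance_ci_hi": hi,
                }
            )
        gene_df = pd.DataFrame(gene_rows)
    return isoform_df, gene_df
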