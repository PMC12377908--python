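"""Data-augmentation Gibbs sampler for isoform abundances.

The model treats the per-isoform abundances X = (X_1, ..., X_P) as a
latent multinomial split of the total abundance n with probabilities
pi, observed only through peptide-level measurements Y.  Each Gibbs
sweep alternates:

1. (``pep`` mode only) draw per-peptide mis-detection indicators
   eps_i ~ Bernoulli(PEP_i); a mis-detected peptide contributes no
   abundance this sweep.
2. For every retained peptide i, redistribute its abundance
   Y_i (1 - eps_i) across the compatible isoforms psi_i with a
   multinomial draw whose probabilities are proportional to
   pi_p / M_p on psi_i — dividing by the detected-peptide count M_p
   normalizes for how many peptides feed each isoform.  Summing the
   allocations over peptides yields x_p.
3. Draw pi from its conjugate posterior Dir(x + delta).

Unique peptides need no randomness in step 2: their whole retained
abundance goes to the single compatible isoform.  Shared peptides are
grouped by the size of psi_i and allocated with a vectorized
conditional-binomial decomposition of the multinomial, which makes the
sweep cost a handful of array operations rather than a per-peptide
loop.  Peptides never couple isoforms across different connectivity
blocks, so the vectorized pass is distributionally identical to
block-wise processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import PeptideDataset, ValidationError
from .preprocess import AnalysisConfig
from .prior import PriorSpec

__all__ = [
    "LatentState",
    "PosteriorChains",
    "sample_misdetection",
    "allocation_probabilities",
    "allocate_peptide",
    "sample_pi",
    "run_mcmc",
]

logger = logging.getLogger(__name__)


@dataclass
class LatentState:
    """Current state of one Gibbs sweep (mainly for inspection/tests)."""

    epsilon: np.ndarray  # (N,) 0/1 mis-detection indicators
    x: np.ndarray  # (P,) integer isoform abundances
    pi: np.ndarray  # (P,) relative abundances, sums to 1


@dataclass(frozen=True)
class PosteriorChains:
    """Post-burn-in draws of the latent abundances and probabilities.

    ``epsilon_draws`` is kept only in ``pep`` mode (it is identically
    zero in ``fdr`` mode); with it, the sweep-level mass balance
    sum_p x_p = sum_i Y_i (1 - eps_i) can be re-verified draw by draw.
    """

    x_draws: np.ndarray  # (kept, P) int64
    pi_draws: np.ndarray  # (kept, P) float
    epsilon_draws: np.ndarray | None = None  # (kept, N) uint8, pep mode

    @property
    def kept_iterations(self) -> int:
        return self.x_draws.shape[0]

    @property
    def n_isoforms(self) -> int:
        return self.x_draws.shape[1]


def sample_misdetection(pep: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw eps_i ~ Bernoulli(PEP_i) independently; 1 = mis-detected."""
    pep = np.asarray(pep, dtype=float)
    if np.isnan(pep).any():
        raise ValidationError("missing PEP value in pep mode")
    if ((pep < 0) | (pep > 1)).any():
        raise ValidationError("PEP values must lie in [0, 1]")
    return (rng.random(pep.shape) < pep).astype(np.uint8)


def allocation_probabilities(
    pi: np.ndarray, psi: np.ndarray, m: np.ndarray
) -> np.ndarray:
    """Multinomial probabilities for one peptide's allocation.

    Returns the full-length vector proportional to pi_p / M_p on the
    compatible set ``psi`` (integer isoform positions) and zero
    elsewhere.  Should every entry underflow to zero, falls back to a
    uniform split over ``psi`` (logged; cannot happen for exact
    Dirichlet draws, which are positive almost surely).
    """
    psi = np.asarray(psi, dtype=np.int64)
    if psi.size == 0:
        raise ValidationError("empty compatibility set")
    w = np.zeros_like(np.asarray(pi, dtype=float))
    w[psi] = np.asarray(pi, dtype=float)[psi] / np.asarray(m, dtype=float)[psi]
    total = w.sum()
    if total <= 0.0:
        logger.warning("allocation probabilities underflowed; uniform fallback")
        w[psi] = 1.0 / psi.size
        return w
    return w / total


def allocate_peptide(
    y: int,
    epsilon: int,
    pi_tilde: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial split of one peptide's retained abundance
    Y (1 - eps) across isoforms with probabilities ``pi_tilde``."""
    n = int(y) * (1 - int(epsilon))
    if n == 0:
        return np.zeros(len(pi_tilde), dtype=np.int64)
    return rng.multinomial(n, pi_tilde).astype(np.int64)


def sample_pi(
    x: np.ndarray, prior: PriorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw pi from the conjugate posterior Dir(x + delta)."""
    alpha = np.asarray(x, dtype=float) + prior.delta
    return rng.dirichlet(alpha)


# ---------------------------------------------------------------------------
# compiled representation for the fast sweep


class _CompiledDataset:
    """Index arrays extracted once from a PeptideDataset."""

    def __init__(self, dataset: PeptideDataset):
        if dataset.abundance_kind != "psm_counts":
            raise ValidationError(
                "the sampler needs integer abundances; rescale and round "
                "intensities first"
            )
        index = dataset.catalog.index()
        self.n_isoforms = dataset.catalog.n_isoforms
        y = dataset.abundances()
        if not np.all(np.abs(y - np.rint(y)) < 1e-9):
            raise ValidationError("PSM-count abundances must be integers")
        self.y = np.rint(y).astype(np.int64)
        self.pep = np.array(
            [np.nan if r.pep is None else r.pep for r in dataset.records]
        )
        self.m = dataset.catalog.m_array().astype(float)

        unique_rows = []
        shared: dict[int, list[int]] = {}
        psi_idx = []
        for n, rec in enumerate(dataset.records):
            psi = np.array([index[i] for i in rec.isoform_ids], dtype=np.int64)
            psi_idx.append(psi)
            if psi.size == 1:
                unique_rows.append(n)
            else:
                shared.setdefault(psi.size, []).append(n)
        self.psi = psi_idx
        self.unique_rows = np.array(unique_rows, dtype=np.int64)
        self.unique_iso = np.array(
            [psi_idx[n][0] for n in unique_rows], dtype=np.int64
        )
        self.unique_y = self.y[self.unique_rows]
        # shared peptides grouped by |psi| into rectangular index matrices
        self.shared_groups = []
        for k in sorted(shared):
            rows = np.array(shared[k], dtype=np.int64)
            idx = np.stack([psi_idx[n] for n in rows])
            inv_m = 1.0 / self.m[idx]
            self.shared_groups.append((rows, idx, self.y[rows], inv_m))


def _allocate_shared(
    x: np.ndarray,
    idx: np.ndarray,
    sizes: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Vectorized multinomial allocation for one group of shared peptides.

    ``weights`` are the unnormalized pi/M values on each peptide's
    compatibility set (rows of ``idx``).  Uses the conditional-binomial
    chain: component j given the remaining total is binomial with
    probability w_j / (w_j + ... + w_{k-1}).  Results are accumulated
    into ``x`` in place.
    """
    n_pep, k = idx.shape
    tails = np.cumsum(weights[:, ::-1], axis=1)[:, ::-1]
    degenerate = tails[:, 0] <= 0.0
    if degenerate.any():  # float underflow guard; uniform over psi
        logger.warning(
            "%d shared peptides hit zero allocation weights; uniform fallback",
            int(degenerate.sum()),
        )
        weights = np.where(degenerate[:, None], 1.0 / k, weights)
        tails = np.cumsum(weights[:, ::-1], axis=1)[:, ::-1]
    remaining = sizes.copy()
    alloc = np.empty((n_pep, k), dtype=np.int64)
    for j in range(k - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = weights[:, j] / tails[:, j]
        p = np.clip(np.nan_to_num(p), 0.0, 1.0)
        draw = rng.binomial(remaining, p)
        alloc[:, j] = draw
        remaining -= draw
    alloc[:, k - 1] = remaining
    np.add.at(x, idx.ravel(), alloc.ravel())


def run_mcmc(
    dataset: PeptideDataset,
    prior: PriorSpec,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> PosteriorChains:
    """Run the Gibbs sampler and return the post-burn-in chains.

    The dataset must already be filtered for the requested mode.  Fully
    reproducible: a given ``config.seed`` (or an explicitly passed
    generator) determines the chains bit for bit.
    """
    compiled = _CompiledDataset(dataset)
    p = compiled.n_isoforms
    if prior.delta.size != p:
        raise ValidationError(
            f"prior dimension {prior.delta.size} != number of isoforms {p}"
        )
    pep_mode = config.mode == "pep"
    if pep_mode and np.isnan(compiled.pep).any():
        raise ValidationError(
            "pep mode requires a PEP value for every retained peptide"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    kept = config.kept_iterations
    n_pep_records = compiled.y.size
    x_draws = np.empty((kept, p), dtype=np.int64)
    pi_draws = np.empty((kept, p), dtype=float)
    eps_draws = (
        np.empty((kept, n_pep_records), dtype=np.uint8) if pep_mode else None
    )

    pi = prior.mean.copy()
    eps = np.zeros(n_pep_records, dtype=np.uint8)
    x_unique_fixed = np.bincount(
        compiled.unique_iso, weights=compiled.unique_y, minlength=p
    ).astype(np.int64)

    for sweep in range(config.mcmc_iterations):
        if pep_mode:
            eps = sample_misdetection(compiled.pep, rng)

        x = np.zeros(p, dtype=np.int64)
        if pep_mode:
            w = compiled.unique_y * (1 - eps[compiled.unique_rows])
            x += np.bincount(
                compiled.unique_iso, weights=w, minlength=p
            ).astype(np.int64)
        else:
            x += x_unique_fixed

        for rows, idx, y_g, inv_m in compiled.shared_groups:
            sizes = y_g * (1 - eps[rows]) if pep_mode else y_g
            weights = pi[idx] * inv_m
            _allocate_shared(x, idx, sizes, weights, rng)

        pi = rng.dirichlet(x + prior.delta)

        t = sweep - config.burn_in
        if t >= 0:
            x_draws[t] = x
            pi_draws[t] = pi
            if pep_mode:
                eps_draws[t] = eps

    return PosteriorChains(
        x_draws=x_draws, pi_draws=pi_draws, epsilon_draws=eps_draws
    )
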