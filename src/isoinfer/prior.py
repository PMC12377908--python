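"""Dirichlet prior construction for the isoform relative abundances.

The relative abundances pi get a conjugate Dirichlet prior Dir(delta).
Without transcript data the prior is weakly informative, delta_p = 1
for every isoform.  With transcript data the hyperparameters are set
proportional to the transcript relative abundances pi^T, encoding the
expectation that a shared peptide's abundance mostly originates from
the isoform with the more abundant mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IsoformCatalog, ValidationError

__all__ = ["PriorSpec", "build_prior"]


@dataclass(frozen=True)
class PriorSpec:
    """Dirichlet hyperparameters delta over the analyzed isoforms."""

    delta: np.ndarray
    informative: bool
    prior_mass: float

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "delta", delta)
        if delta.ndim != 1 or delta.size == 0:
            raise ValidationError("delta must be a non-empty vector")
        if not (delta > 0).all():
            raise ValidationError("all Dirichlet hyperparameters must be > 0")

    @property
    def mean(self) -> np.ndarray:
        """Prior mean of pi, delta / sum(delta)."""
        return self.delta / self.delta.sum()


def build_prior(
    catalog: IsoformCatalog,
    use_mrna: bool = False,
    prior_mass: float | None = None,
) -> PriorSpec:
    """Build the Dirichlet prior for a catalog of P isoforms.

    With ``use_mrna=False`` this is Dir(1, ..., 1).  With
    ``use_mrna=True``, delta is proportional to the transcript relative
    abundances and rescaled to total ``prior_mass`` (default P, so the
    informative prior carries the same total mass as the weakly
    informative one).
    """
    p = catalog.n_isoforms
    if not use_mrna:
        return PriorSpec(delta=np.ones(p), informative=False, prior_mass=float(p))
    pi_t = catalog.transcript_array()
    if pi_t is None:
        raise ValidationError(
            "informative prior requested but the catalog has no "
            "transcript relative abundances"
        )
    mass = float(p) if prior_mass is None else float(prior_mass)
    if mass <= 0:
        raise ValidationError("prior_mass must be positive")
    return PriorSpec(delta=pi_t * mass, informative=True, prior_mass=mass)
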