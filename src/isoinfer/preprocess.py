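"""Filtering, intensity normalization and block decomposition.

Two filtering modes mirror how peptide identification error is handled
downstream: ``fdr`` mode keeps only confidently identified peptides
(FDR strictly below a threshold, typically 0.01) and treats them as
correct; ``pep`` mode keeps everything up to a weak FDR pre-filter
(default 0.10) and lets the sampler weight each peptide by its
posterior error probability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .data import PeptideDataset, PeptideRecord, ValidationError

__all__ = [
    "AnalysisConfig",
    "Block",
    "filter_undetectable_isoforms",
    "apply_fdr_filter",
    "normalize_and_round_intensities",
    "decompose_blocks",
    "INTENSITY_SCALE",
]

#: total to which intensities are rescaled before integer rounding
INTENSITY_SCALE = 1e5


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-level settings for a fit.

    mode : ``"fdr"`` (filter, then treat peptides as correct) or
        ``"pep"`` (sample per-peptide mis-detection indicators).
    fdr_threshold : strict upper bound on peptide FDR in ``fdr`` mode.
    pep_mode_fdr_prefilter : weak FDR cutoff applied in ``pep`` mode;
        peptides above it carry error probabilities too close to 1 to
        be informative.
    mcmc_iterations / burn_in : Gibbs sweep counts; the first
        ``burn_in`` sweeps are discarded.
    ci_level : mass of the highest-posterior-density credible interval.
    lfc_kappa : stabilizing constant added to both relative abundances
        in the protein-vs-transcript log2 fold change.
    """

    mode: str = "fdr"
    fdr_threshold: float = 0.01
    pep_mode_fdr_prefilter: float = 0.10
    intensity_scale: float = INTENSITY_SCALE
    mcmc_iterations: int = 2000
    burn_in: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    lfc_kappa: float = 1.5e-6

    def __post_init__(self) -> None:
        if self.mode not in ("fdr", "pep"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValidationError("fdr_threshold must be in (0, 1]")
        if not (0.0 < self.pep_mode_fdr_prefilter <= 1.0):
            raise ValidationError("pep_mode_fdr_prefilter must be in (0, 1]")
        if self.burn_in >= self.mcmc_iterations:
            raise ValidationError(
                f"burn_in ({self.burn_in}) must be smaller than "
                f"mcmc_iterations ({self.mcmc_iterations})"
            )
        if self.burn_in < 0:
            raise ValidationError("burn_in must be non-negative")
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError("ci_level must be in (0, 1)")
        if self.intensity_scale <= 0 or self.lfc_kappa <= 0:
            raise ValidationError("scales must be positive")

    @property
    def kept_iterations(self) -> int:
        return self.mcmc_iterations - self.burn_in


@dataclass(frozen=True)
class Block:
    """A connected component of the bipartite peptide-isoform graph.

    No peptide in one block is compatible with an isoform of another
    block, so the allocation step factorizes over blocks.
    """

    isoform_ids: tuple[str, ...]
    record_indices: tuple[int, ...]


def filter_undetectable_isoforms(dataset: PeptideDataset) -> PeptideDataset:
    """Drop isoforms with no detected peptide and recompute M_p.

    Only isoforms compatible with at least one detected peptide can be
    identified; everything downstream reports on the retained set.
    Idempotent.
    """
    referenced = set()
    for rec in dataset.records:
        referenced.update(rec.isoform_ids)
    if not referenced:
        raise ValidationError("no detectable isoform remains")
    gene_of = dataset.catalog.gene_of
    rel = dataset.catalog.transcript_rel_abundance
    return PeptideDataset.from_records(
        dataset.records,
        abundance_kind=dataset.abundance_kind,
        gene_of={i: gene_of[i] for i in referenced} if gene_of else None,
        transcript_rel_abundance=_renormalized(rel, referenced),
    )


def _renormalized(rel, keep) -> dict[str, float] | None:
    if rel is None:
        return None
    vals = {i: rel[i] for i in rel if i in keep}
    total = sum(vals.values())
    if total <= 0:
        return None
    return {i: v / total for i, v in vals.items()}


def apply_fdr_filter(
    dataset: PeptideDataset, threshold: float, inclusive: bool = False
) -> PeptideDataset:
    """Keep peptides with FDR below ``threshold``, then drop isoforms
    left without any peptide and recompute M_p.

    The comparison is strict by default (peptides *below* the cutoff
    survive); ``inclusive=True`` keeps the boundary instead, which is
    the reading of the weak pre-filter in ``pep`` mode (peptides
    *above* the cutoff are removed).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("FDR threshold must be in (0, 1]")
    if inclusive:
        kept = [rec for rec in dataset.records if rec.fdr <= threshold]
    else:
        kept = [rec for rec in dataset.records if rec.fdr < threshold]
    if not kept:
        raise ValidationError(
            f"FDR filter at {threshold} removed all "
            f"{dataset.n_peptides} peptides"
        )
    subset = PeptideDataset.from_records(
        kept,
        abundance_kind=dataset.abundance_kind,
        gene_of=dataset.catalog.gene_of,
        transcript_rel_abundance=dataset.catalog.transcript_rel_abundance,
    )
    return filter_undetectable_isoforms(subset)


def normalize_and_round_intensities(dataset: PeptideDataset) -> PeptideDataset:
    """Rescale intensities to a fixed total and round to integers.

    Each intensity is divided by the sample total and multiplied by
    1e5, then rounded half-to-even.  The resulting integers play the
    same role as PSM counts; the relative rounding error is negligible
    at this scale.
    """
    if dataset.abundance_kind != "intensities":
        raise ValidationError(
            "normalize_and_round_intensities expects intensity data"
        )
    y = dataset.abundances()
    total = y.sum()
    if total <= 0:
        raise ValidationError("total intensity is zero")
    scaled = np.rint(y / total * INTENSITY_SCALE)
    records = [
        dataclasses.replace(rec, abundance=float(v))
        for rec, v in zip(dataset.records, scaled)
    ]
    return PeptideDataset(
        records=tuple(records),
        catalog=dataset.catalog,
        abundance_kind="psm_counts",
    )


def decompose_blocks(dataset: PeptideDataset) -> list[Block]:
    """Split the peptide-isoform graph into its connected components.

    Blocks partition both the isoforms and the peptides; the multinomial
    allocation of any peptide only involves isoforms within its block,
    so blocks can be processed independently.  The result is invariant
    to the input row order (blocks are sorted by their first isoform in
    catalog order).
    """
    index = dataset.catalog.index()
    parent = list(range(dataset.catalog.n_isoforms))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for rec in dataset.records:
        ids = [index[i] for i in rec.isoform_ids]
        for other in ids[1:]:
            union(ids[0], other)

    members: dict[int, list[int]] = {}
    for k in range(len(parent)):
        members.setdefault(find(k), []).append(k)
    rec_of_root: dict[int, list[int]] = {root: [] for root in members}
    for n, rec in enumerate(dataset.records):
        rec_of_root[find(index[rec.isoform_ids[0]])].append(n)

    blocks = []
    for root in sorted(members):
        isoforms = tuple(
            dataset.catalog.isoform_ids[k] for k in sorted(members[root])
        )
        blocks.append(
            Block(isoform_ids=isoforms, record_indices=tuple(rec_of_root[root]))
        )
    return blocks
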