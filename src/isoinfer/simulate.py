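"""Synthetic peptide-level data with known ground truth.

The generator emulates the structure of a bottom-up MS experiment on a
gene-partitioned isoform catalog: a bipartite peptide-isoform
compatibility graph with a controllable shared-peptide fraction
(shared peptides preferentially link isoforms of the same gene, as
sequence similarity does in real proteomes), integer isoform
abundances with a stated fraction of absent isoforms, and transcript
abundances correlated with the protein truth on the log scale.

Peptide observations are produced by splitting each isoform's true
abundance across its compatible peptides with an equal-probability
multinomial draw and summing contributions per peptide.  By default
the data is noise-free (FDR = PEP = 0); decoy peptides with high
error probabilities can be injected to exercise the mis-detection
layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PeptideDataset, PeptideRecord, ValidationError

__all__ = ["SimulationTruth", "make_random_truth", "simulate_peptides"]

#: defaults reflecting the structure of deeply fractionated human
#: cell-line datasets: ~80% of peptides shared between isoforms and an
#: mRNA-protein log-scale correlation of ~0.65
DEFAULT_SHARED_FRACTION = 0.8
DEFAULT_MRNA_LOG_CORR = 0.65
DEFAULT_FRAC_ABSENT = 0.3


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind one synthetic dataset.

    ``graph[i]`` lists the isoform indices peptide ``i`` is compatible
    with; ``true_abundance[p] == 0`` marks an absent isoform.
    """

    isoform_ids: tuple[str, ...]
    gene_of: dict[str, str]
    true_abundance: np.ndarray  # (P,) non-negative int
    graph: tuple[np.ndarray, ...]  # peptide -> isoform indices
    true_pi_t: np.ndarray | None = None  # transcript relative abundances

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_ids)

    @property
    def n_peptides(self) -> int:
        return len(self.graph)

    @property
    def present(self) -> np.ndarray:
        return self.true_abundance > 0

    def truth_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "isoform_id": self.isoform_ids,
                "gene_id": [self.gene_of[i] for i in self.isoform_ids],
                "true_abundance": self.true_abundance,
                "present": self.present.astype(int),
            }
        )
        if self.true_pi_t is not None:
            df["true_pi_T"] = self.true_pi_t
        return df

    def transcript_frame(self, total_tpm: float = 1e6) -> pd.DataFrame:
        """Transcript abundances on a TPM-like scale."""
        if self.true_pi_t is None:
            raise ValidationError("truth carries no transcript abundances")
        return pd.DataFrame(
            {
                "isoform_id": self.isoform_ids,
                "tpm": self.true_pi_t * total_tpm,
            }
        )

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isoform_id": self.isoform_ids,
                "gene_id": [self.gene_of[i] for i in self.isoform_ids],
            }
        )


def make_random_truth(
    n_isoforms: int = 200,
    n_genes: int | None = None,
    shared_fraction: float = DEFAULT_SHARED_FRACTION,
    n_peptides: int | None = None,
    frac_absent: float = DEFAULT_FRAC_ABSENT,
    abundance_log10_mean: float = 0.8,
    abundance_log10_sd: float = 0.5,
    mrna_log_corr: float | None = DEFAULT_MRNA_LOG_CORR,
    rng: np.random.Generator | int | None = None,
) -> SimulationTruth:
    """Generate a random gene-structured truth and compatibility graph.

    Each peptide gets a "home" isoform (the first ``P`` peptides cover
    every isoform once, so all isoforms are analyzable); with
    probability ``shared_fraction`` it is shared, gaining extra
    compatible isoforms drawn preferentially from the home gene and
    otherwise at random.  Present-isoform abundances are integer
    log-normal (base-10 mean/sd as given); a ``frac_absent`` fraction
    of isoforms is set to zero.  When ``mrna_log_corr`` is not None,
    transcript relative abundances are generated with that correlation
    to log10(true abundance + 1); at 1.0 they are an exact monotone
    transform of the truth.
    """
    rng = np.random.default_rng(rng)
    p = int(n_isoforms)
    if p < 1:
        raise ValidationError("need at least one isoform")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValidationError("shared_fraction must be in [0, 1]")
    if p == 1 and shared_fraction > 0.0:
        raise ValidationError(
            "cannot share peptides across isoforms with a single isoform"
        )
    if n_genes is None:
        n_genes = max(1, p // 3)
    if n_peptides is None:
        n_peptides = 5 * p
    if n_peptides < p:
        raise ValidationError(
            "need at least one peptide per isoform (n_peptides >= n_isoforms)"
        )

    isoform_ids = tuple(f"iso{k + 1:04d}" for k in range(p))
    # gene partition: every gene gets >= 1 isoform, remainder at random
    gene_idx = np.concatenate(
        [np.arange(n_genes), rng.integers(0, n_genes, size=p - n_genes)]
    )[:p]
    rng.shuffle(gene_idx)
    gene_of = {
        isoform_ids[k]: f"gene{gene_idx[k] + 1:04d}" for k in range(p)
    }
    gene_members: dict[int, np.ndarray] = {
        g: np.flatnonzero(gene_idx == g) for g in range(n_genes)
    }

    # abundances: log-normal integers for present isoforms, 0 for absent
    absent = rng.random(p) < frac_absent
    log10_x = rng.normal(abundance_log10_mean, abundance_log10_sd, size=p)
    x = np.maximum(1, np.rint(10.0**log10_x)).astype(np.int64)
    x[absent] = 0

    # bipartite graph: first P peptides cover each isoform once
    homes = np.concatenate(
        [rng.permutation(p), rng.integers(0, p, size=n_peptides - p)]
    )
    graph: list[np.ndarray] = []
    shared_flags = rng.random(n_peptides) < shared_fraction
    for i in range(n_peptides):
        home = int(homes[i])
        psi = [home]
        if shared_flags[i] and p > 1:
            n_extra = 1 + rng.poisson(1.5)
            same_gene = [
                k for k in gene_members[gene_idx[home]] if k != home
            ]
            rng.shuffle(same_gene)
            psi.extend(same_gene[:n_extra])
            n_missing = n_extra - len(same_gene)
            if n_missing > 0:
                pool = np.setdiff1d(
                    np.arange(p), np.array(psi), assume_unique=False
                )
                if pool.size:
                    extra = rng.choice(
                        pool, size=min(n_missing, pool.size), replace=False
                    )
                    psi.extend(int(e) for e in extra)
        graph.append(np.array(sorted(psi), dtype=np.int64))

    # transcript abundances correlated with the truth on the log scale
    true_pi_t = None
    if mrna_log_corr is not None:
        rho = float(mrna_log_corr)
        if not (-1.0 <= rho <= 1.0):
            raise ValidationError("mrna_log_corr must be in [-1, 1]")
        z = np.log10(x + 1.0)
        sd = z.std()
        u = (z - z.mean()) / sd if sd > 0 else np.zeros(p)
        t = rho * u + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=p)
        tpm = 10.0 ** (t * (sd if sd > 0 else 1.0) + z.mean())
        true_pi_t = tpm / tpm.sum()

    return SimulationTruth(
        isoform_ids=isoform_ids,
        gene_of=gene_of,
        true_abundance=x,
        graph=tuple(graph),
        true_pi_t=true_pi_t,
    )


def simulate_peptides(
    truth: SimulationTruth,
    rng: np.random.Generator | int | None = None,
    decoy_rate: float = 0.0,
    decoy_pep_beta: tuple[float, float] = (40.0, 2.0),
    decoy_fdr_range: tuple[float, float] = (0.02, 0.09),
    attach_transcripts: bool = True,
) -> PeptideDataset:
    """Turn a truth into an observed peptide dataset.

    Each isoform's true abundance is split across its compatible
    peptides by a multinomial draw with equal probability per peptide;
    a peptide's observed abundance is the sum of the contributions of
    all its isoforms, which conserves total abundance exactly.  Real
    peptides carry FDR = PEP = 0.

    With ``decoy_rate > 0``, that fraction (of the real peptide count)
    of decoy peptides is appended: erroneous identifications whose
    abundance is resampled from the real peptides' positive abundances,
    with PEP drawn from a Beta concentrated near 1 and FDR uniform in
    ``decoy_fdr_range`` — retained by a weak FDR pre-filter but removed
    by a strict 0.01 cutoff.
    """
    rng = np.random.default_rng(rng)
    p = truth.n_isoforms

    peptides_of: dict[int, list[int]] = {k: [] for k in range(p)}
    for i, psi in enumerate(truth.graph):
        for k in psi:
            peptides_of[int(k)].append(i)

    y = np.zeros(truth.n_peptides, dtype=np.int64)
    for k in range(p):
        n_k = int(truth.true_abundance[k])
        if n_k == 0:
            continue
        peps = peptides_of[k]
        if not peps:
            raise ValidationError(
                f"isoform {truth.isoform_ids[k]!r} has positive abundance "
                "but no compatible peptide"
            )
        counts = rng.multinomial(n_k, np.full(len(peps), 1.0 / len(peps)))
        y[peps] += counts

    records = [
        PeptideRecord(
            peptide_id=f"pep{i + 1:05d}",
            abundance=float(y[i]),
            fdr=0.0,
            pep=0.0,
            isoform_ids=tuple(truth.isoform_ids[k] for k in truth.graph[i]),
        )
        for i in range(truth.n_peptides)
    ]

    if decoy_rate > 0.0:
        n_decoys = int(round(decoy_rate * truth.n_peptides))
        positive = y[y > 0]
        if positive.size == 0:
            raise ValidationError("no positive abundances to seed decoys from")
        a, b = decoy_pep_beta
        lo, hi = decoy_fdr_range
        for d in range(n_decoys):
            psi = rng.choice(p, size=min(p, 1 + rng.poisson(1.0)), replace=False)
            records.append(
                PeptideRecord(
                    peptide_id=f"decoy{d + 1:05d}",
                    abundance=float(rng.choice(positive)),
                    fdr=float(rng.uniform(lo, hi)),
                    pep=float(np.clip(rng.beta(a, b), 0.0, 1.0)),
                    isoform_ids=tuple(
                        truth.isoform_ids[k] for k in sorted(int(j) for j in psi)
                    ),
                )
            )

    rel = None
    if attach_transcripts and truth.true_pi_t is not None:
        rel = dict(zip(truth.isoform_ids, truth.true_pi_t.tolist()))
    return PeptideDataset.from_records(
        records,
        abundance_kind="psm_counts",
        gene_of=truth.gene_of,
        transcript_rel_abundance=rel,
    )
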