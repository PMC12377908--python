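"""Model / Results interface over the full inference pipeline.

:class:`ProteinIsoformModel` is constructed from a peptide dataset and
performs the deterministic preparation steps up front (intensity
rescaling, mode-specific FDR filtering, removal of undetectable
isoforms, block decomposition, prior construction).  Its :meth:`fit`
runs the Gibbs sampler and returns a :class:`ProteinIsoformResults`
holding the posterior chains, the per-isoform and per-gene summary
tables, and writers for the standard TSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    PeptideDataset,
    ValidationError,
    read_gene_map,
    read_peptide_table,
    read_transcript_abundances,
)
from .mcmc import PosteriorChains, run_mcmc
from .preprocess import (
    AnalysisConfig,
    apply_fdr_filter,
    decompose_blocks,
    filter_undetectable_isoforms,
    normalize_and_round_intensities,
)
from .prior import PriorSpec, build_prior
from .summaries import summarize

__all__ = ["ProteinIsoformModel", "ProteinIsoformResults"]


class ProteinIsoformModel:
    """Bayesian latent-allocation model for protein isoform inference.

    Parameters
    ----------
    dataset : PeptideDataset
        Validated peptide-level input (PSM counts or intensities).
    config : AnalysisConfig, optional
        Run settings; keyword overrides (e.g. ``mode="pep"``,
        ``fdr_threshold=0.01``) are applied on top.
    use_mrna : bool, optional
        Use the transcript-informed Dirichlet prior.  Defaults to
        whether transcript abundances are attached to the catalog.
    prior_mass : float, optional
        Total mass of the informative prior (default: the number of
        analyzed isoforms, matching the weakly informative prior).
    """

    def __init__(
        self,
        dataset: PeptideDataset,
        config: AnalysisConfig | None = None,
        use_mrna: bool | None = None,
        prior_mass: float | None = None,
        **config_overrides,
    ):
        if config is None:
            config = AnalysisConfig(**config_overrides)
        elif config_overrides:
            config = dataclasses.replace(config, **config_overrides)
        self.config = config
        self.n_peptides_input = dataset.n_peptides

        if dataset.abundance_kind == "intensities":
            dataset = normalize_and_round_intensities(dataset)

        if config.mode == "pep":
            if not dataset.has_pep():
                raise ValidationError(
                    "pep mode requires a PEP value for every peptide; "
                    "no silent fallback to fdr mode"
                )
            dataset = apply_fdr_filter(
                dataset, config.pep_mode_fdr_prefilter, inclusive=True
            )
        else:
            dataset = apply_fdr_filter(dataset, config.fdr_threshold)
        dataset = filter_undetectable_isoforms(dataset)

        self.dataset = dataset
        self.blocks = decompose_blocks(dataset)
        if use_mrna is None:
            use_mrna = dataset.catalog.transcript_rel_abundance is not None
        self.prior: PriorSpec = build_prior(
            dataset.catalog, use_mrna=use_mrna, prior_mass=prior_mass
        )

    @classmethod
    def from_files(
        cls,
        peptides: str | Path,
        mrna: str | Path | None = None,
        genes: str | Path | None = None,
        column_map: Mapping[str, str] | None = None,
        isoform_sep: str = ";",
        abundance_kind: str = "psm_counts",
        tpm_zero_floor: float = 1.0,
        **kwargs,
    ) -> "ProteinIsoformModel":
        """Build a model from TSV inputs (peptide table, optional
        transcript-abundance table, optional isoform->gene map)."""
        dataset = read_peptide_table(
            peptides,
            column_map=column_map,
            isoform_sep=isoform_sep,
            abundance_kind=abundance_kind,
        )
        catalog = dataset.catalog
        if genes is not None:
            catalog = read_gene_map(genes, catalog, column_map=column_map)
        if mrna is not None:
            catalog = read_transcript_abundances(
                mrna, catalog, column_map=column_map, zero_floor=tpm_zero_floor
            )
        dataset = PeptideDataset(
            records=dataset.records,
            catalog=catalog,
            abundance_kind=dataset.abundance_kind,
        )
        return cls(dataset, **kwargs)

    @property
    def n_isoforms(self) -> int:
        return self.dataset.catalog.n_isoforms

    @property
    def n_peptides(self) -> int:
        return self.dataset.n_peptides

    def fit(
        self,
        seed: int | None = None,
        iterations: int | None = None,
        burn_in: int | None = None,
    ) -> "ProteinIsoformResults":
        """Run the Gibbs sampler and summarize the posterior."""
        config = self.config
        updates = {}
        if seed is not None:
            updates["seed"] = seed
        if iterations is not None:
            updates["mcmc_iterations"] = iterations
        if burn_in is not None:
            updates["burn_in"] = burn_in
        if updates:
            config = dataclasses.replace(config, **updates)
        t0 = time.perf_counter()
        chains = run_mcmc(self.dataset, self.prior, config)
        isoform_table, gene_table = summarize(
            chains, self.dataset.catalog, config
        )
        elapsed = time.perf_counter() - t0
        return ProteinIsoformResults(
            model=self,
            config=config,
            chains=chains,
            isoform_table=isoform_table,
            gene_table=gene_table,
            wall_clock_s=elapsed,
        )


class ProteinIsoformResults:
    """Fitted results: posterior chains plus summary tables.

    Attributes
    ----------
    isoform_table : pandas.DataFrame
        One row per analyzed isoform: presence probability, posterior
        mean abundance with HPD interval, relative abundance with HPD
        interval, and (when transcript data is present) pi^T, the
        stabilized log2 fold change and Pr(pi_p > pi_p^T).
    gene_table : pandas.DataFrame or None
        Gene aggregates over per-iteration sums of member isoforms.
    chains : PosteriorChains
        Raw post-burn-in draws.
    """

    def __init__(
        self,
        model: ProteinIsoformModel,
        config: AnalysisConfig,
        chains: PosteriorChains,
        isoform_table: pd.DataFrame,
        gene_table: pd.DataFrame | None,
        wall_clock_s: float,
    ):
        self.model = model
        self.config = config
        self.chains = chains
        self.isoform_table = isoform_table
        self.gene_table = gene_table
        self.wall_clock_s = wall_clock_s

    def manifest(
        self, input_digests: Mapping[str, str] | None = None
    ) -> dict:
        """Reproducibility metadata for this run."""
        cfg = dataclasses.asdict(self.config)
        return {
            "software": "isoinfer",
            "version": __version__,
            "config": cfg,
            "seed": self.config.seed,
            "input_digests": dict(input_digests) if input_digests else {},
            "wall_clock_s": round(self.wall_clock_s, 3),
            "counts": {
                "peptides_input": self.model.n_peptides_input,
                "peptides_after_filter": self.model.n_peptides,
                "isoforms_analyzed": self.model.n_isoforms,
                "blocks": len(self.model.blocks),
                "iterations_kept": self.config.kept_iterations,
            },
        }

    def save(
        self,
        outdir: str | Path,
        input_digests: Mapping[str, str] | None = None,
    ) -> dict[str, Path]:
        """Write isoform/gene TSVs (6 significant digits) plus a JSON
        run manifest; identical fits produce byte-identical files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"isoforms": outdir / "isoforms.tsv"}
        self.isoform_table.to_csv(
            paths["isoforms"], sep="\t", index=False, float_format="%.6g"
        )
        if self.gene_table is not None:
            paths["genes"] = outdir / "genes.tsv"
            self.gene_table.to_csv(
                paths["genes"], sep="\t", index=False, float_format="%.6g"
            )
        paths["manifest"] = outdir / "run_manifest.json"
        manifest = self.manifest(input_digests)
        manifest["wall_clock_s"] = None  # keep result files byte-stable
        paths["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return paths

    def summary(self, max_rows: int = 20) -> str:
        """Human-readable fit overview plus the head of the isoform table."""
        c = self.config
        lines = [
            "Protein isoform inference (Dirichlet-multinomial Gibbs sampler)",
            "=" * 64,
            f"mode: {c.mode}    prior: "
            + ("mRNA-informative" if self.model.prior.informative else "Dir(1,...,1)"),
            f"peptides: {self.model.n_peptides_input} in, "
            f"{self.model.n_peptides} after filtering",
            f"isoforms analyzed: {self.model.n_isoforms} "
            f"in {len(self.model.blocks)} independent blocks",
            f"iterations: {c.mcmc_iterations} ({c.burn_in} burn-in), "
            f"seed {c.seed}",
            f"credible level: {c.ci_level:g} (HPD)",
            "",
        ]
        table = self.isoform_table.copy()
        show = [
            "isoform_id",
            "prob_present",
            "abundance_mean",
            "abundance_ci_lo",
            "abundance_ci_hi",
            "rel_abundance_mean",
        ]
        if not np.isnan(table["log2_fc"]).all():
            show += ["log2_fc", "prob_protein_higher"]
        lines.append(
            table[show]
            .head(max_rows)
            .to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )
        if len(table) > max_rows:
            lines.append(f"... {len(table) - max_rows} more isoforms")
        return "\n".join(lines)
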