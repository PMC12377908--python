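"""Core domain types and TSV readers for peptide-level MS data.

Bottom-up proteomics measures peptides, not proteins: each detected
peptide carries an abundance (a PSM count or an intensity), error
annotations from the upstream search engine (an FDR / q-value and
optionally a posterior error probability, PEP), and the list of protein
isoforms its sequence is compatible with.  These types hold that
peptide-level evidence together with the catalog of isoforms under
analysis, which is the unit the inference downstream reports on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideRecord",
    "IsoformCatalog",
    "PeptideDataset",
    "InputFormatError",
    "ValidationError",
    "DEFAULT_COLUMNS",
    "read_peptide_table",
    "write_peptide_table",
    "read_transcript_abundances",
    "read_gene_map",
]


class InputFormatError(ValueError):
    """A required column or field is missing from an input table."""


class ValidationError(ValueError):
    """An input value violates the model's domain constraints."""


#: default column names for the peptide / transcript / gene-map TSVs
DEFAULT_COLUMNS = {
    "peptide": "peptide",
    "abundance": "abundance",
    "fdr": "fdr",
    "pep": "pep",
    "isoforms": "isoforms",
    "isoform_id": "isoform_id",
    "tpm": "tpm",
    "gene_id": "gene_id",
}


@dataclass(frozen=True)
class PeptideRecord:
    """One detected peptide.

    Parameters
    ----------
    peptide_id : str
        Identifier (typically the peptide sequence).
    abundance : float
        Non-negative abundance Y_i: a PSM count (integer) or an
        intensity (continuous).
    fdr : float
        Peptide-level false discovery rate (q-value), in [0, 1].
    pep : float or None
        Posterior error probability of the identification, in [0, 1];
        ``None`` when the search engine did not report one.
    isoform_ids : tuple of str
        Ordered, duplicate-free list of compatible protein isoforms
        (the set psi_i). A single entry marks a unique peptide.
    """

    peptide_id: str
    abundance: float
    fdr: float
    pep: float | None
    isoform_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.isoform_ids:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: empty isoform list"
            )
        if len(set(self.isoform_ids)) != len(self.isoform_ids):
            raise ValidationError(
                f"peptide {self.peptide_id!r}: duplicate isoform ids"
            )
        if not np.isfinite(self.abundance) or self.abundance < 0:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: abundance {self.abundance} "
                "must be a finite non-negative number"
            )
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(
                f"peptide {self.peptide_id!r}: FDR {self.fdr} outside [0, 1]"
            )
        if self.pep is not None and not (0.0 <= self.pep <= 1.0):
            raise ValidationError(
                f"peptide {self.peptide_id!r}: PEP {self.pep} outside [0, 1]"
            )

    @property
    def is_unique(self) -> bool:
        return len(self.isoform_ids) == 1


@dataclass(frozen=True)
class IsoformCatalog:
    """The protein isoforms under analysis.

    ``detected_peptide_count`` holds M_p, the number of detected
    (unique or shared) peptides compatible with each isoform; every
    analyzed isoform has M_p >= 1 because isoforms without any detected
    peptide cannot be identified and are removed upfront.
    ``transcript_rel_abundance`` optionally holds the transcript-level
    relative abundances pi^T (summing to one over the analyzed
    isoforms), used to build the informative prior.
    """

    isoform_ids: tuple[str, ...]
    detected_peptide_count: Mapping[str, int]
    gene_of: Mapping[str, str] | None = None
    transcript_rel_abundance: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.isoform_ids)) != len(self.isoform_ids):
            raise ValidationError("duplicate isoform ids in catalog")
        for iso in self.isoform_ids:
            m = self.detected_peptide_count.get(iso, 0)
            if m < 1:
                raise ValidationError(
                    f"isoform {iso!r}: detected peptide count {m} < 1; "
                    "isoforms without detected peptides are not analyzable"
                )
        if self.transcript_rel_abundance is not None:
            vals = np.array(
                [self.transcript_rel_abundance[i] for i in self.isoform_ids]
            )
            if (vals < 0).any():
                raise ValidationError("negative transcript relative abundance")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    "transcript relative abundances must sum to 1 over the "
                    f"analyzed isoforms (got {vals.sum()!r})"
                )

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_ids)

    def index(self) -> dict[str, int]:
        """Map isoform id -> position in catalog order."""
        return {iso: k for k, iso in enumerate(self.isoform_ids)}

    def m_array(self) -> np.ndarray:
        """Detected-peptide counts M_p as an int array in catalog order."""
        return np.array(
            [self.detected_peptide_count[i] for i in self.isoform_ids],
            dtype=np.int64,
        )

    def transcript_array(self) -> np.ndarray | None:
        if self.transcript_rel_abundance is None:
            return None
        return np.array(
            [self.transcript_rel_abundance[i] for i in self.isoform_ids]
        )


@dataclass(frozen=True)
class PeptideDataset:
    """A validated peptide table plus its isoform catalog.

    ``abundance_kind`` distinguishes integer PSM counts from continuous
    intensities; intensities must be rescaled and rounded (see
    :func:`isoinfer.preprocess.normalize_and_round_intensities`) before
    the sampler can run.
    """

    records: tuple[PeptideRecord, ...]
    catalog: IsoformCatalog
    abundance_kind: str = "psm_counts"

    def __post_init__(self) -> None:
        if self.abundance_kind not in ("psm_counts", "intensities"):
            raise ValidationError(
                f"unknown abundance_kind {self.abundance_kind!r}"
            )
        if not self.records:
            raise ValidationError("dataset has no peptide records")
        known = set(self.catalog.isoform_ids)
        for rec in self.records:
            missing = set(rec.isoform_ids) - known
            if missing:
                raise ValidationError(
                    f"peptide {rec.peptide_id!r} references isoforms absent "
                    f"from the catalog: {sorted(missing)}"
                )

    @property
    def n_peptides(self) -> int:
        return len(self.records)

    @property
    def n_isoforms(self) -> int:
        return self.catalog.n_isoforms

    @classmethod
    def from_records(
        cls,
        records: Iterable[PeptideRecord],
        abundance_kind: str = "psm_counts",
        gene_of: Mapping[str, str] | None = None,
        transcript_rel_abundance: Mapping[str, float] | None = None,
    ) -> "PeptideDataset":
        """Build a dataset whose catalog is the union of referenced isoforms,
        with detected-peptide counts M_p recomputed from the records."""
        records = tuple(records)
        counts: dict[str, int] = {}
        order: list[str] = []
        for rec in records:
            for iso in rec.isoform_ids:
                if iso not in counts:
                    counts[iso] = 0
                    order.append(iso)
                counts[iso] += 1
        catalog = IsoformCatalog(
            isoform_ids=tuple(sorted(order)),
            detected_peptide_count=counts,
            gene_of=dict(gene_of) if gene_of is not None else None,
            transcript_rel_abundance=(
                dict(transcript_rel_abundance)
                if transcript_rel_abundance is not None
                else None
            ),
        )
        return cls(records=records, catalog=catalog, abundance_kind=abundance_kind)

    def has_pep(self) -> bool:
        return all(rec.pep is not None for rec in self.records)

    def abundances(self) -> np.ndarray:
        return np.array([rec.abundance for rec in self.records])

    def to_frame(self, isoform_sep: str = ";") -> pd.DataFrame:
        """Tabular view of the records (one row per peptide)."""
        return pd.DataFrame(
            {
                "peptide": [r.peptide_id for r in self.records],
                "abundance": [r.abundance for r in self.records],
                "fdr": [r.fdr for r in self.records],
                "pep": [np.nan if r.pep is None else r.pep for r in self.records],
                "isoforms": [isoform_sep.join(r.isoform_ids) for r in self.records],
            }
        )


def _resolve_columns(
    df: pd.DataFrame, column_map: Mapping[str, str] | None
) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    return cols


def read_peptide_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    isoform_sep: str = ";",
    abundance_kind: str = "psm_counts",
) -> PeptideDataset:
    """Read a tab-delimited peptide table into a validated dataset.

    The table needs columns for the peptide id, abundance, FDR and a
    delimiter-separated isoform list; a PEP column is optional.  Column
    names default to ``peptide``, ``abundance``, ``fdr``, ``pep`` and
    ``isoforms`` and can be remapped via ``column_map``.  ``isoform_sep``
    accepts ``";"`` (default) or ``"|"``.

    The isoform catalog is built from the union of referenced isoform
    ids, with detected-peptide counts computed per isoform.
    """
    if isoform_sep not in (";", "|"):
        raise InputFormatError(f"unsupported isoform separator {isoform_sep!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df, column_map)
    required = ["peptide", "abundance", "fdr", "isoforms"]
    for key in required:
        if cols[key] not in df.columns:
            raise InputFormatError(
                f"{path}: missing required column {cols[key]!r} "
                f"(have {list(df.columns)})"
            )
    has_pep = cols["pep"] in df.columns

    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        pid = str(row[cols["peptide"]])
        try:
            abundance = float(row[cols["abundance"]])
            fdr = float(row[cols["fdr"]])
            pep_raw = row[cols["pep"]] if has_pep else None
            pep = (
                None
                if pep_raw is None or (isinstance(pep_raw, float) and np.isnan(pep_raw))
                or (isinstance(pep_raw, str) and pep_raw.strip() == "")
                else float(pep_raw)
            )
            isoforms = tuple(
                tok.strip()
                for tok in str(row[cols["isoforms"]]).split(isoform_sep)
                if tok.strip()
            )
            records.append(
                PeptideRecord(
                    peptide_id=pid,
                    abundance=abundance,
                    fdr=fdr,
                    pep=pep,
                    isoform_ids=isoforms,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}, line {row_number}: {err}") from err
        except (TypeError, ValueError) as err:
            raise InputFormatError(f"{path}, line {row_number}: {err}") from err
    if not records:
        raise InputFormatError(f"{path}: no peptide rows")
    return PeptideDataset.from_records(records, abundance_kind=abundance_kind)


def write_peptide_table(
    dataset: PeptideDataset, path: str | Path, isoform_sep: str = ";"
) -> None:
    """Write the peptide records back to TSV (round-trips exactly)."""
    df = dataset.to_frame(isoform_sep=isoform_sep)
    df.to_csv(path, sep="\t", index=False)


def read_transcript_abundances(
    path: str | Path,
    catalog: IsoformCatalog,
    column_map: Mapping[str, str] | None = None,
    zero_floor: float = 1.0,
) -> IsoformCatalog:
    """Attach transcript relative abundances (e.g. TPM) to a catalog.

    The table needs ``isoform_id`` and ``tpm`` columns (remappable).
    Entries for isoforms outside the catalog are dropped; analyzed
    isoforms with no entry or zero TPM are assigned a ``zero_floor``
    pseudo-TPM so every prior weight stays strictly positive.  The
    retained values are renormalized to sum to one.
    """
    df = pd.read_csv(path, sep="\t")
    cols = _resolve_columns(df, column_map)
    for key in ("isoform_id", "tpm"):
        if cols[key] not in df.columns:
            raise InputFormatError(
                f"{path}: missing required column {cols[key]!r}"
            )
    tpm_map: dict[str, float] = {}
    for _, row in df.iterrows():
        iso = str(row[cols["isoform_id"]])
        tpm = float(row[cols["tpm"]])
        if tpm < 0:
            raise ValidationError(f"{path}: negative TPM for isoform {iso!r}")
        tpm_map[iso] = tpm_map.get(iso, 0.0) + tpm
    return attach_transcript_abundances(catalog, tpm_map, zero_floor=zero_floor)


def attach_transcript_abundances(
    catalog: IsoformCatalog,
    tpm: Mapping[str, float],
    zero_floor: float = 1.0,
) -> IsoformCatalog:
    """Restrict TPM-like values to the analyzed isoforms, floor zeros and
    renormalize; see :func:`read_transcript_abundances`."""
    if zero_floor <= 0:
        raise ValidationError("zero_floor must be positive")
    vals = np.array([float(tpm.get(i, 0.0)) for i in catalog.isoform_ids])
    if (vals <= 0).all():
        raise ValidationError(
            "all transcript abundances are zero or missing over the "
            "analyzed isoforms"
        )
    vals = np.where(vals > 0, vals, zero_floor)
    vals = vals / vals.sum()
    rel = dict(zip(catalog.isoform_ids, vals.tolist()))
    return replace(catalog, transcript_rel_abundance=rel)


def read_gene_map(
    path: str | Path,
    catalog: IsoformCatalog,
    column_map: Mapping[str, str] | None = None,
) -> IsoformCatalog:
    """Attach an isoform -> gene map from a two-column TSV
    (``isoform_id``, ``gene_id``; names remappable)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df, column_map)
    for key in ("isoform_id", "gene_id"):
        if cols[key] not in df.columns:
            raise InputFormatError(f"{path}: missing required column {cols[key]!r}")
    mapping = dict(zip(df[cols["isoform_id"]], df[cols["gene_id"]]))
    missing = [i for i in catalog.isoform_ids if i not in mapping]
    if missing:
        raise ValidationError(
            f"gene map lacks entries for analyzed isoforms: {missing[:5]}"
        )
    gene_of = {i: mapping[i] for i in catalog.isoform_ids}
    return replace(catalog, gene_of=gene_of)
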