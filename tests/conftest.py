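import numpy as np
import pytest

from isoinfer import PeptideDataset, PeptideRecord


def make_record(pid, abundance, isoforms, fdr=0.0, pep=0.0):
    return PeptideRecord(
        peptide_id=pid,
        abundance=float(abundance),
        fdr=float(fdr),
        pep=None if pep is None else float(pep),
        isoform_ids=tuple(isoforms),
    )


@pytest.fixture
def tiny_dataset():
    """Three peptides over two isoforms: unique A, shared A;B, unique B."""
    return PeptideDataset.from_records(
        [
            make_record("p1", 4, ["A"]),
            make_record("p2", 6, ["A", "B"]),
            make_record("p3", 2, ["B"]),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def write_tsv(path, header, rows):
    lines = ["\t".join(header)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
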