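import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoinfer import AnalysisConfig, PeptideDataset
from isoinfer.data import ValidationError
from isoinfer.preprocess import (
    INTENSITY_SCALE,
    apply_fdr_filter,
    decompose_blocks,
    filter_undetectable_isoforms,
    normalize_and_round_intensities,
)

from conftest import make_record


class TestConfig:
    def test_burn_in_must_be_below_iterations(self):
        with pytest.raises(ValidationError, match="burn_in"):
            AnalysisConfig(mcmc_iterations=100, burn_in=100)

    @pytest.mark.parametrize("field,value", [
        ("mode", "both"),
        ("fdr_threshold", 0.0),
        ("ci_level", 1.0),
    ])
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValidationError):
            AnalysisConfig(**{field: value})


class TestFdrFilter:
    def test_strictly_below_threshold_kept(self):
        ds = PeptideDataset.from_records(
            [
                make_record("p1", 1, ["A"], fdr=0.001),
                make_record("p2", 1, ["A"], fdr=0.05),
                make_record("p3", 1, ["A"], fdr=0.009),
            ]
        )
        out = apply_fdr_filter(ds, 0.01)
        assert [r.peptide_id for r in out.records] == ["p1", "p3"]

    def test_threshold_one_keeps_everything(self, tiny_dataset):
        assert apply_fdr_filter(tiny_dataset, 1.0).records == tiny_dataset.records

    def test_boundary_is_excluded(self):
        ds = PeptideDataset.from_records(
            [make_record("p1", 1, ["A"], fdr=0.01)]
        )
        with pytest.raises(ValidationError, match="removed all"):
            apply_fdr_filter(ds, 0.01)

    def test_inclusive_variant_keeps_boundary(self):
        ds = PeptideDataset.from_records(
            [make_record("p1", 1, ["A"], fdr=0.10)]
        )
        out = apply_fdr_filter(ds, 0.10, inclusive=True)
        assert out.n_peptides == 1

    def test_undetectable_isoforms_removed_and_counts_recomputed(self):
        ds = PeptideDataset.from_records(
            [
                make_record("p1", 1, ["A", "B"], fdr=0.001),
                make_record("p2", 1, ["B"], fdr=0.5),
                make_record("p3", 1, ["C"], fdr=0.5),
            ]
        )
        out = apply_fdr_filter(ds, 0.01)
        assert out.catalog.isoform_ids == ("A", "B")
        assert out.catalog.detected_peptide_count == {"A": 1, "B": 1}


class TestUndetectableIsoforms:
    def test_definition(self):
        # catalog {A,B,C} but peptides only reach A and B
        ds = PeptideDataset.from_records(
            [make_record("p1", 1, ["A"]), make_record("p2", 1, ["A", "B"])]
        )
        out = filter_undetectable_isoforms(ds)
        assert out.catalog.isoform_ids == ("A", "B")

    def test_idempotent(self, tiny_dataset):
        once = filter_undetectable_isoforms(tiny_dataset)
        twice = filter_undetectable_isoforms(once)
        assert once.catalog == twice.catalog and once.records == twice.records


class TestIntensityNormalization:
    def make(self, values):
        return PeptideDataset.from_records(
            [make_record(f"p{i}", v, ["A"]) for i, v in enumerate(values)],
            abundance_kind="intensities",
        )

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([50.0, 150.0], [25000, 75000]),
            ([7.3], [100000]),
            ([1.0, 1.0, 1.0], [33333, 33333, 33333]),
        ],
    )
    def test_rescaled_and_rounded(self, values, expected):
        out = normalize_and_round_intensities(self.make(values))
        assert out.abundances().tolist() == expected
        assert out.abundance_kind == "psm_counts"

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            normalize_and_round_intensities(self.make([0.0, 0.0]))

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_total_preserved_up_to_rounding(self, values):
        out = normalize_and_round_intensities(self.make(values))
        assert abs(out.abundances().sum() - INTENSITY_SCALE) <= len(values) / 2


class TestBlocks:
    def test_connected_components(self):
        ds = PeptideDataset.from_records(
            [
                make_record("p1", 1, ["A"]),
                make_record("p2", 1, ["A", "B"]),
                make_record("p3", 1, ["C"]),
            ]
        )
        blocks = decompose_blocks(ds)
        assert [b.isoform_ids for b in blocks] == [("A", "B"), ("C",)]
        assert [b.record_indices for b in blocks] == [(0, 1), (2,)]

    def test_one_shared_peptide_joins_everything(self):
        ds = PeptideDataset.from_records(
            [make_record("p1", 1, ["A", "B", "C"])]
        )
        assert len(decompose_blocks(ds)) == 1

    def test_all_unique_gives_singletons(self):
        ds = PeptideDataset.from_records(
            [make_record(f"p{i}", 1, [f"iso{i}"]) for i in range(5)]
        )
        blocks = decompose_blocks(ds)
        assert len(blocks) == 5
        assert all(len(b.isoform_ids) == 1 for b in blocks)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_row_order(self, random):
        records = [
            make_record("p1", 1, ["A", "B"]),
            make_record("p2", 1, ["B", "C"]),
            make_record("p3", 1, ["D"]),
            make_record("p4", 1, ["E", "D"]),
            make_record("p5", 1, ["F"]),
        ]
        shuffled = records[:]
        random.shuffle(shuffled)
        ref = decompose_blocks(PeptideDataset.from_records(records))
        got = decompose_blocks(PeptideDataset.from_records(shuffled))
        assert [b.isoform_ids for b in got] == [b.isoform_ids for b in ref]

    def test_blocks_partition_isoforms_and_peptides(self, tiny_dataset):
        blocks = decompose_blocks(tiny_dataset)
        isoforms = [i for b in blocks for i in b.isoform_ids]
        peptides = [n for b in blocks for n in b.record_indices]
        assert sorted(isoforms) == sorted(tiny_dataset.catalog.isoform_ids)
        assert sorted(peptides) == list(range(tiny_dataset.n_peptides))


def test_mode_and_defaults_roundtrip():
    cfg = AnalysisConfig(mode="pep")
    assert cfg.kept_iterations == 1000
    assert dataclasses.replace(cfg, seed=5).seed == 5
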