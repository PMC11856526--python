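"""I/O round-trips, header aliasing and validation for all three input
families."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from surfrank.annotation_io import (
    CellMatrix,
    FormatError,
    GeneAnnotation,
    ValidationError,
    normalize_category,
    read_annotation_table,
    read_bulk_dataset,
    read_cell_matrix,
    write_annotation_table,
    write_bulk_dataset,
    write_cell_matrix,
)
from surfrank.synthetic_data import simulate_annotations

from conftest import make_bulk_dataset


class TestAnnotationTable:
    def test_single_row_round_trip(self, tmp_path):
        rec = GeneAnnotation(
            gene_symbol="TM4SF4",
            brain_distribution="not_detected",
            tissue_distribution="detected_in_some",
            tissue_nx={"lung": 0.4, "liver": 12.0},
            cancer_fpkm={"liver cancer": 120.0},
            subcellular=[("plasma membrane", 5.0), ("cytosol", 3.0)],
            blood_detected=False,
        )
        path = tmp_path / "one.tsv"
        write_annotation_table([rec], path)
        (back,) = read_annotation_table(path)
        assert back == rec

    def test_empty_subcellular_encodes_as_empty_list(self, tmp_path):
        rec = GeneAnnotation(gene_symbol="G1", subcellular=[])
        path = tmp_path / "t.tsv"
        write_annotation_table([rec], path)
        (back,) = read_annotation_table(path)
        assert back.subcellular == []

    def test_thousand_gene_fixture_round_trips_field_by_field(
        self, tmp_path, annotation_config
    ):
        records = simulate_annotations(annotation_config)
        path = tmp_path / "ann.tsv"
        write_annotation_table(records, path)
        back = read_annotation_table(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a == b

    def test_atlas_style_headers_load_via_aliases(self, tmp_path):
        path = tmp_path / "hpa.tsv"
        path.write_text(
            "Gene\tRNA brain regional distribution\tRNA tissue distribution\t"
            "Tissue RNA - lung [NX]\tRNA cancer specific FPKM - liver cancer\t"
            "Subcellular location\tDetected in blood by mass spectrometry\n"
            "TFR2\tDetected in single\tDetected in some\t0.9\t77\t"
            "plasma membrane:5\ttrue\n"
        )
        (rec,) = read_annotation_table(path)
        assert rec.gene_symbol == "TFR2"
        assert rec.brain_distribution == "detected_in_single"
        assert rec.tissue_nx == {"lung": 0.9}
        assert rec.cancer_fpkm == {"liver cancer": 77.0}
        assert rec.blood_detected is True

    def test_user_extensible_alias(self, tmp_path):
        path = tmp_path / "odd.tsv"
        path.write_text(
            "symbol\tbrain_distribution\ttissue_distribution\tsubcellular\t"
            "blood_detected\nG1\tnot detected\tnot detected\t\tfalse\n"
        )
        (rec,) = read_annotation_table(path, extra_aliases={"symbol": "gene"})
        assert rec.gene_symbol == "G1"

    def test_missing_required_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ttissue_distribution\tsubcellular\tblood_detected\n")
        with pytest.raises(FormatError, match="brain_distribution"):
            read_annotation_table(path)

    def test_duplicate_gene_symbol_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "gene\tbrain_distribution\ttissue_distribution\tsubcellular\t"
            "blood_detected\nG1\tnot detected\tnot detected\t\tfalse\n"
            "G1\tnot detected\tnot detected\t\tfalse\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_annotation_table(path)

    def test_no_silent_row_drops(self, tmp_path, annotation_config):
        records = simulate_annotations(annotation_config)
        path = tmp_path / "ann.tsv"
        write_annotation_table(records, path)
        n_rows = len(path.read_text().rstrip("\n").split("\n")) - 1
        assert len(read_annotation_table(path)) == n_rows

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Detected in all", "detected_in_all"),
            ("  detected_in_single ", "detected_in_single"),
            ("Not detected", "not_detected"),
            ("garbage", "unknown"),
            (None, "unknown"),
        ],
    )
    def test_category_normalization(self, raw, expected):
        assert normalize_category(raw) == expected

    def test_negative_expression_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            GeneAnnotation(gene_symbol="G1", tissue_nx={"lung": -1.0})

    def test_subcellular_sorted_by_descending_confidence(self):
        rec = GeneAnnotation(
            gene_symbol="G1",
            subcellular=[("cytosol", 2.0), ("plasma membrane", 5.0)],
        )
        assert rec.subcellular[0] == ("plasma membrane", 5.0)


class TestBulkDataset:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        ds = make_bulk_dataset(rng.gamma(2, 5, (6, 3)), ["a", "b", "c"],
                               "D1", "protein", n_case=4)
        path = tmp_path / "bulk.tsv"
        write_bulk_dataset(ds, path)
        back = read_bulk_dataset(path, "D1", "protein")
        assert back.sample_groups == ds.sample_groups
        np.testing.assert_allclose(back.values.to_numpy(), ds.values.to_numpy())

    def test_missing_group_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\tg1\ns1\t3.0\n")
        with pytest.raises(FormatError, match="group"):
            read_bulk_dataset(path)

    def test_dataset_without_cases_rejected(self):
        with pytest.raises(ValidationError, match="case"):
            make_bulk_dataset(np.ones((3, 2)), ["a", "b"], n_case=0)


class TestCellMatrix:
    def _write(self, tmp_path, m):
        paths = (tmp_path / "c.mtx", tmp_path / "cells.tsv", tmp_path / "genes.tsv")
        write_cell_matrix(m, *paths)
        return paths

    def test_single_entry_matrix(self, tmp_path):
        m = CellMatrix(
            counts=sp.csr_matrix(np.array([[0, 0], [0, 5], [0, 0]])),
            cell_ids=["c1", "c2", "c3"],
            gene_ids=["g1", "g2"],
            cell_groups={"c1": "case", "c2": "case", "c3": "control"},
            mito_flags=np.array([False, False]),
        )
        back = read_cell_matrix(*self._write(tmp_path, m))
        assert back.counts.nnz == 1
        assert back.counts[1, 1] == 5

    def test_round_trip_preserves_sparse_structure(self, tmp_path):
        rng = np.random.default_rng(1)
        counts = sp.random(30, 20, density=0.2, random_state=1,
                           data_rvs=lambda n: rng.integers(1, 9, n)).tocsr()
        m = CellMatrix(
            counts=counts,
            cell_ids=[f"c{i}" for i in range(30)],
            gene_ids=[f"g{i}" for i in range(20)],
            cell_groups={f"c{i}": "case" for i in range(30)},
            mito_flags=np.zeros(20, bool),
        )
        back = read_cell_matrix(*self._write(tmp_path, m))
        assert (back.counts != m.counts).nnz == 0
        assert back.cell_ids == m.cell_ids and back.gene_ids == m.gene_ids

    def test_mito_prefix_rule(self, tmp_path):
        m = CellMatrix(
            counts=sp.csr_matrix(np.ones((2, 3), dtype=int)),
            cell_ids=["c1", "c2"],
            gene_ids=["MT-CO1", "GAPDH", "mt-nd1"],
            cell_groups={"c1": "case", "c2": "control"},
            mito_flags=np.array([True, False, True]),
        )
        mtx, cells, genes = self._write(tmp_path, m)
        # strip the mito column so the reader must fall back to the prefix
        lines = genes.read_text().splitlines()
        genes.write_text("\n".join(line.split("\t")[0] for line in lines) + "\n")
        back = read_cell_matrix(mtx, cells, genes)
        assert back.mito_flags.tolist() == [True, False, True]

    def test_dimension_mismatch_rejected(self, tmp_path):
        m = CellMatrix(
            counts=sp.csr_matrix(np.ones((2, 2), dtype=int)),
            cell_ids=["c1", "c2"],
            gene_ids=["g1", "g2"],
            cell_groups={"c1": "case", "c2": "case"},
            mito_flags=np.zeros(2, bool),
        )
        mtx, cells, genes = self._write(tmp_path, m)
        cells.write_text(cells.read_text() + "c3\tcase\n")
        with pytest.raises(FormatError, match="does not match"):
            read_cell_matrix(mtx, cells, genes)

    def test_non_integral_counts_rejected(self):
        with pytest.raises(ValidationError, match="integral"):
            CellMatrix(
                counts=sp.csr_matrix(np.array([[0.5]])),
                cell_ids=["c1"],
                gene_ids=["g1"],
                cell_groups={"c1": "case"},
                mito_flags=np.zeros(1, bool),
            )
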