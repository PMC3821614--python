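import numpy as np
import pandas as pd
import pytest

from ripchip.io import ProbeAnnotation, Scale
from ripchip.preprocess import (
    collapse_to_genes,
    filter_detection,
    filter_refseq,
    log2_transform,
    quantile_normalize,
    preprocess,
)

from conftest import make_design, make_probe_matrix


def rank_average_oracle(values: np.ndarray) -> np.ndarray:
    """Brute-force quantile normalization: reference = mean of sorted
    columns; each value replaced by the reference at its within-column
    rank, ties averaged over their block of reference positions."""
    n, m = values.shape
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(m):
        col = values[:, j]
        for i in range(n):
            tied = np.flatnonzero(np.sort(col) == col[i])
            out[i, j] = ref[tied].mean()
    return out


class TestQuantileNormalize:
    def test_two_column_example(self):
        m = make_probe_matrix(
            np.array([[1, 4], [2, 5], [3, 6]]), ["p1", "p2", "p3"], ["a", "b"]
        )
        result = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(result.intensities.to_numpy(), expected)

    def test_identical_columns_are_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        m = make_probe_matrix(np.column_stack([col, col]), ["p1", "p2", "p3"], ["a", "b"])
        result = quantile_normalize(m)
        np.testing.assert_allclose(result.intensities.to_numpy(), np.column_stack([col, col]))

    def test_matches_rank_average_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            values = rng.uniform(0, 100, size=(10, 4))
            m = make_probe_matrix(values, [f"p{i}" for i in range(10)], list("abcd"))
            result = quantile_normalize(m).intensities.to_numpy()
            np.testing.assert_allclose(result, rank_average_oracle(values), rtol=1e-12)

    def test_columns_share_sorted_values_and_ranks_preserved(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(3, 1, size=(50, 6))
        m = make_probe_matrix(values, [f"p{i}" for i in range(50)], list("abcdef"))
        result = quantile_normalize(m).intensities.to_numpy()
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(result[:, 0]), np.sort(result[:, j]))
            assert (np.argsort(result[:, j]) == np.argsort(values[:, j])).all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(1, 50, size=(20, 3))
        m = make_probe_matrix(values, [f"p{i}" for i in range(20)], list("abc"))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.intensities.to_numpy(), twice.intensities.to_numpy(), rtol=1e-12
        )

    def test_ties_get_mean_of_tied_reference_positions(self):
        values = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        m = make_probe_matrix(values, ["p1", "p2", "p3"], ["a", "b"])
        result = quantile_normalize(m).intensities.to_numpy()
        ref = np.sort(values, axis=0).mean(axis=1)
        assert result[0, 0] == result[1, 0] == pytest.approx(ref[:2].mean())
        assert result[2, 0] == pytest.approx(ref[2])

    def test_single_column_returned_unchanged(self, caplog):
        m = make_probe_matrix(np.array([[1.0], [2.0]]), ["p1", "p2"], ["a"])
        with caplog.at_level("WARNING"):
            result = quantile_normalize(m)
        np.testing.assert_allclose(result.intensities.to_numpy(), [[1.0], [2.0]])


class TestLog2Transform:
    def test_exact_power_of_two_and_floor(self):
        m = make_probe_matrix(np.array([[8.0], [0.0]]), ["p1", "p2"], ["a"])
        result = log2_transform(m, floor=1.0)
        assert result.scale is Scale.LOG2
        np.testing.assert_allclose(result.intensities.to_numpy().ravel(), [3.0, 0.0])

    def test_inverse_identity(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 100, size=(30, 2))
        m = make_probe_matrix(values, [f"p{i}" for i in range(30)], ["a", "b"])
        result = log2_transform(m, floor=0.5)
        np.testing.assert_allclose(
            2.0 ** result.intensities.to_numpy(), np.maximum(values, 0.5), rtol=1e-12
        )

    def test_non_positive_floor_fatal(self):
        m = make_probe_matrix(np.array([[1.0]]), ["p"], ["a"])
        with pytest.raises(ValueError, match="floor"):
            log2_transform(m, floor=0.0)


class TestFilterDetection:
    def _matrix(self, detection_rows):
        design = make_design(3)
        det = np.array(detection_rows, dtype=float)
        values = np.full_like(det, 100.0)
        probes = [f"p{i}" for i in range(det.shape[0])]
        return make_probe_matrix(values, probes, design.sample_ids, det), design

    def test_undetected_everywhere_removed(self):
        m, design = self._matrix([[0.5] * 12])
        retained, removed = filter_detection(m, design, 0.01)
        assert removed == ["p0"]
        assert len(retained.probe_ids) == 0

    def test_detected_everywhere_retained(self):
        m, design = self._matrix([[0.0] * 12])
        retained, removed = filter_detection(m, design, 0.01)
        assert removed == []
        assert list(retained.probe_ids) == ["p0"]

    def test_detected_in_single_condition_by_majority_is_retained(self):
        # detected (p=0.005) in 2 of 3 replicates of the KO IP cell only:
        # the genotype-restricted absence case — present in KO, absent in WT
        row = [0.5] * 12
        design = make_design(3)
        for i, sid in enumerate(design.sample_ids):
            if sid in ("KO_IP_1", "KO_IP_2"):
                row[i] = 0.005
        m, design = self._matrix([row])
        retained, removed = filter_detection(m, design, 0.01)
        assert list(retained.probe_ids) == ["p0"]

    def test_minority_detection_is_not_enough(self):
        row = [0.5] * 12
        design = make_design(3)
        row[design.sample_ids.index("KO_IP_1")] = 0.005
        m, design = self._matrix([row])
        _, removed = filter_detection(m, design, 0.01)
        assert removed == ["p0"]

    def test_alpha_one_is_identity_and_partition_holds(self):
        rng = np.random.default_rng(4)
        det = rng.uniform(0, 1, size=(20, 12))
        m, design = self._matrix(det.tolist())
        retained, removed = filter_detection(m, design, 1.0)
        assert removed == []
        retained2, removed2 = filter_detection(m, design, 0.01)
        assert set(retained2.probe_ids) | set(removed2) == set(m.probe_ids)
        assert set(retained2.probe_ids) & set(removed2) == set()

    def test_invalid_alpha_fatal(self):
        m, design = self._matrix([[0.5] * 12])
        with pytest.raises(ValueError, match="alpha"):
            filter_detection(m, design, 0.0)


class TestFilterRefseq:
    def _annotation(self, refseqs):
        return ProbeAnnotation(
            pd.DataFrame(
                {
                    "SYMBOL": [f"G{i}" for i in range(len(refseqs))],
                    "REFSEQ": refseqs,
                    "DEFINITION": "",
                },
                index=[f"p{i}" for i in range(len(refseqs))],
            )
        )

    def test_annotated_kept_unannotated_removed(self):
        m = make_probe_matrix(np.ones((2, 1)), ["p0", "p1"], ["a"])
        retained, removed = filter_refseq(m, self._annotation(["NM_012345", ""]))
        assert list(retained.probe_ids) == ["p0"]
        assert removed == ["p1"]

    def test_all_annotated_is_identity(self):
        m = make_probe_matrix(np.ones((2, 1)), ["p0", "p1"], ["a"])
        retained, removed = filter_refseq(m, self._annotation(["NM_1", "NM_2"]))
        assert list(retained.probe_ids) == ["p0", "p1"] and removed == []

    def test_probe_missing_from_annotation_fatal(self):
        m = make_probe_matrix(np.ones((2, 1)), ["p0", "zzz"], ["a"])
        with pytest.raises(ValueError, match="zzz"):
            filter_refseq(m, self._annotation(["NM_1", "NM_2"]))


class TestCollapseToGenes:
    def _setup(self, probes, symbols, means):
        # 2-sample log2 matrix whose row means equal `means`
        values = np.column_stack([np.array(means) - 1, np.array(means) + 1])
        m = make_probe_matrix(values, probes, ["a", "b"], scale=Scale.LOG2)
        ann = ProbeAnnotation(
            pd.DataFrame(
                {"SYMBOL": symbols, "REFSEQ": "NM_1", "DEFINITION": ""}, index=probes
            )
        )
        return m, ann

    def test_single_probe_gene_is_identity(self):
        m, ann = self._setup(["p0"], ["GeneA"], [7.0])
        g = collapse_to_genes(m, ann)
        assert list(g.gene_symbols) == ["GeneA"]
        assert g.provenance["GeneA"] == "p0"

    def test_highest_mean_probe_chosen(self):
        m, ann = self._setup(["p0", "p1"], ["GeneA", "GeneA"], [7.1, 9.3])
        g = collapse_to_genes(m, ann)
        assert g.provenance["GeneA"] == "p1"
        np.testing.assert_allclose(g.log2_values.loc["GeneA"], [8.3, 10.3])

    def test_tie_breaks_lexicographically(self):
        m, ann = self._setup(["ILMN_2", "ILMN_10"], ["GeneA", "GeneA"], [8.0, 8.0])
        g = collapse_to_genes(m, ann)
        assert g.provenance["GeneA"] == "ILMN_10"  # "ILMN_10" < "ILMN_2"

    def test_row_count_equals_distinct_symbols(self):
        rng = np.random.default_rng(5)
        probes = [f"p{i}" for i in range(30)]
        symbols = [f"G{i % 11}" for i in range(30)]
        m, ann = self._setup(probes, symbols, rng.uniform(5, 12, 30).tolist())
        assert len(collapse_to_genes(m, ann).gene_symbols) == 11


def test_full_preprocess_chain_counts(default_sim):
    genes, removed = preprocess(default_sim.matrix, default_sim.annotation, default_sim.design)
    # every simulated gene survives; decoys are removed by the RefSeq filter
    assert len(genes.gene_symbols) == 2000
    assert (removed["reason"] == "no_refseq").sum() == 20
    assert set(genes.sample_ids) == set(default_sim.design.sample_ids)
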