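import numpy as np
import pandas as pd
import pytest

from ripchip.io import Fraction, Genotype, Thresholds
from ripchip.ripcalling import (
    call_rip_targets,
    call_targets,
    compute_enrichment,
    negative_control_check,
)

from conftest import make_design, make_gene_matrix


def _matrix_with_ip_boost(design, log2_ip_boost, base=8.0):
    """One gene per boost value; IP samples of both genotypes shifted."""
    n = len(log2_ip_boost)
    log2 = np.full((n, len(design)), base)
    ip_cols = [i for i, s in enumerate(design) if s.fraction is Fraction.IP]
    log2[:, ip_cols] += np.asarray(log2_ip_boost)[:, None]
    return make_gene_matrix(log2, [f"G{i}" for i in range(n)], design)


class TestComputeEnrichment:
    def test_exact_power_of_two(self):
        design = make_design(3)
        g = _matrix_with_ip_boost(design, [2.0])  # IP 2 log2 units above total
        rec = compute_enrichment(g, design, "WT")
        assert rec.loc[0, "enrichment"] == pytest.approx(4.0)

    def test_equal_fractions_give_unit_enrichment_p_one(self):
        design = make_design(3)
        g = _matrix_with_ip_boost(design, [0.0])
        rec = compute_enrichment(g, design, "KO")
        assert rec.loc[0, "enrichment"] == pytest.approx(1.0)
        assert rec.loc[0, "p_value"] == 1.0

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(31)
        design = make_design(3)
        log2 = rng.normal(8, 1, size=(10, 12))
        g = make_gene_matrix(log2, [f"G{i}" for i in range(10)], design)
        forward = compute_enrichment(g, design, "WT")["enrichment"].to_numpy()
        # swap fractions by relabeling columns: TOTAL <-> IP
        swapped_cols = {}
        for s in design:
            other = "IP" if s.fraction is Fraction.TOTAL else "TOTAL"
            swapped_cols[s.sample_id] = f"{s.genotype.value}_{other}_{s.replicate}"
        g2 = make_gene_matrix(log2, [f"G{i}" for i in range(10)], design)
        g2.log2_values.columns = [swapped_cols[c] for c in g2.log2_values.columns]
        g2.detection_p.columns = g2.log2_values.columns
        backward = compute_enrichment(g2, design, "WT")["enrichment"].to_numpy()
        np.testing.assert_allclose(forward * backward, 1.0, rtol=1e-10)

    def test_missing_fraction_fatal(self):
        design = make_design(3)
        g = _matrix_with_ip_boost(design, [1.0])
        with pytest.raises(ValueError, match="replicate"):
            compute_enrichment(g, make_design(1), "WT")


class TestCallTargets:
    def _records(self, enrichments, p_values, genotype="KO"):
        return pd.DataFrame(
            {
                "gene_symbol": [f"G{i}" for i in range(len(enrichments))],
                "genotype": genotype,
                "enrichment": enrichments,
                "log2_enrichment": np.log2(enrichments),
                "statistic": 0.0,
                "p_value": p_values,
            }
        )

    def test_unit_enrichment_is_non_target(self):
        out, summary = call_targets(self._records([1.0], [1.0]))
        assert not out.loc[0, "is_target"] and summary.n_targets == 0

    def test_exact_twofold_is_non_target(self):
        out, _ = call_targets(self._records([2.0], [1e-9]))
        assert not out.loc[0, "is_target"]  # strict > 2 boundary

    def test_planted_targets_recovered_without_false_calls(self):
        # 20 targets at enrichment 4 (sd 0.2, n=3) over 500 background genes:
        # effect >> noise, all planted called, no background gene survives FDR
        rng = np.random.default_rng(32)
        design = make_design(3)
        n, n_t = 520, 20
        log2 = rng.normal(8, 0.2, size=(n, 12))
        ip_cols = [i for i, s in enumerate(design) if s.fraction is Fraction.IP]
        log2[np.ix_(range(n_t), ip_cols)] += 2.0
        g = make_gene_matrix(log2, [f"G{i}" for i in range(n)], design)
        rec = compute_enrichment(g, design, "WT")
        out, summary = call_targets(rec)
        called = set(out.loc[out["is_target"], "gene_symbol"])
        assert called == {f"G{i}" for i in range(n_t)}
        assert summary.n_targets == n_t

    def test_platform_fraction_one_decimal(self):
        enr = [3.0] * 731 + [1.0] * 50
        p = [1e-8] * 731 + [0.9] * 50
        _, summary = call_targets(self._records(enr, p), platform_size=30855)
        assert summary.platform_fraction_pct == 2.4

    def test_detection_gate_blocks_targets(self):
        rec = self._records([4.0], [1e-9])
        detected = pd.Series([False], index=["G0"])
        out, _ = call_targets(rec, detected=detected)
        assert not out.loc[0, "is_target"]


class TestNegativeControl:
    def test_planted_unit_control_passes_both_genotypes(self, default_sim):
        from ripchip.preprocess import preprocess

        g, _ = preprocess(default_sim.matrix, default_sim.annotation, default_sim.design)
        records, _ = call_rip_targets(g, default_sim.design)
        result = negative_control_check(records, {"Gapdh"})
        assert result.loc[0, "status"] == "pass"
        assert result.loc[0, "max_enrichment"] < 2.0

    def test_enriched_control_fails(self):
        records = pd.DataFrame(
            {"gene_symbol": ["Gapdh"], "genotype": ["WT"], "enrichment": [3.0]}
        )
        result = negative_control_check(records, {"Gapdh"})
        assert result.loc[0, "status"] == "fail"

    def test_absent_control_is_not_evaluable(self):
        records = pd.DataFrame(
            {"gene_symbol": ["GeneA"], "genotype": ["WT"], "enrichment": [1.0]}
        )
        result = negative_control_check(records, {"Gapdh"})
        assert result.loc[0, "status"] == "not_evaluable"


def test_target_sets_invariant_to_sample_relabeling(default_sim):
    from ripchip.io import Sample, StudyDesign
    from ripchip.preprocess import preprocess

    g, _ = preprocess(default_sim.matrix, default_sim.annotation, default_sim.design)
    records, _ = call_rip_targets(g, default_sim.design)
    baseline = set(records.loc[records["is_target"], ["gene_symbol", "genotype"]].itertuples(index=False))

    renamed = StudyDesign(
        [Sample("X_" + s.sample_id, s.genotype, s.fraction, s.replicate)
         for s in default_sim.design]
    )
    g2 = type(g)(
        g.log2_values.set_axis(renamed.sample_ids, axis=1),
        g.detection_p.set_axis(renamed.sample_ids, axis=1),
        g.provenance,
    )
    records2, _ = call_rip_targets(g2, renamed)
    relabeled = set(records2.loc[records2["is_target"], ["gene_symbol", "genotype"]].itertuples(index=False))
    assert baseline == relabeled


def test_absent_gene_is_target_only_where_detected(default_sim):
    """A transcript absent in WT (background signal, detection p > 0.01)
    stays eligible — and is typically called — in KO."""
    from ripchip.preprocess import preprocess

    g, _ = preprocess(default_sim.matrix, default_sim.annotation, default_sim.design)
    records, _ = call_rip_targets(g, default_sim.design)
    absent = default_sim.truth.index[default_sim.truth["absent_in"] == "WT"]
    sub = records[records["gene_symbol"].isin(absent)]
    wt = sub[sub["genotype"] == "WT"]
    ko = sub[sub["genotype"] == "KO"]
    assert not wt["is_target"].any()
    assert not wt["detected"].any()
    assert ko["detected"].all()
    assert ko["is_target"].sum() >= len(absent) - 1  # allow one borderline miss
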