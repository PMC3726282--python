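"""Read accounting, RPKM, fold changes and the consistent-induction filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from butomics import (
    FoldChangeTable,
    SampleReadStats,
    compute_fold_changes,
    compute_rpkm,
    filter_consistent_induction,
    replicate_correlation,
    summarize_read_stats,
)
from butomics.transcriptomics import rpkm_to_counts


class TestReadStats:
    def test_mapping_ratio_denominator_is_qualified_reads(self):
        r = SampleReadStats("C242", 15535317, 5552572, 3177168)
        assert round(100 * r.mapping_ratio, 2) == 57.22

    def test_fully_mapped_sample_is_100_percent(self):
        r = SampleReadStats("s", 2000, 1000, 1000)
        assert round(100 * r.mapping_ratio, 2) == 100.00

    def test_invariant_raw_ge_qualified_ge_mapped(self):
        with pytest.raises(ValueError):
            SampleReadStats("bad", 100, 200, 50)
        with pytest.raises(ValueError):
            SampleReadStats("bad", 200, 100, 150)

    def test_zero_qualified_reads_has_undefined_ratio(self):
        r = SampleReadStats("empty", 10, 0, 0)
        with pytest.raises(ZeroDivisionError):
            r.mapping_ratio

    def test_aggregates_equal_hand_computed_sums(self, table1_stats):
        s = summarize_read_stats(table1_stats)
        raws = [r.raw_reads for r in table1_stats]
        quals = [r.qualified_reads for r in table1_stats]
        pcts = [round(100 * r.mapped_reads / r.qualified_reads, 2) for r in table1_stats]
        assert s["total_raw"] == sum(raws)
        assert s["total_qualified"] == sum(quals)
        assert s["mean_raw"] == pytest.approx(sum(raws) / 6)
        assert s["mean_mapping_ratio_pct"] == round(sum(pcts) / 6, 1)


class TestRpkm:
    def test_unit_identity(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        expr = compute_rpkm(counts, pd.Series([1000], index=["g"]),
                            pd.Series([10**6], index=["s"]))
        assert expr.rpkm.loc["g", "s"] == 10.0

    def test_zero_count_gives_zero_rpkm(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        expr = compute_rpkm(counts, pd.Series([500], index=["g"]),
                            pd.Series([10**6], index=["s"]))
        assert expr.rpkm.loc["g", "s"] == 0.0

    def test_matches_elementwise_formula_oracle(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{j}" for j in range(4)]
        counts = pd.DataFrame(rng.integers(0, 5000, (20, 4)), index=genes,
                              columns=samples)
        lengths = pd.Series(rng.integers(100, 4000, 20), index=genes)
        totals = pd.Series(rng.integers(10**6, 10**7, 4), index=samples)
        expr = compute_rpkm(counts, lengths, totals)
        for g in genes:  # independent elementwise oracle
            for s in samples:
                expected = counts.loc[g, s] * 1e9 / (lengths[g] * totals[s])
                assert expr.rpkm.loc[g, s] == pytest.approx(expected, rel=1e-12)
        # round-trip inversion
        back = rpkm_to_counts(expr)
        assert np.allclose(back.values, counts.values, rtol=1e-9)

    def test_zero_length_rejected_naming_gene(self):
        counts = pd.DataFrame({"s": [1]}, index=["gX"])
        with pytest.raises(ValueError, match="gX"):
            compute_rpkm(counts, pd.Series([0], index=["gX"]),
                         pd.Series([10**6], index=["s"]))


def _expr_from_rpkm(rpkm: pd.DataFrame):
    from butomics.transcriptomics import ExpressionMatrix

    return ExpressionMatrix(
        rpkm=rpkm,
        gene_lengths=pd.Series(1000.0, index=rpkm.index),
        mapped_totals=pd.Series(1e6, index=rpkm.columns),
    )


class TestFoldChanges:
    manifest = pd.DataFrame(
        {
            "sample_id": ["C24", "B24"],
            "condition": ["control", "butanol"],
            "time_h": [24, 24],
        }
    )

    @pytest.mark.parametrize(
        "treated,control,expected", [(3.0, 1.0, 3.0), (1.0, 3.0, -3.0), (2.0, 2.0, 1.0)]
    )
    def test_signed_convention(self, treated, control, expected):
        rpkm = pd.DataFrame({"C24": [control], "B24": [treated]}, index=["g"])
        fc = compute_fold_changes(_expr_from_rpkm(rpkm), self.manifest)
        assert fc.fc.loc["g", 24] == pytest.approx(expected)

    def test_missing_condition_is_design_error(self):
        rpkm = pd.DataFrame({"C24": [1.0], "B24": [1.0]}, index=["g"])
        bad = self.manifest.assign(condition=["control", "control"])
        with pytest.raises(ValueError, match="24"):
            compute_fold_changes(_expr_from_rpkm(rpkm), bad)

    def test_zeros_handled_by_pseudocount(self):
        rpkm = pd.DataFrame({"C24": [0.0, 4.0], "B24": [4.0, 0.0]}, index=["g1", "g2"])
        fc = compute_fold_changes(_expr_from_rpkm(rpkm), self.manifest)
        assert np.isfinite(fc.fc.values).all()
        assert fc.fc.loc["g1", 24] > 1 and fc.fc.loc["g2", 24] < -1


class TestInductionFilter:
    def test_table2_fixture_all_pass(self, table2_fc):
        fc = FoldChangeTable(
            fc=table2_fc[["fc_24h", "fc_48h", "fc_72h"]].set_axis([24, 48, 72], axis=1)
        )
        induced = filter_consistent_induction(fc, 1.5)
        assert len(induced) == len(table2_fc) == 70

    def test_threshold_inclusive_and_failure_at_one_time_point(self):
        fc = FoldChangeTable(
            fc=pd.DataFrame(
                {24: [2.52, 32.0, 1.50], 48: [1.54, 1.49, 1.50], 72: [1.86, 7.0, 1.50]},
                index=["keeps", "fails_48h", "exactly_at_threshold"],
            )
        )
        induced = filter_consistent_induction(fc, 1.5)
        assert induced.genes == ["exactly_at_threshold", "keeps"]

    @given(
        arrays(
            float,
            (12, 3),
            elements=st.one_of(
                st.floats(1.0, 40.0), st.floats(-40.0, -1.0)
            ),
        ),
        st.floats(1.1, 5.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_per_gene_brute_force_oracle(self, values, threshold):
        fc = FoldChangeTable(
            fc=pd.DataFrame(values, index=[f"g{i}" for i in range(12)],
                            columns=[24, 48, 72])
        )
        got = set(filter_consistent_induction(fc, threshold).genes)
        expected = {
            g
            for g in fc.fc.index
            if all(fc.fc.loc[g, t] >= threshold for t in fc.fc.columns)
        }
        assert got == expected

    @given(
        arrays(float, (10, 3), elements=st.floats(-20.0, 20.0).filter(lambda v: abs(v) >= 1))
    )
    @settings(deadline=None, max_examples=40)
    def test_raising_threshold_never_adds_genes(self, values):
        fc = FoldChangeTable(
            fc=pd.DataFrame(values, index=[f"g{i}" for i in range(10)],
                            columns=[24, 48, 72])
        )
        lo = set(filter_consistent_induction(fc, 1.5).genes)
        hi = set(filter_consistent_induction(fc, 2.5).genes)
        assert hi <= lo


class TestReplicateCorrelation:
    def test_identical_replicates_correlate_perfectly(self):
        v = np.array([1.0, 5.0, 20.0, 100.0])
        assert replicate_correlation(v, v) == pytest.approx(1.0)

    def test_mirrored_log_deviations_correlate_negatively(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        assert replicate_correlation(
            np.exp(x), np.exp(-x), pseudocount=0.0
        ) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation(np.ones(5), np.arange(1.0, 6.0))

    def test_synthetic_replicate_pair_value_frozen_from_seeded_run(self):
        """Duplicated 72 h treated samples at 5% CV correlate near 0.99."""
        import pandas as pd

        from butomics import SimConfig, compute_rpkm, gen_transcriptome

        counts, lengths, stats, _ = gen_transcriptome(SimConfig(seed=2, noise_cv=0.05))
        mapped = pd.Series({s.sample_id: s.mapped_reads for s in stats})
        expr = compute_rpkm(counts, lengths, mapped)
        r = replicate_correlation(expr.rpkm["B72R1"], expr.rpkm["B72R2"])
        assert r == pytest.approx(0.9891357880507522, abs=1e-9)
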