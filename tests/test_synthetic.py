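"""Synthetic-data generators: determinism, design integrity, planted truth."""

import math

import numpy as np
import pandas as pd
import pytest

from butomics import (
    SimConfig,
    build_ratio_cube,
    compute_fold_changes,
    compute_rpkm,
    filter_consistent_induction,
    gen_metabolome,
    gen_qpcr,
    gen_transcriptome,
    normalize_abundances,
    score_and_qualify,
)
from butomics.metabolomics import assign_cluster


class TestConfigValidation:
    def test_invalid_fields_name_the_field(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError, match="induced_fc_range"):
            SimConfig(induced_fc_range=(1.2, 3.0))
        with pytest.raises(ValueError, match="cluster_plan"):
            SimConfig(metabolite_cluster_plan={"VII": 3})
        with pytest.raises(ValueError, match="noise_cv"):
            SimConfig(noise_cv=-0.1)
        with pytest.raises(ValueError, match="time_points"):
            SimConfig(time_points=(48, 24, 72))


class TestDeterminism:
    def test_same_seed_identical_transcriptome(self):
        sim = SimConfig(seed=42, n_genes=100)
        a = gen_transcriptome(sim)
        b = gen_transcriptome(SimConfig(seed=42, n_genes=100))
        assert a[0].to_csv() == b[0].to_csv()  # byte-identical counts
        assert a[1].to_csv() == b[1].to_csv()
        assert [s.__dict__ for s in a[2]] == [s.__dict__ for s in b[2]]

    def test_same_seed_identical_metabolome_and_qpcr(self):
        sim = SimConfig(seed=42, n_metabolites=50)
        ra, ca, _ = gen_metabolome(sim)
        rb, cb, _ = gen_metabolome(SimConfig(seed=42, n_metabolites=50))
        assert ra.to_csv() == rb.to_csv() and ca.to_csv() == cb.to_csv()
        qa, _ = gen_qpcr(sim)
        qb, _ = gen_qpcr(SimConfig(seed=42, n_metabolites=50))
        assert qa.to_csv() == qb.to_csv()

    def test_different_seeds_differ(self):
        a, *_ = gen_transcriptome(SimConfig(seed=1, n_genes=50))
        b, *_ = gen_transcriptome(SimConfig(seed=2, n_genes=50))
        assert a.to_csv() != b.to_csv()


class TestDesignIntegrity:
    def test_transcriptome_read_stats_ordering(self):
        _, _, stats, _ = gen_transcriptome(SimConfig(seed=0, n_genes=50))
        for s in stats:
            assert s.raw_reads >= s.qualified_reads >= s.mapped_reads > 0

    def test_metabolome_manifest_covers_full_grid(self):
        sim = SimConfig(seed=0, n_metabolites=50)
        _, _, truth = gen_metabolome(sim)
        man = truth.manifest_frame()
        assert len(man) == 18  # 2 conditions x 3 times x 3 replicates
        assert not man.duplicated(["condition", "time_h", "replicate"]).any()
        grid = man.groupby(["condition", "time_h"])["replicate"].apply(sorted)
        assert all(reps == [1, 2, 3] for reps in grid)

    def test_treated_72h_is_duplicated_by_default(self):
        _, _, _, truth = gen_transcriptome(SimConfig(seed=0, n_genes=50))
        man = truth.manifest_frame()
        treated_72 = man[(man.condition == "butanol") & (man.time_h == 72)]
        assert len(treated_72) == 2

    def test_planted_truth_matches_cluster_patterns(self):
        from butomics.synthetic import PLANT_PATTERNS

        _, _, truth = gen_metabolome(SimConfig(seed=5, n_metabolites=60))
        for m, (label, signs) in truth.metabolite_patterns.items():
            assert tuple(signs[t] for t in (24, 48, 72)) == PLANT_PATTERNS[label]


class TestZeroNoiseRecovery:
    def test_planted_rpkm_ratios_exact_at_fc_bound(self):
        sim = SimConfig(seed=3, n_genes=80, induced_fc_range=(1.5, 1.5), noise_cv=0)
        counts, lengths, stats, truth = gen_transcriptome(sim)
        mapped = pd.Series({s.sample_id: s.mapped_reads for s in stats})
        expr = compute_rpkm(counts, lengths, mapped)
        fc = compute_fold_changes(expr, truth.manifest_frame())
        for g in truth.induced_genes:
            for t in (24, 48, 72):
                assert fc.fc.loc[g, t] == pytest.approx(1.5, rel=1e-12)

    def test_full_recovery_of_planted_genes(self):
        sim = SimConfig(seed=6, n_genes=150, noise_cv=0)
        counts, lengths, stats, truth = gen_transcriptome(sim)
        mapped = pd.Series({s.sample_id: s.mapped_reads for s in stats})
        fc = compute_fold_changes(compute_rpkm(counts, lengths, mapped),
                                  truth.manifest_frame())
        induced = filter_consistent_induction(fc)
        assert set(induced.genes) == set(truth.induced_genes)

    def test_noiseless_cluster_I_metabolites_score_plus_nine(self):
        sim = SimConfig(seed=4, noise_cv=0, metabolite_effect_size=3.0)
        raw, cells, truth = gen_metabolome(sim)
        table = normalize_abundances(raw.drop(index="IS"), raw.loc["IS"], cells)
        sm = score_and_qualify(build_ratio_cube(table, truth.manifest_frame()))
        cluster1 = [m for m, (lab, _) in truth.metabolite_patterns.items()
                    if lab == "I"]
        assert (sm.scores.loc[cluster1].values == 9).all()
        # full planted set recovered, assigned its planted cluster
        assert set(sm.qualified_ids) == set(truth.metabolite_patterns)
        assignment = assign_cluster(sm.scores.loc[sm.qualified_ids])
        for m in sm.qualified_ids:
            assert assignment.loc[m, "cluster"] == truth.metabolite_patterns[m][0]

    def test_empty_cluster_plan_qualifies_nothing(self):
        sim = SimConfig(seed=4, noise_cv=0, metabolite_cluster_plan={})
        raw, cells, truth = gen_metabolome(sim)
        table = normalize_abundances(raw.drop(index="IS"), raw.loc["IS"], cells)
        sm = score_and_qualify(build_ratio_cube(table, truth.manifest_frame()))
        assert sm.qualified_ids == []


class TestSeededRecoveryFrozen:
    def test_noisy_induction_recall_and_precision(self):
        """Frozen from the seeded reference run (500 genes, 10% induced, CV 0.1)."""
        sim = SimConfig(seed=1, n_genes=500, induced_gene_fraction=0.1, noise_cv=0.1)
        counts, lengths, stats, truth = gen_transcriptome(sim)
        mapped = pd.Series({s.sample_id: s.mapped_reads for s in stats})
        fc = compute_fold_changes(compute_rpkm(counts, lengths, mapped),
                                  truth.manifest_frame())
        got = set(filter_consistent_induction(fc).genes)
        planted = set(truth.induced_genes)
        assert len(got & planted) / len(planted) == pytest.approx(0.9)
        assert len(got & planted) / len(got) == pytest.approx(1.0)

    def test_noisy_metabolite_qualification_recall(self):
        """Frozen from the seeded reference run (CV 0.15, effect 2.5)."""
        sim = SimConfig(seed=7, noise_cv=0.15, metabolite_effect_size=2.5)
        raw, cells, truth = gen_metabolome(sim)
        table = normalize_abundances(raw.drop(index="IS"), raw.loc["IS"], cells)
        sm = score_and_qualify(build_ratio_cube(table, truth.manifest_frame()))
        planted = set(truth.metabolite_patterns)
        got = set(sm.qualified_ids)
        assert len(got & planted) / len(planted) == pytest.approx(1.0)
        assert len(got & planted) / len(got) == pytest.approx(1.0)


class TestQpcrGenerator:
    def test_noiseless_perfect_doubling_slope(self):
        from butomics import fit_standard_curve

        qdf, _ = gen_qpcr(SimConfig(seed=0), efficiency=1.0, noise_sd=0.0)
        std = qdf[qdf["role"] == "standard"]
        curve = fit_standard_curve(list(zip(std["known_quantity"], std["ct"])))
        assert curve.slope == pytest.approx(-1 / math.log10(2))

    def test_noiseless_ratios_recovered_exactly(self):
        from butomics.pipeline import _fit_qpcr

        qdf, truth = gen_qpcr(SimConfig(seed=5), efficiency=0.9, noise_sd=0.0)
        res = _fit_qpcr(qdf, 1.5)
        for g, per_t in truth.induced_genes.items():
            plain = per_t[48]
            expected = plain if plain >= 1 else -1.0 / plain
            assert res["expression_ratios"][g] == pytest.approx(expected, rel=1e-6)

    def test_nonpositive_efficiency_rejected(self):
        with pytest.raises(ValueError):
            gen_qpcr(SimConfig(seed=0), efficiency=0.0)
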