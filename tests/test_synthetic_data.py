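"""Generators: determinism, boundary behavior, parameter recovery."""

import numpy as np
import pytest

from paleosweep.adna_qc import contamination_screen, damage_profile, fit_standard_curve
from paleosweep.sample_stats import observed_allele_frequency, summarize_genotype_table
from paleosweep.synthetic_data import (
    CASP12_DAMAGE_RATES,
    MTDNA_DAMAGE_RATES,
    SpecError,
    SyntheticSpec,
    dilution_series_csv,
    gen_clone_sets,
    gen_dilution_series,
    gen_genotype_table,
    gen_haplotype_survey,
)


class TestSpecValidation:
    def test_bad_genotype_distribution(self):
        with pytest.raises(SpecError):
            SyntheticSpec(genotype_distribution={"TT": 0.5, "CT": 0.2, "CC": 0.0})

    def test_bad_probability(self):
        with pytest.raises(SpecError):
            SyntheticSpec(dropout_rate=1.2)

    def test_bad_count_model(self):
        with pytest.raises(SpecError):
            SyntheticSpec(damage_count_model="negative-binomial")

    def test_layout_mismatch(self):
        with pytest.raises(SpecError, match="layout"):
            gen_genotype_table(SyntheticSpec(n_samples=10))


class TestGenotypeTable:
    def test_layout_mirrors_the_excavation_sites(self):
        table = gen_genotype_table(SyntheticSpec(seed=1, dropout_rate=0.0))
        summary = summarize_genotype_table(table)
        assert summary["total"] == 24
        assert summary["per_site"]["SJAPL (Araba)"] == 17

    def test_no_dropout_all_tt(self):
        table = gen_genotype_table(SyntheticSpec(seed=2, dropout_rate=0.0))
        assert set(table.df["genotype"]) == {"TT"}
        assert observed_allele_frequency(table, "T")["frequency"] == 1.0

    def test_full_dropout_all_missing(self):
        table = gen_genotype_table(SyntheticSpec(seed=3, dropout_rate=1.0))
        assert set(table.df["genotype"]) == {"missing"}

    def test_heterozygote_dropout_miscalls_homozygous(self):
        spec = SyntheticSpec(
            seed=4,
            genotype_distribution={"CC": 0.0, "CT": 1.0, "TT": 0.0},
            dropout_rate=0.4,
        )
        table = gen_genotype_table(spec)
        calls = ",".join(table.df["replicates"])
        assert "CC" in calls or "TT" in calls  # dropout-induced miscalls

    def test_deterministic_under_seed(self):
        a = gen_genotype_table(SyntheticSpec(seed=5, dropout_rate=0.3))
        b = gen_genotype_table(SyntheticSpec(seed=5, dropout_rate=0.3))
        assert a.df.equals(b.df)


class TestCloneSets:
    def test_zero_rates_give_identical_clones(self):
        spec = SyntheticSpec(
            seed=6, damage_rates={"mtdna_hvr1": {"A>G": 0.0}, "casp12": {}}
        )
        for cs in gen_clone_sets(spec, "mtdna_hvr1"):
            assert all(c == cs.consensus for c in cs.clones)
        assert damage_profile(gen_clone_sets(spec, "mtdna_hvr1")).mean_total == 0.0

    def test_deterministic_count_model_plants_exact_counts(self):
        # one clone per sample so clone deduplication cannot merge events
        import warnings

        spec = SyntheticSpec(
            seed=7,
            damage_rates={"mtdna_hvr1": {"A>G": 10.0}, "casp12": {}},
            damage_count_model="deterministic",
            clones_per_sample=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            prof = damage_profile(gen_clone_sets(spec, "mtdna_hvr1", n_samples=5))
        assert prof.per_type_means["A>G"] == pytest.approx(10.0)
        assert prof.mean_total == pytest.approx(10.0)

    def test_mtdna_rate_recovery_within_3_se(self):
        n = 200
        clonesets = gen_clone_sets(SyntheticSpec(seed=8), "mtdna_hvr1", n_samples=n)
        prof = damage_profile(clonesets)
        truth = sum(MTDNA_DAMAGE_RATES.values())  # 5.82
        se = np.std(prof.per_sample_totals, ddof=1) / np.sqrt(n)
        assert abs(prof.mean_total - truth) < 3 * se
        # per-type means individually within 3 SE of their Poisson rates
        for t, rate in MTDNA_DAMAGE_RATES.items():
            assert abs(prof.per_type_means[t] - rate) < 3 * max(
                np.sqrt(rate / n), 0.01
            )

    def test_casp12_rate_recovery_within_3_se(self):
        n = 200
        prof = damage_profile(
            gen_clone_sets(SyntheticSpec(seed=9), "casp12", n_samples=n)
        )
        truth = sum(CASP12_DAMAGE_RATES.values())  # 1.8
        se = np.std(prof.per_sample_totals, ddof=1) / np.sqrt(n)
        assert abs(prof.mean_total - truth) < 3 * se

    def test_fragment_lengths(self):
        spec = SyntheticSpec(seed=10)
        assert len(gen_clone_sets(spec, "casp12", n_samples=1)[0].consensus) == 80
        assert len(gen_clone_sets(spec, "mtdna_hvr1", n_samples=1)[0].consensus) == 100

    def test_unknown_locus_rejected(self):
        with pytest.raises(SpecError):
            gen_clone_sets(SyntheticSpec(seed=11), "nuclear")

    def test_determinism(self):
        a = gen_clone_sets(SyntheticSpec(seed=12), "mtdna_hvr1", n_samples=5)
        b = gen_clone_sets(SyntheticSpec(seed=12), "mtdna_hvr1", n_samples=5)
        assert [(x.consensus, x.clones) for x in a] == [
            (x.consensus, x.clones) for x in b
        ]


class TestHaplotypeSurvey:
    def test_no_contamination_passes_screen(self):
        samples, researchers, truth = gen_haplotype_survey(
            SyntheticSpec(seed=13, contamination_rate=0.0), 8, n_samples=40
        )
        assert truth == []
        assert contamination_screen(samples, researchers).passed

    def test_full_contamination_flags_everyone(self):
        samples, researchers, truth = gen_haplotype_survey(
            SyntheticSpec(seed=14, contamination_rate=1.0), 8, n_samples=30
        )
        report = contamination_screen(samples, researchers)
        assert len(truth) == 30
        assert sorted(m[0] for m in report.matches) == sorted(t[0] for t in truth)

    def test_screen_recovers_exact_planted_truth(self):
        samples, researchers, truth = gen_haplotype_survey(
            SyntheticSpec(seed=15, contamination_rate=0.2), 8, n_samples=50
        )
        report = contamination_screen(samples, researchers)
        assert sorted(report.matches) == sorted(truth)

    def test_researchers_are_distinct(self):
        _, researchers, _ = gen_haplotype_survey(SyntheticSpec(seed=16), 10)
        assert len({r.variants for r in researchers}) == 10


class TestDilutionSeries:
    def test_noiseless_perfect_doubling_recovered(self):
        spec = SyntheticSpec(seed=17, qpcr_efficiency=1.0, qpcr_ct_sd=0.0)
        curve = fit_standard_curve(gen_dilution_series(spec))
        assert curve.slope == pytest.approx(-1.0 / np.log10(2.0), abs=1e-5)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_design_layout(self):
        df = gen_dilution_series(SyntheticSpec(seed=18))
        assert sorted(df["copies_per_ul"].unique()) == [1.4e4, 1.4e5, 1.4e6]
        assert df.groupby("copies_per_ul").size().eq(4).all()

    def test_csv_byte_identical_under_seed(self):
        spec = SyntheticSpec(seed=19)
        assert dilution_series_csv(spec) == dilution_series_csv(spec)

    def test_efficiency_recovery_within_tolerance(self):
        spec = SyntheticSpec(seed=20, qpcr_efficiency=1.02, qpcr_ct_sd=0.1)
        curve = fit_standard_curve(gen_dilution_series(spec))
        assert curve.efficiency == pytest.approx(1.02, abs=0.15)

    def test_invalid_spec_rejected(self):
        with pytest.raises(SpecError):
            gen_dilution_series(SyntheticSpec(seed=21, qpcr_efficiency=0.0))
        with pytest.raises(SpecError):
            gen_dilution_series(SyntheticSpec(seed=22, qpcr_points=(0.0, 1e4, 1e5)))
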