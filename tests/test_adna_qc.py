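"""Damage profiling, contamination screening, concordance and qPCR curves."""

import numpy as np
import pytest

from paleosweep.adna_qc import (
    CloneSet,
    Haplotype,
    clone_majority_check,
    contamination_screen,
    damage_profile,
    fit_standard_curve,
    genotype_concordance,
    quantify_extract,
    read_clone_sets,
    write_clone_sets,
)

CONS = "ATGGCCATTGCAGGACCTAGACCTAATGCGTGAATTCAAG"


def _clones(*seqs, n_pad=10):
    """A clone set padded with consensus copies to meet the >=10 protocol."""
    clones = list(seqs) + [CONS] * max(0, n_pad - len(seqs))
    return CloneSet("s1", CONS, clones)


class TestDamageProfile:
    def test_identical_clone_gives_zero_profile(self):
        prof = damage_profile([_clones(CONS)])
        assert prof.mean_total == 0.0
        assert all(v == 0.0 for v in prof.per_type_means.values())
        assert prof.mean_total_damaged_only is None

    def test_hand_built_counts(self):
        # two A->G and one C->T planted by hand
        seq = list(CONS)
        assert seq[0] == "A" and seq[6] == "A" and seq[4] == "C"
        seq[0], seq[6], seq[4] = "G", "G", "T"
        prof = damage_profile([_clones("".join(seq))])
        assert prof.per_type_means["A>G"] == 2
        assert prof.per_type_means["C>T"] == 1
        assert prof.mean_total == 3

    def test_duplicate_clones_counted_once(self):
        seq = CONS[:10] + "G" + CONS[11:]  # one substitution
        assert CONS[10] != "G"
        prof_once = damage_profile([_clones(seq)])
        prof_dup = damage_profile([_clones(seq, seq, seq)])
        assert prof_dup.mean_total == prof_once.mean_total

    def test_single_base_insertions_classified(self):
        with_ins_a = CONS[:7] + "A" + CONS[7:]
        with_ins_g = CONS[:20] + "G" + CONS[20:]
        prof = damage_profile([_clones(with_ins_a, with_ins_g)])
        assert prof.per_type_means["insA"] == 1
        assert prof.per_type_means["insG"] == 1

    def test_position_by_position_oracle_on_substitution_only_sets(self):
        # brute-force oracle: direct base comparison at equal length
        rng = np.random.default_rng(17)
        clonesets = []
        expected = dict.fromkeys(["A>G", "G>A", "C>T", "T>C"], 0)
        n_other = 0
        for s in range(12):
            clones = []
            for _ in range(4):
                seq = list(CONS)
                for pos in rng.choice(len(seq), size=rng.integers(0, 3), replace=False):
                    old = seq[pos]
                    new = rng.choice([b for b in "ACGT" if b != old])
                    seq[pos] = new
                clones.append("".join(seq))
            cs = CloneSet(f"s{s}", CONS, clones + [CONS] * 6)
            clonesets.append(cs)
            for clone in dict.fromkeys(cs.clones):
                for a, b in zip(CONS, clone):
                    if a != b:
                        key = f"{a}>{b}"
                        if key in expected:
                            expected[key] += 1
                        else:
                            n_other += 1
        prof = damage_profile(clonesets)
        n = len(clonesets)
        for key, count in expected.items():
            assert prof.per_type_means[key] == pytest.approx(count / n)
        assert prof.per_type_means["other"] == pytest.approx(n_other / n)

    def test_total_mean_equals_sum_of_type_means(self):
        seq = CONS[:10] + "G" + CONS[11:]
        prof = damage_profile([_clones(seq), CloneSet("s2", CONS, [CONS] * 10)])
        assert prof.mean_total == pytest.approx(sum(prof.per_type_means.values()))
        assert prof.mean_total_damaged_only == pytest.approx(1.0)

    def test_unalignable_clone_excluded_with_warning(self):
        garbage = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in CONS)
        with pytest.warns(UserWarning, match="unalignable"):
            prof = damage_profile([_clones(garbage)])
        assert prof.excluded_clones == [("s1", 0)]
        assert prof.mean_total == 0.0


class TestCloneMajority:
    def test_unanimous(self):
        check = clone_majority_check(_clones(CONS), 5)
        assert check.passed and check.majority_fraction == 1.0

    def test_six_of_ten(self):
        variant = CONS[:5] + "T" + CONS[6:]
        assert CONS[5] != "T"
        cs = CloneSet("s1", CONS, [variant] * 4 + [CONS] * 6)
        check = clone_majority_check(cs, 5)
        assert check.passed and check.majority_fraction == 0.6

    def test_five_of_ten_is_a_tie_failure(self):
        variant = CONS[:5] + "T" + CONS[6:]
        cs = CloneSet("s1", CONS, [variant] * 5 + [CONS] * 5)
        check = clone_majority_check(cs, 5)
        assert not check.passed and check.tie

    def test_needs_three_clones(self):
        with pytest.warns(UserWarning):
            cs = CloneSet("s1", CONS, [CONS, CONS])
        with pytest.raises(ValueError):
            clone_majority_check(cs, 0)


def _hap(hid, *variants):
    return Haplotype(hid, frozenset(variants))


class TestContaminationScreen:
    def test_planted_match_flagged(self):
        shared = ((16126, "T", "C"), (16294, "C", "T"))
        report = contamination_screen(
            [_hap("s1", *shared), _hap("s2", (16304, "T", "C"))],
            [_hap("r1", *shared), _hap("r2", (16311, "T", "C"))],
        )
        assert report.matches == [("s1", "r1")]
        assert not report.passed

    def test_all_distinct_passes(self):
        report = contamination_screen(
            [_hap("s1", (16126, "T", "C"))],
            [_hap("r1", (16294, "C", "T"))],
        )
        assert report.passed and report.matches == []

    def test_shared_sample_haplotype_is_a_note_not_a_flag(self):
        v = (16223, "C", "T")
        report = contamination_screen(
            [_hap("s1", v), _hap("s2", v)],
            [_hap("r1", (16304, "T", "C"))],
        )
        assert report.passed
        assert report.shared_sample_haplotypes == [("s1", "s2")]

    def test_variant_validation(self):
        with pytest.raises(ValueError, match="outside HVR-I"):
            _hap("s1", (15000, "A", "G"))
        with pytest.raises(ValueError, match="malformed"):
            _hap("s1", (16126, "", "C"))


class TestConcordance:
    @pytest.mark.parametrize(
        "calls, status, genotype",
        [
            (["TT", "TT"], "authenticated", "TT"),
            (["TT", "missing"], "unconfirmed", None),
            (["CT", "TT"], "discordant", None),
            (["TT"], "unconfirmed", None),
            (["missing", "missing"], "unconfirmed", None),
            (["TT", "TT", "TT"], "authenticated", "TT"),
        ],
    )
    def test_rules(self, calls, status, genotype):
        res = genotype_concordance(calls)
        assert (res.status, res.genotype) == (status, genotype)

    def test_order_invariance(self):
        import itertools

        for calls in ([["CT", "TT", "missing"], ["TT", "TT", "missing"]]):
            results = {
                genotype_concordance(list(p)) for p in itertools.permutations(calls)
            }
            assert len(results) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genotype_concordance([])


class TestStandardCurve:
    def test_perfect_doubling_identity(self):
        # slope exactly -1/log10(2): 100% efficiency, r^2 = 1
        slope = -1.0 / np.log10(2.0)
        pts = [(c, 40.0 + slope * np.log10(c)) for c in (1e3, 1e4, 1e5, 1e6)]
        curve = fit_standard_curve(pts)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(slope, abs=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)

    def test_high_concentration_design_accepted(self):
        # the 3-point design at 1.4e4/1.4e5/1.4e6 copies/ul, 4 replicates
        slope, icpt = -3.1, 39.0
        pts = [
            (c, icpt + slope * np.log10(c))
            for c in (1.4e4, 1.4e5, 1.4e6)
            for _ in range(4)
        ]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(slope, abs=1e-9)

    def test_quantification_inverts_the_curve(self):
        slope = -1.0 / np.log10(2.0)
        pts = [(c, 40.0 + slope * np.log10(c)) for c in (1e3, 1e4, 1e5)]
        curve = fit_standard_curve(pts)
        assert quantify_extract(curve.intercept, curve) == pytest.approx(1.0)
        for q in (448.0, 1.4e5, 2.3e6):
            assert quantify_extract(curve.predict_ct(q), curve) == pytest.approx(
                q, rel=1e-9
            )

    def test_needs_three_distinct_concentrations(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_standard_curve([(1e3, 30.0), (1e3, 30.1), (1e4, 27.0)])

    def test_estimator_recovery_with_noise(self):
        # noisy series: the true efficiency falls inside the fit's own 95% CI
        # in >= 90% of simulations
        from scipy import stats as sps

        rng = np.random.default_rng(12)
        true_eff, icpt, sd = 0.92, 40.0, 0.1
        slope_true = -1.0 / np.log10(1 + true_eff)
        covered = 0
        n_sim = 60
        for _ in range(n_sim):
            pts = [
                (c, icpt + slope_true * np.log10(c) + rng.normal(0, sd))
                for c in (1.4e4, 1.4e5, 1.4e6)
                for _ in range(4)
            ]
            arr = np.asarray(pts)
            res = sps.linregress(np.log10(arr[:, 0]), arr[:, 1])
            tcrit = sps.t.ppf(0.975, len(pts) - 2)
            lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
            eff_bounds = sorted(10 ** (-1.0 / np.array([lo, hi])) - 1.0)
            covered += eff_bounds[0] <= true_eff <= eff_bounds[1]
        assert covered / n_sim >= 0.9


class TestCloneSetIO:
    def test_fasta_round_trip(self, tmp_path):
        cs = [
            _clones(CONS[:10] + "G" + CONS[11:]),
            CloneSet("s2", CONS, [CONS] * 10),
        ]
        path = tmp_path / "clones.fasta"
        write_clone_sets(cs, path)
        back = read_clone_sets(path)
        assert [c.sample_id for c in back] == ["s1", "s2"]
        assert back[0].consensus == CONS
        assert back[0].clones == cs[0].clones

    def test_missing_consensus_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">s1|clone1\nACGT\n")
        with pytest.raises(ValueError, match="no consensus"):
            read_clone_sets(path)
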