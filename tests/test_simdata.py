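"""Simulator: closed-form genotype distributions, sampling, PLINK text I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gwasmodels import (
    MISSING,
    DegenerateModelError,
    PedParseError,
    SimulationSpec,
    genotype_freqs_given_status,
    inject_missingness,
    read_ped_map,
    simulate_dataset,
    write_ped_map,
)


def or_spec(maf, odds_ratio, hom_rule="recessive", **kw):
    kw.setdefault("n_cases", 100)
    kw.setdefault("n_controls", 100)
    kw.setdefault("n_snps", 10)
    kw.setdefault("n_causal", 1)
    kw.setdefault("seed", 0)
    return SimulationSpec(
        causal_maf=maf, odds_ratio=odds_ratio, hom_rule=hom_rule, **kw
    )


def pen_spec(maf, pi, **kw):
    kw.setdefault("n_cases", 100)
    kw.setdefault("n_controls", 100)
    kw.setdefault("n_snps", 10)
    kw.setdefault("n_causal", 1)
    kw.setdefault("seed", 0)
    return SimulationSpec(
        causal_maf=maf,
        disease_model="penetrance_model",
        pi_AA=pi[0],
        pi_Aa=pi[1],
        pi_aa=pi[2],
        **kw,
    )


class TestGenotypeFreqs:
    def test_penetrance_closed_form(self):
        # f=(0.25,0.5,0.25), f*pi=(0.0025,0.005,0.025), normalizer 0.0325
        case, ctrl = genotype_freqs_given_status(pen_spec(0.5, (0.01, 0.01, 0.1)))
        assert case[2] == pytest.approx(0.025 / 0.0325)
        expected_ctrl = np.array([0.2475, 0.495, 0.225]) / 0.9675
        np.testing.assert_allclose(ctrl, expected_ctrl, rtol=1e-12)

    def test_unit_odds_ratio_is_null(self):
        case, ctrl = genotype_freqs_given_status(or_spec(0.3, 1.0))
        f = np.array([0.49, 0.42, 0.09])
        np.testing.assert_allclose(case, f, rtol=1e-12)
        np.testing.assert_allclose(ctrl, f, rtol=1e-12)

    def test_multiplicative_rule_closed_form(self):
        # w=(1,2,4): f*w=(0.49,0.84,0.36), normalizer 1.69
        case, _ = genotype_freqs_given_status(or_spec(0.3, 2.0, hom_rule="mult"))
        np.testing.assert_allclose(
            case, np.array([0.49, 0.84, 0.36]) / 1.69, rtol=1e-12
        )

    def test_recessive_rule_closed_form(self):
        # w=(1,1,2): f*w=(0.49,0.42,0.18), normalizer 1.09
        case, ctrl = genotype_freqs_given_status(or_spec(0.3, 2.0))
        np.testing.assert_allclose(
            case, np.array([0.49, 0.42, 0.18]) / 1.09, rtol=1e-12
        )
        np.testing.assert_allclose(ctrl, [0.49, 0.42, 0.09], rtol=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(
        maf=st.floats(0.01, 0.5),
        eff=st.floats(0.1, 10.0),
        rule=st.sampled_from(["recessive", "mult"]),
    )
    def test_distributions_sum_to_one(self, maf, eff, rule):
        case, ctrl = genotype_freqs_given_status(or_spec(maf, eff, hom_rule=rule))
        assert case.sum() == pytest.approx(1.0, abs=1e-12)
        assert ctrl.sum() == pytest.approx(1.0, abs=1e-12)
        assert (case >= 0).all() and (ctrl >= 0).all()

    @settings(deadline=None, max_examples=30)
    @given(maf=st.floats(0.01, 0.5), pi=st.floats(0.001, 0.999))
    def test_equal_penetrances_reduce_to_population(self, maf, pi):
        case, ctrl = genotype_freqs_given_status(pen_spec(maf, (pi, pi, pi)))
        p, q = maf, 1 - maf
        f = np.array([q * q, 2 * p * q, p * p])
        np.testing.assert_allclose(case, f, rtol=1e-10)
        np.testing.assert_allclose(ctrl, f, rtol=1e-10)

    @pytest.mark.parametrize("rule", ["recessive", "mult"])
    def test_homozygote_prob_increases_with_odds_ratio(self, rule):
        values = [
            genotype_freqs_given_status(or_spec(0.3, o, hom_rule=rule))[0][2]
            for o in (1.0, 1.5, 2.0, 5.0)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_all_zero_penetrances_raise(self):
        with pytest.raises(DegenerateModelError):
            genotype_freqs_given_status(pen_spec(0.3, (0.0, 0.0, 0.0)))

    def test_prospective_sampling_oracle(self):
        # independent route: draw a population from HWE, assign disease by
        # penetrance, condition on status
        rng = np.random.default_rng(42)
        n = 400_000
        maf, pi = 0.3, np.array([0.05, 0.1, 0.4])
        g = rng.choice(3, size=n, p=[0.49, 0.42, 0.09])
        disease = rng.random(n) < pi[g]
        emp_case = np.bincount(g[disease], minlength=3) / disease.sum()
        emp_ctrl = np.bincount(g[~disease], minlength=3) / (~disease).sum()
        case, ctrl = genotype_freqs_given_status(pen_spec(maf, tuple(pi)))
        se = np.sqrt(case * (1 - case) / disease.sum())
        assert np.all(np.abs(emp_case - case) < 4 * se + 1e-9)
        se = np.sqrt(ctrl * (1 - ctrl) / (~disease).sum())
        assert np.all(np.abs(emp_ctrl - ctrl) < 4 * se + 1e-9)


class TestSimulateDataset:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            or_spec(0.3, 1.5, n_causal=20, n_snps=10)
        with pytest.raises(ValueError):
            or_spec(0.7, 1.5)  # MAF above 0.5
        with pytest.raises(ValueError):
            SimulationSpec(10, 10, 5, 1, 0.3, seed=0)  # no odds ratio given
        with pytest.raises(ValueError):
            SimulationSpec(
                10, 10, 5, 1, 0.3, seed=0, odds_ratio=1.5, pi_Aa=0.05
            )  # both models configured

    def test_null_dataset_has_no_causal_flags(self):
        data = simulate_dataset(
            SimulationSpec(50, 50, 200, 0, 0.3, seed=3, odds_ratio=1.5)
        )
        assert not data.snp_meta["is_causal"].any()
        assert data.n_individuals == 100

    def test_shapes_and_counts(self):
        spec = or_spec(0.2, 1.5, n_cases=30, n_controls=20, n_snps=50, n_causal=5)
        data = simulate_dataset(spec)
        assert data.genotypes.shape == (50, 50)
        assert (data.phenotypes == 1).sum() == 30
        assert data.snp_meta["is_causal"].sum() == 5
        assert np.isin(data.genotypes, [0, 1, 2]).all()

    def test_deterministic_given_seed(self):
        spec = or_spec(0.2, 1.5, seed=99, n_snps=100)
        a, b = simulate_dataset(spec), simulate_dataset(spec)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.phenotypes, b.phenotypes)
        assert a.snp_meta.equals(b.snp_meta)

    def test_case_genotype_frequencies_match_closed_form(self):
        # large case sample: empirical aa frequency within Monte-Carlo error
        spec = pen_spec(0.5, (0.01, 0.01, 0.1), n_cases=100_000, n_controls=10,
                        n_snps=1, n_causal=1, seed=7)
        data = simulate_dataset(spec)
        aa = (data.genotypes[data.case_mask, 0] == 2).mean()
        expected = 0.025 / 0.0325
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(aa - expected) < 3 * se

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_goodness_of_fit_against_closed_form(self, seed):
        # 100k case draws per seed; Pearson GOF not rejected at alpha=0.001
        spec = or_spec(0.3, 1.8, n_cases=100_000, n_controls=100, n_snps=1,
                       n_causal=1, seed=seed)
        data = simulate_dataset(spec)
        counts = np.bincount(data.genotypes[data.case_mask, 0], minlength=3)
        case_p, _ = genotype_freqs_given_status(spec)
        stat, p = stats.chisquare(counts, case_p * counts.sum())
        assert p > 0.001


class TestInjectMissingness:
    def test_rate_zero_is_identity(self):
        data = simulate_dataset(or_spec(0.3, 1.5, n_snps=50))
        out = inject_missingness(data, 0.0, seed=1)
        np.testing.assert_array_equal(out.genotypes, data.genotypes)

    def test_rate_one_all_missing(self):
        data = simulate_dataset(or_spec(0.3, 1.5, n_snps=50))
        out = inject_missingness(data, 1.0, seed=1)
        assert (out.genotypes == MISSING).all()

    def test_rate_within_binomial_error(self):
        spec = or_spec(0.3, 1.5, n_cases=1000, n_controls=1000, n_snps=1000,
                       n_causal=1)
        data = simulate_dataset(spec)
        out = inject_missingness(data, 0.05, seed=5)
        frac = (out.genotypes == MISSING).mean()
        se = np.sqrt(0.05 * 0.95 / out.genotypes.size)
        assert abs(frac - 0.05) < 3 * se

    def test_input_untouched(self):
        data = simulate_dataset(or_spec(0.3, 1.5, n_snps=20))
        before = data.genotypes.copy()
        inject_missingness(data, 0.5, seed=2)
        np.testing.assert_array_equal(data.genotypes, before)


class TestPedMapIO:
    def test_round_trip_identity(self, tmp_path):
        data = simulate_dataset(or_spec(0.3, 1.5, n_cases=20, n_controls=20,
                                        n_snps=30, n_causal=3))
        data = inject_missingness(data, 0.1, seed=4)
        prefix = tmp_path / "toy"
        write_ped_map(data, prefix)
        back = read_ped_map(prefix)
        np.testing.assert_array_equal(back.genotypes, data.genotypes)
        np.testing.assert_array_equal(back.phenotypes, data.phenotypes)
        assert list(back.snp_meta["snp_id"]) == list(data.snp_meta["snp_id"])
        np.testing.assert_array_equal(
            back.snp_meta["is_causal"], data.snp_meta["is_causal"]
        )
        assert back.individual_ids == data.individual_ids

    def test_minor_allele_letter_coding(self, tmp_path):
        from tests.conftest import make_dataset

        # counts 0,1,2 across three individuals -> 0, 1, 2 minor letters
        data = make_dataset([[0], [1], [2]], [1, 1, 0])
        write_ped_map(data, tmp_path / "t")
        rows = (tmp_path / "t.ped").read_text().strip().split("\n")
        genos = [" ".join(r.split()[6:8]) for r in rows]
        assert genos == ["A A", "A C", "C C"]

    def test_missing_written_as_zero_zero(self, tmp_path):
        from tests.conftest import make_dataset

        data = make_dataset([[MISSING, 1], [0, 2]], [1, 0])
        write_ped_map(data, tmp_path / "m")
        first = (tmp_path / "m.ped").read_text().split("\n")[0].split()
        assert first[6:8] == ["0", "0"]

    def test_parse_error_names_line(self, tmp_path):
        (tmp_path / "bad.map").write_text("1 snp1 0 1\n")
        (tmp_path / "bad.ped").write_text("f1 i1 0 0 0 2 A C\nf2 i2 0 0 0 9 A A\n")
        with pytest.raises(PedParseError, match="line 2"):
            read_ped_map(tmp_path / "bad")

    def test_odd_field_count_rejected(self, tmp_path):
        (tmp_path / "odd.map").write_text("1 snp1 0 1\n")
        (tmp_path / "odd.ped").write_text("f1 i1 0 0 0 2 A\n")
        with pytest.raises(PedParseError, match="line 1"):
            read_ped_map(tmp_path / "odd")
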