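import math

import numpy as np
import pytest
from scipy import stats

from liabilitymr.estimators import InsufficientInstrumentsError, ivw
from liabilitymr.harmonize import HarmonizedSet
from liabilitymr.sensitivity import (
    fixed_effect_meta,
    leave_one_snp_out,
    leave_one_study_out,
    pool_studies,
    rerun_without_hla,
    steiger_filter,
    steiger_filtered_estimate,
)
from liabilitymr.instruments import InstrumentSet
from liabilitymr.summary_data import SummaryDataset

from conftest import make_pair, make_set, make_variant


def pair_with_z(rsid, z_exp, n_exp, z_out, n_out, se_exp=0.01, se_out=0.01):
    return make_pair(
        rsid=rsid,
        beta_exp=z_exp * se_exp,
        se_exp=se_exp,
        beta_out=z_out * se_out,
        se_out=se_out,
        n_exp=n_exp,
        n_out=n_out,
    )


class TestSteiger:
    def test_exposure_variance_dominates_snp_retained(self):
        hs = HarmonizedSet("c", "o", [pair_with_z("rs1", 10, 50_000, 1, 100_000)])
        filtered, records = steiger_filter(hs)
        assert filtered.n_snp == 1
        assert records[0].direction_ok
        assert not records[0].removed

    def test_tie_retains(self):
        hs = HarmonizedSet("c", "o", [pair_with_z("rs1", 5, 10_000, 5, 10_000)])
        filtered, records = steiger_filter(hs)
        assert filtered.n_snp == 1
        assert records[0].direction_ok

    def test_reverse_direction_removed_with_oracle_pvalue(self):
        z_exp, z_out, n = 1.0, 20.0, 10_000
        hs = HarmonizedSet("c", "o", [pair_with_z("rs1", z_exp, n, z_out, n)])
        filtered, records = steiger_filter(hs)
        assert filtered.n_snp == 0
        rec = records[0]
        assert rec.removed and not rec.direction_ok
        # Closed-form oracle: atanh of the z-implied correlations, normal tail.
        r_exp = z_exp / math.sqrt(z_exp**2 + n)
        r_out = z_out / math.sqrt(z_out**2 + n)
        z_f = (math.atanh(r_exp) - math.atanh(r_out)) / math.sqrt(2 / (n - 3))
        assert rec.steiger_pval == pytest.approx(stats.norm.cdf(z_f), rel=1e-12)

    def test_never_removes_snp_with_more_exposure_variance(self):
        rng = np.random.default_rng(5)
        pairs = [
            pair_with_z(f"rs{i}", z, 50_000, z_out, 80_000)
            for i, (z, z_out) in enumerate(
                zip(rng.uniform(6, 30, 20), rng.uniform(0, 5, 20))
            )
        ]
        filtered, records = steiger_filter(HarmonizedSet("c", "o", pairs))
        for rec in records:
            if rec.r2_exp is not None and rec.r2_exp >= rec.r2_out:
                assert not rec.removed
        assert filtered.n_snp == 20

    def test_tiny_sample_size_unevaluable_and_retained(self):
        hs = HarmonizedSet("c", "o", [pair_with_z("rs1", 1, 2, 20, 2)])
        filtered, records = steiger_filter(hs)
        assert filtered.n_snp == 1
        assert not records[0].evaluable

    def test_filtered_estimate_downgrades_to_wald_with_one_snp(self):
        pairs = [
            pair_with_z("rs1", 10, 50_000, 1, 100_000),
            pair_with_z("rs2", 1, 10_000, 25, 500_000),
        ]
        res, records = steiger_filtered_estimate(HarmonizedSet("c", "o", pairs))
        assert res is not None
        assert res.method == "wald"
        assert sum(r.removed for r in records) == 1


class TestLeaveOneSnpOut:
    def test_homogeneous_ratios_no_influential_snp(self):
        bx = [0.2, 0.3, 0.4, 0.5]
        hs = make_set(bx=bx, by=[0.1 * b for b in bx], sy=[0.01] * 4)
        loo = leave_one_snp_out(hs)
        assert len(loo) == 4
        for r in loo:
            assert r.result.beta == pytest.approx(0.1)
            assert r.delta_vs_full == pytest.approx(0.0, abs=1e-12)
            assert not r.influential

    def test_planted_outlier_is_flagged_against_oracle(self):
        # k=4 with one outlier ratio; oracle recomputes all four 3-SNP IVWs
        # by the weighted-mean formula.
        bx = np.array([0.4, 0.4, 0.4, 0.4])
        ratios = np.array([0.1, 0.1, 0.1, 1.0])
        by = ratios * bx
        sy = np.array([0.01, 0.01, 0.01, 0.01])
        hs = make_set(bx=list(bx), by=list(by), sy=list(sy))
        loo = leave_one_snp_out(hs)
        w = bx**2 / sy**2
        for i, r in enumerate(loo):
            mask = np.arange(4) != i
            oracle = np.sum(w[mask] * ratios[mask]) / np.sum(w[mask])
            assert r.result.beta == pytest.approx(oracle, rel=1e-10)
        flagged = [r.omitted_id for r in loo if r.influential]
        assert flagged == ["rs4"]

    def test_three_snps_give_three_two_snp_results(self):
        hs = make_set(bx=[0.2, 0.3, 0.4], by=[0.02, 0.03, 0.05], sy=[0.01] * 3)
        loo = leave_one_snp_out(hs)
        assert len(loo) == 3
        assert all(r.result.n_snp == 2 for r in loo)

    def test_too_few_instruments(self):
        hs = make_set(bx=[0.2, 0.3], by=[0.02, 0.03], sy=[0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            leave_one_snp_out(hs)

    def test_betas_bracket_full_estimate_on_monotone_instance(self):
        bx = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
        ratios = np.array([0.05, 0.08, 0.1, 0.12, 0.15])
        hs = make_set(bx=list(bx), by=list(ratios * bx), sy=[0.01] * 5)
        full = ivw(hs).beta
        betas = [r.result.beta for r in leave_one_snp_out(hs)]
        assert min(betas) <= full <= max(betas)


def study_datasets(instruments, beta_by_study, se_by_study):
    """Per-study outcome datasets aligned to the given instrument alleles."""
    out = {}
    for label in beta_by_study:
        variants = [
            make_variant(
                rsid=v.rsid,
                effect_allele=v.effect_allele,
                other_allele=v.other_allele,
                beta=beta_by_study[label][i],
                se=se_by_study[label][i],
                pval=0.5,
            )
            for i, v in enumerate(instruments)
        ]
        out[label] = SummaryDataset.from_variants("outcome", variants)
    return out


class TestLeaveOneStudyOut:
    def instruments(self, k=3):
        return InstrumentSet(
            "cond",
            [make_variant(rsid=f"rs{i}", beta=0.2 + 0.1 * i, se=0.01,
                          chrom="1", pos=10 ** 6 * (i + 1))
             for i in range(k)],
        )

    def test_fixed_effect_meta_oracle(self):
        beta, se = fixed_effect_meta([0.1, 0.3], [0.01, 0.02])
        w = np.array([1 / 0.01**2, 1 / 0.02**2])
        assert beta == pytest.approx(float(np.sum(w * [0.1, 0.3]) / w.sum()))
        assert se == pytest.approx(float(w.sum() ** -0.5))

    def test_duplicated_studies_halve_variance_and_reproduce_single_study(self):
        inst = self.instruments()
        betas = [0.02, 0.03, 0.04]
        ses = [0.01, 0.01, 0.01]
        studies = study_datasets(
            inst, {"a": betas, "b": betas}, {"a": ses, "b": ses}
        )
        pooled = pool_studies(studies, inst)
        for p, b, s in zip(pooled.pairs, betas, ses):
            assert p.beta_out == pytest.approx(b)
            assert p.se_out == pytest.approx(s / math.sqrt(2))
        loo = leave_one_study_out(studies, inst)
        single = ivw(pool_studies({"a": studies["a"]}, inst))
        for r in loo:
            assert r.result.beta == pytest.approx(single.beta)
            assert r.result.se == pytest.approx(single.se)

    def test_omitting_inverted_study_moves_estimate_toward_clean_value(self):
        inst = self.instruments()
        clean = [0.02, 0.03, 0.04]
        studies = study_datasets(
            inst,
            {"a": clean, "b": clean, "inv": [-b for b in clean]},
            {"a": [0.01] * 3, "b": [0.01] * 3, "inv": [0.01] * 3},
        )
        loo = {r.omitted_id: r for r in leave_one_study_out(studies, inst)}
        clean_beta = ivw(pool_studies({"a": studies["a"], "b": studies["b"]}, inst)).beta
        full_beta = ivw(pool_studies(studies, inst)).beta
        assert loo["inv"].result.beta == pytest.approx(clean_beta)
        assert abs(loo["inv"].result.beta - clean_beta) < abs(full_beta - clean_beta)
        # Oracle for the omit-"a" replicate: per-SNP fixed-effect meta of b+inv,
        # then the IVW weighted mean.
        bx = np.array([v.beta for v in inst])
        meta = [fixed_effect_meta([c, -c], [0.01, 0.01]) for c in clean]
        by = np.array([m[0] for m in meta])
        sy = np.array([m[1] for m in meta])
        w = bx**2 / sy**2
        assert loo["a"].result.beta == pytest.approx(
            float(np.sum(w * by / bx) / w.sum())
        )

    def test_snp_covered_only_by_omitted_study_is_dropped(self):
        inst = self.instruments(k=3)
        full = study_datasets(
            inst, {"a": [0.02, 0.03, 0.04]}, {"a": [0.01] * 3}
        )["a"]
        partial = SummaryDataset.from_variants(
            "outcome",
            [
                make_variant(rsid=v.rsid, effect_allele=v.effect_allele,
                             other_allele=v.other_allele, beta=b, se=0.01, pval=0.5)
                for v, b in zip(list(inst)[:2], [0.02, 0.03])
            ],
        )  # only rs0, rs1
        pooled = pool_studies({"a": full, "b": partial}, inst, omit="a")
        assert [p.rsid for p in pooled.pairs] == ["rs0", "rs1"]

    def test_single_study_is_an_error(self):
        inst = self.instruments()
        studies = study_datasets(inst, {"a": [0.02, 0.03, 0.04]}, {"a": [0.01] * 3})
        with pytest.raises(ValueError):
            leave_one_study_out(studies, inst)

    def test_omit_none_control_equals_pooled_ivw(self):
        inst = self.instruments()
        studies = study_datasets(
            inst,
            {"a": [0.02, 0.03, 0.04], "b": [0.01, 0.05, 0.03]},
            {"a": [0.01] * 3, "b": [0.02] * 3},
        )
        pooled = pool_studies(studies, inst, omit=None)
        assert ivw(pooled).beta == pytest.approx(ivw(pool_studies(studies, inst)).beta)


class TestHLAExcludedRerun:
    def hla_set(self, hla_flags):
        bx = [0.2, 0.3, 0.4, 0.5]
        chroms = ["6" if f else "2" for f in hla_flags]
        poss = [30_000_000 if f else 1_000_000 for f in hla_flags]
        return make_set(bx=bx, by=[0.1 * b for b in bx], sy=[0.01] * 4,
                        chrom=chroms, pos=poss)

    def test_no_hla_snps_is_a_no_op(self):
        hs = self.hla_set([False] * 4)
        assert rerun_without_hla(hs).beta == pytest.approx(ivw(hs).beta)
        assert rerun_without_hla(hs).n_snp == 4

    def test_all_hla_snps_gives_absent_result(self):
        assert rerun_without_hla(self.hla_set([True] * 4)) is None

    def test_partial_exclusion_reduces_n_snp(self):
        res = rerun_without_hla(self.hla_set([True, False, False, True]))
        assert res.n_snp == 2

    def test_single_survivor_downgrades_to_wald(self):
        res = rerun_without_hla(self.hla_set([True, True, True, False]))
        assert res.method == "wald"
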