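from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from liverewas.genetics import (
    cis_meqtl_scan,
    conditional_association,
    dosage_summary,
    hwe_exact_test,
    select_top_variant,
    variant_qc,
)


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional HWE distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    denom = comb(2 * n, rare)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        probs[het] = Fraction(
            2**het * comb(n, hom_rare) * comb(n - hom_rare, het), denom
        )
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    def test_modal_table_p_is_one(self):
        # 25/50/25 is the most probable configuration for its allele counts
        assert hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), abs=1e-12
        )
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_small_table_matches_enumeration(self):
        assert hwe_exact_test(5, 1, 5) == pytest.approx(
            hwe_enumeration_oracle(5, 1, 5), abs=1e-12
        )

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 200))
            n_ab = int(rng.integers(0, n + 1))
            n_aa = int(rng.integers(0, n - n_ab + 1))
            n_bb = n - n_ab - n_aa
            got = hwe_exact_test(n_aa, n_ab, n_bb)
            want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
            assert got == pytest.approx(want, abs=1e-12), (n_aa, n_ab, n_bb)


class TestVariantQc:
    def test_low_maf_fails_on_maf_only(self):
        # 1000 samples, 38 alt alleles all as hets -> MAF 0.019
        d = np.zeros(1000)
        d[:38] = 1
        rep = variant_qc(pd.DataFrame([d], index=["v"]))
        assert not rep.loc["v", "pass_maf"]
        assert rep.loc["v", "pass_hwe"]
        assert rep.loc["v", "pass_missing"]
        assert not rep.loc["v", "pass_qc"]

    def test_missingness_boundary_is_strict(self):
        d = np.ones(100)
        d[50:] = 0.0
        d[:5] = np.nan  # exactly 5% missing: "less than 5%" fails
        rep = variant_qc(pd.DataFrame([d], index=["v"]))
        assert not rep.loc["v", "pass_missing"]

    def test_clean_variants_all_pass(self, rng):
        d = rng.binomial(2, 0.3, (5, 500)).astype(float)
        rep = variant_qc(pd.DataFrame(d))
        assert rep["pass_qc"].all()

    def test_maf_threshold_monotone(self, rng):
        d = rng.binomial(2, rng.uniform(0.01, 0.5, 40)[:, None], (40, 400)).astype(float)
        G = pd.DataFrame(d)
        loose = set(variant_qc(G, maf_min=0.02).query("pass_qc").index)
        tight = set(variant_qc(G, maf_min=0.10).query("pass_qc").index)
        assert tight <= loose

    def test_maf_from_nonmissing_dosages(self):
        d = np.array([0, 0, 1, 1, 2, np.nan, np.nan, np.nan])
        s = dosage_summary(d)
        assert s["maf"] == pytest.approx(4 / 10)
        assert s["missingness"] == pytest.approx(3 / 8)


def _scan_setup(rng, n=800, n_var=6, effect=0.0):
    pos = pd.DataFrame(
        {"chrom": "1", "pos": [1_500_000 + i * 100_000 for i in range(n_var)]},
        index=[f"rs{i}" for i in range(n_var)],
    )
    G = pd.DataFrame(
        rng.binomial(2, 0.3, (n_var, n)).astype(float),
        index=pos.index,
        columns=[f"s{i}" for i in range(n)],
    )
    m = pd.Series(
        0.5 + effect * G.iloc[0].to_numpy() + rng.normal(0, 0.08, n),
        index=G.columns,
    )
    return m, G, pos


class TestCisScan:
    def test_planted_meqtl_genome_wide_significant(self, rng):
        m, G, pos = _scan_setup(rng, n=1500, effect=0.05)
        recs = cis_meqtl_scan("cgX", ("1", 1_600_000), m, G, pos)
        row = recs[recs["variant"] == "rs0"].iloc[0]
        assert row["p"] < 5e-8
        assert row["significant"]

    def test_window_boundary_closed(self, rng):
        m, G, pos = _scan_setup(rng)
        pos.loc["rs5", "pos"] = 2_600_000  # distance exactly = window
        recs = cis_meqtl_scan("cgX", ("1", 1_600_000), m, G, pos, window=1_000_000)
        assert "rs5" in set(recs["variant"])
        pos.loc["rs5", "pos"] = 2_600_001
        recs = cis_meqtl_scan("cgX", ("1", 1_600_000), m, G, pos, window=1_000_000)
        assert "rs5" not in set(recs["variant"])

    def test_result_invariant_to_variant_order(self, rng):
        m, G, pos = _scan_setup(rng)
        a = cis_meqtl_scan("cgX", ("1", 1_600_000), m, G, pos)
        perm = list(reversed(G.index))
        b = cis_meqtl_scan("cgX", ("1", 1_600_000), m, G.loc[perm], pos.loc[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_null_variants_no_excess_significance(self, rng):
        n, n_var = 300, 1000
        pos = pd.DataFrame(
            {"chrom": "1", "pos": rng.integers(1_000_000, 2_000_000, n_var)},
            index=[f"rs{i}" for i in range(n_var)],
        )
        G = pd.DataFrame(
            rng.binomial(2, 0.3, (n_var, n)).astype(float),
            index=pos.index,
            columns=[f"s{i}" for i in range(n)],
        )
        m = pd.Series(rng.beta(5, 5, n), index=G.columns)
        recs = cis_meqtl_scan("cgX", ("1", 1_500_000), m, G, pos)
        assert recs["significant"].sum() == 0
        assert recs["p"].min() > 1e-6

    def test_empty_window_returns_empty(self, rng):
        m, G, pos = _scan_setup(rng)
        recs = cis_meqtl_scan("cgX", ("2", 1_600_000), m, G, pos)
        assert len(recs) == 0


class TestSelectTop:
    def _records(self, ps, dists):
        return pd.DataFrame(
            {
                "variant": [f"rs{i}" for i in range(len(ps))],
                "p": ps,
                "distance": dists,
                "significant": [True] * len(ps),
            }
        )

    def test_lowest_p_selected(self):
        top = select_top_variant(self._records([1e-9, 1e-12, 2e-8], [10, 20, 30]))
        assert top["variant"] == "rs1"
        assert top["is_top"]

    def test_tie_broken_by_distance(self):
        top = select_top_variant(self._records([1e-10, 1e-10], [50_000, 500]))
        assert top["variant"] == "rs1"

    def test_single_record_returned(self):
        top = select_top_variant(self._records([1e-9], [100]))
        assert top["variant"] == "rs0"

    def test_no_significant_records_gives_none(self):
        recs = self._records([1e-9], [100])
        recs["significant"] = False
        assert select_top_variant(recs) is None


class TestConditionalAssociation:
    def _base(self, rng, n=3000):
        d = pd.Series(
            rng.binomial(2, 0.3, n).astype(float), index=[f"s{i}" for i in range(n)]
        )
        u = rng.normal(0, 0.06, n)  # non-genetic methylation component
        m = pd.Series(0.5 + 0.05 * d.to_numpy() + u, index=d.index)
        cov = pd.DataFrame({"age": rng.normal(50, 8, n)}, index=d.index)
        return d, m, u, cov

    def test_methylation_path_keeps_cpg_significant_snp_null(self, rng):
        """Phenotype acts through methylation itself (including its
        genetic component): the CpG stays significant with and without
        the SNP, while the SNP has no independent association once
        methylation is in the model."""
        d, m, u, cov = self._base(rng)
        y = pd.Series(2.0 * m.to_numpy() + rng.normal(0, 0.2, len(d)), index=d.index)
        res = conditional_association(y, m, d, cov)
        assert res.cpg_p_marginal < 1e-8
        assert res.cpg_p_conditional < 1e-8
        assert res.snp_p > 0.05

    def test_snp_confounding_attenuates_cpg_effect(self, rng):
        d, m, u, cov = self._base(rng)
        y = pd.Series(1.0 * d.to_numpy() + rng.normal(0, 0.5, len(d)), index=d.index)
        res = conditional_association(y, m, d, cov)
        assert abs(res.cpg_effect_conditional) < 0.5 * abs(res.cpg_effect_marginal)

    def test_irrelevant_snp_leaves_effect_unchanged(self, rng):
        d, m, u, cov = self._base(rng)
        m = pd.Series(0.5 + u, index=d.index)  # methylation not genetic
        y = pd.Series(2.0 * u + rng.normal(0, 0.2, len(d)), index=d.index)
        res = conditional_association(y, m, d, cov)
        assert res.cpg_effect_conditional == pytest.approx(
            res.cpg_effect_marginal, rel=0.02
        )

    def test_models_share_identical_sample(self, rng):
        d, m, u, cov = self._base(rng, n=500)
        d.iloc[:20] = np.nan
        y = pd.Series(rng.normal(0, 1, 500), index=d.index)
        res = conditional_association(y, m, d, cov)
        assert res.n == 480
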