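import numpy as np
import pytest
from scipy import stats

from pathgwas import association as assoc
from pathgwas.containers import Cohort
from pathgwas.errors import ValidationError
from pathgwas.simulate import SimulationConfig, simulate_cohort


def _cohort_from_genotypes(g, phenotype, seed=0):
    rng = np.random.default_rng(seed)
    n = len(phenotype)
    return Cohort(
        sample_ids=[f"s{i}" for i in range(n)],
        phenotype=phenotype,
        age=rng.integers(40, 70, size=n),
        gender=rng.integers(0, 2, size=n),
        smoking=rng.integers(0, 2, size=n),
        genotypes=np.asarray(g, dtype=float),
        snp_ids=[f"rs{j}" for j in range(np.asarray(g).shape[1])],
        snp_chrom=["chr1"] * np.asarray(g).shape[1],
        snp_pos=np.arange(1, np.asarray(g).shape[1] + 1) * 1000,
    )


def test_recessive_model_unavailable():
    with pytest.raises(ValidationError):
        assoc.code_genotypes(np.array([0.0, 1.0, 2.0]), "recessive")


def test_constant_genotype_flagged_p_one():
    c = _cohort_from_genotypes(np.ones((30, 1)), [1] * 15 + [0] * 15)
    fit = assoc.fit_snp_logistic(c, 0, "additive")
    assert fit.flag == "monomorphic"
    assert fit.p == 1.0
    table = assoc.association_table(c, models=("additive",))
    assert table["flag"].iloc[0] == "monomorphic"
    assert table["p"].iloc[0] == 1.0


def test_unadjusted_dominant_fit_equals_2x2_cross_product_or():
    """Carrier/non-carrier logistic OR equals the 2×2 table ad/bc."""
    # cases: 30 carriers / 20 non; controls: 15 carriers / 35 non
    g = np.array([1.0] * 30 + [0.0] * 20 + [1.0] * 15 + [0.0] * 35)[:, None]
    y = [1] * 50 + [0] * 50
    c = _cohort_from_genotypes(g, y)
    fit = assoc.fit_snp_logistic(c, 0, "dominant", adjust=())
    or_2x2 = (30 * 35) / (20 * 15)
    assert np.exp(fit.coef) == pytest.approx(or_2x2, rel=1e-6)


def test_batched_wald_matches_statsmodels(null_sim):
    cohort = null_sim.cohort
    table = assoc.association_table(cohort, models=("additive", "dominant"))
    rng = np.random.default_rng(1)
    for model in ("additive", "dominant"):
        sub = table[table.model == model].reset_index(drop=True)
        for j in rng.choice(cohort.n_snps, size=8, replace=False):
            ref = assoc.fit_snp_logistic(cohort, int(j), model)
            row = sub.iloc[int(j)]
            if ref.flag or row.flag:
                assert ref.flag == row.flag
                continue
            assert row.coef == pytest.approx(ref.coef, abs=1e-5)
            assert row.tstat == pytest.approx(ref.tstat, abs=1e-4)


def test_additive_equals_dominant_without_hom_minor():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 2, size=(120, 5)).astype(float)  # only 0/1 genotypes
    y = rng.integers(0, 2, size=120)
    c = _cohort_from_genotypes(g, y)
    add = assoc.association_table(c, models=("additive",))
    dom = assoc.association_table(c, models=("dominant",))
    np.testing.assert_allclose(
        add["tstat"].to_numpy(), dom["tstat"].to_numpy(), rtol=1e-8
    )


def test_risk_allele_gives_positive_statistic():
    """Sign convention: minor allele enriched in cases => positive t."""
    g = np.array([2.0] * 25 + [1.0] * 15 + [0.0] * 10 + [0.0] * 40 + [1.0] * 10)[:, None]
    y = [1] * 50 + [0] * 50
    fit = assoc.fit_snp_logistic(_cohort_from_genotypes(g, y), 0, "additive", adjust=())
    assert fit.tstat > 0


def test_score_path_agrees_with_wald_on_clean_data():
    rng = np.random.default_rng(11)
    n, m = 500, 40
    g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    y = rng.integers(0, 2, size=n)
    c = _cohort_from_genotypes(g, y)
    C = c.covariate_matrix()
    z, p, flags = assoc.batch_logistic_score(assoc.mean_impute(g), C, c.phenotype)
    table = assoc.association_table(c, models=("additive",))
    t = table["tstat"].to_numpy()
    assert np.corrcoef(z, t)[0, 1] > 0.999
    assert np.max(np.abs(z - t)) < 0.05


def test_demographic_or_reproduces_published_univariate_values():
    g = assoc.demographic_or(466, 892, 403, 641)
    assert round(g["or"], 2) == 0.83
    assert round(g["ci_low"], 2) == 0.70
    assert round(g["ci_high"], 2) == 0.98
    s = assoc.demographic_or(429, 803, 440, 730)
    assert round(s["or"], 2) == 0.89
    assert round(s["ci_low"], 2) == 0.75
    assert round(s["ci_high"], 2) == 1.05


def test_demographic_or_symmetric_table():
    r = assoc.demographic_or(10, 10, 10, 10)
    assert r["or"] == pytest.approx(1.0)
    assert r["ci_low"] * r["ci_high"] == pytest.approx(1.0)


def test_demographic_or_zero_cell():
    with pytest.raises(ValidationError, match="continuity"):
        assoc.demographic_or(10, 0, 5, 5)
    r = assoc.demographic_or(10, 0, 5, 5, continuity=True)
    assert np.isfinite(r["or"])


def test_null_genotype_pvalues_uniform():
    """Covariate-adjusted p-values of null SNPs follow U(0,1) (KS, coarse)."""
    rng = np.random.default_rng(5)
    n, m = 600, 250
    g = rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m)).astype(float)
    y = rng.integers(0, 2, size=n)
    c = _cohort_from_genotypes(g, y)
    table = assoc.association_table(c, models=("additive",))
    p = table.loc[table.flag == "", "p"].to_numpy()
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_multivariate_and_genotype_recovery_at_large_n():
    """Planted covariate and per-allele effects recovered within 3 SE."""
    cfg = SimulationConfig(
        n_cases=10_000, n_controls=10_000, n_genes=10, n_snps_per_gene=1,
        n_pathways=2, genes_per_pathway=5, causal_pathways=(0,),
        causal_fraction=0.6, per_allele_or=1.5, missing_rate=0.0, seed=17,
    )
    sim = simulate_cohort(cfg)
    demo = assoc.multivariate_demographics(sim.cohort).set_index("covariate")
    planted = {"gender": 0.48, "smoking": 0.52, "age": 0.98}
    import statsmodels.api as sm

    X = sim.cohort.covariate_matrix()
    res = sm.Logit(sim.cohort.phenotype.astype(float), X).fit(disp=0)
    for i, name in enumerate(("age", "gender", "smoking"), start=1):
        z = (res.params[i] - np.log(planted[name])) / res.bse[i]
        assert abs(z) < 3, f"{name}: z={z:.2f}"
        assert demo.loc[name, "or"] == pytest.approx(np.exp(res.params[i]))

    snp = sim.truth["causal_snps"][0]
    fit = assoc.fit_snp_logistic(sim.cohort, snp, "additive")
    z = (fit.coef - np.log(1.5)) / fit.se
    assert abs(z) < 3


def test_null_covariate_ci_coverage():
    """A zero-effect covariate's 95% CI covers 1 in >=93/100 replicates."""
    rng = np.random.default_rng(23)
    import statsmodels.api as sm

    covered = 0
    n = 300
    for _ in range(100):
        x = rng.integers(0, 2, size=n).astype(float)  # no effect on y
        age = rng.integers(40, 70, size=n).astype(float)
        y = rng.integers(0, 2, size=n).astype(float)
        X = np.column_stack([np.ones(n), age, x])
        res = sm.Logit(y, X).fit(disp=0)
        lo = np.exp(res.params[2] - 1.96 * res.bse[2])
        hi = np.exp(res.params[2] + 1.96 * res.bse[2])
        covered += lo <= 1.0 <= hi
    assert covered >= 93
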