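import numpy as np
import pytest
from oracles import es_step_oracle, fdr_oracle

from pathgwas import gsea, mapping
from pathgwas.errors import ValidationError
from pathgwas.perm import permutation_engine, permutation_labels


def test_es_single_member_at_rank_one():
    stats = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    member = np.array([True, False, False, False, False])
    assert gsea.enrichment_score(stats, member) == pytest.approx(1.0)


def test_es_hand_computed_running_sum():
    # members at ranks {1, 3}: N_R = 8, running sum peaks at 2/3
    stats = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    member = np.array([True, False, True, False, False])
    assert gsea.enrichment_score(stats, member) == pytest.approx(2.0 / 3.0)


def test_es_single_member_at_last_rank_is_zero():
    stats = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    member = np.array([False, False, False, False, True])
    assert gsea.enrichment_score(stats, member) == pytest.approx(0.0)


def test_es_member_set_errors():
    stats = np.array([2.0, 1.0])
    with pytest.raises(ValidationError):
        gsea.enrichment_score(stats, np.array([True, True]))
    with pytest.raises(ValidationError):
        gsea.enrichment_score(stats, np.array([False, False]))


def test_es_matches_step_through_oracle_on_random_instances():
    rng = np.random.default_rng(31)
    for _ in range(150):
        n = int(rng.integers(5, 60))
        stats = np.round(np.abs(rng.normal(size=n)) * 3, 3)
        nh = int(rng.integers(1, n))
        member_idx = rng.choice(n, size=nh, replace=False)
        member = np.zeros(n, dtype=bool)
        member[member_idx] = True
        got = gsea.enrichment_score(stats, member)
        want = es_step_oracle(stats, member_idx)
        assert got == pytest.approx(want, abs=1e-10)


def test_es_scale_invariance_at_unit_weight():
    rng = np.random.default_rng(4)
    stats = np.abs(rng.normal(size=30))
    member = np.zeros(30, dtype=bool)
    member[[2, 5, 11, 17]] = True
    a = gsea.enrichment_score(stats, member, weight=1.0)
    b = gsea.enrichment_score(stats * 7.3, member, weight=1.0)
    assert a == pytest.approx(b)


def test_normalize_and_p():
    perm = np.array([0.1, 0.2, 0.3, 0.4])
    nes, p = gsea.normalize_and_p(0.25, perm)
    assert nes == pytest.approx(0.0)
    # observed beats all B = 999 permutations -> p = 1/1000
    perm999 = np.linspace(0, 0.5, 999)
    _, p = gsea.normalize_and_p(0.9, perm999)
    assert p == pytest.approx(1.0 / 1000.0)


def test_nes_of_null_observation_near_zero():
    rng = np.random.default_rng(8)
    perm = rng.normal(size=2000)
    nes, _ = gsea.normalize_and_p(0.0, perm)
    assert abs(nes) < 3 / np.sqrt(2000)


def test_fdr_trivial_and_oracle():
    # observed NES above every permuted value -> FDR 0
    out = gsea.gsea_fdr(np.array([2.5]), np.array([[0.1, 0.3, -0.2]]))
    assert out[0] == 0.0
    # all observed equal -> all FDRs equal
    obs = np.array([1.1, 1.1, 1.1])
    perm = np.array([[0.5, 1.5], [0.2, 0.9], [1.2, -0.3]])
    out = gsea.gsea_fdr(obs, perm)
    assert len(set(np.round(out, 12))) == 1
    # random instances vs double-loop oracle
    rng = np.random.default_rng(12)
    for _ in range(100):
        P, B = int(rng.integers(2, 10)), int(rng.integers(3, 20))
        obs = rng.normal(size=P)
        perm = rng.normal(size=(P, B))
        np.testing.assert_allclose(
            gsea.gsea_fdr(obs, perm), fdr_oracle(obs.tolist(), perm.tolist())
        )


def test_screen_candidates_or_semantics_and_boundaries():
    import pandas as pd

    def res(rows):
        t = pd.DataFrame(rows, columns=["pathway", "source", "n_genes",
                                        "es", "nes", "p", "fdr"])
        return gsea.EnrichmentResult(model="m", table=t, es=None, nes=None)

    results = {
        "additive": res([("A", "s", 20, 0, 0, 0.01, 0.2),   # candidate
                         ("B", "s", 20, 0, 0, 0.01, 0.3),   # fdr fails
                         ("C", "s", 20, 0, 0, 0.025, 0.25)]),  # boundary in
        "dominant": res([("A", "s", 20, 0, 0, 0.5, 0.9),
                         ("B", "s", 20, 0, 0, 0.03, 0.2),   # p fails
                         ("C", "s", 20, 0, 0, 0.5, 0.9)]),
    }
    assert gsea.screen_candidates(results) == ["A", "C"]


def test_permutation_labels_preserve_case_count_and_determinism():
    y = np.array([1] * 30 + [0] * 70, dtype=np.int8)
    lab1 = permutation_labels(y, 50, np.random.default_rng(3))
    lab2 = permutation_labels(y, 50, np.random.default_rng(3))
    np.testing.assert_array_equal(lab1, lab2)
    np.testing.assert_array_equal(lab1[0], y)
    assert (lab1.sum(axis=1) == 30).all()
    with pytest.raises(ValidationError):
        permutation_labels(y, 0, np.random.default_rng(0))


def test_stratified_permutation_preserves_cases_within_strata(null_sim):
    from pathgwas import qc

    cohort, _ = qc.apply_qc(null_sim.cohort)
    strata = cohort.gender.astype(int) * 2 + cohort.smoking
    lab = permutation_labels(cohort.phenotype, 20, np.random.default_rng(0),
                             strata=strata)
    for s in np.unique(strata):
        idx = strata == s
        assert (lab[:, idx].sum(axis=1) == cohort.phenotype[idx].sum()).all()


@pytest.mark.parametrize("stat_method", ["score", "wald"])
def test_identity_permutation_column_is_bitwise_observed(null_sim, stat_method):
    """Column 0 must equal a from-scratch observed-label computation exactly."""
    from pathgwas import qc

    cohort, _ = qc.apply_qc(null_sim.cohort)
    cohort = cohort.subset_snps(np.arange(min(60, cohort.n_snps)))
    idx = mapping.build_gene_snp_index(
        null_sim.genes, cohort.snp_ids, cohort.snp_chrom, cohort.snp_pos
    )
    perm = permutation_engine(cohort, idx, models=("additive",), B=5, seed=1,
                              stat_method=stat_method)
    gsm = perm.gene_stats["additive"]

    from pathgwas.association import (batch_logistic_score, batch_logistic_wald,
                                      code_genotypes, mean_impute)
    from pathgwas.mapping import best_snp_reduce

    G = code_genotypes(cohort.genotypes, "additive")
    C = cohort.covariate_matrix()
    if stat_method == "score":
        z, p, fl = batch_logistic_score(mean_impute(G), C, cohort.phenotype)
    else:
        _, _, z, p, fl = batch_logistic_wald(G, C, cohort.phenotype)
    gstat, gp, chosen = best_snp_reduce(idx, z[:, None], p[:, None], fl)
    np.testing.assert_array_equal(gsm.stat[:, 0], gstat[:, 0])
    np.testing.assert_array_equal(gsm.pval[:, 0], gp[:, 0])
    np.testing.assert_array_equal(gsm.chosen[:, 0], chosen[:, 0])


def test_engine_deterministic_under_fixed_seed(null_sim):
    from pathgwas import qc

    cohort, _ = qc.apply_qc(null_sim.cohort)
    idx = mapping.build_gene_snp_index(
        null_sim.genes, cohort.snp_ids, cohort.snp_chrom, cohort.snp_pos
    )
    a = permutation_engine(cohort, idx, models=("additive",), B=10, seed=99)
    b = permutation_engine(cohort, idx, models=("additive",), B=10, seed=99)
    np.testing.assert_array_equal(a.perm_labels, b.perm_labels)
    np.testing.assert_array_equal(a.gene_stats["additive"].stat,
                                  b.gene_stats["additive"].stat)


def test_run_gsea_table_shape_and_p_bounds(null_sim):
    from pathgwas import qc

    cohort, _ = qc.apply_qc(null_sim.cohort)
    idx = mapping.build_gene_snp_index(
        null_sim.genes, cohort.snp_ids, cohort.snp_chrom, cohort.snp_pos
    )
    filtered = mapping.filter_gene_sets(null_sim.pathways, idx.genes, 5, 200)
    perm = permutation_engine(cohort, idx, models=("additive",), B=20, seed=0)
    res = gsea.run_gsea(perm.gene_stats["additive"], filtered)
    B = 20
    assert res.table["p"].between(1 / (B + 1), 1.0).all()
    assert res.table["fdr"].between(0.0, 1.0).all()
    assert (res.table["n_genes"] == [len(m) for m in filtered.members]).all()
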