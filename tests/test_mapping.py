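import numpy as np
import pandas as pd
import pytest
from oracles import best_snp_oracle

from pathgwas import mapping
from pathgwas.containers import GeneCatalog, PathwayCatalog
from pathgwas.errors import ValidationError


def _genes(rows):
    return GeneCatalog(pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "strand"]))


def test_window_boundaries_inclusive():
    genes = _genes([("G1", "chr1", 100_000, 110_000, "+")])
    snp_pos = [80_000, 79_999, 130_000, 130_001]
    idx = mapping.build_gene_snp_index(
        genes, [f"rs{i}" for i in range(4)], ["chr1"] * 4, snp_pos, flank=20_000
    )
    mapped = set(idx.snp_lists[0])
    assert 0 in mapped      # exactly start - 20000
    assert 1 not in mapped  # one bp beyond
    assert 2 in mapped      # exactly end + 20000
    assert 3 not in mapped


def test_snp_between_close_genes_counted_twice():
    genes = _genes([
        ("G1", "chr1", 50_000, 60_000, "+"),
        ("G2", "chr1", 90_000, 100_000, "-"),
    ])
    # SNP at 75000: within 20 kb of G1's end and of G2's start
    idx = mapping.build_gene_snp_index(genes, ["rsX"], ["chr1"], [75_000])
    assert all(0 in lst for lst in idx.snp_lists)
    assert idx.snp_to_genes[0] == ["G1", "G2"]


def test_unmappable_genes_recorded():
    genes = _genes([
        ("G1", "chr1", 100, 200, "+"),
        ("LONELY", "chr9", 100, 200, "+"),
    ])
    idx = mapping.build_gene_snp_index(genes, ["rs1"], ["chr1"], [150])
    assert idx.genes == ["G1"]
    assert idx.unmappable == ["LONELY"]


def test_index_symmetry_on_random_instance():
    rng = np.random.default_rng(0)
    rows = []
    pos = 1
    for i in range(20):
        length = int(rng.integers(1_000, 30_000))
        rows.append((f"G{i}", "chr1", pos, pos + length, "+"))
        pos += length + int(rng.integers(1_000, 80_000))
    genes = _genes(rows)
    snp_pos = np.sort(rng.integers(1, pos, size=200))
    idx = mapping.build_gene_snp_index(
        genes, [f"rs{j}" for j in range(200)], ["chr1"] * 200, snp_pos
    )
    # SNP in gene's list <=> gene in SNP's list
    s2g = idx.snp_to_genes
    for gene, snps in zip(idx.genes, idx.snp_lists):
        for j in snps:
            assert gene in s2g[int(j)]
    for j, gene_list in s2g.items():
        for gene in gene_list:
            gi = idx.genes.index(gene)
            assert j in set(int(x) for x in idx.snp_lists[gi])


def test_best_snp_trivial_cases():
    idx = mapping.GeneSnpIndex(genes=["G1", "G2"],
                               snp_lists=[np.array([0]), np.array([1, 2])],
                               n_snps=3)
    stat = np.array([[2.0], [1.2], [0.5]])
    pval = np.array([[0.04], [0.01], [0.5]])
    gstat, gp, chosen = mapping.best_snp_reduce(idx, stat, pval)
    assert chosen[0, 0] == 0          # single SNP
    assert chosen[1, 0] == 1          # p 0.01 beats 0.5
    assert gp[1, 0] == 0.01


def test_best_snp_flagged_ineligible_and_all_flagged_missing():
    idx = mapping.GeneSnpIndex(genes=["G1"], snp_lists=[np.array([0, 1])], n_snps=2)
    stat = np.array([[5.0], [1.0]])
    pval = np.array([[1e-6], [0.3]])
    flags = np.array(["separation", ""], dtype=object)
    gstat, gp, chosen = mapping.best_snp_reduce(idx, stat, pval, flags)
    assert chosen[0, 0] == 1
    flags_all = np.array(["separation", "monomorphic"], dtype=object)
    _, _, chosen = mapping.best_snp_reduce(idx, stat, pval, flags_all)
    assert chosen[0, 0] == -1


def test_best_snp_matches_argmin_p_oracle():
    rng = np.random.default_rng(9)
    for _ in range(120):
        m = int(rng.integers(3, 30))
        n_genes = int(rng.integers(1, 6))
        snp_lists = []
        for _ in range(n_genes):
            k = int(rng.integers(1, m + 1))
            snp_lists.append(np.sort(rng.choice(m, size=k, replace=False)))
        idx = mapping.GeneSnpIndex(
            genes=[f"G{i}" for i in range(n_genes)], snp_lists=snp_lists, n_snps=m
        )
        z = rng.normal(size=(m, 1)) * 2
        from scipy.stats import norm
        p = 2 * norm.sf(np.abs(z))
        _, _, chosen = mapping.best_snp_reduce(idx, z, p)
        want = best_snp_oracle(p[:, 0], snp_lists)
        assert [int(c) for c in chosen[:, 0]] == want


def test_filter_gene_sets_boundaries():
    genes = [f"G{i}" for i in range(250)]
    catalog = PathwayCatalog(
        names=["P19", "P20", "P200", "P201", "Punmapped"],
        sources=["s"] * 5,
        members=[tuple(genes[:19]), tuple(genes[:20]), tuple(genes[:200]),
                 tuple(genes[:201]), tuple(genes[:25]) + ("NOT_MAPPED",)],
    )
    out = mapping.filter_gene_sets(catalog, genes, min_size=20, max_size=200)
    assert out.names == ["P20", "P200", "Punmapped"]
    # membership intersected with mappable genes
    assert "NOT_MAPPED" not in out.genes_of("Punmapped")
    assert len(out.genes_of("Punmapped")) == 25


def test_overlap_fraction():
    a = {f"g{i}" for i in range(10)}
    b = a | {f"g{i}" for i in range(10, 20)}
    assert mapping.overlap_fraction(a, b) == 100.0
    assert mapping.overlap_fraction({"x"}, {"y"}) == 0.0
    assert mapping.overlap_fraction({"a", "b", "c", "d"},
                                    {"a", "b"} | {f"z{i}" for i in range(8)}) == 50.0
    with pytest.raises(ValidationError):
        mapping.overlap_fraction(set(), {"a"})


def test_overlap_matrix_symmetric_and_subset_detection(pathway_catalog):
    cat = pathway_catalog.add("P1sub", "src", ("GA",))
    M = mapping.overlap_matrix(cat)
    assert np.allclose(M.to_numpy(), M.to_numpy().T)
    assert np.allclose(np.diag(M.to_numpy()), 100.0)
    for i, a in enumerate(cat.names):
        for j, b in enumerate(cat.names):
            if i == j:
                continue
            sa, sb = set(cat.genes_of(a)), set(cat.genes_of(b))
            assert (M.iloc[i, j] == 100.0) == (sa <= sb or sb <= sa)


def test_eliminate_supersets_pair_chain_equal():
    cat = PathwayCatalog(
        names=["A", "B", "C", "D", "E"],
        sources=["s"] * 5,
        members=[("g1", "g2"), ("g1", "g2", "g3"), ("g1", "g2", "g3", "g4"),
                 ("x1", "x2"), ("g2", "g1")],
    )
    # chain A ⊂ B ⊂ C: both supersets removed; E equals A: first kept
    survivors, log = mapping.eliminate_supersets(cat)
    assert survivors == ["A", "D"]
    removed = dict(zip(log["removed"], log["justified_by"]))
    assert removed["B"] == "A" and removed["C"] == "A"
    assert removed["E"] == "A"
    assert log.loc[log.removed == "E", "relation"].iloc[0] == "equal"


def test_eliminate_supersets_no_inclusions_unchanged():
    cat = PathwayCatalog(
        names=["A", "B"], sources=["s", "s"],
        members=[("g1", "g2"), ("g2", "g3")],
    )
    survivors, log = mapping.eliminate_supersets(cat)
    assert survivors == ["A", "B"]
    assert log.empty
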