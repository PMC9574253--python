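import numpy as np
import pytest
from skbio import TreeNode

from ovitherm.diversity import (
    FstMatrix,
    ValidationError,
    diversity_table,
    index_of_association,
    nei_gene_diversity,
    nj_tree,
    weir_cockerham_fst,
    weir_cockerham_theta,
)
from ovitherm.simulate import simulate_admixed_genotypes

from conftest import make_geno


# ----------------------------------------------------------------------
# independent scalar transcription of the Weir-Cockerham (1984)
# component formulas for two populations, one locus at a time
# ----------------------------------------------------------------------

def wc_theta_oracle(g1, g2):
    num = den = 0.0
    r = 2
    for j in range(g1.shape[1]):
        stats = []
        for g in (g1, g2):
            col = g[:, j]
            col = col[~np.isnan(col)]
            if col.size < 2:
                stats = None
                break
            n_i = col.size
            p_i = col.sum() / (2 * n_i)
            h_i = np.mean(col == 1)
            stats.append((n_i, p_i, h_i))
        if stats is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else 0.0


def test_hexp_monomorphic_is_zero():
    g = make_geno([[0, 0], [0, 2]])
    # first marker monomorphic (h=0); second: N=4 copies, p=0.5
    assert nei_gene_diversity(g) == pytest.approx((0 + (4 / 3) * 0.5) / 2)


def test_hexp_two_individuals_hand_value():
    g = make_geno([[0], [2]])
    assert nei_gene_diversity(g) == pytest.approx(2 / 3)


def test_hexp_large_n_limit():
    rng = np.random.default_rng(0)
    g = make_geno(rng.binomial(1, 0.5, size=(2000, 1)) * 2)
    # p near 0.5 -> h near 0.5 once the N/(N-1) correction vanishes
    assert nei_gene_diversity(g) == pytest.approx(0.5, abs=0.03)


def test_ia_duplicated_locus_identity():
    rng = np.random.default_rng(1)
    col = rng.integers(0, 3, size=40)
    g = make_geno(np.column_stack([col, col]))
    ia, rbar = index_of_association(g)
    assert ia == pytest.approx(1.0, abs=1e-12)
    assert rbar == pytest.approx(1.0, abs=1e-12)


def test_ia_independent_loci_near_zero():
    g, _ = simulate_admixed_genotypes(200, 500, 1, 0.5, 1.0, 0.0, seed=7)
    ia, rbar = index_of_association(g)
    assert abs(ia) < 0.05
    assert abs(rbar) < 0.01


def test_ia_degenerate_identical_individuals():
    g = make_geno([[1, 1], [1, 1], [1, 1]])
    with pytest.raises(ValidationError):
        index_of_association(g)


def test_ia_permutation_invariance():
    rng = np.random.default_rng(3)
    calls = rng.integers(0, 3, size=(20, 8))
    g = make_geno(calls)
    ia, rbar = index_of_association(g)
    perm_s = rng.permutation(20)
    perm_m = rng.permutation(8)
    g2 = make_geno(calls[perm_s][:, perm_m])
    ia2, rbar2 = index_of_association(g2)
    assert ia2 == pytest.approx(ia)
    assert rbar2 == pytest.approx(rbar)
    assert rbar <= 1.0 + 1e-12


def test_fst_identical_groups_near_zero():
    rng = np.random.default_rng(5)
    block = rng.binomial(2, 0.4, size=(100, 200)).astype(np.int16)
    g = make_geno(np.vstack([block, block]))
    labels = ["a"] * 100 + ["b"] * 100
    fst = weir_cockerham_fst(g, labels)
    assert abs(fst.values[0, 1]) < 0.01


def test_fst_fixed_opposite_alleles():
    g = make_geno([[0] * 5] * 10 + [[2] * 5] * 10)
    fst = weir_cockerham_fst(g, ["a"] * 10 + ["b"] * 10)
    assert fst.values[0, 1] == pytest.approx(1.0)


def test_fst_matches_independent_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n1, n2 = rng.integers(4, 20, 2)
        m = int(rng.integers(2, 10))
        g1 = rng.binomial(2, rng.uniform(0.1, 0.9, m), (n1, m)).astype(float)
        g2 = rng.binomial(2, rng.uniform(0.1, 0.9, m), (n2, m)).astype(float)
        assert weir_cockerham_theta(g1, g2) == pytest.approx(
            wc_theta_oracle(g1, g2), abs=1e-10)


def test_fst_hwe_textbook_pair():
    rng = np.random.default_rng(13)
    g1 = (rng.random((50, 1)) < 0.9).astype(float) + (rng.random((50, 1)) < 0.9)
    g2 = (rng.random((50, 1)) < 0.1).astype(float) + (rng.random((50, 1)) < 0.1)
    assert weir_cockerham_theta(g1, g2) == pytest.approx(
        wc_theta_oracle(g1, g2), abs=1e-10)


def test_fst_small_group_excluded():
    g = make_geno(np.random.default_rng(17).integers(0, 3, (7, 5)))
    with pytest.warns(UserWarning):
        fst = weir_cockerham_fst(g, ["a"] * 3 + ["b"] * 3 + ["c"])
    assert fst.labels == ["a", "b"]


# ----------------------------------------------------------------------
# neighbour joining
# ----------------------------------------------------------------------

def _branch_lengths(newick):
    tree = TreeNode.read([newick])
    return {t.name: t.length for t in tree.tips()}


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]])
    nwk = nj_tree(FstMatrix(["A", "B", "C"], d))
    bl = _branch_lengths(nwk)
    assert bl["A"] == pytest.approx((0.1 + 0.2 - 0.3) / 2, abs=1e-12)
    assert bl["B"] == pytest.approx((0.1 + 0.3 - 0.2) / 2, abs=1e-12)
    assert bl["C"] == pytest.approx((0.2 + 0.3 - 0.1) / 2, abs=1e-12)


def _additive_matrix(split, lengths):
    """4-taxon additive distances for topology (AB|CD) under `split`."""
    (a, b), (c, d) = split
    ta, tb, tc, td, mid = lengths
    dm = np.zeros((4, 4))
    ext = {a: ta, b: tb, c: tc, d: td}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            same = {i, j} in ({a, b}, {c, d})
            dm[i, j] = ext[i] + ext[j] + (0 if same else mid)
    return dm


@pytest.mark.parametrize("split", [((0, 1), (2, 3)), ((0, 2), (1, 3)),
                                   ((0, 3), (1, 2))])
@pytest.mark.parametrize("rep", range(5))
def test_nj_recovers_four_taxon_topology(split, rep):
    rng = np.random.default_rng(rep)
    lengths = rng.uniform(0.05, 0.5, 5)
    dm = _additive_matrix(split, lengths)
    nwk = nj_tree(FstMatrix(list("ABCD"), dm))
    tree = TreeNode.read([nwk])
    names = set("ABCD")
    sisters = None
    for node in tree.non_tips(include_self=False):
        tips = {t.name for t in node.tips()}
        if len(tips) == 2:
            sisters = tips
    expected_a = {"ABCD"[i] for i in split[0]}
    expected_b = names - expected_a
    assert sisters in (expected_a, expected_b)


def test_nj_zero_matrix_zero_branches():
    nwk = nj_tree(FstMatrix(list("WXYZ"), np.zeros((4, 4))))
    tree = TreeNode.read([nwk])
    assert all((n.length or 0) == 0 for n in tree.traverse() if n.length is not None)


def test_nj_too_few_taxa():
    with pytest.raises(ValidationError):
        nj_tree(FstMatrix(["a", "b"], np.zeros((2, 2))))


# ----------------------------------------------------------------------
# table assembly
# ----------------------------------------------------------------------

def test_diversity_table_single_group_equals_total():
    rng = np.random.default_rng(23)
    g = make_geno(rng.integers(0, 3, (12, 30)), breed=["only"] * 12)
    rows = diversity_table(g, "breed")
    assert len(rows) == 2
    grp, tot = rows
    assert grp.n == tot.n == 12
    assert grp.hexp == pytest.approx(tot.hexp)
    assert grp.ia == pytest.approx(tot.ia)


def test_diversity_table_counts_sum():
    g, _ = simulate_admixed_genotypes(40, 200, 2, 0.1, 0.2, 0.0, seed=3)
    rows = diversity_table(g, "location")
    assert sum(r.n for r in rows[:-1]) == 40
    assert rows[-1].group == "Total"


def test_diversity_table_unknown_grouping():
    g, _ = simulate_admixed_genotypes(10, 20, 1, 0.1, 1.0, 0.0, seed=3)
    with pytest.raises(ValidationError):
        diversity_table(g, "flock")
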