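"""NJ genealogies per 50-SNP window and rooted sister classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import ploidypaint as pp
from ploidypaint.ancestry_paint import HaplotypeMatrix
from ploidypaint.window_trees import (
    classification_table,
    classify_sister,
    nj_tree,
    pairwise_p_distance,
    window_genealogies,
)


def matrix_from_rows(rows: dict, positions=None, contig="c1"):
    n = len(next(iter(rows.values())))
    alleles = pd.DataFrame(
        {i: {k: rows[k][i] for k in rows} for i in range(n)}
    ).reindex(list(rows))
    alleles = alleles.where(alleles != "N", other=None)
    if positions is None:
        positions = list(range(10, 10 * (n + 1), 10))
    sites = pd.DataFrame(
        {"contig": contig, "pos0": positions, "ref": "A", "alt": "G"}
    )
    return HaplotypeMatrix(alleles=alleles, sites=sites)


class TestPDistance:
    def test_identical_rows_give_zero(self):
        m = matrix_from_rows({"a": "AAAA", "b": "AAAA", "c": "GGGG", "d": "AGAG"})
        d = pairwise_p_distance(m)
        assert d.loc["a", "b"] == 0
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.all(np.diag(d.to_numpy()) == 0)

    def test_five_of_fifty_differences_is_point_one(self):
        a = "A" * 50
        b = "G" * 5 + "A" * 45
        m = matrix_from_rows({"a": a, "b": b, "c": a, "d": a})
        assert np.isclose(pairwise_p_distance(m).loc["a", "b"], 0.1)

    def test_missing_cells_use_pairwise_complete_columns(self):
        m = matrix_from_rows({"a": "AANG", "b": "AGNA", "c": "AAAA", "d": "GGGG"})
        # a vs b: complete columns 0,1,3 -> 2 differ -> 2/3
        assert np.isclose(pairwise_p_distance(m).loc["a", "b"], 2 / 3)

    def test_pair_with_no_shared_columns_is_error(self):
        m = matrix_from_rows({"a": "ANN", "b": "NAA", "c": "AAA", "d": "GGG"})
        with pytest.raises(ValueError, match="'a'.*'b'"):
            pairwise_p_distance(m)

    def test_matches_bruteforce_counting_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            rows = {
                name: [
                    None if rng.random() < 0.1 else "ACGT"[rng.integers(4)]
                    for _ in range(30)
                ]
                for name in "abcde"
            }
            m = matrix_from_rows(
                {k: ["N" if v is None else v for v in vals] for k, vals in rows.items()}
            )
            try:
                d = pairwise_p_distance(m)
            except ValueError:
                continue
            for x, y in itertools.combinations("abcde", 2):
                num = den = 0
                for u, v in zip(rows[x], rows[y]):
                    if u is not None and v is not None:
                        den += 1
                        num += u != v
                assert np.isclose(d.loc[x, y], num / den)


def _canonical_split(pair, taxa=("a", "b", "c", "d")):
    """Bipartition of a 4-taxon tree, reported as the side holding taxa[0]."""
    pair = frozenset(pair)
    return pair if taxa[0] in pair else frozenset(taxa) - pair


def _additive_matrix(rng):
    """Random additive 4-taxon matrix; returns (D, true bipartition)."""
    taxa = ["a", "b", "c", "d"]
    pair = tuple(sorted(rng.choice(4, size=2, replace=False)))
    ((i, j), (k, l)) = (pair, tuple(x for x in range(4) if x not in pair))
    # external branches e0..e3, internal branch m
    e = rng.uniform(0.05, 1.0, size=4)
    mid = rng.uniform(0.05, 1.0)
    D = np.zeros((4, 4))
    D[i, j] = D[j, i] = e[i] + e[j]
    D[k, l] = D[l, k] = e[k] + e[l]
    for x, y in [(i, k), (i, l), (j, k), (j, l)]:
        D[x, y] = D[y, x] = e[x] + e[y] + mid
    return pd.DataFrame(D, index=taxa, columns=taxa), _canonical_split(
        {taxa[i], taxa[j]}
    )


def _nj_split(tree):
    """The bipartition of a 4-taxon NJ tree (side holding taxon 'a')."""
    for node in tree.traverse():
        tips = [t.name for t in node.tips()]
        if len(tips) == 2:
            return _canonical_split(tips)
    raise AssertionError("no cherry found")


def _least_squares_topology(D):
    """Exhaustive LS search over the 3 resolved 4-taxon topologies."""
    taxa = list(D.index)
    best, best_cost = None, np.inf
    for pair in [(0, 1), (0, 2), (0, 3)]:
        other = [x for x in range(4) if x not in pair]
        # columns: 4 external branches + internal; rows: 6 pairwise distances
        rows, y = [], []
        for x, z in itertools.combinations(range(4), 2):
            path = np.zeros(5)
            path[x] = path[z] = 1
            same = ({x, z} == set(pair)) or ({x, z} == set(other))
            if not same:
                path[4] = 1
            rows.append(path)
            y.append(D.iloc[x, z])
        coef, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        resid = np.array(rows) @ coef - np.array(y)
        cost = float(resid @ resid)
        if cost < best_cost:
            best_cost, best = cost, _canonical_split({taxa[pair[0]], taxa[pair[1]]})
    return best


class TestNJ:
    def test_recovers_additive_topology(self):
        rng = np.random.default_rng(0)
        D, split = _additive_matrix(rng)
        assert _nj_split(nj_tree(D)) == split

    def test_agrees_with_exhaustive_least_squares_on_additive_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            D, split = _additive_matrix(rng)
            assert _nj_split(nj_tree(D)) == _least_squares_topology(D) == split

    def test_star_tree_resolved_deterministically(self):
        taxa = ["a", "b", "c", "d"]
        D = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=taxa, columns=taxa)
        s1 = _nj_split(nj_tree(D))
        s2 = _nj_split(nj_tree(D))
        assert s1 == s2  # tie rule makes the choice reproducible

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(5)
        D, _ = _additive_matrix(rng)
        perm = ["c", "a", "d", "b"]
        Dp = D.loc[perm, perm]
        assert _nj_split(nj_tree(D)) == _nj_split(nj_tree(Dp))

    def test_rejects_asymmetric_and_small_inputs(self):
        taxa = ["a", "b", "c", "d"]
        D = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=taxa, columns=taxa)
        D.iloc[0, 1] = 5
        with pytest.raises(ValueError):
            nj_tree(D)
        small = pd.DataFrame(np.zeros((3, 3)), index=taxa[:3], columns=taxa[:3])
        with pytest.raises(ValueError):
            nj_tree(small)

    def test_negative_branch_lengths_clamped(self):
        taxa = ["a", "b", "c", "d"]
        D = pd.DataFrame(
            [[0, 0.1, 1, 1], [0.1, 0, 1.05, 1], [1, 1.05, 0, 0.1], [1, 1, 0.1, 0]],
            index=taxa, columns=taxa,
        )
        tree = nj_tree(D)
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


class TestWindowGenealogies:
    def test_trailing_partial_window_dropped(self):
        rng = np.random.default_rng(2)
        rows = {
            name: "".join(rng.choice(list("ACGT"), size=120)) for name in
            ["other", "lupina", "vulpina", "columbiana"]
        }
        m = matrix_from_rows(rows, positions=list(range(0, 1200, 10)))
        wins = window_genealogies(m, window_snps=50)
        assert len(wins) == 2  # 50 + 50, trailing 20 dropped

    def test_wide_window_flagged_discarded(self):
        rng = np.random.default_rng(3)
        rows = {
            name: "".join(rng.choice(list("ACGT"), size=50)) for name in
            ["other", "lupina", "vulpina", "columbiana"]
        }
        m = matrix_from_rows(rows, positions=[i * 300 for i in range(50)])  # 14.7 kb
        wins = window_genealogies(m, window_snps=50, max_span_bp=10_000)
        assert wins[0].discarded and wins[0].reason == "span"

    def test_discarded_fraction_rises_with_missingness(self, panel):
        calls = pp.classify_alleles(panel.metagenome)
        m = pp.build_haplotype_matrix(calls, panel.haploids)
        frac = []
        for thin in (1.0, 0.4):
            keep = np.random.default_rng(0).random(m.n_sites()) < thin
            sub = HaplotypeMatrix(
                alleles=m.alleles.loc[:, keep].set_axis(
                    range(int(keep.sum())), axis=1
                ),
                sites=m.sites.loc[keep].reset_index(drop=True),
            )
            wins = window_genealogies(sub)
            frac.append(np.mean([w.discarded for w in wins]))
        assert frac[1] > frac[0]


class TestClassifySister:
    def test_stated_topology(self):
        tree = TreeNode.read(
            ["((other,vulpina),(lupina,rugosa),columbiana);"]
        )
        topo = classify_sister(tree)
        assert topo.sister_other == frozenset({"vulpina"})
        assert topo.sister_lupina == frozenset({"rugosa"})
        assert not topo.other_lupina_sisters

    def test_other_lupina_sisters_flag(self):
        tree = TreeNode.read(["((other,lupina),(vulpina,rugosa),columbiana);"])
        assert classify_sister(tree).other_lupina_sisters

    def test_sister_set_when_not_single_taxon(self):
        tree = TreeNode.read(["((other,(vulpina,rugosa)),lupina,columbiana);"])
        topo = classify_sister(tree)
        assert topo.sister_other == frozenset({"vulpina", "rugosa"})

    def test_missing_outgroup_is_error(self):
        tree = TreeNode.read(["((other,vulpina),(lupina,rugosa),x);"])
        with pytest.raises(ValueError, match="columbiana"):
            classify_sister(tree)

    def test_invariant_to_branch_length_scaling(self):
        t1 = TreeNode.read(["((other:1,vulpina:2):1,(lupina:1,rugosa:3):2,columbiana:9);"])
        t2 = TreeNode.read(["((other:10,vulpina:20):10,(lupina:10,rugosa:30):20,columbiana:90);"])
        assert classify_sister(t1) == classify_sister(t2)

    def test_donor_recovery_on_simulated_panel(self, panel):
        calls = pp.classify_alleles(panel.metagenome)
        m = pp.build_haplotype_matrix(calls, panel.haploids)
        tab = classification_table(window_genealogies(m))
        ok = tab[~tab["discarded"]]
        assert len(ok) >= 50
        assert (ok["sister_other"] == panel.donor).mean() >= 0.90
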