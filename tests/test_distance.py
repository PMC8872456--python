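"""Jost's D (with an independent re-implementation as oracle), Nei's D,
neighbor-joining recovery of additive trees, and locus-bootstrap supports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sympop.distance import (
    DestResult,
    bootstrap_support,
    dest_distribution_compare,
    dest_profile,
    distance_matrix,
    jost_dest,
    nei_d,
    nj_tree,
    tree_bipartitions,
)
from sympop.genotypes import AlleleFrequencyTable

import pandas as pd


def reference_dest(counts_a: dict, counts_b: dict) -> float:
    """Independent evaluation of the bias-corrected two-population Jost's D:
    harmonic-mean sample size, corrected H_S and H_T, D = (HT-HS)/(1-HS)*2."""
    na, nb = sum(counts_a.values()), sum(counts_b.values())
    alleles = sorted(set(counts_a) | set(counts_b))
    pa = np.array([counts_a.get(a, 0) / na for a in alleles])
    pb = np.array([counts_b.get(a, 0) / nb for a in alleles])
    n_harm = 2.0 / (2.0 / na + 2.0 / nb)  # harmonic mean of individuals
    hs = (2 * n_harm / (2 * n_harm - 1)) * (1 - ((pa**2).sum() + (pb**2).sum()) / 2)
    ht = 1 - (((pa + pb) / 2) ** 2).sum() + hs / (4 * n_harm)
    return (ht - hs) / (1 - hs) * 2


def _freq_table(entries):
    groups = list(dict.fromkeys(k[0] for k in entries))
    loci = list(dict.fromkeys(k[1] for k in entries))
    return AlleleFrequencyTable(
        groups=groups,
        loci=loci,
        freqs={k: v[0] for k, v in entries.items()},
        n_copies={k: v[1] for k, v in entries.items()},
    )


class TestJostDest:
    def test_identical_populations_near_zero(self):
        c = {100: 60, 102: 40}
        assert abs(jost_dest(c, dict(c))["dest"]) < 0.02

    def test_fixed_difference_near_one(self):
        res = jost_dest({100: 100}, {102: 100})
        assert res["dest"] >= 0.98

    def test_matches_independent_implementation(self):
        ca, cb = {1: 30, 2: 10}, {1: 10, 2: 30}
        assert jost_dest(ca, cb)["dest"] == pytest.approx(reference_dest(ca, cb), abs=1e-12)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ca = {a: int(c) for a, c in enumerate(rng.integers(1, 40, 5), 1)}
            cb = {a: int(c) for a, c in enumerate(rng.integers(1, 40, 5), 1)}
            ref = reference_dest(ca, cb)
            assert jost_dest(ca, cb)["dest"] == pytest.approx(max(ref, 0.0), abs=1e-12)

    def test_allele_relabeling_invariance(self):
        ca, cb = {1: 30, 2: 10, 3: 5}, {1: 5, 2: 30, 3: 10}
        relab = {10: 30, 99: 10, 7: 5}, {10: 5, 99: 30, 7: 10}
        assert jost_dest(ca, cb)["dest"] == pytest.approx(jost_dest(*relab)["dest"])

    def test_population_swap_symmetry(self):
        ca, cb = {1: 35, 2: 5}, {1: 12, 2: 28}
        assert jost_dest(ca, cb)["dest"] == pytest.approx(jost_dest(cb, ca)["dest"])

    def test_monomorphic_locus_flagged_zero(self):
        res = jost_dest({100: 40}, {100: 60})
        assert res["dest"] == 0.0 and res["monomorphic"]


class TestNeiD:
    def test_identical_vectors_zero(self):
        fr = _freq_table(
            {
                ("A", "L1"): ({1: 0.7, 2: 0.3}, 40),
                ("B", "L1"): ({1: 0.7, 2: 0.3}, 40),
            }
        )
        assert nei_d(fr, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        # x=(0.8,0.2), y=(0.2,0.8): I = 0.32/0.68, D = -ln(0.470588...)
        fr = _freq_table(
            {
                ("A", "L1"): ({1: 0.8, 2: 0.2}, 40),
                ("B", "L1"): ({1: 0.2, 2: 0.8}, 40),
            }
        )
        assert nei_d(fr, "A", "B") == pytest.approx(-np.log(0.32 / 0.68), abs=1e-12)

    def test_monomorphic_shared_locus_dilutes_distance(self):
        one = _freq_table(
            {
                ("A", "L1"): ({1: 0.8, 2: 0.2}, 40),
                ("B", "L1"): ({1: 0.2, 2: 0.8}, 40),
            }
        )
        two = _freq_table(
            {
                ("A", "L1"): ({1: 0.8, 2: 0.2}, 40),
                ("B", "L1"): ({1: 0.2, 2: 0.8}, 40),
                ("A", "L2"): ({5: 1.0}, 40),
                ("B", "L2"): ({5: 1.0}, 40),
            }
        )
        assert nei_d(two, "A", "B") < nei_d(one, "A", "B")

    def test_no_shared_alleles_is_infinite(self):
        fr = _freq_table(
            {("A", "L1"): ({1: 1.0}, 40), ("B", "L1"): ({2: 1.0}, 40)}
        )
        with pytest.warns(UserWarning, match="no shared alleles"):
            assert nei_d(fr, "A", "B") == np.inf

    def test_symmetry_and_nonnegativity(self, radiation_freqs):
        pops = radiation_freqs.groups[:6]
        dm = distance_matrix(radiation_freqs, pops)
        arr = dm.to_numpy()
        assert np.allclose(arr, arr.T)
        assert (arr >= 0).all() and np.allclose(np.diag(arr), 0)


def random_additive_tree(n_taxa: int, rng) -> tuple[pd.DataFrame, set[frozenset]]:
    """Random unrooted binary tree with positive branch lengths; returns its
    path-length distance matrix and its non-trivial bipartitions."""
    # grow by random edge attachment: start from a 3-star
    parent = {}
    nodes = ["t0", "t1", "t2"]
    internal = ["x0"]
    edges = {("t0", "x0"), ("t1", "x0"), ("t2", "x0")}
    for k in range(3, n_taxa):
        split = list(edges)[rng.integers(0, len(edges))]
        edges.remove(split)
        new_int = f"x{k - 2}"
        new_tip = f"t{k}"
        edges |= {(split[0], new_int), (split[1], new_int), (new_tip, new_int)}
        internal.append(new_int)
        nodes.append(new_tip)
    lengths = {e: float(rng.uniform(0.5, 2.0)) for e in edges}
    import networkx as nx

    g = nx.Graph()
    for e, w in lengths.items():
        g.add_edge(*e, weight=w)
    tips = [f"t{i}" for i in range(n_taxa)]
    dm = pd.DataFrame(0.0, index=tips, columns=tips)
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for a in tips:
        for b in tips:
            dm.loc[a, b] = paths[a][b]
    # bipartitions: removing each internal edge splits the tips
    parts = set()
    anchor = sorted(tips)[0]
    for e in edges:
        if e[0].startswith("x") and e[1].startswith("x"):
            h = g.copy()
            h.remove_edge(*e)
            comp = nx.node_connected_component(h, e[0])
            side = frozenset(t for t in tips if t in comp)
            if anchor in side:
                side = frozenset(set(tips) - side)
            if 1 < len(side) < len(tips) - 1:
                parts.add(side)
    return dm, parts


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("abc"), columns=list("abc")
        )
        tree = nj_tree(dm)
        # three-point formulas: la = (dab+dac-dbc)/2 etc.
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(0)
        dm, parts = random_additive_tree(4, rng)
        tree = nj_tree(dm)
        assert tree_bipartitions(tree) == parts
        # branch lengths: tip-to-tip path distances reproduce the matrix
        for a in dm.index:
            for b in dm.columns:
                if a != b:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                        dm.loc[a, b], abs=1e-9
                    )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(4, 8), st.integers(0, 10_000))
    def test_random_additive_trees_recovered(self, n_taxa, seed):
        dm, parts = random_additive_tree(n_taxa, np.random.default_rng(seed))
        assert tree_bipartitions(nj_tree(dm)) == parts

    def test_bad_matrices_rejected(self):
        bad = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            nj_tree(bad)  # too few taxa
        nan = pd.DataFrame(np.full((3, 3), np.nan), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            nj_tree(nan)
        asym = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc")
        )
        with pytest.raises(ValueError):
            nj_tree(asym)


class TestBootstrapSupport:
    def _duplicated_signal_table(self):
        fm = {
            ("A", "L1"): ({1: 0.9, 2: 0.1}, 100),
            ("B", "L1"): ({1: 0.85, 2: 0.15}, 100),
            ("C", "L1"): ({1: 0.1, 2: 0.9}, 100),
            ("D", "L1"): ({1: 0.15, 2: 0.85}, 100),
        }
        entries = dict(fm)
        for (p, _), (f, n) in fm.items():
            entries[(p, "L2")] = (dict(f), n)
            entries[(p, "L3")] = (dict(f), n)
        return _freq_table(entries)

    def test_duplicated_loci_give_full_support(self):
        fr = self._duplicated_signal_table()
        _, support = bootstrap_support(fr, reps=200, seed=0)
        assert support and all(v == 100.0 for v in support.values())

    def test_seeded_reproducibility(self, radiation_freqs):
        pops = radiation_freqs.groups[:8]
        _, s1 = bootstrap_support(radiation_freqs, pops, reps=50, seed=3)
        _, s2 = bootstrap_support(radiation_freqs, pops, reps=50, seed=3)
        assert s1 == s2

    def test_low_reps_warns(self):
        fr = self._duplicated_signal_table()
        with pytest.warns(UserWarning, match="replicates"):
            bootstrap_support(fr, reps=50, seed=0)

    def test_noise_gives_weak_support(self):
        rng = np.random.default_rng(4)
        entries = {}
        for p in "ABCDEF":
            for l in range(8):
                n = 100
                c = rng.binomial(n, 0.5)
                entries[(p, f"L{l}")] = ({1: c / n, 2: 1 - c / n}, n)
        fr = _freq_table(entries)
        _, support = bootstrap_support(fr, reps=200, seed=5)
        assert np.mean([v < 70 for v in support.values()]) > 0.5


class TestDestComparison:
    def test_identical_profiles(self):
        df = pd.DataFrame({"locus": ["a", "b", "c"], "dest": [0.1, 0.2, 0.3]})
        a = DestResult("x", df)
        res = dest_distribution_compare(a, DestResult("y", df.copy()))
        assert res["t"] == pytest.approx(0.0) and res["p"] == pytest.approx(1.0)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(6)
        a = DestResult("a", pd.DataFrame({"dest": 0.2 + 0.1 * rng.standard_normal(19)}))
        b = DestResult("b", pd.DataFrame({"dest": 0.6 + 0.1 * rng.standard_normal(19)}))
        assert dest_distribution_compare(a, b)["p"] < 0.001

    def test_welch_df_not_pooled(self):
        rng = np.random.default_rng(7)
        a = DestResult("a", pd.DataFrame({"dest": 0.3 + 0.02 * rng.standard_normal(19)}))
        b = DestResult("b", pd.DataFrame({"dest": 0.3 + 0.3 * rng.standard_normal(19)}))
        res = dest_distribution_compare(a, b)
        assert res["df"] < 36  # unequal variances shrink the Welch df
        pooled = dest_distribution_compare(a, b, equal_var=True)
        assert pooled["df"] == 36
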