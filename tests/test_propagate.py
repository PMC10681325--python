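"""Random walk with restart, pathway scores, gene modules, propensity."""

import numpy as np
import pytest
import scipy.sparse as sp

from scnetpas import assembly, propagate
from scnetpas.propagate import RWRConfig
from scnetpas.types import GeneSetCollection, PhenotypeTable
from conftest import random_network


class TestRWR:
    def test_two_node_hand_solution(self):
        net = assembly.assemble(
            sp.csr_matrix((1, 1)), sp.csr_matrix((1, 1)), sp.csr_matrix([[1.0]])
        )
        p = propagate.rwr(net, [net.genes[0]], RWRConfig(r=0.7, tol=1e-12))
        assert p[0] == pytest.approx(10 / 13, abs=1e-9)
        assert p[1] == pytest.approx(3 / 13, abs=1e-9)

    def test_uniform_on_symmetric_regular_graph(self):
        # ring of 4 genes, no cells involved beyond a dummy: use all nodes as seeds
        ring = np.roll(np.eye(4), 1, axis=1) + np.roll(np.eye(4), -1, axis=1)
        net = assembly.assemble(
            sp.csr_matrix(ring), sp.csr_matrix((1, 1)), sp.csr_matrix(np.zeros((4, 1)))
        )
        p = propagate.rwr(net, net.genes + net.cells, RWRConfig(r=0.5))
        # the dummy cell is isolated with a self-loop: regular-graph symmetry holds on genes
        assert np.allclose(p[:4], p[0])

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, m=int(rng.integers(3, 15)), n=int(rng.integers(3, 12)))
        seeds = [net.genes[0], net.cells[0]]
        it = propagate.rwr(net, seeds, RWRConfig(r=0.7, tol=1e-9))
        ex = propagate.rwr_exact(net, seeds, r=0.7)
        assert np.abs(it - ex).sum() < 1e-6
        assert it.sum() == pytest.approx(1.0, abs=1e-9)

    def test_converges_within_contraction_bound(self, rng):
        bound = propagate.contraction_bound(0.7, 1e-6)
        net = random_network(rng, m=10, n=8)
        p0 = propagate._restart_vector(net, [net.genes[0]])
        p = p0.copy()
        for it in range(bound + 1):
            p_next = 0.3 * (net.W @ p) + 0.7 * p0
            if np.abs(p_next - p).sum() < 1e-6:
                break
            p = p_next
        assert it <= bound

    def test_missing_seed_listed(self, rng):
        net = random_network(rng)
        with pytest.raises(ValueError, match="nope"):
            propagate.rwr(net, ["nope"])


class TestPathwayScores:
    def test_extremes_and_substitution(self, rng):
        net = random_network(rng, m=12, n=6)
        cfg = RWRConfig(n_perm=100, seed=0)
        observed = propagate.rwr(net, net.genes[:3], cfg)[12:]
        perm = rng.random((100, 6)) * observed.max() * 2
        # direct check of the score rule on a synthetic permutation store
        pas = 1.0 - (perm >= observed[None, :]).sum(axis=0) / 100
        for j in range(6):
            count = int((perm[:, j] >= observed[j]).sum())
            assert pas[j] == pytest.approx(1.0 - count / 100)
        assert np.all((pas >= 0) & (pas <= 1))

    def test_pathway_scoring_properties(self, rng):
        net = random_network(rng, m=15, n=8)
        sets = GeneSetCollection({
            "big": net.genes[:5],
            "small": net.genes[:2],        # below min_genes -> skipped
            "unmapped": ["zz1", "zz2", "zz3"],  # no genes map -> skipped
        })
        with pytest.warns(UserWarning):
            scores = propagate.pathway_scores(net, sets, RWRConfig(n_perm=20, seed=1))
        assert scores.pathways == ["big"]
        assert scores.scores.shape == (1, 8)
        assert scores.seed_gene_counts["big"] == 5
        assert (scores.scores >= 0).all() and (scores.scores <= 1).all()

    def test_empty_collection_errors(self, rng):
        net = random_network(rng)
        with pytest.raises(ValueError, match="empty"):
            propagate.pathway_scores(net, GeneSetCollection({}), RWRConfig())

    def test_pas_invariant_under_monotone_rescaling(self, rng):
        observed = rng.random(10)
        perm = rng.random((50, 10))
        pas1 = 1.0 - (perm >= observed[None, :]).sum(axis=0) / 50
        f = lambda v: np.log1p(3 * v)  # strictly monotone
        pas2 = 1.0 - (f(perm) >= f(observed)[None, :]).sum(axis=0) / 50
        assert np.array_equal(pas1, pas2)


class TestGeneModules:
    def test_add_one_estimator_arithmetic(self, rng):
        net = random_network(rng, m=10, n=12)
        phen = PhenotypeTable({c: ("A" if i < 6 else "B") for i, c in enumerate(net.cells)})
        mods = propagate.gene_modules(net, phen, RWRConfig(n_perm=100, seed=0))
        for mod in mods.values():
            pvals = np.array(list(mod.p_values.values()))
            assert ((pvals > 0) & (pvals <= 1)).all()
            # p-values live on the add-one grid (k+1)/(N+1)
            assert np.allclose(pvals * 101, np.round(pvals * 101), atol=1e-9)
            assert set(mod.members) == {g for g, p in mod.p_values.items() if p < 0.01}

    def test_all_cells_as_seeds_degenerate(self, rng):
        net = random_network(rng, m=8, n=6)
        phen = PhenotypeTable({c: "all" for c in net.cells})
        with pytest.warns(UserWarning, match="degenerate"):
            mods = propagate.gene_modules(net, phen, RWRConfig(n_perm=30, seed=0))
        # permutation seeds equal the observed seeds: p = 1 for every gene
        assert all(p == 1.0 for p in mods["all"].p_values.values())
        assert mods["all"].members == []


class TestPropensity:
    def _module(self, label, scores, members):
        return propagate.GeneModule(label, scores, {g: 0.001 for g in members}, members)

    def test_single_module_gene(self):
        mods = {"A": self._module("A", {"g1": 0.02}, ["g1"])}
        assert propagate.phenotype_propensity(mods) == {"g1": {"A": 1.0}}

    def test_symmetric_split(self):
        mods = {
            "A": self._module("A", {"g1": 0.02}, ["g1"]),
            "B": self._module("B", {"g1": 0.02}, ["g1"]),
        }
        prop = propagate.phenotype_propensity(mods)
        assert prop["g1"] == {"A": 0.5, "B": 0.5}

    def test_hand_ratio_and_sum_to_one(self):
        mods = {
            "A": self._module("A", {"g1": 0.03}, ["g1"]),
            "B": self._module("B", {"g1": 0.01}, ["g1"]),
        }
        prop = propagate.phenotype_propensity(mods)
        assert prop["g1"]["A"] == pytest.approx(0.75)
        assert sum(prop["g1"].values()) == pytest.approx(1.0, abs=1e-12)


class TestGeneImportance:
    def test_matches_closed_form_on_toy(self, rng):
        net = random_network(rng, m=4, n=3)
        imp, subnet = propagate.pathway_gene_importance(
            net, net.genes[:3], cfg=RWRConfig(r=0.7, tol=1e-10)
        )
        exact = propagate.rwr_exact(net, net.cells, r=0.7)
        for k, g in enumerate(net.genes[:3]):
            assert imp[g] == pytest.approx(exact[k], abs=1e-6)
        assert subnet.shape == (3, 3)

    def test_automorphic_genes_equal_importance(self):
        # two genes symmetrically attached to the same cell
        K = sp.csr_matrix(np.array([[1.0], [1.0]]))
        net = assembly.assemble(sp.csr_matrix((2, 2)), sp.csr_matrix((1, 1)), K)
        imp, _ = propagate.pathway_gene_importance(net, net.genes, min_genes=2)
        vals = list(imp.values())
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)
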