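import itertools

import numpy as np
import pandas as pd
import pytest

import connectotype as ct
from connectotype.modules import _louvain_once, _canonical
from connectotype.parcellation import SUBCORTICAL_BLOCK_STRUCTURES, Parcellation


def toy_parcellation(m_left, m_right, per_module=2, with_blocks=True):
    """Minimal parcellation with planted hemisphere-pure modules."""
    rows, labels = [], {}
    rid = 0
    for hemi, m in (("left", m_left), ("right", m_right)):
        for mod in range(m):
            for k in range(per_module):
                rows.append({"name": f"{hemi[0]}m{mod}r{k}", "hemisphere": hemi,
                             "region_class": "cortical"})
                labels[rid] = mod if hemi == "left" else m_left + mod
                rid += 1
    if with_blocks:
        for hemi in ("left", "right"):
            for s in SUBCORTICAL_BLOCK_STRUCTURES:
                rows.append({"name": f"{hemi[0]}_{s}", "hemisphere": hemi,
                             "region_class": "subcortical"})
    regions = pd.DataFrame(rows)
    regions.index.name = "region_id"
    parc = Parcellation(regions)
    part = ct.ModulePartition(labels=pd.Series(labels), provenance="user")
    return parc, part


def two_clique_setup():
    """Two disjoint 10-node cliques, one per hemisphere."""
    parc, _ = toy_parcellation(1, 1, per_module=10, with_blocks=False)
    w = np.zeros((20, 20))
    w[:10, :10] = 1.0
    w[10:, 10:] = 1.0
    np.fill_diagonal(w, 0)
    return parc, w


class TestLouvainConsensus:
    def test_two_cliques_recovered(self):
        parc, w = two_clique_setup()
        with pytest.warns(UserWarning, match="connected components"):
            part = ct.louvain_consensus(w, parc, n_runs=5, seed=0)
        assert part.n_modules == 2
        labels = part.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_consensus_of_one_is_a_single_run(self):
        parc, w = two_clique_setup()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = ct.louvain_consensus(w, parc, n_runs=1, seed=9)
        import networkx as nx
        single_seed = int(np.random.default_rng(9).integers(0, 2**31 - 1, size=1)[0])
        single = _canonical(_louvain_once(nx.from_numpy_array(w), 1.0, single_seed))
        assert np.array_equal(part.labels.to_numpy(), single)

    def test_planted_eight_blocks_recovered(self):
        # 8-block weighted planted partition: 4 modules per hemisphere
        parc, truth = toy_parcellation(4, 4, per_module=15, with_blocks=False)
        n = 120
        rng = np.random.default_rng(1)
        lab = truth.labels.to_numpy()
        w = np.where(lab[:, None] == lab[None, :], 1.0, 0.1)
        w = w * (1 + 0.05 * ((r := rng.random((n, n))) + r.T))
        np.fill_diagonal(w, 0)
        part = ct.louvain_consensus(w, parc, n_runs=100, seed=2)
        assert part.n_modules == 8
        agree = pd.crosstab(part.labels, truth.labels).max(axis=1).sum() / n
        assert agree >= 0.95

    def test_permutation_equivariance(self):
        parc, w = two_clique_setup()
        perm = np.random.default_rng(4).permutation(20)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ct.louvain_consensus(w, parc, n_runs=3, seed=5).labels.to_numpy()
            b = ct.louvain_consensus(w[np.ix_(perm, perm)], parc, n_runs=3,
                                     seed=5).labels.to_numpy()
        # co-membership structure is identical after undoing the permutation
        co_a = a[:, None] == a[None, :]
        b_unperm = np.empty_like(b)
        b_unperm[perm] = b
        co_b = b_unperm[:, None] == b_unperm[None, :]
        assert np.array_equal(co_a, co_b)

    def test_determinism(self, small_cohort):
        gm = ct.mean_connectome(small_cohort.connectomes)
        p1 = ct.louvain_consensus(gm, small_cohort.parcellation, n_runs=3, seed=8)
        p2 = ct.louvain_consensus(gm, small_cohort.parcellation, n_runs=3, seed=8)
        assert p1.labels.equals(p2.labels)


class TestRandomPartitionNull:
    def test_covers_all_cortical_and_deterministic(self, small_cohort):
        gm = ct.mean_connectome(small_cohort.connectomes)
        parc = small_cohort.parcellation
        p1 = ct.random_partition_null(gm, parc, seed=3)
        p2 = ct.random_partition_null(gm, parc, seed=3)
        assert p1.provenance == "random_null"
        assert p1.n_modules >= 1
        assert set(p1.labels.index) == set(parc.cortical_ids)
        assert p1.labels.equals(p2.labels)


class TestEnumeration:
    def _counts(self, classes):
        out = {}
        for c in classes:
            out[c.kind] = out.get(c.kind, 0) + 1
        return out

    def test_study_layout_yields_44(self):
        parc, part = toy_parcellation(4, 4)
        classes = ct.enumerate_connection_classes(part, parc)
        assert self._counts(classes) == {
            "interhemispheric": 16, "intrahemispheric": 12,
            "intramodular": 8, "subcortical_cortical": 8,
        }
        assert len(classes) == 44

    def test_smallest_case(self):
        parc, part = toy_parcellation(1, 1)
        classes = ct.enumerate_connection_classes(part, parc)
        assert self._counts(classes) == {
            "interhemispheric": 1, "intramodular": 2, "subcortical_cortical": 2,
        }
        assert len(classes) == 5

    @pytest.mark.parametrize("m_left,m_right",
                             list(itertools.product(range(1, 7), range(1, 7))))
    def test_counts_match_brute_force(self, m_left, m_right):
        parc, part = toy_parcellation(m_left, m_right)
        counts = self._counts(ct.enumerate_connection_classes(part, parc))
        left = [f"L{i}" for i in range(m_left)]
        right = [f"R{i}" for i in range(m_right)]
        brute = {
            "interhemispheric": len([(a, b) for a in left for b in right]),
            "intrahemispheric": len(list(itertools.combinations(left, 2)))
            + len(list(itertools.combinations(right, 2))),
            "intramodular": len(left + right),
            "subcortical_cortical": len(left) + len(right),
        }
        brute = {k: v for k, v in brute.items() if v}
        assert counts == brute

    def test_ordering_deterministic(self):
        parc, part = toy_parcellation(3, 2)
        a = [c.label for c in ct.enumerate_connection_classes(part, parc)]
        b = [c.label for c in ct.enumerate_connection_classes(part, parc)]
        assert a == b
        assert a[0].startswith("interhemispheric:L")

    def test_mixed_module_error_names_module(self):
        parc, part = toy_parcellation(2, 2)
        labels = part.labels.copy()
        labels.iloc[-1] = 0  # attach a right-hemisphere region to left module 0
        mixed = ct.ModulePartition(labels=labels, provenance="user")
        with pytest.raises(ValueError, match=r"\[0\]"):
            ct.enumerate_connection_classes(mixed, parc)

    def test_random_null_relaxed_path(self):
        parc, part = toy_parcellation(2, 2)
        labels = part.labels.copy()
        labels.iloc[-1] = 0
        mixed = ct.ModulePartition(labels=labels, provenance="random_null")
        classes = ct.enumerate_connection_classes(mixed, parc)
        kinds = {c.kind for c in classes}
        assert kinds == {"intermodular", "intramodular"}


class TestClassStrengths:
    def test_hand_enumerated_toy(self):
        # 2 modules of 2 nodes; one cross-module edge w=3, one within w=2
        parc, part = toy_parcellation(2, 1)
        n = parc.n_regions
        w = np.zeros((n, n))
        w[0, 2] = w[2, 0] = 3.0   # module L0 <-> module L1
        w[0, 1] = w[1, 0] = 2.0   # within module L0
        classes = ct.enumerate_connection_classes(part, parc)
        s = ct.class_strengths(w, classes)
        assert s["intrahemispheric:L0-L1"] == 3.0
        assert s["intramodular:L0"] == 2.0

    def test_conservation_every_subject(self, small_cohort):
        classes = ct.enumerate_connection_classes(
            small_cohort.partition, small_cohort.parcellation)
        cort = small_cohort.parcellation.cortical_ids
        cortical_kinds = ("interhemispheric", "intrahemispheric", "intramodular")
        for c in small_cohort.connectomes:
            s = ct.class_strengths(c, classes)
            total = c.weights[np.ix_(cort, cort)].sum() / 2
            summed = sum(s[cl.label] for cl in classes if cl.kind in cortical_kinds)
            assert summed == pytest.approx(total, abs=1e-9 * max(total, 1))

    def test_zeroed_interhemispheric_edges(self, small_cohort):
        parc = small_cohort.parcellation
        classes = ct.enumerate_connection_classes(small_cohort.partition, parc)
        w = small_cohort.connectomes[0].weights.copy()
        before = ct.class_strengths(w, classes)
        left = set(parc.cortical_ids_of("left")) | set(parc.subcortical_block("left"))
        is_left = np.array([i in left for i in range(parc.n_regions)])
        w[np.ix_(is_left, ~is_left)] = 0
        w[np.ix_(~is_left, is_left)] = 0
        after = ct.class_strengths(w, classes)
        for c in classes:
            if c.kind == "interhemispheric":
                assert after[c.label] == 0.0
            elif c.kind != "subcortical_cortical":
                assert after[c.label] == before[c.label]


class TestClassLengths:
    def test_constant_lengths(self):
        parc, part = toy_parcellation(2, 2)
        n = parc.n_regions
        L = np.full((n, n), 7.0)
        np.fill_diagonal(L, 0)
        classes = ct.enumerate_connection_classes(part, parc)
        means, edges = ct.class_lengths(L, classes)
        assert np.allclose(means.to_numpy(), 7.0)
        assert set(edges["kind"]) == set(ct.modules.KINDS)

    def test_two_length_toy(self):
        parc, part = toy_parcellation(2, 1)
        n = parc.n_regions
        L = np.zeros((n, n))
        L[0, 1] = L[1, 0] = 10.0  # within L0
        L[2, 3] = L[3, 2] = 20.0  # within L1
        classes = ct.enumerate_connection_classes(part, parc)
        w = np.zeros((n, n))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        means, _ = ct.class_lengths(L, classes, weights=w)
        assert means["intramodular:L0"] == 10.0
        assert means["intramodular:L1"] == 20.0

    def test_generator_length_ordering(self, small_cohort):
        classes = ct.enumerate_connection_classes(
            small_cohort.partition, small_cohort.parcellation)
        w = small_cohort.connectomes[0].weights
        means, _ = ct.class_lengths(small_cohort.lengths, classes, weights=w)
        kind_mean = means.groupby(
            means.index.map(lambda s: s.split(":")[0])).mean()
        assert kind_mean["subcortical_cortical"] > kind_mean["intramodular"]
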