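"""Cortical module partitioning and connection-type classification.

Cortical regions of a group-averaged connectome are partitioned into modules
by consensus Louvain community detection. Edges are then classified by the
module/hemisphere membership of their endpoints into four connection types:

* ``interhemispheric`` — between a left and a right cortical module,
* ``intrahemispheric`` — between two distinct modules of one hemisphere,
* ``intramodular`` — within a single cortical module,
* ``subcortical_cortical`` — between a hemisphere's subcortical block
  (thalamus, caudate, putamen, pallidum, accumbens, ventral diencephalon)
  and an ipsilateral cortical module.

Each cortical-cortical edge belongs to exactly one class, so class strengths
partition the total cortical edge weight.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .connectome import Connectome
from .parcellation import Parcellation

__all__ = [
    "ModulePartition",
    "ConnectionClass",
    "louvain_consensus",
    "random_partition_null",
    "enumerate_connection_classes",
    "class_strengths",
    "cohort_class_strengths",
    "class_lengths",
    "mean_connectome",
]

KINDS = (
    "interhemispheric",
    "intrahemispheric",
    "intramodular",
    "subcortical_cortical",
)


@dataclass
class ModulePartition:
    """Assignment of cortical regions to modules.

    ``labels`` maps cortical region id -> integer module label. Subcortical
    regions carry no label.
    """

    labels: pd.Series
    gamma: float = 1.0
    provenance: str = "user"

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)

    @property
    def n_modules(self) -> int:
        return self.labels.nunique()

    def module_members(self) -> dict[int, np.ndarray]:
        return {
            int(m): idx.to_numpy()
            for m, idx in self.labels.groupby(self.labels).groups.items()
        }


@dataclass(frozen=True)
class ConnectionClass:
    """One classified module-pair (or block-module pair) connection.

    ``members_a``/``members_b`` are the region-id sets whose spanning edges
    make up the class; for intramodular classes both sets coincide.
    """

    kind: str
    endpoint_a: str
    endpoint_b: str
    members_a: tuple = field(repr=False)
    members_b: tuple = field(repr=False)

    @property
    def label(self) -> str:
        if self.endpoint_a == self.endpoint_b:
            return f"{self.kind}:{self.endpoint_a}"
        return f"{self.kind}:{self.endpoint_a}-{self.endpoint_b}"


# ---------------------------------------------------------------------------
# Louvain consensus partitioning
# ---------------------------------------------------------------------------


def _louvain_once(graph: nx.Graph, gamma: float, seed: int) -> np.ndarray:
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=gamma, seed=int(seed)
    )
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    for k, members in enumerate(comms):
        labels[list(members)] = k
    return labels


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel modules by order of first appearance (permutation-invariant)."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def louvain_consensus(
    group_mean: Connectome | np.ndarray,
    parcellation: Parcellation,
    *,
    gamma: float = 1.0,
    n_runs: int = 1000,
    seed: int | None = None,
    max_iter: int = 20,
) -> ModulePartition:
    """Consensus Louvain partition of the cortical subgraph.

    Runs Louvain ``n_runs`` times with independent seeds, builds the
    co-assignment matrix (fraction of runs in which two regions share a
    module), thresholds it at its own off-diagonal mean and re-clusters the
    thresholded matrix, iterating until every run returns the same partition
    (at most ``max_iter`` rounds). Deterministic given ``seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cort = parcellation.cortical_ids
    w = group_mean.weights if isinstance(group_mean, Connectome) else np.asarray(group_mean)
    if w.shape[0] == parcellation.n_regions:
        w = w[np.ix_(cort, cort)]
    n = w.shape[0]
    n_comp, _ = connected_components(w > 0, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"cortical graph has {n_comp} connected components; "
            "components are partitioned separately"
        )
    rng = np.random.default_rng(seed)

    current = w.copy()
    for _ in range(max_iter):
        graph = nx.from_numpy_array(current)
        seeds = rng.integers(0, 2**31 - 1, size=n_runs)
        runs = np.stack([_canonical(_louvain_once(graph, gamma, s)) for s in seeds])
        if all(np.array_equal(runs[0], r) for r in runs[1:]):
            labels = runs[0]
            break
        co = np.zeros((n, n))
        for r in runs:
            co += r[:, None] == r[None, :]
        co /= n_runs
        np.fill_diagonal(co, 0.0)
        thr = co[np.triu_indices(n, k=1)].mean()
        current = np.where(co > thr, co, 0.0)
    else:
        labels = runs[0]
        warnings.warn("consensus did not converge; returning last partition")

    return ModulePartition(
        labels=pd.Series(labels, index=cort),
        gamma=gamma,
        provenance="louvain_consensus",
    )


def random_partition_null(
    group_mean: Connectome | np.ndarray,
    parcellation: Parcellation,
    *,
    gamma: float = 1.0,
    seed: int | None = None,
) -> ModulePartition:
    """Module partition of a degree-agnostic random graph.

    Builds a random undirected weighted graph with the same number of
    cortical nodes and edges as the observed graph (observed nonzero weights
    shuffled onto uniformly random edges), then runs Louvain on it. The
    resulting labels serve as a negative-control module allocation: they
    carry no anatomical structure, so connection classes built from them mix
    edge types.
    """
    cort = parcellation.cortical_ids
    w = group_mean.weights if isinstance(group_mean, Connectome) else np.asarray(group_mean)
    if w.shape[0] == parcellation.n_regions:
        w = w[np.ix_(cort, cort)]
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    nz = vals[vals > 0]
    rng = np.random.default_rng(seed)
    edge_idx = rng.choice(len(iu[0]), size=len(nz), replace=False)
    rand = np.zeros((n, n))
    rand[iu[0][edge_idx], iu[1][edge_idx]] = rng.permutation(nz)
    rand = rand + rand.T
    labels = _canonical(
        _louvain_once(nx.from_numpy_array(rand), gamma, int(rng.integers(2**31 - 1)))
    )
    return ModulePartition(
        labels=pd.Series(labels, index=cort), gamma=gamma, provenance="random_null"
    )


# ---------------------------------------------------------------------------
# Connection-class enumeration
# ---------------------------------------------------------------------------


def _module_hemispheres(
    partition: ModulePartition, parcellation: Parcellation
) -> dict[int, set]:
    hemi = parcellation.regions["hemisphere"]
    return {
        int(m): set(hemi.loc[members])
        for m, members in partition.module_members().items()
    }


def enumerate_connection_classes(
    partition: ModulePartition,
    parcellation: Parcellation,
    *,
    strict: bool | None = None,
) -> list[ConnectionClass]:
    """Enumerate all connection classes implied by a module partition.

    With ``mL`` left and ``mR`` right hemisphere-pure modules the counts are
    ``mL*mR`` interhemispheric, ``C(mL,2) + C(mR,2)`` intrahemispheric,
    ``mL + mR`` intramodular and ``mL + mR`` subcortical-cortical classes.
    Ordering is deterministic: left before right, ascending module label.

    ``strict`` (default: True except for ``random_null`` partitions) demands
    hemisphere-pure modules and raises on violation. In the relaxed path —
    used for random-allocation negative controls, whose modules mix
    hemispheres by construction — classes are generic cortical module pairs
    (``intramodular`` / ``intermodular``); subcortical blocks, being
    anatomical rather than partition-derived, are left out of the null.
    """
    if strict is None:
        strict = partition.provenance != "random_null"
    members = partition.module_members()
    hemis = _module_hemispheres(partition, parcellation)
    blocks = {
        "left": parcellation.subcortical_block("left"),
        "right": parcellation.subcortical_block("right"),
    }

    mixed = [m for m, h in hemis.items() if len(h) > 1]
    if strict and mixed:
        raise ValueError(
            f"modules {sorted(mixed)} span both hemispheres; "
            "hemisphere-pure modules are required"
        )

    def cc(kind, ea, eb, ma, mb):
        return ConnectionClass(kind, ea, eb, tuple(np.sort(ma)), tuple(np.sort(mb)))

    classes: list[ConnectionClass] = []
    if not mixed:
        by_hemi = {
            h: sorted(m for m in members if hemis[m] == {h})
            for h in ("left", "right")
        }
        tag = {h: h[0].upper() for h in ("left", "right")}
        name = lambda h, m: f"{tag[h]}{m}"
        # interhemispheric: every left module x every right module
        for l in by_hemi["left"]:
            for r in by_hemi["right"]:
                classes.append(cc("interhemispheric", name("left", l),
                                  name("right", r), members[l], members[r]))
        # intrahemispheric: distinct module pairs within a hemisphere
        for h in ("left", "right"):
            for a, b in itertools.combinations(by_hemi[h], 2):
                classes.append(cc("intrahemispheric", name(h, a), name(h, b),
                                  members[a], members[b]))
        # intramodular
        for h in ("left", "right"):
            for m in by_hemi[h]:
                classes.append(cc("intramodular", name(h, m), name(h, m),
                                  members[m], members[m]))
        # subcortical block to ipsilateral modules
        for h in ("left", "right"):
            for m in by_hemi[h]:
                classes.append(cc("subcortical_cortical", f"subcortical_{h}",
                                  name(h, m), blocks[h], members[m]))
    else:
        # Negative-control path: only cortical module-pair classes. The
        # subcortical blocks are anatomical constants that module
        # randomisation cannot scramble, so block-module classes would
        # re-test the main analysis rather than the null.
        mods = sorted(members)
        for a, b in itertools.combinations(mods, 2):
            classes.append(cc("intermodular", f"M{a}", f"M{b}",
                              members[a], members[b]))
        for m in mods:
            classes.append(cc("intramodular", f"M{m}", f"M{m}",
                              members[m], members[m]))
    return classes


# ---------------------------------------------------------------------------
# Class strengths and lengths
# ---------------------------------------------------------------------------


def class_strengths(
    connectome: Connectome | np.ndarray, classes: list[ConnectionClass]
) -> pd.Series:
    """Summed edge weight per connection class (unordered pairs once)."""
    w = connectome.weights if isinstance(connectome, Connectome) else np.asarray(connectome)
    out = {}
    for c in classes:
        a = np.asarray(c.members_a, dtype=int)
        b = np.asarray(c.members_b, dtype=int)
        block = w[np.ix_(a, b)].sum()
        if c.members_a == c.members_b:
            block /= 2.0  # each unordered within-module pair counted twice
        out[c.label] = float(block)
    return pd.Series(out, name="strength")


def cohort_class_strengths(
    connectomes: list[Connectome], classes: list[ConnectionClass]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject class strengths plus a subject metadata table.

    Returns ``(strengths, meta)``: strengths indexed by subject id with one
    column per class label; meta holds group and covariates (age, sex, ...).
    """
    rows, meta = {}, {}
    for c in connectomes:
        rows[c.subject_id] = class_strengths(c, classes)
        meta[c.subject_id] = {"group": c.group, **c.covariates}
    strengths = pd.DataFrame(rows).T
    strengths.index.name = "subject_id"
    meta_df = pd.DataFrame.from_dict(meta, orient="index").infer_objects()
    return strengths, meta_df.rename_axis("subject_id")


def class_lengths(
    length_matrix: np.ndarray,
    classes: list[ConnectionClass],
    *,
    weights: np.ndarray | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Mean streamline length per class, plus edge-level records.

    The per-class mean is unweighted over member region pairs; if a weight
    matrix is supplied only pairs with nonzero connection contribute. The
    second return value lists every contributing edge with its length and
    class label, for edge-level length-loss correlations.
    """
    L = np.asarray(length_matrix, dtype=float)
    if np.abs(L - L.T).max() > 1e-9 or (L < 0).any():
        raise ValueError("length matrix must be symmetric and nonnegative")
    means, records = {}, []
    for c in classes:
        a = np.asarray(c.members_a, dtype=int)
        b = np.asarray(c.members_b, dtype=int)
        if c.members_a == c.members_b:
            ii, jj = np.triu_indices(len(a), k=1)
            pairs_i, pairs_j = a[ii], a[jj]
        else:
            pairs_i = np.repeat(a, len(b))
            pairs_j = np.tile(b, len(a))
        if weights is not None:
            keep = weights[pairs_i, pairs_j] > 0
            pairs_i, pairs_j = pairs_i[keep], pairs_j[keep]
        vals = L[pairs_i, pairs_j]
        means[c.label] = float(vals.mean()) if len(vals) else np.nan
        records.append(pd.DataFrame({
            "region_a": pairs_i, "region_b": pairs_j, "length": vals,
            "class": c.label, "kind": c.kind,
        }))
    edges = pd.concat(records, ignore_index=True) if records else pd.DataFrame()
    return pd.Series(means, name="mean_length"), edges


def mean_connectome(connectomes: list[Connectome], group: str | None = "control") -> np.ndarray:
    """Arithmetic mean weight matrix over (a group's) subjects."""
    mats = [c.weights for c in connectomes if group is None or c.group == group]
    if not mats:
        raise ValueError(f"no connectomes in group {group!r}")
    return np.mean(mats, axis=0)
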