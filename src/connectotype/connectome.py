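"""Subject-level weighted structural connectomes.

Connectomes are dense, symmetric, nonnegative region-by-region matrices of
streamline-derived connection weights. No threshold is applied at load:
thresholding sparse weak edges is deliberately avoided and density is simply
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .parcellation import Parcellation

__all__ = [
    "Connectome",
    "load_connectome",
    "density",
    "topological_distance",
]

GROUPS = ("control", "pd_high", "pd_low")

_SYM_TOL_LOAD = 1e-6
_SYM_TOL_FINAL = 1e-9


@dataclass
class Connectome:
    """One subject's weighted connectivity matrix plus metadata.

    ``weights`` is symmetric with zero diagonal and nonnegative entries,
    ordered by the parcellation's region ids.
    """

    subject_id: str
    group: str
    weights: np.ndarray
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.isnan(w).any():
            raise ValueError("weights contain NaN")
        if (w < 0).any():
            raise ValueError("weights contain negative entries")
        asym = np.abs(w - w.T).max()
        if asym > _SYM_TOL_FINAL:
            raise ValueError(f"weights asymmetric (max |A - A.T| = {asym:g})")
        if np.abs(np.diag(w)).max() > 0:
            raise ValueError("diagonal must be zero")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def load_connectome(
    matrix, parcellation: Parcellation, *, subject_id: str, group: str, **covariates
) -> Connectome:
    """Validate a raw weight matrix against a parcellation.

    Accepts an array or DataFrame. Small numerical asymmetry (below 1e-6)
    is repaired by averaging with the transpose; anything larger is an
    error. The diagonal is zeroed.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.to_numpy(dtype=float)
    w = np.asarray(matrix, dtype=float)
    if w.shape != (parcellation.n_regions, parcellation.n_regions):
        raise ValueError(
            f"matrix shape {w.shape} does not match parcellation size "
            f"{parcellation.n_regions}"
        )
    if np.isnan(w).any():
        raise ValueError("matrix contains NaN entries")
    if (w < 0).any():
        raise ValueError("matrix contains negative weights")
    asym = np.abs(w - w.T).max()
    if asym >= _SYM_TOL_LOAD:
        raise ValueError(
            f"matrix asymmetry {asym:g} exceeds tolerance {_SYM_TOL_LOAD:g}"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return Connectome(subject_id=subject_id, group=group, weights=w,
                      covariates=dict(covariates))


def density(connectome: Connectome | np.ndarray) -> float:
    """Connectome density as a percentage of possible edges present.

    Fraction of off-diagonal unordered region pairs with weight > 0,
    times 100.
    """
    w = connectome.weights if isinstance(connectome, Connectome) else np.asarray(connectome)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    return 100.0 * float(np.count_nonzero(w[iu])) / len(iu[0])


def topological_distance(weights: np.ndarray | Connectome) -> np.ndarray:
    """Shortest weighted path lengths with edge length = 1 / weight.

    Strong connections are short; the distance therefore reflects both
    anatomical routing and connection strength. Unreachable pairs come back
    as NaN (with a warning), mirroring a disconnected graph.
    """
    w = weights.weights if isinstance(weights, Connectome) else np.asarray(weights, float)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(lengths, directed=False)
    if np.isinf(d).any():
        warnings.warn("graph is disconnected; unreachable pairs set to NaN")
        d[np.isinf(d)] = np.nan
    np.fill_diagonal(d, 0.0)
    return d
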