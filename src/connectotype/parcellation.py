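"""Parcellation data model: the node universe of the connectome.

A parcellation fixes the region order for every matrix in the analysis:
cortical regions (with spherical centroids, one unit sphere per hemisphere)
and subcortical regions. The default study layout is 360 cortical regions
(180 per hemisphere) plus 19 subcortical, 379 in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Parcellation", "SUBCORTICAL_BLOCK_STRUCTURES"]

#: Subcortical structures forming the per-hemisphere "subcortical block" used
#: in subcortical-cortical connection classes (basal ganglia + thalamus +
#: ventral diencephalon). Other subcortical regions (e.g. brainstem,
#: cerebellum, hippocampus, amygdala) are carried in the parcellation but do
#: not enter any connection class.
SUBCORTICAL_BLOCK_STRUCTURES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
    "ventraldc",
)

_CENTROID_TOL = 1e-6


@dataclass
class Parcellation:
    """Region lookup table plus cortical centroids.

    Parameters
    ----------
    regions
        DataFrame indexed by contiguous 0-based ``region_id`` with columns
        ``name`` (str), ``hemisphere`` ({'left', 'right'}), ``region_class``
        ({'cortical', 'subcortical'}) and optionally ``module`` (planted or
        assigned module label, cortical rows only).
    centroids
        DataFrame indexed by cortical ``region_id`` with columns x, y, z;
        unit-norm points on the per-hemisphere sphere.
    """

    regions: pd.DataFrame
    centroids: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        r = self.regions
        ids = np.asarray(r.index)
        if not np.array_equal(ids, np.arange(len(r))):
            raise ValueError("region ids must be unique and contiguous from 0")
        bad_hemi = set(r["hemisphere"]) - {"left", "right"}
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        bad_cls = set(r["region_class"]) - {"cortical", "subcortical"}
        if bad_cls:
            raise ValueError(f"unknown region classes: {sorted(bad_cls)}")
        if self.centroids is not None:
            c = self.centroids
            missing = set(self.cortical_ids) - set(c.index)
            if missing:
                raise ValueError(
                    f"{len(missing)} cortical regions lack centroids"
                )
            xyz = c.loc[self.cortical_ids, ["x", "y", "z"]].to_numpy(float)
            if not np.all(np.isfinite(xyz)):
                raise ValueError("non-finite centroid coordinates")
            norms = np.linalg.norm(xyz, axis=1)
            if np.any(np.abs(norms - 1.0) > _CENTROID_TOL):
                raise ValueError("cortical centroids must have unit norm")

    # -- derived index sets -------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def cortical_ids(self) -> np.ndarray:
        return self.regions.index[
            self.regions["region_class"] == "cortical"
        ].to_numpy()

    @property
    def subcortical_ids(self) -> np.ndarray:
        return self.regions.index[
            self.regions["region_class"] == "subcortical"
        ].to_numpy()

    def cortical_ids_of(self, hemisphere: str) -> np.ndarray:
        m = (self.regions["region_class"] == "cortical") & (
            self.regions["hemisphere"] == hemisphere
        )
        return self.regions.index[m].to_numpy()

    def subcortical_block(self, hemisphere: str) -> np.ndarray:
        """Region ids of the hemisphere's subcortical block.

        Membership is by name: a subcortical region whose lower-cased name
        contains one of :data:`SUBCORTICAL_BLOCK_STRUCTURES`.
        """
        sub = self.regions[
            (self.regions["region_class"] == "subcortical")
            & (self.regions["hemisphere"] == hemisphere)
        ]
        names = sub["name"].str.lower().str.replace("[^a-z]", "", regex=True)
        keep = names.apply(
            lambda s: any(k in s for k in SUBCORTICAL_BLOCK_STRUCTURES)
        )
        return sub.index[keep].to_numpy()

    def hemisphere_of(self, region_ids) -> pd.Series:
        return self.regions.loc[region_ids, "hemisphere"]

    def cortical_centroids(self, hemisphere: str | None = None) -> pd.DataFrame:
        ids = (
            self.cortical_ids
            if hemisphere is None
            else self.cortical_ids_of(hemisphere)
        )
        return self.centroids.loc[ids, ["x", "y", "z"]]

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tables(
        cls, lookup: pd.DataFrame, centroids: pd.DataFrame | None = None
    ) -> "Parcellation":
        """Build from a lookup table (region_id, name, hemisphere, class)."""
        lut = lookup.rename(columns={"class": "region_class"}).copy()
        lut = lut.set_index("region_id").sort_index()
        cen = None
        if centroids is not None:
            cen = centroids.set_index("region_id").sort_index()
        return cls(lut, cen)
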