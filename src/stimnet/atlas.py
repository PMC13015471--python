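"""Parcel atlas container.

A parcellation reduces the brain to a few hundred regions ("parcels"); every
connectivity quantity downstream is defined at parcel resolution.  Parcels are
identified by contiguous integer ids starting at 1, and each carries a centroid
in millimetres (arbitrary right-handed frame, no template registration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ParcelAtlas"]


@dataclass
class ParcelAtlas:
    """Table of parcels: id, name, centroid (mm), hemisphere.

    Parameters
    ----------
    ids
        Integer parcel ids, unique and contiguous from 1.
    names
        Human-readable labels, one per parcel.
    centroids
        ``(n_parcels, 3)`` array of centroid coordinates in mm.
    hemispheres
        ``"L"`` or ``"R"`` per parcel.
    """

    ids: np.ndarray
    names: list[str] = field(repr=False)
    centroids: np.ndarray = field(repr=False)
    hemispheres: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        n = self.ids.size
        if n < 1:
            raise ValueError("atlas must contain at least one parcel")
        if not np.array_equal(np.sort(self.ids), np.arange(1, n + 1)):
            raise ValueError("parcel ids must be unique and contiguous from 1")
        if self.centroids.shape != (n, 3):
            raise ValueError("centroids must have shape (n_parcels, 3)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def n_parcels(self) -> int:
        return self.ids.size

    def index_of(self, parcel_id: int) -> int:
        """0-based row index of a parcel id (ids are contiguous from 1)."""
        idx = int(parcel_id) - 1
        if idx < 0 or idx >= self.n_parcels:
            raise KeyError(f"parcel id {parcel_id} not in atlas")
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "name": self.names,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
                "hemisphere": self.hemispheres,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcelAtlas":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("id").reset_index(drop=True)
        return cls(
            ids=df["id"].to_numpy(),
            names=df["name"].astype(str).tolist(),
            centroids=df[["x", "y", "z"]].to_numpy(float),
            hemispheres=df["hemisphere"].astype(str).tolist(),
        )
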