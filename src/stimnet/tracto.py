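"""ChaCo-style structural connectivity profiles of spherical stimulation masks.

A stimulation site is modelled as a sphere (default radius 12 mm) centred at
the bipolar electrode midpoint.  Against a normative tractogram — streamline
polylines whose endpoints carry parcel labels — the site's structural
footprint is summarised by ChaCo (Change in Connectivity) ratios:

* pairwise ChaCo of a parcel pair = fraction of the streamlines connecting
  that pair which pass through the sphere;
* cumulative ChaCo of a parcel   = sum of its pairwise ratios over all
  partner parcels (can exceed 1).

Intersection is decided geometrically: the minimum point-to-segment distance
from the sphere centre to any polyline segment is compared to the radius.
This is exact and resolution-free, a deliberate analogue of voxel-mask
intersection schemes used with normative connectome databases.

Parcel pairs connected by zero streamlines receive ratio 0.  The resulting
zero-inflated, right-skewed distribution of connectivity values is the reason
downstream association mapping defaults to Kendall's tau-b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .atlas import ParcelAtlas

__all__ = [
    "Streamline",
    "Tractogram",
    "StimulationSite",
    "ChaCoProfile",
    "streamline_intersects_sphere",
    "pairwise_chaco",
    "cumulative_chaco",
    "normative_average",
]


@dataclass
class Streamline:
    """One tractography streamline: an ordered 3D polyline with endpoint labels."""

    vertices: np.ndarray  # (k, 3) mm
    parcel_a: int
    parcel_b: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (k, 3)")
        if self.vertices.shape[0] < 2:
            raise ValueError("a streamline needs at least 2 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("streamline vertices must be finite")


@dataclass
class Tractogram:
    """Collection of labelled streamlines; the structural substrate."""

    streamlines: list[Streamline]
    _packed: dict | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.streamlines)

    # Segment arrays are packed once and cached so that per-site sphere
    # queries are a single vectorized pass over all segments.
    def packed(self) -> dict:
        if self._packed is None:
            starts, ends, owner = [], [], []
            for i, sl in enumerate(self.streamlines):
                v = sl.vertices
                starts.append(v[:-1])
                ends.append(v[1:])
                owner.append(np.full(v.shape[0] - 1, i, dtype=np.intp))
            self._packed = {
                "seg_a": np.concatenate(starts) if starts else np.empty((0, 3)),
                "seg_b": np.concatenate(ends) if ends else np.empty((0, 3)),
                "owner": np.concatenate(owner) if owner else np.empty(0, dtype=np.intp),
                "parcel_a": np.array([s.parcel_a for s in self.streamlines], dtype=int),
                "parcel_b": np.array([s.parcel_b for s in self.streamlines], dtype=int),
            }
        return self._packed

    def translate(self, offset) -> "Tractogram":
        off = np.asarray(offset, dtype=float)
        return Tractogram(
            [Streamline(s.vertices + off, s.parcel_a, s.parcel_b) for s in self.streamlines]
        )

    def to_jsonl(self, path) -> None:
        """Write the JSON-lines dialect: one streamline object per line."""
        with open(path, "w") as fh:
            for s in self.streamlines:
                fh.write(
                    json.dumps(
                        {
                            "parcel_a": int(s.parcel_a),
                            "parcel_b": int(s.parcel_b),
                            "vertices": [[float(c) for c in v] for v in s.vertices],
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "Tractogram":
        streamlines = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                streamlines.append(
                    Streamline(np.asarray(rec["vertices"], float), rec["parcel_a"], rec["parcel_b"])
                )
        return cls(streamlines)


@dataclass
class StimulationSite:
    """Spherical stimulation mask plus site-level covariates.

    ``wmp`` is the white-matter proximity: shortest distance (mm) from the
    site to the gray–white matter interface.  ``baseline_recall`` is the
    site's non-stimulated recall fraction.
    """

    site_id: str
    center: np.ndarray  # (3,) mm
    radius: float = 12.0
    mode: str = "closed"
    wmp: float = 0.0
    baseline_recall: float | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.wmp < 0:
            raise ValueError("wmp must be non-negative")
        if self.mode not in ("closed", "random"):
            raise ValueError("mode must be 'closed' or 'random'")


@dataclass
class ChaCoProfile:
    """Structural connectivity profile of one site.

    ``pairwise`` is a symmetric (n_parcels, n_parcels) matrix of intersection
    ratios in [0, 1]; ``cumulative`` sums each parcel's pairwise ratios over
    its partners.
    """

    site_id: str
    pairwise: np.ndarray
    cumulative: np.ndarray

    def to_tsv(self, path, atlas: ParcelAtlas) -> None:
        pd.DataFrame(
            {"parcel_id": atlas.ids, "cumulative_chaco": self.cumulative}
        ).to_csv(path, sep="\t", index=False)


def _min_dist_to_segments(center: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from a point to each segment [a_i, b_i] (vectorized)."""
    d = b - a
    len2 = np.einsum("ij,ij->i", d, d)
    ca = center[None, :] - a
    t = np.zeros_like(len2)
    nz = len2 > 0
    t[nz] = np.clip(np.einsum("ij,ij->i", ca[nz], d[nz]) / len2[nz], 0.0, 1.0)
    closest = a + t[:, None] * d
    return np.linalg.norm(center[None, :] - closest, axis=1)


def streamline_intersects_sphere(streamline: Streamline, center, radius: float) -> bool:
    """True iff any polyline segment comes within ``radius`` of ``center``.

    Uses exact point-to-segment distances (not vertex-only sampling), so a
    straight segment passing through the sphere between two distant vertices
    is correctly detected.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    v = np.asarray(streamline.vertices, float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("invalid streamline: fewer than 2 vertices")
    c = np.asarray(center, float).reshape(3)
    dists = _min_dist_to_segments(c, v[:-1], v[1:])
    return bool(np.min(dists) <= radius)


def _intersection_mask(tractogram: Tractogram, center, radius: float) -> np.ndarray:
    """Boolean per-streamline intersection flags for one sphere."""
    packed = tractogram.packed()
    c = np.asarray(center, float).reshape(3)
    dists = _min_dist_to_segments(c, packed["seg_a"], packed["seg_b"])
    hit = np.zeros(len(tractogram), dtype=bool)
    seg_hit = dists <= radius
    if seg_hit.any():
        np.logical_or.at(hit, packed["owner"][seg_hit], True)
    return hit


def pairwise_chaco(tractogram: Tractogram, site: StimulationSite, atlas: ParcelAtlas) -> np.ndarray:
    """Pairwise ChaCo matrix: per parcel pair, the fraction of its streamlines
    intersecting the site sphere.  Pairs with no streamlines get 0."""
    if len(tractogram) == 0:
        raise ValueError("tractogram is empty")
    n = atlas.n_parcels
    packed = tractogram.packed()
    hit = _intersection_mask(tractogram, site.center, site.radius)
    ia = packed["parcel_a"] - 1
    ib = packed["parcel_b"] - 1
    if ia.min() < 0 or ib.min() < 0 or ia.max() >= n or ib.max() >= n:
        raise ValueError("streamline endpoint parcel id outside atlas")
    # unordered pair -> flat index
    lo = np.minimum(ia, ib)
    hi = np.maximum(ia, ib)
    flat = lo * n + hi
    total = np.bincount(flat, minlength=n * n).reshape(n, n).astype(float)
    inter = np.bincount(flat[hit], minlength=n * n).reshape(n, n).astype(float)
    ratio = np.zeros((n, n), dtype=float)
    nz = total > 0
    ratio[nz] = inter[nz] / total[nz]
    # symmetrize (upper triangle holds the counts)
    ratio = np.maximum(ratio, ratio.T)
    return ratio


def cumulative_chaco(pairwise: np.ndarray, atlas: ParcelAtlas) -> np.ndarray:
    """Per-parcel cumulative ChaCo: sum of pairwise ratios over all partners."""
    pw = np.asarray(pairwise, float)
    if pw.shape != (atlas.n_parcels, atlas.n_parcels):
        raise ValueError("pairwise matrix shape does not match atlas")
    return pw.sum(axis=1)


def chaco_profile(tractogram: Tractogram, site: StimulationSite, atlas: ParcelAtlas) -> ChaCoProfile:
    """Convenience: pairwise + cumulative ChaCo for one site."""
    pw = pairwise_chaco(tractogram, site, atlas)
    return ChaCoProfile(site.site_id, pw, cumulative_chaco(pw, atlas))


def normative_average(profiles: list[ChaCoProfile], atlas: ParcelAtlas) -> ChaCoProfile:
    """Average ChaCo profiles of one site over several normative tractograms.

    Element-wise mean of the pairwise ratios; cumulative recomputed from the
    averaged pairwise matrix.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    shape = (atlas.n_parcels, atlas.n_parcels)
    for p in profiles:
        if p.pairwise.shape != shape:
            raise ValueError("profiles computed against mismatched atlases")
    pw = np.mean([p.pairwise for p in profiles], axis=0)
    return ChaCoProfile(profiles[0].site_id, pw, cumulative_chaco(pw, atlas))
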