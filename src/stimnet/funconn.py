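"""Seed-based functional connectivity of stimulation sites.

The seed series of a site is the unweighted mean of the task time series of
all parcels whose centroid falls inside the site sphere (nearest parcel if
none).  Per subject, functional connectivity to every atlas parcel is the
Pearson correlation between the seed series and that parcel's series; the
normative profile averages the raw r maps over subjects.  Task-evoked
structure is deliberately left in the series — coactivation during encoding
is the signal of interest, so no nuisance regression is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .tracto import StimulationSite

__all__ = ["FCProfile", "site_timeseries", "seed_fc", "normative_fc"]


@dataclass
class FCProfile:
    """Per-parcel Pearson r of one site's seed series; ``flags`` marks parcels
    whose correlation was undefined (zero variance) and recorded as 0."""

    site_id: str
    r: np.ndarray
    flags: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        if self.flags is None:
            self.flags = np.zeros(self.r.size, dtype=bool)

    def to_tsv(self, path, atlas: ParcelAtlas) -> None:
        pd.DataFrame({"parcel_id": atlas.ids, "r": self.r}).to_csv(
            path, sep="\t", index=False
        )


def site_timeseries(
    site: StimulationSite, atlas: ParcelAtlas, subject_timeseries: np.ndarray
) -> np.ndarray:
    """Seed time series of a site from one subject's (parcels x time) matrix.

    Unweighted mean over parcels whose centroid lies within the sphere; if no
    centroid is inside, the single nearest parcel's series is used.
    """
    ts = np.asarray(subject_timeseries, float)
    if ts.ndim != 2 or ts.shape[0] != atlas.n_parcels:
        raise ValueError("subject_timeseries must be (n_parcels, n_timepoints)")
    if ts.shape[1] == 0:
        raise ValueError("empty time series")
    dist = np.linalg.norm(atlas.centroids - site.center[None, :], axis=1)
    inside = dist <= site.radius
    if not inside.any():
        inside = dist == dist.min()
    return ts[inside].mean(axis=0)


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of each row of ``rows`` against ``y``; zero-variance
    rows (or y) give r=0 with a flag."""
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    xc = rows - rows.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    denom = sx * sy
    bad = denom == 0
    r = np.zeros(rows.shape[0])
    if not bad.all():
        r[~bad] = (xc[~bad] @ yc) / denom[~bad]
    return np.clip(r, -1.0, 1.0), bad


def seed_fc(
    site: StimulationSite, atlas: ParcelAtlas, subject_timeseries: np.ndarray
) -> FCProfile:
    """Single-subject FC profile: Pearson r between the site seed series and
    every parcel's series (self-parcels included)."""
    ts = np.asarray(subject_timeseries, float)
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    seed = site_timeseries(site, atlas, ts)
    r, bad = _pearson_rows(ts, seed)
    return FCProfile(site.site_id, r, bad)


def normative_fc(
    site: StimulationSite,
    atlas: ParcelAtlas,
    all_subject_timeseries: list[np.ndarray],
    fisher_z: bool = False,
) -> FCProfile:
    """Normative FC profile: mean of per-subject r maps.

    Raw r values are averaged by default; ``fisher_z=True`` averages
    arctanh-transformed values and back-transforms the mean.
    """
    if not all_subject_timeseries:
        raise ValueError("need at least one subject")
    profiles = [seed_fc(site, atlas, ts) for ts in all_subject_timeseries]
    rs = np.stack([p.r for p in profiles])
    if fisher_z:
        z = np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12))
        mean_r = np.tanh(z.mean(axis=0))
    else:
        mean_r = rs.mean(axis=0)
    flags = np.any([p.flags for p in profiles], axis=0)
    return FCProfile(site.site_id, mean_r, flags)
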