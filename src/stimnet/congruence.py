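"""Structure-function congruence: dual thresholding, Dice overlap, and the
threshold-grid sweep with FDR control.

The verbal-encoding network (a parcel weight map) and a site's cumulative
ChaCo profile are each binarized — the network by keeping a top fraction of
positively weighted parcels, the connectivity profile by a strict cutoff —
and their spatial overlap is summarized by the Dice coefficient

    dice(A, B) = 2|A n B| / (|A| + |B|).

Per-site Dice values are then related to memory change by Spearman rank
correlation.  Because the binarization thresholds are analysis choices, the
association is swept over a 10 x 6 grid (network fractions 0.1..1.0 by 0.1;
connectivity cutoffs {0.001, 0.01, 0.1, 1, 10, 50}, log-spaced between the
endpoints) with Benjamini-Hochberg FDR control across the grid.  The
representative cell is (top 30%, cutoff 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .behavior import spearman_rho

__all__ = [
    "NETWORK_THRESHOLDS",
    "SC_THRESHOLDS",
    "REPRESENTATIVE_CELL",
    "threshold_network",
    "threshold_sc",
    "dice",
    "site_dice",
    "congruence_association",
    "grid_sweep",
    "CongruenceGrid",
]

NETWORK_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.1, 1))
SC_THRESHOLDS: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 50.0)
REPRESENTATIVE_CELL: tuple[float, float] = (0.3, 1.0)


def threshold_network(weights, top_fraction: float) -> np.ndarray:
    """Binary mask of the top fraction of positively weighted parcels.

    Among parcels with weight > 0, the ceil(top_fraction * count) highest are
    selected; ties are broken by parcel id (lower id wins).
    """
    w = np.asarray(weights, float)
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    pos = np.flatnonzero(w > 0)
    mask = np.zeros(w.size, dtype=bool)
    if pos.size == 0:
        return mask
    k = int(np.ceil(top_fraction * pos.size))
    # stable sort on (-weight, id): mergesort on descending weight keeps id order
    order = pos[np.argsort(-w[pos], kind="stable")]
    mask[order[:k]] = True
    return mask


def threshold_sc(cumulative_chaco, tau: float) -> np.ndarray:
    """Binary mask of parcels with cumulative ChaCo strictly above ``tau``."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return np.asarray(cumulative_chaco, float) > tau


def dice(mask_a, mask_b) -> float:
    """Dice similarity coefficient of two binary parcel masks.

    Both masks empty is a degenerate overlap and returns 0.
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share the same parcel universe")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def site_dice(
    cumulative_profiles: np.ndarray,
    encoding_weights,
    top_fraction: float,
    tau: float,
) -> np.ndarray:
    """Per-site Dice congruence between each site's thresholded cumulative
    ChaCo profile and the thresholded encoding network."""
    profiles = np.atleast_2d(np.asarray(cumulative_profiles, float))
    net_mask = threshold_network(encoding_weights, top_fraction)
    return np.array([dice(threshold_sc(row, tau), net_mask) for row in profiles])


@dataclass
class CongruenceResult:
    rho: float
    p: float
    dice_values: np.ndarray
    degenerate: bool


def congruence_association(
    cumulative_profiles,
    encoding_weights,
    top_fraction: float,
    tau: float,
    deltas,
) -> CongruenceResult:
    """Spearman correlation between per-site Dice congruence and memory change."""
    deltas = np.asarray(deltas, float)
    profiles = np.atleast_2d(np.asarray(cumulative_profiles, float))
    if profiles.shape[0] < 5:
        raise ValueError("need at least 5 sites")
    if profiles.shape[0] != deltas.size:
        raise ValueError("profiles and deltas must align")
    d = site_dice(profiles, encoding_weights, top_fraction, tau)
    net_empty = not threshold_network(encoding_weights, top_fraction).any()
    if net_empty or np.all(d == d[0]):
        return CongruenceResult(np.nan, np.nan, d, True)
    rho, p = spearman_rho(d, deltas)
    return CongruenceResult(rho, p, d, False)


@dataclass
class CongruenceGrid:
    """Full threshold-grid sweep with BH-FDR q-values."""

    table: pd.DataFrame  # net_thr, sc_thr, rho, p, q, n_sites, degenerate_flag

    def cell(self, net_thr: float, sc_thr: float) -> pd.Series:
        t = self.table
        row = t[(np.isclose(t.net_thr, net_thr)) & (np.isclose(t.sc_thr, sc_thr))]
        if row.empty:
            raise KeyError(f"no grid cell at ({net_thr}, {sc_thr})")
        return row.iloc[0]

    @property
    def representative(self) -> pd.Series:
        return self.cell(*REPRESENTATIVE_CELL)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def grid_sweep(
    cumulative_profiles,
    encoding_weights,
    deltas,
    network_thresholds=NETWORK_THRESHOLDS,
    sc_thresholds=SC_THRESHOLDS,
    fdr_alpha: float = 0.05,
) -> CongruenceGrid:
    """Sweep the Dice-congruence association over the full threshold grid.

    BH-FDR is applied across all non-degenerate cells; degenerate cells
    (empty or constant masks) are excluded from the FDR family and flagged.
    """
    deltas = np.asarray(deltas, float)
    profiles = np.atleast_2d(np.asarray(cumulative_profiles, float))
    rows = []
    for nt in network_thresholds:
        for st in sc_thresholds:
            res = congruence_association(profiles, encoding_weights, nt, st, deltas)
            rows.append(
                {
                    "net_thr": nt,
                    "sc_thr": st,
                    "rho": res.rho,
                    "p": res.p,
                    "n_sites": profiles.shape[0],
                    "degenerate_flag": res.degenerate,
                }
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    valid = ~table["degenerate_flag"]
    if valid.any():
        _, q, _, _ = multipletests(table.loc[valid, "p"].to_numpy(), method="fdr_bh")
        table.loc[valid, "q"] = q
    table["significant_flag"] = (table["q"] < fdr_alpha) & valid
    return CongruenceGrid(table)
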