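"""Parcelwise connectivity-behavior association maps with max-statistic
family-wise error correction.

For each atlas parcel, the association between a site-level connectivity
value (structural: Kendall tau-b; functional: Pearson r) and the memory
change score is computed across sites.  Family-wise error over parcels is
controlled by the max-statistic permutation procedure: on each permutation
the delta scores are shuffled across sites jointly for all parcels
(preserving the inter-parcel correlation of connectivity), every parcel
statistic is recomputed, and the maximum absolute statistic is retained as
one draw of the null.  Corrected p-values use the add-one estimator

    p_corr = (1 + #{perm maxima >= |observed|}) / (1 + n_perm)

which can never return 0.  Uncorrected p-values come from each parcel's own
permutation distribution, so p_corr >= p_uncorr holds exactly.

Statistics are permuted on their own scale (|tau-b| or |r|), not converted
to t or z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AssociationMap", "parcelwise_association", "maxstat_correct"]


@dataclass
class AssociationMap:
    """Per-parcel association statistics with permutation-corrected p-values."""

    statistic: np.ndarray
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray
    flags: np.ndarray  # parcels with undefined statistics (constant input)
    method: str
    n_perm: int
    seed: int | None

    def to_frame(self, parcel_ids=None) -> pd.DataFrame:
        ids = parcel_ids if parcel_ids is not None else np.arange(1, self.statistic.size + 1)
        return pd.DataFrame(
            {
                "parcel_id": ids,
                "statistic": self.statistic,
                "p_uncorrected": self.p_uncorrected,
                "p_corrected": self.p_corrected,
                "significant_flag": self.significant,
                "undefined_flag": self.flags,
            }
        )

    def to_tsv(self, path, parcel_ids=None) -> None:
        self.to_frame(parcel_ids).to_csv(path, sep="\t", index=False)


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _sign_pairs(x: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    return np.sign(x[..., ii] - x[..., jj])


def _kendall_stats(sign_x: np.ndarray, denom_x: np.ndarray, y: np.ndarray,
                   ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """tau-b per parcel from precomputed per-parcel sign matrices.

    ``sign_x``: (P, m) pairwise signs per parcel; ``denom_x``: (P,) the
    tie-corrected term (n0 - n1) per parcel; returns 0 where undefined.
    """
    sy = _sign_pairs(y, ii, jj)
    m = sy.size
    n2 = m - np.count_nonzero(sy)
    denom = np.sqrt(denom_x * (m - n2))
    num = sign_x @ sy
    tau = np.zeros(sign_x.shape[0])
    ok = denom > 0
    tau[ok] = num[ok] / denom[ok]
    return np.clip(tau, -1.0, 1.0)


def _pearson_stats(xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r per column of pre-standardized ``xs`` against raw y."""
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        return np.zeros(xs.shape[1])
    return np.clip(xs.T @ (yc / sy), -1.0, 1.0)


def _prepare(conn: np.ndarray, deltas: np.ndarray, method: str):
    conn = np.asarray(conn, float)
    deltas = np.asarray(deltas, float)
    if conn.ndim != 2:
        raise ValueError("conn_matrix must be 2-D (sites x parcels)")
    if conn.shape[0] != deltas.size:
        raise ValueError("rows of conn_matrix must align with deltas")
    if conn.shape[0] < 5:
        raise ValueError("need at least 5 sites")
    if method not in ("kendall", "pearson"):
        raise ValueError("method must be 'kendall' or 'pearson'")
    flags = np.ptp(conn, axis=0) == 0
    if np.ptp(deltas) == 0:
        flags = np.ones(conn.shape[1], dtype=bool)
    return conn, deltas, flags


def parcelwise_association(conn_matrix, deltas, method: str = "kendall") -> tuple[np.ndarray, np.ndarray]:
    """One association coefficient per parcel column of ``conn_matrix``.

    Returns ``(statistics, flags)`` where flagged parcels (constant
    connectivity column or constant deltas) carry statistic 0.
    """
    conn, deltas, flags = _prepare(conn_matrix, deltas, method)
    n = conn.shape[0]
    if method == "kendall":
        ii, jj = _pair_indices(n)
        sign_x = _sign_pairs(conn.T, ii, jj)
        m = ii.size
        denom_x = m - (sign_x == 0).sum(axis=1)
        stats_vec = _kendall_stats(sign_x, denom_x, deltas, ii, jj)
    else:
        xc = conn - conn.mean(axis=0)
        sx = np.sqrt((xc**2).sum(axis=0))
        xs = np.where(sx > 0, xc / np.where(sx > 0, sx, 1.0), 0.0)
        stats_vec = _pearson_stats(xs, deltas)
    stats_vec = np.where(flags, 0.0, stats_vec)
    return stats_vec, flags


def maxstat_correct(
    conn_matrix,
    deltas,
    method: str = "kendall",
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> AssociationMap:
    """Max-statistic permutation FWE correction over parcels."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    conn, deltas, flags = _prepare(conn_matrix, deltas, method)
    n, n_parcels = conn.shape
    rng = np.random.default_rng(seed)

    if method == "kendall":
        ii, jj = _pair_indices(n)
        sign_x = _sign_pairs(conn.T, ii, jj)
        m = ii.size
        denom_x = m - (sign_x == 0).sum(axis=1)

        def stat_fn(y):
            return _kendall_stats(sign_x, denom_x, y, ii, jj)
    else:
        xc = conn - conn.mean(axis=0)
        sx = np.sqrt((xc**2).sum(axis=0))
        xs = np.where(sx > 0, xc / np.where(sx > 0, sx, 1.0), 0.0)

        def stat_fn(y):
            return _pearson_stats(xs, y)

    observed = np.where(flags, 0.0, stat_fn(deltas))
    abs_obs = np.abs(observed)
    count_unc = np.zeros(n_parcels, dtype=np.int64)
    count_max = np.zeros(n_parcels, dtype=np.int64)
    active = ~flags
    for _ in range(n_perm):
        perm_stats = np.abs(stat_fn(rng.permutation(deltas)))
        perm_stats[flags] = 0.0
        count_unc += perm_stats >= abs_obs
        if active.any():
            count_max += perm_stats[active].max() >= abs_obs
    p_unc = (1.0 + count_unc) / (1.0 + n_perm)
    p_corr = (1.0 + count_max) / (1.0 + n_perm)
    p_unc[flags] = 1.0
    p_corr[flags] = 1.0
    significant = (p_corr < alpha) & ~flags
    return AssociationMap(
        statistic=observed,
        p_uncorrected=p_unc,
        p_corrected=p_corr,
        significant=significant,
        flags=flags,
        method=method,
        n_perm=n_perm,
        seed=seed,
    )
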