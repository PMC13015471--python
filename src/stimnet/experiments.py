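"""Replicate-level validation studies of the pipeline.

These routines run the package end to end on synthetic cohorts to measure
the properties that matter for trusting the statistics on real data:
worked-example arithmetic on published summary numbers, family-wise error
and false-discovery calibration under a global null, bootstrap type-I
calibration, and recovery of planted effects at realistic cohort sizes.
They are shared by the validation test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as bh
from . import congruence as cg
from . import permmap as pm
from . import plspath as pls
from . import synthdata as sd

__all__ = [
    "worked_examples",
    "fixed_substrate",
    "cohort_replicates",
    "fwer_null",
    "bootstrap_type1",
    "grid_fdr_null",
]


def worked_examples() -> dict:
    """Arithmetic on published cohort summaries.

    One-sample t statistics from printed mean/SEM pairs (closed-loop cohort
    12.4 +/- 4.18, n=39; low-baseline subgroup 21.54 +/- 6.44, n=21;
    high-baseline subgroup 2.80 +/- 3.30, n=18) and the product-of-paths
    mediation decomposition (a=-0.302, b=0.493, total=-0.343).
    """
    t_closed, _ = bh.t_from_summary(12.4, 4.18, df=38)
    t_low, _ = bh.t_from_summary(21.54, 6.44, df=20)
    t_high, _ = bh.t_from_summary(2.80, 3.30, df=17)
    a, b, total = -0.302, 0.493, -0.343
    indirect = a * b
    proportion = indirect / total
    return {
        "t_closed": t_closed,
        "t_low_baseline": t_low,
        "t_high_baseline": t_high,
        "mediation_indirect": indirect,
        "proportion_mediated_pct": 100.0 * proportion,
        "dice_worked_example": cg.dice(
            np.array([True, True, False, False]), np.array([False, True, True, False])
        ),
    }


def fixed_substrate(seed: int, **config_overrides):
    """One normative substrate (atlas, tractogram, encoding network) shared
    by all cohort replicates, mirroring a single normative connectome."""
    cfg = sd.SynthConfig(seed=seed, **config_overrides)
    atlas = sd.generate_atlas(cfg.n_parcels, cfg.seed)
    tractogram = sd.generate_tractogram(atlas, cfg)
    weights = sd.generate_encoding_network(atlas, 12, cfg.seed)
    return atlas, tractogram, weights


def _moderation_p(table: pd.DataFrame, n_boot: int, seed: int) -> float:
    spec = pls.PathModelSpec(
        blocks={"congruence": ["dice"], "mode": ["mode_flag"], "memory": ["delta"]},
        paths=[("congruence", "memory"), ("mode", "memory")],
        moderations=[("mode", "congruence", "memory")],
        n_boot=n_boot,
        seed=seed,
    )
    boot = pls.bootstrap_inference(spec, pls.preprocess_indicators(table))
    return float(boot.path_row("mode*congruence", "memory").p)


def cohort_replicates(
    n_reps: int,
    seed: int,
    n_boot_moderation: int = 200,
    **config_overrides,
) -> pd.DataFrame:
    """Per-replicate planted-effect recovery on fresh synthetic cohorts.

    Returns one row per replicate with the recovered congruence Spearman rho
    (closed-loop), the baseline-vs-delta Pearson r (closed-loop), the
    moderation interaction p (all sites), and the closed-loop mean delta.
    """
    atlas, tractogram, weights = fixed_substrate(seed, **config_overrides)
    top, tau = cg.REPRESENTATIVE_CELL
    rows = []
    for i in range(n_reps):
        cfg = sd.SynthConfig(seed=seed + 1000 + i, **config_overrides)
        sites, sessions, cum = sd.generate_cohort(
            atlas, tractogram, weights, cfg, return_profiles=True
        )
        outs = {o.site_id: o for o in (bh.memory_change(s) for s in sessions)
                if o.included}
        keep = [j for j, s in enumerate(sites) if s.site_id in outs]
        deltas = np.array([outs[sites[j].site_id].delta for j in keep])
        mode = np.array([1.0 if sites[j].mode == "closed" else 0.0 for j in keep])
        dice = cg.site_dice(cum[keep], weights, top, tau)
        closed = mode == 1.0
        rho, _ = bh.spearman_rho(dice[closed], deltas[closed])
        r_ns = np.array([outs[sites[j].site_id].r_ns for j in keep])
        r_base, _ = bh.pearson_r(r_ns[closed], deltas[closed])
        table = pd.DataFrame({"dice": dice, "mode_flag": mode, "delta": deltas})
        p_mod = _moderation_p(table, n_boot_moderation, seed=seed + 5000 + i)
        rows.append(
            {
                "rho": rho,
                "baseline_r": r_base,
                "moderation_p": p_mod,
                "mean_delta_closed": deltas[closed].mean(),
                "n_closed": int(closed.sum()),
            }
        )
    return pd.DataFrame(rows)


def _null_substrate(seed: int, **config_overrides):
    """Closed-loop cumulative profiles from one cohort, for null calibration
    (deltas are redrawn independently of connectivity on every replicate)."""
    atlas, tractogram, weights = fixed_substrate(seed, **config_overrides)
    cfg = sd.SynthConfig(seed=seed, **config_overrides)
    sites, _, cum = sd.generate_cohort(
        atlas, tractogram, weights, cfg, return_profiles=True
    )
    closed = np.array([s.mode == "closed" for s in sites])
    return cum[closed], weights


def fwer_null(
    n_reps: int = 500,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Family-wise error of the max-statistic map under a global null."""
    conn, _ = _null_substrate(seed)
    rng = np.random.default_rng([seed, 77])
    n_sites = conn.shape[0]
    hits = 0
    for i in range(n_reps):
        deltas = rng.normal(12.0, 27.0, n_sites)
        amap = pm.maxstat_correct(conn, deltas, method="kendall",
                                  n_perm=n_perm, seed=seed + 7000 + i, alpha=alpha)
        hits += bool(amap.significant.any())
    fwer = hits / n_reps
    return {"fwer": fwer, "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
            "n_reps": n_reps}


def bootstrap_type1(
    n_reps: int = 400,
    n: int = 100,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I rate of the bootstrap path test when the true beta is zero."""
    rng = np.random.default_rng([seed, 88])
    spec = pls.PathModelSpec(blocks={"X": ["x"], "Y": ["y"]}, paths=[("X", "Y")])
    rejections = 0
    for i in range(n_reps):
        df = pd.DataFrame({"x": rng.standard_normal(n), "y": rng.standard_normal(n)})
        boot = pls.bootstrap_inference(spec, df, n_boot=n_boot, seed=seed + 9000 + i)
        rejections += boot.path_row("X", "Y").p < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps}


def grid_fdr_null(n_reps: int = 200, seed: int = 0, alpha: float = 0.05) -> dict:
    """Mean false-discovery proportion of the BH-corrected threshold grid
    under a global null (all 60 cells null)."""
    conn, weights = _null_substrate(seed)
    rng = np.random.default_rng([seed, 99])
    n_sites = conn.shape[0]
    fdp = []
    for _ in range(n_reps):
        deltas = rng.normal(12.0, 27.0, n_sites)
        grid = cg.grid_sweep(conn, weights, deltas, fdr_alpha=alpha)
        v = int(grid.table["significant_flag"].sum())
        fdp.append(v / max(v, 1) if v else 0.0)
    return {"mean_fdp": float(np.mean(fdp)), "n_reps": n_reps,
            "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps))}
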