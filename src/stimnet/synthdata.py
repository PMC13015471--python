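"""Synthetic atlases, tractograms, task series and stimulation cohorts.

Every downstream stage of the pipeline is exercised on data generated here,
with planted, parameterized effect structure that mirrors the phenomenology
of closed-loop memory stimulation cohorts:

* zero-inflated, right-skewed structural connectivity (a fraction of parcel
  pairs has no streamlines; positive counts are geometric);
* approximately normal functional-connectivity values (shared task and
  spatially correlated noise);
* a closed-loop-only association between a site's structure-function
  congruence and its memory-change score delta;
* a negative correlation between baseline recall and delta in the
  closed-loop group only;
* white-matter proximity (WMP) negatively correlated with a site's overall
  structural connectivity.

Recall is simulated at the list level (Bernoulli words, default 12 words x
25 lists, first three lists never stimulated), so the behavioral pipeline's
exclusion rules are genuinely exercised rather than bypassed by sampling
delta directly.  Planted correlations are induced through a Gaussian copula
on latent site scores; the copula correlations are calibrated analytically
(delta method) so that the *realized* correlations — after binomial recall
noise and the mechanical role of the baseline in delta's denominator — match
the requested effects.  Requests that would require a latent correlation
outside (-1, 1) raise :class:`ConfigError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ParcelAtlas
from .behavior import MIN_BASELINE_PCT, N_BASELINE_EXCLUDED_LISTS, SessionRecord
from .congruence import REPRESENTATIVE_CELL, site_dice
from .tracto import StimulationSite, Streamline, Tractogram, chaco_profile

__all__ = [
    "SynthConfig",
    "TaskDesign",
    "ConfigError",
    "generate_atlas",
    "generate_tractogram",
    "generate_timeseries",
    "generate_encoding_network",
    "generate_cohort",
    "write_sites",
    "read_sites",
    "write_sessions",
    "read_sessions",
]


class ConfigError(ValueError):
    """Raised when a requested effect structure is infeasible."""


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults follow the cohort sizes and headline effects of closed-loop
    lateral-temporal stimulation studies: 39 closed-loop and 22 random
    (open-loop) sites, a planted rank correlation of 0.6 between
    structure-function congruence and memory change in the closed-loop group,
    a baseline-recall vs memory-change correlation of -0.48 (closed-loop
    only), and WMP anticorrelated (-0.5) with overall structural
    connectivity.  ``noise_sd`` is the SD (percent points) of the latent
    memory-change score around its planted mean before list-level sampling
    noise.
    """

    n_parcels: int = 60
    n_closed: int = 39
    n_random: int = 22
    streamline_density: float = 5.0
    connection_sparsity: float = 0.5
    effect_sc_memory: float = 0.6
    effect_baseline: float = -0.48
    effect_wmp_sc: float = -0.5
    noise_sd: float = 20.0
    seed: int = 0
    # task / recall structure
    n_lists: int = 25
    words_per_list: int = 12
    site_radius: float = 12.0
    baseline_mean: float = 0.30
    baseline_sd: float = 0.10
    delta_mean: float = 12.4

    def __post_init__(self) -> None:
        if min(self.n_parcels, self.n_closed, self.n_random) < 1:
            raise ConfigError("all counts must be >= 1")
        if not 0 <= self.connection_sparsity < 1:
            raise ConfigError("connection_sparsity must be in [0, 1)")
        for eff in (self.effect_sc_memory, self.effect_baseline, self.effect_wmp_sc):
            if not -1 < eff < 1:
                raise ConfigError("planted correlations must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.n_lists < N_BASELINE_EXCLUDED_LISTS + 2:
            raise ConfigError("need at least 5 lists")


# --------------------------------------------------------------------------
# atlas / tractogram / time series


def generate_atlas(n_parcels: int, seed: int) -> ParcelAtlas:
    """Random parcel centroids in a brain-sized box, >= 2 mm apart."""
    if n_parcels < 2:
        raise ValueError("n_parcels must be >= 2")
    rng = np.random.default_rng([seed, 11])
    lo = np.array([-70.0, -85.0, -60.0])
    hi = np.array([70.0, 85.0, 60.0])
    pts: list[np.ndarray] = []
    while len(pts) < n_parcels:
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - p) >= 2.0 for p in pts):
            pts.append(cand)
    centroids = np.array(pts)
    ids = np.arange(1, n_parcels + 1)
    return ParcelAtlas(
        ids=ids,
        names=[f"parcel_{i:03d}" for i in ids],
        centroids=centroids,
        hemispheres=["L" if c[0] < 0 else "R" for c in centroids],
    )


def _bezier(a: np.ndarray, c: np.ndarray, b: np.ndarray, n_vertices: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_vertices)[:, None]
    return (1 - t) ** 2 * a + 2 * t * (1 - t) * c + t**2 * b


def generate_tractogram(
    atlas: ParcelAtlas, config: SynthConfig, seed: int | None = None
) -> Tractogram:
    """Zero-inflated streamline counts per parcel pair with curved geometry.

    With probability (1 - connection_sparsity) a pair receives a geometric
    number of streamlines (mean ``streamline_density``); each streamline is a
    quadratic Bezier from near one centroid to near the other with a random
    control point, sampled at 12 vertices.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 22])
    n = atlas.n_parcels
    streamlines: list[Streamline] = []
    p_geo = min(1.0, 1.0 / max(config.streamline_density, 1.0))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.connection_sparsity:
                continue
            count = rng.geometric(p_geo)
            ci, cj = atlas.centroids[i], atlas.centroids[j]
            for _ in range(count):
                a = ci + rng.normal(0.0, 2.0, 3)
                b = cj + rng.normal(0.0, 2.0, 3)
                ctrl = (a + b) / 2 + rng.normal(0.0, 8.0, 3)
                streamlines.append(
                    Streamline(_bezier(a, ctrl, b, 12), int(atlas.ids[i]), int(atlas.ids[j]))
                )
    return Tractogram(streamlines)


@dataclass
class TaskDesign:
    """Block task structure for synthetic encoding-task series.

    ``loadings`` is a per-parcel amplitude on the shared block regressor
    (None = no task signal); ``shared_noise`` is the fraction of noise
    variance carried by a global component, giving spatially correlated
    noise.
    """

    block_length: int = 20
    loadings: np.ndarray | None = None
    shared_noise: float = 0.1


def generate_timeseries(
    atlas: ParcelAtlas,
    n_subjects: int,
    n_timepoints: int,
    block_design: TaskDesign | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-subject (parcels x time) matrices, standardized per parcel."""
    if n_timepoints < 20:
        raise ValueError("n_timepoints must be >= 20")
    design = block_design or TaskDesign()
    rng = np.random.default_rng([seed, 33])
    n = atlas.n_parcels
    task = (np.arange(n_timepoints) // design.block_length) % 2
    task = (task - task.mean()) / max(task.std(), 1e-12)
    lam = np.zeros(n) if design.loadings is None else np.asarray(design.loadings, float)
    rho = float(design.shared_noise)
    out = []
    for _ in range(n_subjects):
        g = rng.standard_normal(n_timepoints)
        eps = rng.standard_normal((n, n_timepoints))
        noise = np.sqrt(1 - rho) * eps + np.sqrt(rho) * g[None, :]
        x = lam[:, None] * task[None, :] + noise
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out.append((x - x.mean(axis=1, keepdims=True)) / sd)
    return out


def generate_encoding_network(atlas: ParcelAtlas, n_core: int, seed: int) -> np.ndarray:
    """Parcel weight vector with ``n_core`` high-positive core weights and
    small zero-centered weights elsewhere."""
    if not 1 <= n_core <= atlas.n_parcels:
        raise ValueError("n_core must lie in [1, n_parcels]")
    rng = np.random.default_rng([seed, 44])
    w = rng.normal(0.0, 0.25, atlas.n_parcels)
    core = rng.choice(atlas.n_parcels, size=n_core, replace=False)
    w[core] = 2.0 + rng.exponential(0.5, n_core)
    return w


# --------------------------------------------------------------------------
# cohort generation


def _rank_normal_scores(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blom-type normal scores of ranks; random jitter resolves exact ties so
    the scores have full support."""
    x = np.asarray(x, float)
    jitter = rng.uniform(-1e-9, 1e-9, x.size) * (1.0 + np.abs(x))
    ranks = stats.rankdata(x + jitter)
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def _copula_calibration(config: SynthConfig) -> tuple[float, float]:
    """Latent copula correlations that realize the requested effects after
    list-level binomial noise (delta-method attenuation correction)."""
    eligible = config.n_lists - N_BASELINE_EXCLUDED_LISTS
    n_stim_lists = eligible // 2
    n_ns_lists = eligible - n_stim_lists
    w = config.words_per_list
    p = config.baseline_mean
    var_s = p * (1 - p) / (n_stim_lists * w)
    var_ns = p * (1 - p) / (n_ns_lists * w)
    # sampling variance of realized delta (percent points)
    s2 = (100.0 / p) ** 2 * (var_s + var_ns)
    sd_delta_tot = np.hypot(config.noise_sd, np.sqrt(s2))

    # congruence -> delta: Spearman target, converted to the latent Pearson
    # scale, then inflated for attenuation by sampling noise
    rho_pearson = 2.0 * np.sin(np.pi * config.effect_sc_memory / 6.0)
    rho_sc = rho_pearson * sd_delta_tot / config.noise_sd
    if abs(rho_sc) >= 0.999:
        raise ConfigError(
            "effect_sc_memory infeasible at this noise_sd: required latent "
            f"correlation {rho_sc:.3f} outside (-1, 1)"
        )

    # baseline -> delta (Pearson): account for measurement noise on both
    # sides and for the mechanical negative covariance from R_NS appearing
    # in delta's denominator
    sd_b_pp = 100.0 * config.baseline_sd
    sd_b_tot = np.hypot(sd_b_pp, 100.0 * np.sqrt(var_ns))
    cov_mech = -(100.0**2 / p) * var_ns
    rho_base = (
        config.effect_baseline * sd_b_tot * sd_delta_tot - cov_mech
    ) / (sd_b_pp * config.noise_sd)
    if abs(rho_base) >= 0.999:
        raise ConfigError(
            "effect_baseline infeasible at this noise_sd: required latent "
            f"correlation {rho_base:.3f} outside (-1, 1)"
        )
    return float(rho_sc), float(rho_base)


def _simulate_session(
    site_id: str,
    mode: str,
    p_ns: float,
    p_s: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> SessionRecord:
    n_lists, w = config.n_lists, config.words_per_list
    list_index = np.arange(1, n_lists + 1)
    stimulated = np.zeros(n_lists, dtype=bool)
    eligible = np.arange(N_BASELINE_EXCLUDED_LISTS, n_lists)
    stim_lists = rng.permutation(eligible)[: eligible.size // 2]
    stimulated[stim_lists] = True
    probs = np.where(stimulated, p_s, p_ns)
    recalled = rng.binomial(w, probs)
    # the 8.33% inclusion floor holds by construction: regenerate eligible
    # non-stimulated lists while the baseline falls below one word per list
    elig_ns = (~stimulated) & (list_index > N_BASELINE_EXCLUDED_LISTS)
    for _ in range(1000):
        r_ns = 100.0 * recalled[elig_ns].sum() / (w * elig_ns.sum())
        if r_ns >= MIN_BASELINE_PCT:
            break
        recalled[elig_ns] = rng.binomial(w, p_ns, elig_ns.sum())
    else:
        recalled[elig_ns] = np.maximum(recalled[elig_ns], 1)
    return SessionRecord(
        site_id=site_id,
        list_index=list_index,
        stimulated=stimulated,
        n_words=np.full(n_lists, w),
        n_recalled=recalled,
        mode=mode,
    )


def generate_cohort(
    atlas: ParcelAtlas,
    tractogram: Tractogram,
    encoding_weights: np.ndarray,
    config: SynthConfig,
    return_profiles: bool = False,
):
    """Stimulation sites and recall sessions with planted effect structure.

    Closed-loop sites receive a latent memory-change score whose rank
    correlation with the site's Dice congruence to the encoding network (at
    the representative thresholds) equals ``effect_sc_memory``, and whose
    correlation with baseline recall equals ``effect_baseline``; random-mode
    sites get pure noise around zero.  WMP is drawn to correlate
    ``effect_wmp_sc`` with the site's total cumulative ChaCo.
    """
    rng = np.random.default_rng([config.seed, 55])
    rho_sc, rho_base = _copula_calibration(config)
    n_sites = config.n_closed + config.n_random
    modes = ["closed"] * config.n_closed + ["random"] * config.n_random

    # site geometry: centers jittered off random parcel centroids
    parcel_idx = rng.integers(0, atlas.n_parcels, n_sites)
    centers = atlas.centroids[parcel_idx] + rng.normal(0.0, 3.0, (n_sites, 3))
    site_ids = [f"S{i + 1:03d}" for i in range(n_sites)]

    cumulative = np.array(
        [
            chaco_profile(
                tractogram,
                StimulationSite(sid, c, config.site_radius, m),
                atlas,
            ).cumulative
            for sid, c, m in zip(site_ids, centers, modes)
        ]
    )

    # WMP anticorrelated with total structural connectivity
    z_sc = _rank_normal_scores(cumulative.sum(axis=1), rng)
    z_w = config.effect_wmp_sc * z_sc + np.sqrt(
        1 - config.effect_wmp_sc**2
    ) * rng.standard_normal(n_sites)
    wmp = np.maximum(0.1, 2.5 + 1.2 * z_w)

    # latent memory-change and baseline scores via Gaussian copula
    top_frac, sc_tau = REPRESENTATIVE_CELL
    dice_vals = site_dice(cumulative, encoding_weights, top_frac, sc_tau)
    closed = np.array([m == "closed" for m in modes])
    z_delta = np.zeros(n_sites)
    z_c = _rank_normal_scores(dice_vals[closed], rng)
    # ties among Dice values attenuate the realized rank correlation below
    # the copula's; measure the tie loss and compensate
    if dice_vals[closed].std() > 0:
        s_tie, _ = stats.spearmanr(dice_vals[closed], z_c)
        rho_sc = rho_sc / max(s_tie, 0.5)
        if abs(rho_sc) >= 0.999:
            raise ConfigError(
                "effect_sc_memory infeasible after tie correction: required "
                f"latent correlation {rho_sc:.3f} outside (-1, 1)"
            )
    z_delta[closed] = rho_sc * z_c + np.sqrt(1 - rho_sc**2) * rng.standard_normal(
        closed.sum()
    )
    z_delta[~closed] = rng.standard_normal((~closed).sum())
    delta_latent = np.where(closed, config.delta_mean, 0.0) + config.noise_sd * z_delta

    z_b = np.where(
        closed,
        rho_base * z_delta + np.sqrt(1 - rho_base**2) * rng.standard_normal(n_sites),
        rng.standard_normal(n_sites),
    )
    baseline = np.clip(config.baseline_mean + config.baseline_sd * z_b, 0.15, 0.70)

    sites: list[StimulationSite] = []
    sessions: list[SessionRecord] = []
    for i in range(n_sites):
        p_ns = float(baseline[i])
        p_s = float(np.clip(p_ns * (1.0 + delta_latent[i] / 100.0), 0.02, 0.95))
        sites.append(
            StimulationSite(
                site_id=site_ids[i],
                center=centers[i],
                radius=config.site_radius,
                mode=modes[i],
                wmp=float(wmp[i]),
                baseline_recall=p_ns,
                subject_id=site_ids[i],
            )
        )
        sessions.append(_simulate_session(site_ids[i], modes[i], p_ns, p_s, config, rng))
    if return_profiles:
        return sites, sessions, cumulative
    return sites, sessions


# --------------------------------------------------------------------------
# flat-file dialects


def write_sites(sites: list[StimulationSite], path) -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "subject_id": [s.subject_id or s.site_id for s in sites],
            "x": [s.center[0] for s in sites],
            "y": [s.center[1] for s in sites],
            "z": [s.center[2] for s in sites],
            "radius_mm": [s.radius for s in sites],
            "mode": [s.mode for s in sites],
            "wmp_mm": [s.wmp for s in sites],
        }
    ).to_csv(path, index=False)


def read_sites(path) -> list[StimulationSite]:
    df = pd.read_csv(path)
    return [
        StimulationSite(
            site_id=str(r.site_id),
            center=np.array([r.x, r.y, r.z]),
            radius=float(r.radius_mm),
            mode=str(r.mode),
            wmp=float(r.wmp_mm),
            subject_id=str(r.subject_id),
        )
        for r in df.itertuples()
    ]


def write_sessions(sessions: list[SessionRecord], path) -> None:
    rows = []
    for s in sessions:
        for i in range(s.list_index.size):
            rows.append(
                {
                    "site_id": s.site_id,
                    "list_index": s.list_index[i],
                    "stimulated_flag": int(s.stimulated[i]),
                    "n_words": s.n_words[i],
                    "n_recalled": s.n_recalled[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sessions(path, modes: dict[str, str] | None = None) -> list[SessionRecord]:
    df = pd.read_csv(path)
    sessions = []
    for site_id, grp in df.groupby("site_id", sort=False):
        grp = grp.sort_values("list_index")
        sessions.append(
            SessionRecord(
                site_id=str(site_id),
                list_index=grp["list_index"].to_numpy(),
                stimulated=grp["stimulated_flag"].to_numpy().astype(bool),
                n_words=grp["n_words"].to_numpy(),
                n_recalled=grp["n_recalled"].to_numpy(),
                mode=(modes or {}).get(str(site_id), "closed"),
            )
        )
    return sessions
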