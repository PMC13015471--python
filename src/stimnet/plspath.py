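"""Partial least squares structural equation modeling (PLS-SEM).

Variance-based path modeling for small neuro-behavioral cohorts: latent
variables are estimated as weighted composites of their indicator blocks by
the iterative PLS algorithm (Mode A / reflective outer estimation, inner
path-weighting scheme), and structural ("path") coefficients are the
standardized OLS regressions of each endogenous latent score on its
predecessors.  Inference is by nonparametric bootstrap over observations.

Supported model features mirror common brain-stimulation analyses:

* moderation — a two-stage interaction: latent scores are estimated first,
  then the standardized product of moderator and predictor scores enters the
  target's structural regression;
* mediation — indirect effect a*b with bootstrap inference and the
  proportion of the total effect transmitted through the mediator;
* quality diagnostics — AVE, composite reliability and the HTMT ratio;
* model comparison — regression BIC on an endogenous construct.

Structural-connectivity indicators are zero-inflated and right-skewed, so
``preprocess_indicators`` replaces zeros with the column's minimal non-zero
value and applies a natural log before standardization.

When every latent has a single indicator the whole engine degenerates to
standardized OLS path analysis, which serves as an exact oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "BootstrapResult",
    "MediationResult",
    "QualityDiagnostics",
    "preprocess_indicators",
    "fit_pls",
    "bootstrap_inference",
    "moderation_beta",
    "mediation",
    "quality_diagnostics",
    "model_bic",
]


# --------------------------------------------------------------------------
# specification


@dataclass
class PathModelSpec:
    """Declarative PLS path model.

    ``blocks`` maps each latent to its (reflective) indicator columns;
    ``paths`` are directed (source, target) latent pairs forming a DAG;
    ``moderations`` are (moderator, predictor, target) triples whose
    interaction enters the target's structural regression.
    """

    blocks: dict[str, list[str]]
    paths: list[tuple[str, str]]
    moderations: list[tuple[str, str, str]] = field(default_factory=list)
    log_transform: list[str] = field(default_factory=list)
    n_boot: int = 5000
    seed: int | None = None
    tol: float = 1e-7
    max_iter: int = 300

    def __post_init__(self) -> None:
        self.paths = [tuple(p) for p in self.paths]
        self.moderations = [tuple(m) for m in self.moderations]
        seen: set[str] = set()
        for latent, cols in self.blocks.items():
            if not cols:
                raise ValueError(f"block '{latent}' has no indicators")
            dup = seen.intersection(cols)
            if dup:
                raise ValueError(f"indicators in more than one block: {sorted(dup)}")
            seen.update(cols)
        for s, t in self.paths:
            if s not in self.blocks or t not in self.blocks:
                raise ValueError(f"path ({s} -> {t}) references unknown latent")
        for mod, pred, tgt in self.moderations:
            for name in (mod, pred, tgt):
                if name not in self.blocks:
                    raise ValueError(f"moderation references unknown latent '{name}'")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        order: list[str] = []
        indeg = {l: 0 for l in self.blocks}
        for _, t in self.paths:
            indeg[t] += 1
        queue = [l for l, d in indeg.items() if d == 0]
        while queue:
            node = queue.pop()
            order.append(node)
            for s, t in self.paths:
                if s == node:
                    indeg[t] -= 1
                    if indeg[t] == 0:
                        queue.append(t)
        if len(order) != len(self.blocks):
            raise ValueError("path graph must be acyclic")

    @property
    def latents(self) -> list[str]:
        return list(self.blocks)

    def predecessors(self, latent: str) -> list[str]:
        return [s for s, t in self.paths if t == latent]

    def successors(self, latent: str) -> list[str]:
        return [t for s, t in self.paths if s == latent]

    def endogenous(self) -> list[str]:
        targets = {t for _, t in self.paths} | {t for _, _, t in self.moderations}
        return [l for l in self.latents if l in targets]

    def structural_terms(self, latent: str) -> list[tuple[str, ...]]:
        """Predictor terms of a latent's structural regression: plain
        predecessors plus ('mod', moderator, predictor) interaction terms."""
        terms: list[tuple[str, ...]] = [(p,) for p in self.predecessors(latent)]
        for mod, pred, tgt in self.moderations:
            if tgt == latent:
                terms.append(("mod", mod, pred))
        return terms

    @classmethod
    def from_dict(cls, d: dict) -> "PathModelSpec":
        return cls(
            blocks={k: list(v) for k, v in d["blocks"].items()},
            paths=[tuple(p) for p in d.get("paths", [])],
            moderations=[tuple(m) for m in d.get("moderations", [])],
            log_transform=list(d.get("log_transform", [])),
            n_boot=int(d.get("n_boot", 5000)),
            seed=d.get("seed"),
            tol=float(d.get("tol", 1e-7)),
            max_iter=int(d.get("max_iter", 300)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PathModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# preprocessing


def preprocess_indicators(table: pd.DataFrame, log_columns=()) -> pd.DataFrame:
    """Standardize indicator columns; log-transform flagged ones first.

    Flagged (zero-inflated) columns have zeros replaced by the column's
    minimal non-zero value, then take natural logs.  Every column is then
    z-standardized (sample sd).
    """
    out = table.copy()
    for col in log_columns:
        x = out[col].to_numpy(float)
        if np.any(x < 0):
            raise ValueError(f"column '{col}' has negative values; cannot log-transform")
        nz = x[x > 0]
        if nz.size == 0:
            raise ValueError(f"column '{col}' is all zeros")
        x = np.where(x == 0, nz.min(), x)
        out[col] = np.log(x)
    for col in out.columns:
        x = out[col].to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column '{col}' is constant")
        out[col] = (x - x.mean()) / sd
    return out


# --------------------------------------------------------------------------
# fitting


def _standardize(y: np.ndarray) -> np.ndarray:
    sd = y.std()
    if sd == 0:
        raise ValueError("zero-variance composite")
    return (y - y.mean()) / sd


@dataclass
class PathModelFit:
    spec: PathModelSpec
    weights: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]  # standardized latent scores (mean 0, var 1)
    paths: dict[tuple[str, str], float]  # (source-or-interaction, target) -> beta
    r2: dict[str, float]
    sse: dict[str, float]
    n_obs: int
    n_iter: int

    def path_keys(self) -> list[tuple[str, str]]:
        keys = []
        for latent in self.spec.latents:
            for term in self.spec.structural_terms(latent):
                keys.append((_term_name(term), latent))
        return keys

    def path_vector(self) -> np.ndarray:
        return np.array([self.paths[k] for k in self.path_keys()])

    def loading_vector(self) -> np.ndarray:
        return np.concatenate([self.loadings[l] for l in self.spec.latents])

    def paths_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": s, "target": t, "beta": b} for (s, t), b in self.paths.items()]
        )


def _term_name(term: tuple[str, ...]) -> str:
    if term[0] == "mod":
        return f"{term[1]}*{term[2]}"
    return term[0]


def _fit_arrays(spec: PathModelSpec, blocks: dict[str, np.ndarray]) -> PathModelFit:
    n = next(iter(blocks.values())).shape[0]
    # standardize indicators (each bootstrap resample is re-standardized)
    X = {}
    for latent, mat in blocks.items():
        sd = mat.std(axis=0)
        if np.any(sd == 0):
            raise ValueError(f"constant indicator in block '{latent}'")
        X[latent] = (mat - mat.mean(axis=0)) / sd

    latents = spec.latents
    preds = {l: spec.predecessors(l) for l in latents}
    succs = {l: spec.successors(l) for l in latents}

    w_unit = {l: np.ones(X[l].shape[1]) / np.sqrt(X[l].shape[1]) for l in latents}
    scores = {l: _standardize(X[l] @ w_unit[l]) for l in latents}

    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        # inner approximation: path-weighting scheme
        inner = {}
        for l in latents:
            z = np.zeros(n)
            if preds[l]:
                P = np.column_stack([scores[m] for m in preds[l]])
                b, *_ = np.linalg.lstsq(P, scores[l], rcond=None)
                z = z + P @ b
            for m in succs[l]:
                z = z + float(np.dot(scores[l], scores[m]) / n) * scores[m]
            if not preds[l] and not succs[l]:
                z = scores[l].copy()
            inner[l] = _standardize(z)
        # outer update, Mode A: weight = corr(indicator, inner proxy)
        max_delta = 0.0
        for l in latents:
            w = X[l].T @ inner[l] / n
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(f"degenerate outer weights for latent '{l}'")
            w = w / norm
            # orient so the sum of loadings is non-negative
            y = _standardize(X[l] @ w)
            if float(np.sum(X[l].T @ y / n)) < 0:
                w = -w
                y = -y
            max_delta = max(max_delta, float(np.max(np.abs(w - w_unit[l]))))
            w_unit[l] = w
            scores[l] = y
        if max_delta < spec.tol:
            break
    else:
        raise RuntimeError(
            f"PLS did not converge in {spec.max_iter} iterations (last change {max_delta:.2e})"
        )

    loadings = {l: X[l].T @ scores[l] / n for l in latents}

    paths: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    sse: dict[str, float] = {}
    for l in latents:
        terms = spec.structural_terms(l)
        if not terms:
            continue
        cols = []
        for term in terms:
            if term[0] == "mod":
                inter = scores[term[1]] * scores[term[2]]
                cols.append(_standardize(inter))
            else:
                cols.append(scores[term[0]])
        D = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(D, scores[l], rcond=None)
        resid = scores[l] - D @ beta
        for term, b in zip(terms, beta):
            paths[(_term_name(term), l)] = float(b)
        sse[l] = float(resid @ resid)
        r2[l] = 1.0 - sse[l] / n  # scores have variance 1 (n denominator)

    return PathModelFit(
        spec=spec,
        weights=w_unit,
        loadings=loadings,
        scores=scores,
        paths=paths,
        r2=r2,
        sse=sse,
        n_obs=n,
        n_iter=n_iter,
    )


def _block_arrays(spec: PathModelSpec, data: pd.DataFrame) -> dict[str, np.ndarray]:
    return {l: data[cols].to_numpy(float) for l, cols in spec.blocks.items()}


def fit_pls(spec: PathModelSpec, data: pd.DataFrame) -> PathModelFit:
    """Fit the PLS path model on an observations x indicators table."""
    n = len(data)
    max_block = max(len(c) for c in spec.blocks.values())
    if n <= max_block:
        raise ValueError("need more observations than the largest block")
    return _fit_arrays(spec, _block_arrays(spec, data))


# --------------------------------------------------------------------------
# bootstrap inference


@dataclass
class BootstrapResult:
    fit: PathModelFit
    path_table: pd.DataFrame  # source, target, beta, se, p, ci_low, ci_high
    loading_table: pd.DataFrame
    path_draws: np.ndarray  # (n_boot_ok, n_paths)
    n_failed: int
    seed: int | None

    def path_row(self, source: str, target: str) -> pd.Series:
        t = self.path_table
        row = t[(t.source == source) & (t.target == target)]
        if row.empty:
            raise KeyError(f"no path {source} -> {target}")
        return row.iloc[0]


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def bootstrap_inference(
    spec: PathModelSpec,
    data: pd.DataFrame,
    n_boot: int | None = None,
    seed: int | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap over observations.

    Each resample is refit from scratch; path coefficients and outer
    loadings are summarized by bootstrap SE, normal-theory two-tailed p and
    percentile CIs.  More than 5% failed resamples aborts.
    """
    n_boot = spec.n_boot if n_boot is None else n_boot
    seed = spec.seed if seed is None else seed
    fit = fit_pls(spec, data)
    blocks = _block_arrays(spec, data)
    n = fit.n_obs
    rng = np.random.default_rng(seed)

    keys = fit.path_keys()
    path_draws = np.empty((n_boot, len(keys)))
    loading_draws = np.empty((n_boot, fit.loading_vector().size))
    n_failed = 0
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            bfit = _fit_arrays(spec, {l: m[idx] for l, m in blocks.items()})
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        path_draws[kept] = bfit.path_vector()
        loading_draws[kept] = bfit.loading_vector()
        kept += 1
    if n_failed > 0.05 * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap resamples failed")
    path_draws = path_draws[:kept]
    loading_draws = loading_draws[:kept]

    obs = fit.path_vector()
    se = path_draws.std(axis=0, ddof=1)
    ci = np.percentile(path_draws, [2.5, 97.5], axis=0)
    path_table = pd.DataFrame(
        {
            "source": [k[0] for k in keys],
            "target": [k[1] for k in keys],
            "beta": obs,
            "se": se,
            "p": [_normal_p(b, s) for b, s in zip(obs, se)],
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )

    lnames = [
        (l, col) for l in spec.latents for col in spec.blocks[l]
    ]
    lobs = fit.loading_vector()
    lse = loading_draws.std(axis=0, ddof=1)
    lci = np.percentile(loading_draws, [2.5, 97.5], axis=0)
    loading_table = pd.DataFrame(
        {
            "latent": [x[0] for x in lnames],
            "indicator": [x[1] for x in lnames],
            "loading": lobs,
            "se": lse,
            "p": [_normal_p(b, s) for b, s in zip(lobs, lse)],
            "ci_low": lci[0],
            "ci_high": lci[1],
        }
    )
    return BootstrapResult(fit, path_table, loading_table, path_draws, n_failed, seed)


def moderation_beta(fit: PathModelFit, moderator: str, predictor: str, target: str) -> float:
    """Interaction coefficient of a (moderator, predictor, target) triple."""
    return fit.paths[(f"{moderator}*{predictor}", target)]


# --------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    a: float
    b: float
    direct: float
    indirect: float
    total: float
    proportion_mediated: float  # NaN when flagged
    flagged: bool
    indirect_se: float | None = None
    indirect_p: float | None = None
    indirect_ci: tuple[float, float] | None = None


def mediation(
    fit: PathModelFit,
    predictor: str,
    mediator: str,
    outcome: str,
    boot: BootstrapResult | None = None,
) -> MediationResult:
    """Decompose predictor -> outcome into direct and indirect (via mediator)
    effects.

    indirect = a*b; total = c' + a*b; the proportion mediated is
    indirect/total when the two agree in sign, otherwise flagged (an
    inconsistent mediation has no meaningful proportion).  With a bootstrap
    result, indirect-effect inference uses the distribution of a*b products.
    """
    a = fit.paths[(predictor, mediator)]
    b = fit.paths[(mediator, outcome)]
    direct = fit.paths.get((predictor, outcome), 0.0)
    indirect = a * b
    total = direct + indirect
    flagged = abs(total) < 1e-8 or (indirect != 0 and np.sign(indirect) != np.sign(total))
    proportion = np.nan if flagged else (0.0 if indirect == 0 else indirect / total)
    res = MediationResult(a, b, direct, indirect, total, proportion, flagged)
    if boot is not None:
        keys = fit.path_keys()
        ia = keys.index((predictor, mediator))
        ib = keys.index((mediator, outcome))
        draws = boot.path_draws[:, ia] * boot.path_draws[:, ib]
        res.indirect_se = float(draws.std(ddof=1))
        res.indirect_p = _normal_p(indirect, res.indirect_se)
        res.indirect_ci = tuple(np.percentile(draws, [2.5, 97.5]))
    return res


# --------------------------------------------------------------------------
# quality diagnostics and model comparison


@dataclass
class QualityDiagnostics:
    ave: dict[str, float]
    composite_reliability: dict[str, float]
    htmt: pd.DataFrame  # symmetric latent x latent


def quality_diagnostics(fit: PathModelFit, data: pd.DataFrame) -> QualityDiagnostics:
    """AVE, composite reliability and HTMT discriminant-validity ratios.

    AVE is the mean squared standardized loading of a block (1 for a single
    indicator).  HTMT is the mean absolute heterotrait correlation divided
    by the geometric mean of the two blocks' mean absolute monotrait
    correlations; single-indicator blocks contribute a monotrait term of 1.
    """
    spec = fit.spec
    ave = {}
    cr = {}
    for l in spec.latents:
        lam = np.clip(fit.loadings[l], -1.0, 1.0)
        ave[l] = float(np.mean(lam**2))
        s = float(np.abs(lam).sum())
        cr[l] = s**2 / (s**2 + float(np.sum(1 - lam**2))) if lam.size else np.nan

    cols = [c for l in spec.latents for c in spec.blocks[l]]
    corr = np.corrcoef(data[cols].to_numpy(float), rowvar=False)
    corr = np.atleast_2d(corr)
    offsets = {}
    pos = 0
    for l in spec.latents:
        offsets[l] = (pos, pos + len(spec.blocks[l]))
        pos += len(spec.blocks[l])

    def mono(l: str) -> float:
        lo, hi = offsets[l]
        k = hi - lo
        if k == 1:
            return 1.0
        sub = np.abs(corr[lo:hi, lo:hi])
        iu = np.triu_indices(k, 1)
        return float(sub[iu].mean())

    names = spec.latents
    H = np.ones((len(names), len(names)))
    for i, li in enumerate(names):
        for j in range(i + 1, len(names)):
            lj = names[j]
            (alo, ahi), (blo, bhi) = offsets[li], offsets[lj]
            hetero = float(np.abs(corr[alo:ahi, blo:bhi]).mean())
            H[i, j] = H[j, i] = hetero / np.sqrt(mono(li) * mono(lj))
    return QualityDiagnostics(ave, cr, pd.DataFrame(H, index=names, columns=names))


def model_bic(fit: PathModelFit, endogenous: str) -> float:
    """Regression BIC of an endogenous construct's structural equation:
    n*ln(SSE/n) + (k+1)*ln(n), k = number of predictor terms."""
    if endogenous not in fit.sse:
        raise KeyError(f"'{endogenous}' has no structural equation")
    n = fit.n_obs
    k = len(fit.spec.structural_terms(endogenous))
    sse = fit.sse[endogenous]
    if sse <= 0:
        sse = np.finfo(float).tiny
    return float(n * np.log(sse / n) + (k + 1) * np.log(n))
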