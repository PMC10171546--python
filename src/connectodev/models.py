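"""Region-wise longitudinal model comparison of developmental trajectories.

For every region and metric, four nested Gaussian mixed models of the metric
value are fitted by maximum likelihood, each with the nuisance covariates
(framewise displacement, scanner epoch, medication status, sex) and a
per-subject random intercept for the repeated waves:

* **null** — covariates only;
* **age** — adds a smooth (B-spline, basis dimension 4 by default) of age;
* **group** — adds a group main effect (diagnosis offset);
* **interaction** — adds a group-specific age smooth, letting the two groups
  follow different trajectories.

The winning model is the most complex one whose added term is significant
(p < alpha) *and* whose AIC undercuts every simpler nested model by more
than a margin (default 2 AIC units); otherwise selection falls back toward
the null. Region-wise p-values for the group and interaction contrasts are
then FDR-corrected (Benjamini–Hochberg) across regions, one family per
metric and contrast.

The smooth uses an unpenalized B-spline basis with ``basis_dim - 1`` columns,
the effective dimension a penalized smooth of basis dimension k has after
its identifiability constraint; with k = 4 the fit is at most cubic-flexible,
so an explicit wiggliness penalty has little to bite on. The random-intercept
model is fitted by profiling the marginal likelihood over the variance ratio
(subject variance over residual variance): given the ratio, the GLS estimate
and residual variance are closed-form, leaving a one-dimensional bounded
optimization. This is exact maximum likelihood for this model class and is
fast enough for hundreds of regions times replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

MODEL_ORDER = ("null", "age", "group", "interaction")

METRIC_NAMES = ("degree", "eloc", "bc", "eglob")

OBS_COLUMNS = (
    "region_label", "metric_name", "value",
    "subject_id", "wave", "age", "group", "sex", "fd", "scanner", "medicated",
)


@dataclass
class ModelConfig:
    """Settings of the trajectory-model comparison.

    basis_dim
        Basis dimension of the age smooth (k); the smooth contributes
        ``basis_dim - 1`` design columns. Must be >= 3.
    alpha
        Significance level the winning model's added term must reach.
    aic_margin
        AIC units by which a winner must undercut simpler models (strict).
    fdr_q
        Benjamini–Hochberg level applied across regions per contrast.
    compare_all_simpler
        If True (default) the winner must beat *every* simpler nested model
        by the margin; if False only its immediate parent.
    """

    basis_dim: int = 4
    alpha: float = 0.05
    aic_margin: float = 2.0
    fdr_q: float = 0.05
    compare_all_simpler: bool = True

    def __post_init__(self) -> None:
        if self.basis_dim < 3:
            raise ValueError("basis_dim must be >= 3")
        if not 0 < self.alpha < 1 or not 0 < self.fdr_q < 1:
            raise ValueError("alpha and fdr_q must lie in (0, 1)")
        if self.aic_margin < 0:
            raise ValueError("aic_margin must be >= 0")


@dataclass
class ModelFit:
    """One fitted mixed model: likelihood, AIC and the added-term test."""

    name: str
    loglik: float
    aic: float
    n_params: int
    params: np.ndarray
    param_names: list[str]
    cov_params: np.ndarray
    var_subject: float
    var_resid: float
    p_term: float  # nan for the null model
    available: bool = True
    design: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Spline basis
# ---------------------------------------------------------------------------


def age_spline_basis(
    age: np.ndarray, basis_dim: int, bounds: tuple[float, float] | None = None
) -> np.ndarray:
    """B-spline design for the age smooth: ``basis_dim - 1`` columns.

    Boundary knots at the observed (or given) age range, interior knots
    evenly spaced; the first basis function is dropped against the model
    intercept. Ages outside the bounds are clamped (prediction only).
    """
    age = np.asarray(age, dtype=float)
    df = basis_dim - 1
    deg = min(3, df)
    lo, hi = bounds if bounds is not None else (age.min(), age.max())
    if hi <= lo:
        raise ValueError("degenerate age range for spline basis")
    n_interior = df - deg  # so that df + 1 basis functions exist
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.r_[[lo] * (deg + 1), interior, [hi] * (deg + 1)]
    x = np.clip(age, lo, hi)
    design = interpolate.BSpline.design_matrix(x, knots, deg).toarray()
    return design[:, 1:]


# ---------------------------------------------------------------------------
# Random-intercept ML fitting (profiled likelihood)
# ---------------------------------------------------------------------------


def _check_full_rank(x: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        _, rmat = np.linalg.qr(x)
        bad = [names[i] for i in np.flatnonzero(np.abs(np.diag(rmat)) < 1e-8)]
        raise ValueError(f"rank-deficient design; collinear column(s): {', '.join(bad)}")


def fit_random_intercept_ml(
    y: np.ndarray, x: np.ndarray, subject_idx: np.ndarray, param_names: Sequence[str]
) -> dict:
    """Exact ML fit of ``y = X b + u_subject + e`` via the profiled likelihood.

    For variance ratio lam = var_u/var_e the marginal covariance per subject
    block is ``var_e (I + lam J)`` whose inverse and determinant are
    closed-form, so beta and var_e profile out and only lam is optimized
    (bounded, on a log scale, with the lam = 0 boundary checked explicitly).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    _check_full_rank(x, param_names)
    subjects, subject_codes = np.unique(subject_idx, return_inverse=True)
    q = subjects.size
    nj = np.bincount(subject_codes, minlength=q).astype(float)
    sx = np.zeros((q, p))
    np.add.at(sx, subject_codes, x)
    sy = np.bincount(subject_codes, weights=y, minlength=q)
    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)

    def solve_at(lam: float) -> tuple[np.ndarray, np.ndarray, float, float]:
        c = lam / (1.0 + lam * nj)
        axx = xtx - sx.T @ (c[:, None] * sx)
        axy = xty - sx.T @ (c * sy)
        ayy = yty - float(c @ sy**2)
        beta = linalg.solve(axx, axy, assume_a="pos")
        rss = max(ayy - float(beta @ axy), 1e-300)
        return beta, axx, rss, float(np.log1p(lam * nj).sum())

    def negll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        try:
            _, _, rss, logdet = solve_at(lam)
        except linalg.LinAlgError:
            return np.inf
        s2 = rss / n
        return 0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + logdet)

    res = optimize.minimize_scalar(negll, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    nll = float(res.fun)
    # boundary: no subject variance at all
    _, _, rss0, _ = solve_at(0.0)
    nll0 = 0.5 * n * (np.log(2 * np.pi * rss0 / n) + 1.0)
    if nll0 <= nll:
        lam, nll = 0.0, nll0
    beta, axx, rss, _ = solve_at(lam)
    s2 = rss / n
    cov = s2 * linalg.inv(axx)
    return {
        "params": beta,
        "cov_params": cov,
        "loglik": -nll,
        "var_resid": s2,
        "var_subject": lam * s2,
        "lam": lam,
    }


# ---------------------------------------------------------------------------
# Nested model battery
# ---------------------------------------------------------------------------


def _encode_covariates(data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed nuisance design; constant covariates (e.g. nobody medicated)
    carry no information and are dropped rather than breaking the fit."""
    candidates = {
        "fd": data["fd"].to_numpy(dtype=float),
        "scanner_post": (data["scanner"] == "post_upgrade").to_numpy(dtype=float),
        "medicated": data["medicated"].to_numpy(dtype=float),
        "sex_male": (data["sex"] == "M").to_numpy(dtype=float),
    }
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["intercept"]
    for name, col in candidates.items():
        if np.ptp(col) > 0:
            cols.append(col)
            names.append(name)
    return np.column_stack(cols), names


def fit_nested_models(data: pd.DataFrame, cfg: ModelConfig | None = None) -> dict[str, ModelFit]:
    """Fit the null/age/group/interaction battery for one region and metric.

    ``data`` needs columns value, age, group, sex, fd, scanner, medicated and
    subject_id. With only one group present the group and interaction fits
    are marked unavailable rather than raised.
    """
    cfg = cfg or ModelConfig()
    data = data.sort_values(["subject_id", "wave"] if "wave" in data.columns else ["subject_id"],
                            kind="mergesort").reset_index(drop=True)
    if data["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    y = data["value"].to_numpy(dtype=float)
    subj = data["subject_id"].to_numpy()
    xc, names_c = _encode_covariates(data)
    age = data["age"].to_numpy(dtype=float)
    bounds = (float(age.min()), float(age.max()))
    basis = age_spline_basis(age, cfg.basis_dim, bounds=bounds)
    spline_names = [f"s(age){j}" for j in range(basis.shape[1])]
    grp = (data["group"] == "ADHD").to_numpy(dtype=float)
    both_groups = 0 < grp.sum() < len(grp)

    design_meta = {
        "basis_dim": cfg.basis_dim,
        "age_bounds": bounds,
        "fd_ref": float(data["fd"].mean()),
    }

    def _fit(name: str, x: np.ndarray, names: list[str]) -> ModelFit:
        r = fit_random_intercept_ml(y, x, subj, names)
        k = x.shape[1] + 2  # fixed effects + residual and subject variances
        return ModelFit(
            name=name, loglik=r["loglik"], aic=2 * k - 2 * r["loglik"], n_params=k,
            params=r["params"], param_names=names, cov_params=r["cov_params"],
            var_subject=r["var_subject"], var_resid=r["var_resid"],
            p_term=np.nan, design=design_meta,
        )

    fits: dict[str, ModelFit] = {}
    fits["null"] = _fit("null", xc, names_c)

    x_age = np.column_stack([xc, basis])
    fits["age"] = _fit("age", x_age, names_c + spline_names)
    lr = max(0.0, 2 * (fits["age"].loglik - fits["null"].loglik))
    fits["age"].p_term = float(stats.chi2.sf(lr, df=basis.shape[1]))

    if both_groups:
        x_grp = np.column_stack([x_age, grp])
        fits["group"] = _fit("group", x_grp, fits["age"].param_names + ["group_adhd"])
        gi = fits["group"].param_names.index("group_adhd")
        se = float(np.sqrt(fits["group"].cov_params[gi, gi]))
        z = fits["group"].params[gi] / se
        fits["group"].p_term = float(2 * stats.norm.sf(abs(z)))

        x_int = np.column_stack([x_grp, basis * grp[:, None]])
        int_names = fits["group"].param_names + [f"group:{s}" for s in spline_names]
        fits["interaction"] = _fit("interaction", x_int, int_names)
        lr = max(0.0, 2 * (fits["interaction"].loglik - fits["group"].loglik))
        fits["interaction"].p_term = float(stats.chi2.sf(lr, df=basis.shape[1]))
    else:
        for name in ("group", "interaction"):
            fits[name] = ModelFit(
                name=name, loglik=np.nan, aic=np.nan, n_params=0, params=np.empty(0),
                param_names=[], cov_params=np.empty((0, 0)), var_subject=np.nan,
                var_resid=np.nan, p_term=np.nan, available=False, design=design_meta,
            )
    return fits


def select_best_model(fits: Mapping[str, ModelFit], cfg: ModelConfig | None = None) -> tuple[str, float]:
    """Apply the AIC-margin + significance rule; returns (winner, its p).

    The most complex available model whose added-term p is below alpha and
    whose AIC is more than ``aic_margin`` units below every simpler nested
    model (or only its parent, per config) wins; otherwise the null is
    retained. Equal AICs therefore keep the simpler model.
    """
    cfg = cfg or ModelConfig()
    if "null" not in fits or not fits["null"].available:
        raise ValueError("the null fit is required")
    order = list(MODEL_ORDER)
    for idx in range(len(order) - 1, 0, -1):
        name = order[idx]
        fit = fits.get(name)
        if fit is None or not fit.available or not np.isfinite(fit.aic):
            continue
        if not (np.isfinite(fit.p_term) and fit.p_term < cfg.alpha):
            continue
        simpler = order[:idx] if cfg.compare_all_simpler else [order[idx - 1]]
        deltas = [
            fits[s].aic - fit.aic
            for s in simpler
            if s in fits and fits[s].available and np.isfinite(fits[s].aic)
        ]
        if deltas and all(d > cfg.aic_margin for d in deltas):
            return name, float(fit.p_term)
    return "null", float("nan")


def fdr_correct(p_values: Mapping[str, float], q: float = 0.05) -> dict[str, tuple[float, bool]]:
    """Benjamini–Hochberg step-up across one family (e.g. regions of a metric)."""
    keys = list(p_values)
    p = np.array([p_values[k] for k in keys], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return {}
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return {k: (float(qa), bool(rj)) for k, qa, rj in zip(keys, q_adj, reject)}


# ---------------------------------------------------------------------------
# Region-wise orchestration
# ---------------------------------------------------------------------------


def regionwise_analysis(
    obs: pd.DataFrame,
    cfg: ModelConfig | None = None,
    return_fits: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Fit and select models for every (metric, region); FDR across regions.

    ``obs`` is long-format with the OBS_COLUMNS fields. Output has one row
    per region and metric with the four AICs, contrast p-values, the winner
    under the selection rule, and BH-adjusted q-values computed per metric
    and contrast across regions. Row order in ``obs`` does not affect any
    output. Families with a single region (e.g. the scan-level global
    efficiency) pass through BH unchanged.
    """
    cfg = cfg or ModelConfig()
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing column(s): {', '.join(missing)}")
    rows = []
    all_fits: dict[tuple[str, str], dict[str, ModelFit]] = {}
    for metric in sorted(obs["metric_name"].unique()):
        sub = obs[obs.metric_name == metric]
        for region in sorted(sub["region_label"].unique()):
            data = sub[sub.region_label == region]
            fits = fit_nested_models(data, cfg)
            winner, p_term = select_best_model(fits, cfg)
            all_fits[(metric, region)] = fits
            rows.append(
                {
                    "metric_name": metric,
                    "region_label": region,
                    "aic_null": fits["null"].aic,
                    "aic_age": fits["age"].aic,
                    "aic_group": fits["group"].aic if fits["group"].available else np.nan,
                    "aic_interaction": fits["interaction"].aic
                    if fits["interaction"].available else np.nan,
                    "p_age": fits["age"].p_term,
                    "p_group": fits["group"].p_term if fits["group"].available else np.nan,
                    "p_interaction": fits["interaction"].p_term
                    if fits["interaction"].available else np.nan,
                    "winner": winner,
                    "p_term": p_term,
                }
            )
    results = pd.DataFrame(rows)
    if results.empty:
        results = pd.DataFrame(columns=[
            "metric_name", "region_label", "aic_null", "aic_age", "aic_group",
            "aic_interaction", "p_age", "p_group", "p_interaction", "winner",
            "p_term", "q_group", "q_interaction", "q_value", "significant"])
        return (results, all_fits) if return_fits else results
    for contrast in ("group", "interaction"):
        results[f"q_{contrast}"] = np.nan
        for metric in results.metric_name.unique():
            sel = (results.metric_name == metric) & results[f"p_{contrast}"].notna()
            fam = results.loc[sel]
            if fam.empty:
                continue
            adj = fdr_correct(dict(zip(fam.region_label, fam[f"p_{contrast}"])), cfg.fdr_q)
            results.loc[sel, f"q_{contrast}"] = [
                adj[r][0] for r in results.loc[sel, "region_label"]
            ]
    q_value = np.full(len(results), np.nan)
    for i, row in results.iterrows():
        if row.winner == "group":
            q_value[i] = row.q_group
        elif row.winner == "interaction":
            q_value[i] = row.q_interaction
        elif row.winner == "age":
            q_value[i] = row.p_age  # age effects are not FDR-pooled across regions
    results["q_value"] = q_value
    results["significant"] = (results.winner.isin(["group", "interaction"])
                              & (results.q_value < cfg.fdr_q))
    results = results.sort_values(["metric_name", "region_label"]).reset_index(drop=True)
    return (results, all_fits) if return_fits else results


# ---------------------------------------------------------------------------
# Trajectory prediction
# ---------------------------------------------------------------------------


def predict_trajectories(
    fit: ModelFit, age_grid: np.ndarray, groups: Sequence[str] = ("control", "ADHD")
) -> pd.DataFrame:
    """Predicted metric vs age per group with pointwise standard errors.

    Covariates are held at reference levels: fd at the sample mean, scanner
    pre-upgrade, unmedicated, sex at the (female) reference. Grid ages
    outside the fitted range are flagged as extrapolated (and clamped in the
    spline basis).
    """
    if not fit.available:
        raise ValueError(f"model {fit.name!r} was not fitted")
    age_grid = np.asarray(age_grid, dtype=float)
    lo, hi = fit.design["age_bounds"]
    basis = (
        age_spline_basis(age_grid, fit.design["basis_dim"], bounds=(lo, hi))
        if any(n.startswith("s(age)") for n in fit.param_names)
        else None
    )
    rows = []
    for group in groups:
        gval = 1.0 if group == "ADHD" else 0.0
        x = np.zeros((age_grid.size, len(fit.param_names)))
        for j, name in enumerate(fit.param_names):
            if name == "intercept":
                x[:, j] = 1.0
            elif name == "fd":
                x[:, j] = fit.design["fd_ref"]
            elif name == "group_adhd":
                x[:, j] = gval
            elif name.startswith("group:s(age)"):
                k = int(name.rsplit(")", 1)[1])
                x[:, j] = gval * basis[:, k]
            elif name.startswith("s(age)"):
                k = int(name.rsplit(")", 1)[1])
                x[:, j] = basis[:, k]
            # scanner_post, medicated, sex_male stay at 0 (reference levels)
        pred = x @ fit.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", x, fit.cov_params, x))
        for a, p_, s_ in zip(age_grid, pred, se):
            rows.append(
                {
                    "age": float(a),
                    "group": group,
                    "predicted": float(p_),
                    "se": float(s_),
                    "extrapolated": bool(a < lo or a > hi),
                }
            )
    return pd.DataFrame(rows)
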