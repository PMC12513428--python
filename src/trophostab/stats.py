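"""Inference layer: how diversity and web structure relate to stability.

The workflow mirrors standard practice for cross-ecosystem comparative
analyses: indicators and stability metrics are log-transformed and
z-scored, screened for collinearity (VIF), then related to stability with
linear mixed models (random intercept per ecosystem type), random-forest
permutation importance, and a piecewise structural equation model whose
non-significant paths are backward-eliminated; direct and mediated
(indirect) effects are decomposed as products of standardized path
coefficients with bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

__all__ = [
    "zscore",
    "vif_screen",
    "GLMMResult",
    "fit_glmm",
    "rf_importance",
    "PathModel",
    "default_dag",
    "fit_piecewise_sem",
    "mediation",
    "quantile_partial_correlation",
    "group_compare",
]


def zscore(frame: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = frame.copy()
    for c in cols:
        v = out[c].astype(float)
        sd = v.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {c!r} has zero or undefined variance")
        out[c] = (v - v.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# collinearity screening


def vif_screen(frame: pd.DataFrame, predictors: list[str],
               threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor per predictor from auxiliary regressions."""
    x = frame[predictors].astype(float).to_numpy()
    rows = []
    for k, name in enumerate(predictors):
        others = np.column_stack([np.ones(len(x)), np.delete(x, k, axis=1)])
        y = x[:, k]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum(resid ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": name, "vif": vif, "flagged": vif > threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear mixed model with ecosystem-type random intercept


@dataclass
class GLMMResult:
    table: pd.DataFrame  # index: predictor; beta, se, ci_low, ci_high, p
    r2m: float
    r2c: float
    method: str = "mixed-lm-wald-z"
    converged: bool = True


class _OLSShim:
    """Quacks like a MixedLM result when the mixed fit is degenerate."""

    def __init__(self, res):
        self.params = res.params
        self.bse = res.bse
        self.cov_re = np.zeros((1, 1))
        self.scale = float(np.var(res.resid))
        self.converged = False


def _fit_mixed(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    exog = sm.add_constant(x, has_constant="add")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        for method in ("lbfgs", "powell"):
            try:
                return sm.MixedLM(y, exog, groups=groups).fit(
                    reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
        # degenerate sample for the mixed fit: plain least squares,
        # zero random-effect variance
        return _OLSShim(sm.OLS(y, exog).fit())


def fit_glmm(frame: pd.DataFrame, response: str,
             predictors: list[str] | None = None,
             group_col: str = "ecosystem_type") -> GLMMResult:
    """Standardized linear mixed model of one stability metric.

    Response and predictors are z-scored so fixed-effect estimates are
    directly comparable standardized coefficients; the ecosystem type
    enters as a random intercept.  Marginal/conditional R^2 follow the
    variance-partition convention (fixed vs fixed+random over total).
    """
    if predictors is None:
        predictors = [c for c in frame.columns
                      if c not in (response, group_col) and
                      np.issubdtype(frame[c].dtype, np.number)]
    df = frame[[response, *predictors, group_col]].dropna()
    df = zscore(df, [response, *predictors])
    res = _fit_mixed(df[response].to_numpy(),
                     df[predictors].to_numpy(),
                     df[group_col].to_numpy())
    k = len(predictors)
    beta = res.params[1:k + 1]
    se = res.bse[1:k + 1]
    z = sps.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2 * sps.norm.sf(np.abs(beta / se))
    table = pd.DataFrame({
        "beta": beta, "se": se,
        "ci_low": beta - z * se, "ci_high": beta + z * se, "p": pvals,
    }, index=predictors)
    xmat = sm.add_constant(df[predictors].to_numpy(), has_constant="add")
    yhat_fixed = xmat @ res.params[:k + 1]
    var_f = float(np.var(yhat_fixed))
    var_re = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    var_eps = float(res.scale)
    tot = var_f + var_re + var_eps
    return GLMMResult(
        table=table, r2m=var_f / tot, r2c=(var_f + var_re) / tot,
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# random forest permutation importance


def rf_importance(frame: pd.DataFrame, response: str,
                  predictors: list[str] | None = None,
                  n_trees: int = 1000, seed: int = 0,
                  n_repeats: int = 10) -> pd.DataFrame:
    """Permutation %IncMSE per predictor, ranked (largest first).

    %IncMSE is the increase in mean squared prediction error when one
    predictor is randomly permuted, as a percentage of the unpermuted MSE.
    """
    if predictors is None:
        predictors = [c for c in frame.columns
                      if c != response and np.issubdtype(frame[c].dtype, np.number)]
    df = frame[[response, *predictors]].dropna()
    x = df[predictors].to_numpy()
    y = df[response].to_numpy()
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(x, y)
    base_mse = float(np.mean((y - rf.predict(x)) ** 2))
    imp = permutation_importance(
        rf, x, y, scoring="neg_mean_squared_error",
        n_repeats=n_repeats, random_state=seed,
    )
    out = pd.DataFrame({
        "predictor": predictors,
        "pct_inc_mse": 100.0 * imp.importances_mean / max(base_mse, 1e-300),
        "sd": 100.0 * imp.importances_std / max(base_mse, 1e-300),
    }).sort_values("pct_inc_mse", ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# piecewise SEM


@dataclass
class PathModel:
    """A fitted piecewise structural equation model."""

    graph: nx.DiGraph
    coefficients: pd.DataFrame  # response, predictor, beta, se, p
    r2: pd.DataFrame            # response, r2m, r2c
    fisher_c: float
    fisher_df: int
    fisher_p: float
    eliminated: list[tuple[str, str, float]] = field(default_factory=list)
    group_col: str | None = "ecosystem_type"
    method: str = "mixed-lm-wald-z"
    warnings: list[str] = field(default_factory=list)

    def coef(self, source: str, target: str) -> float:
        m = self.coefficients
        row = m[(m["predictor"] == source) & (m["response"] == target)]
        return float(row["beta"].iloc[0]) if len(row) else 0.0


def default_dag(stability_var: str = "log_resistance") -> nx.DiGraph:
    """Conceptual starting model: diversity acts on stability directly and
    through connectance, interaction-strength heterogeneity and cycling."""
    g = nx.DiGraph()
    mediators = ["log_CI", "log_ISI_sd", "log_FCI"]
    for m in mediators:
        g.add_edge("log_NLG", m)
        g.add_edge(m, stability_var)
    g.add_edge("log_NLG", stability_var)
    return g


def _fit_node(df: pd.DataFrame, response: str, parents: list[str],
              group_col: str | None):
    """One local regression; returns (coef table rows, r2m, r2c)."""
    y = df[response].to_numpy()
    x = df[parents].to_numpy()
    if group_col is not None:
        res = _fit_mixed(y, x, df[group_col].to_numpy())
        k = len(parents)
        beta, se = res.params[1:k + 1], res.bse[1:k + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2 * sps.norm.sf(np.abs(beta / se))
        xmat = sm.add_constant(x, has_constant="add")
        var_f = float(np.var(xmat @ res.params[:k + 1]))
        var_re = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
        var_eps = float(res.scale)
    else:
        res = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
        k = len(parents)
        beta, se = res.params[1:k + 1], res.bse[1:k + 1]
        p = res.pvalues[1:k + 1]
        var_f = float(np.var(res.fittedvalues))
        var_re, var_eps = 0.0, float(np.var(res.resid))
    tot = var_f + var_re + var_eps
    rows = [{"response": response, "predictor": par,
             "beta": float(b), "se": float(s), "p": float(pv)}
            for par, b, s, pv in zip(parents, beta, se, p)]
    return rows, var_f / tot, (var_f + var_re) / tot


def _dsep_basis(graph: nx.DiGraph) -> list[tuple[str, str, list[str]]]:
    """Shipley's basis set: for each non-adjacent pair (excluding pairs of
    exogenous nodes), test independence conditioning on both parent sets."""
    order = list(nx.topological_sort(graph))
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if graph.has_edge(u, v) or graph.has_edge(v, u):
                continue
            pu = list(graph.predecessors(u))
            pv = list(graph.predecessors(v))
            if not pu and not pv:
                continue  # exogenous-exogenous correlations are unconstrained
            # regress the later (downstream) vertex on the earlier
            resp, pred = (v, u) if pv else (u, v)
            cond = sorted(set(pu) | set(pv) - {resp, pred})
            cond = [c for c in cond if c not in (resp, pred)]
            claims.append((resp, pred, cond))
    return claims


def fisher_c(df: pd.DataFrame, graph: nx.DiGraph,
             group_col: str | None) -> tuple[float, int, float]:
    """Fisher's C over the d-separation basis set; C ~ chi2(2k) under the
    hypothesis that no claimed-independent pair is linked."""
    claims = _dsep_basis(graph)
    if not claims:
        return 0.0, 0, 1.0
    logs = []
    for resp, pred, cond in claims:
        rows, _, _ = _fit_node(df, resp, [pred, *cond], group_col)
        logs.append(np.log(max(rows[0]["p"], 1e-300)))
    c = -2.0 * float(np.sum(logs))
    dof = 2 * len(claims)
    return c, dof, float(sps.chi2.sf(c, dof))


def fit_piecewise_sem(frame: pd.DataFrame, dag: nx.DiGraph,
                      alpha: float = 0.05,
                      group_col: str | None = "ecosystem_type") -> PathModel:
    """Fit each endogenous node as a (mixed) regression and backward-
    eliminate the least significant path while any p >= alpha.

    Ties in p are broken by removing the smaller |coefficient|.  Variables
    are z-scored once so all path coefficients are standardized.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("path specification contains a cycle")
    nodes = list(dag.nodes)
    cols = nodes + ([group_col] if group_col else [])
    df = frame[cols].dropna().reset_index(drop=True)
    df = zscore(df, nodes)

    g = dag.copy()
    eliminated: list[tuple[str, str, float]] = []
    warnings: list[str] = []
    while True:
        coef_rows, r2_rows = [], []
        for node in g.nodes:
            parents = list(g.predecessors(node))
            if not parents:
                continue
            rows, r2m, r2c = _fit_node(df, node, parents, group_col)
            coef_rows.extend(rows)
            r2_rows.append({"response": node, "r2m": r2m, "r2c": r2c})
        if not coef_rows:
            warnings.append("all paths eliminated")
            break
        worst = max(coef_rows, key=lambda r: (r["p"], -abs(r["beta"])))
        if worst["p"] >= alpha:
            g.remove_edge(worst["predictor"], worst["response"])
            eliminated.append(
                (worst["predictor"], worst["response"], worst["p"]))
            continue
        break

    coefs = pd.DataFrame(coef_rows if coef_rows else [],
                         columns=["response", "predictor", "beta", "se", "p"])
    r2 = pd.DataFrame(r2_rows if coef_rows else [],
                      columns=["response", "r2m", "r2c"])
    c, dof, p = fisher_c(df, g, group_col)
    return PathModel(graph=g, coefficients=coefs, r2=r2, fisher_c=c,
                     fisher_df=dof, fisher_p=p, eliminated=eliminated,
                     group_col=group_col, warnings=warnings)


def mediation(pathmodel: PathModel, frame: pd.DataFrame, source: str,
              mediator: str, target: str, n_boot: int = 2000,
              seed: int = 0) -> dict:
    """Decompose the source->target association into a direct path and the
    indirect path through one mediator (product of standardized
    coefficients), with percentile bootstrap CIs over webs."""
    a = pathmodel.coef(source, mediator)
    b = pathmodel.coef(mediator, target)
    direct = pathmodel.coef(source, target)
    indirect = a * b
    out = {"direct": direct, "indirect": indirect, "total": direct + indirect}
    if n_boot <= 0:
        return out

    g = pathmodel.graph
    nodes = list(g.nodes)
    group_col = pathmodel.group_col
    cols = nodes + ([group_col] if group_col else [])
    df = frame[cols].dropna().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(df)
    boots = {"direct": [], "indirect": [], "total": []}
    for _ in range(n_boot):
        samp = df.iloc[rng.integers(0, n, n)].reset_index(drop=True)
        try:
            samp_z = zscore(samp, nodes)
        except ValueError:
            continue
        coefs = {}
        for node in (mediator, target):
            parents = list(g.predecessors(node))
            if not parents:
                continue
            rows, _, _ = _fit_node(samp_z, node, parents, group_col)
            for r in rows:
                coefs[(r["predictor"], r["response"])] = r["beta"]
        ab = coefs.get((source, mediator), 0.0) * coefs.get((mediator, target), 0.0)
        d = coefs.get((source, target), 0.0)
        boots["indirect"].append(ab)
        boots["direct"].append(d)
        boots["total"].append(ab + d)
    for key in ("direct", "indirect", "total"):
        v = np.asarray(boots[key])
        if v.size:
            out[f"{key}_ci"] = (float(np.percentile(v, 2.5)),
                                float(np.percentile(v, 97.5)))
    return out


# ---------------------------------------------------------------------------
# quantile partial correlations and group comparison


def quantile_partial_correlation(quantile_frame: pd.DataFrame,
                                 indicators: pd.DataFrame) -> pd.DataFrame:
    """Partial correlation of stability at every 5% quantile with each
    indicator, controlling for the remaining indicators.

    Rows are quantile columns of ``quantile_frame``; a perfectly collinear
    control set yields NaN for that cell.
    """
    ind_cols = list(indicators.columns)
    x = indicators.to_numpy(dtype=float)
    out = {}
    for qcol in quantile_frame.columns:
        y = quantile_frame[qcol].to_numpy(dtype=float)
        row = {}
        for k, name in enumerate(ind_cols):
            controls = np.column_stack(
                [np.ones(len(y)), np.delete(x, k, axis=1)])
            rank = np.linalg.matrix_rank(controls)
            if rank < controls.shape[1]:
                row[name] = np.nan
                continue
            ry = y - controls @ np.linalg.lstsq(controls, y, rcond=None)[0]
            xk = x[:, k]
            rx = xk - controls @ np.linalg.lstsq(controls, xk, rcond=None)[0]
            # a residual that is numerically zero means the variable is
            # collinear with its controls: flag rather than report noise
            if (np.sum(rx**2) < 1e-10 * np.sum((xk - xk.mean()) ** 2)
                    or np.sum(ry**2) < 1e-10 * np.sum((y - y.mean()) ** 2)):
                row[name] = np.nan
                continue
            denom = np.sqrt(np.sum(ry**2) * np.sum(rx**2))
            row[name] = float(np.sum(ry * rx) / denom)
        out[qcol] = row
    return pd.DataFrame(out).T[ind_cols]


def group_compare(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-style all-pairs comparison with a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    v = np.asarray(values, dtype=float)
    glab = np.asarray(groups)
    keep = np.isfinite(v)
    v, glab = v[keep], glab[keep]
    uniq = sorted(pd.unique(glab))
    means = {u: float(v[glab == u].mean()) for u in uniq}
    if len(uniq) < 2:
        letters = {uniq[0]: "a"} if uniq else {}
    else:
        tk = pairwise_tukeyhsd(v, glab, alpha=alpha)
        sig_pairs = []
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, r in res.iterrows():
            if bool(r["reject"]):
                sig_pairs.append((str(r["group1"]), str(r["group2"])))
        sets: list[set] = [set(uniq)]
        for g1, g2 in sig_pairs:
            nxt = []
            for s in sets:
                if g1 in s and g2 in s:
                    nxt.append(s - {g1})
                    nxt.append(s - {g2})
                else:
                    nxt.append(s)
            sets = [s for s in nxt if s and
                    not any(s < t for t in nxt if s is not t)]
            dedup = []
            for s in sets:
                if s not in dedup:
                    dedup.append(s)
            sets = dedup
        order = sorted(uniq, key=lambda u: -means[u])
        sets.sort(key=lambda s: min(order.index(u) for u in s))
        letters = {u: "" for u in uniq}
        for ch, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
            for u in s:
                letters[u] += ch
    return pd.DataFrame({
        "group": uniq,
        "n": [int(np.sum(glab == u)) for u in uniq],
        "mean": [means[u] for u in uniq],
        "letters": [letters[u] for u in uniq],
    })
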