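"""Structural and flow-based ecosystem indicators.

Covers the descriptors used to characterize web architecture: number of
living groups (NLG), connectance (CI), trophic levels and the system
omnivory index (SOI), Finn's cycling index (FCI) and its detritus-free
variant (PCI), Finn's mean path length (FML), and the taxonomic resolution
index.  Flow-based indices operate on a :class:`FlowNetwork` of absolute
trophic flows derived from a balanced model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FoodWebModel, balance_residuals
from .local_stability import build_interaction_matrix, interaction_strength_stats

__all__ = [
    "FlowNetwork",
    "build_flow_network",
    "trophic_levels",
    "nlg",
    "resolution_index",
    "connectance_index",
    "system_omnivory_index",
    "finn_cycling_index",
    "predatory_cycling_index",
    "finn_mean_path_length",
    "indicator_table",
]


@dataclass
class FlowNetwork:
    """Absolute flows (t/km^2/yr) at steady state.

    ``t[i, j]`` is the flow from compartment ``i`` to ``j`` (consumption and
    flows to detritus).  Primary production enters as an import to producers
    so that every compartment satisfies inflow = outflow.
    """

    names: list[str]
    t: np.ndarray
    imports: np.ndarray
    exports: np.ndarray
    respiration: np.ndarray
    detritus: np.ndarray  # boolean mask
    warnings: list[str] = field(default_factory=list)

    @property
    def throughflow(self) -> np.ndarray:
        return self.imports + self.t.sum(axis=0)

    @property
    def total_system_throughflow(self) -> float:
        return float(self.throughflow.sum())

    def check_steady_state(self, rtol: float = 1e-6) -> None:
        inflow = self.throughflow
        outflow = self.t.sum(axis=1) + self.exports + self.respiration
        scale = max(1.0, float(inflow.max()))
        if np.max(np.abs(inflow - outflow)) > rtol * scale:
            raise ValueError("flow network violates per-compartment steady state")


def build_flow_network(model: FoodWebModel) -> FlowNetwork:
    """Derive the absolute flow matrix from a balanced model.

    Unassimilated consumption (gs*Q) and non-predation mortality
    ((1-EE)*P) flow to detritus, split equally across detritus pools;
    surplus detritus inflow is exported, a shortfall becomes a (flagged)
    detritus import so the steady-state bookkeeping closes.
    """
    resid = balance_residuals(model)
    n = model.n
    b = model.param("biomass")
    pb = model.param("pb")
    qb = model.param("qb")
    ee = model.param("ee")
    scale = max(1.0, float(np.nanmax(np.abs(pb * b))))
    if np.max(np.abs(resid)) > 1e-6 * scale:
        raise ValueError("model is not balanced")

    warnings: list[str] = []
    t = np.zeros((n, n))
    imports = np.zeros(n)
    exports = np.zeros(n)
    resp = np.zeros(n)
    det_idx = np.where(model.detritus)[0]
    imp_frac = model.diet_import()

    for j, g in enumerate(model.groups):
        if not g.is_living:
            continue
        q = b[j] * (qb[j] if qb[j] else 0.0)
        p = b[j] * pb[j]
        t[:, j] += q * model.diet[:, j]
        imports[j] += imp_frac[j] * q
        if g.is_producer:
            imports[j] += p  # primary production as external input
        imports[j] += max(-g.emig, 0.0) + max(-g.ba, 0.0)
        exports[j] += g.catch + max(g.emig, 0.0) + max(g.ba, 0.0)
        to_det = g.gs * q + (1.0 - ee[j]) * p
        if det_idx.size:
            t[j, det_idx] += to_det / det_idx.size
        else:
            exports[j] += to_det
        if not g.is_producer:
            r = (1.0 - g.gs) * q - p
            if r < 0:
                warnings.append(f"{g.name}: negative respiration floored at 0")
                r = 0.0
            resp[j] = r

    for d in det_idx:
        inflow = t[:, d].sum()
        consumption = t[d, :].sum()
        if inflow >= consumption:
            exports[d] = inflow - consumption
        else:
            imports[d] = consumption - inflow
            warnings.append(
                f"{model.groups[d].name}: detritus deficit covered by import"
            )

    fn = FlowNetwork(
        names=model.names, t=t, imports=imports, exports=exports,
        respiration=resp, detritus=model.detritus.copy(), warnings=warnings,
    )
    fn.check_steady_state()
    return fn


# ---------------------------------------------------------------------------
# structural indices


def trophic_levels(model: FoodWebModel) -> np.ndarray:
    """Fractional trophic levels: 1 for producers and detritus,
    TL_j = 1 + sum_i DC_ij TL_i for consumers (linear solve)."""
    n = model.n
    a = np.eye(n)
    bvec = np.ones(n)
    for j, g in enumerate(model.groups):
        if g.is_living and (g.qb or 0) > 0:
            # TL_j - sum_i DC_ij TL_i = 1 (self-feeding stays on the lhs)
            a[j, :] = -model.diet[:, j]
            a[j, j] += 1.0
    try:
        tl = np.linalg.solve(a, bvec)
    except np.linalg.LinAlgError as exc:
        raise ValueError("trophic levels undefined: pure diet cycle with no "
                         "basal input") from exc
    if not np.all(np.isfinite(tl)):
        raise ValueError("trophic levels are non-finite")
    return tl


def nlg(model: FoodWebModel) -> int:
    """Number of living groups (trophic-species diversity)."""
    return int(model.living.sum())


def resolution_index(model: FoodWebModel) -> float:
    """Mean taxonomic resolution index over living groups (0.1..1)."""
    vals = [g.resolution for g in model.groups if g.is_living]
    return float(np.mean(vals))


def connectance_index(model: FoodWebModel, threshold: float = 0.0) -> float:
    """CI = L / S^2 over living groups, counting diet links with DC > threshold."""
    live = model.living
    s = int(live.sum())
    sub = model.diet[np.ix_(live, live)]
    links = int(np.count_nonzero(sub > threshold))
    return links / s**2


def system_omnivory_index(
    model: FoodWebModel, *, weighting: str = "log_q"
) -> float:
    """Consumption-weighted mean of per-consumer omnivory indices.

    OI_j = sum_i DC_ij (TL_i - (TL_j - 1))^2, the diet-weighted variance of
    prey trophic levels; SOI averages OI over consumers weighted by log of
    total consumption (consumers with Q <= 1 carry no weight), or
    unweighted with ``weighting='unweighted'``.
    """
    tl = trophic_levels(model)
    b = model.param("biomass")
    qb = model.param("qb")
    ois, weights = [], []
    for j, g in enumerate(model.groups):
        if not (g.is_living and (g.qb or 0) > 0):
            continue
        col = model.diet[:, j]
        oi = float(np.sum(col * (tl - (tl[j] - 1.0)) ** 2))
        q = b[j] * qb[j]
        ois.append(oi)
        weights.append(math.log(q) if q > 1 else 0.0)
    if not ois:
        return float("nan")
    if weighting == "unweighted" or sum(weights) <= 0:
        return float(np.mean(ois))
    return float(np.dot(ois, weights) / sum(weights))


# ---------------------------------------------------------------------------
# flow indices


def _fci(t: np.ndarray, throughflow: np.ndarray) -> float:
    active = throughflow > 0
    if not np.any(active):
        return 0.0
    tt = t[np.ix_(active, active)]
    tau = throughflow[active]
    g = tt / tau[np.newaxis, :]
    try:
        leon = np.linalg.inv(np.eye(len(tau)) - g)
    except np.linalg.LinAlgError as exc:
        raise ValueError("non-dissipative network") from exc
    diag = np.diag(leon)
    if np.any(diag <= 0) or not np.all(np.isfinite(leon)):
        raise ValueError("non-dissipative network")
    cycled = float(np.sum((diag - 1.0) / diag * tau))
    tst = float(throughflow.sum())
    return cycled / tst


def finn_cycling_index(flows: FlowNetwork) -> float:
    """Fraction of total system throughflow that is recycled (Leontief)."""
    return _fci(flows.t, flows.throughflow)


def predatory_cycling_index(flows: FlowNetwork) -> float:
    """FCI recomputed with detritus compartments removed (their consumption
    becomes an import to the consumer, flows into them an export)."""
    keep = ~flows.detritus
    if np.all(keep):
        return finn_cycling_index(flows)
    t = flows.t[np.ix_(keep, keep)]
    imports = flows.imports[keep] + flows.t[np.ix_(~keep, keep)].sum(axis=0)
    throughflow = imports + t.sum(axis=0)
    return _fci(t, throughflow)


def finn_mean_path_length(flows: FlowNetwork) -> float:
    """FML = total system throughflow / total external input (imports
    include primary production)."""
    total_in = float(flows.imports.sum())
    if total_in <= 0:
        raise ValueError("network has no external input")
    return flows.total_system_throughflow / total_in


# ---------------------------------------------------------------------------
# indicator table

#: indices that can be exactly zero get log(x + eps)
_EPS_COLS = ("CI", "ISI_mean", "ISI_sd", "SOI", "FCI", "PCI")
LOG_EPS = 1e-6


def indicator_table(
    models: list[FoodWebModel],
    *,
    ci_threshold: float = 0.0,
    isi_scope: str = "both",
    soi_weighting: str = "log_q",
) -> pd.DataFrame:
    """One row of structural indicators per web, plus natural-log columns."""
    rows = []
    for m in models:
        fn = build_flow_network(m)
        im = build_interaction_matrix(m)
        isi = interaction_strength_stats(im, scope=isi_scope)
        rows.append({
            "web": m.name,
            "ecosystem_type": m.ecosystem_type,
            "NLG": nlg(m),
            "CI": connectance_index(m, ci_threshold),
            "ISI_mean": isi["ISI_mean"],
            "ISI_sd": isi["ISI_sd"],
            "SOI": system_omnivory_index(m, weighting=soi_weighting),
            "FCI": finn_cycling_index(fn),
            "PCI": predatory_cycling_index(fn),
            "FML": finn_mean_path_length(fn),
            "resolution": resolution_index(m),
        })
    df = pd.DataFrame(rows)
    for col in ("NLG", "FML", "resolution"):
        df[f"log_{col}"] = np.log(df[col].astype(float))
    for col in _EPS_COLS:
        df[f"log_{col}"] = np.log(df[col].astype(float) + LOG_EPS)
    return df
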