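"""Community interaction matrix and local (asymptotic) stability.

For each realized trophic link (prey ``i``, predator ``j``) the per-unit
interaction strengths are

    a_ij = -(Q/B)_j * DC_ij / B_i          (effect of predator on prey, < 0)
    a_ji = -e_ij * a_ij,  e_ij = (P/B)_j / (Q/B)_j   (prey on predator, > 0)

with a zero diagonal (no self-regulation), so the matrix trace is zero and
local stability = -Re[lambda_max(A)] is at most 0: the measure is a
*relative* local stability, larger meaning more stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FoodWebModel, balance_residuals

__all__ = [
    "InteractionMatrix",
    "build_interaction_matrix",
    "local_stability",
    "interaction_strength_stats",
]


@dataclass
class InteractionMatrix:
    """Square community matrix over living groups (1/yr units).

    ``a[i, j]`` is the per-unit effect of group ``j`` on group ``i``;
    ``links[i, j]`` marks realized predator(j)-prey(i) pairs.
    """

    a: np.ndarray
    names: list[str]
    links: np.ndarray

    @property
    def n(self) -> int:
        return self.a.shape[0]


def build_interaction_matrix(
    model: FoodWebModel, *, literal_printed_aij: bool = False
) -> InteractionMatrix:
    """Build A from a balanced model; detritus rows/columns are dropped.

    ``literal_printed_aij=True`` uses the prey's Q/B in a_ij instead of the
    predator's (a non-standard dialect kept for comparison; producers then
    contribute no top-down term since their Q/B is 0).
    """
    resid = balance_residuals(model)
    b = model.param("biomass")
    pb = model.param("pb")
    qb = model.param("qb")
    scale = max(1.0, float(np.nanmax(pb[model.living] * b[model.living])))
    if np.max(np.abs(resid)) > 1e-6 * scale:
        raise ValueError("model is not balanced; run solve_mass_balance first")

    live = np.where(model.living)[0]
    pos = {gi: k for k, gi in enumerate(live)}
    n = len(live)
    a = np.zeros((n, n))
    links = np.zeros((n, n), dtype=bool)
    for j in live:
        gj = model.groups[j]
        col = model.diet[:, j]
        if (gj.qb or 0) == 0:
            if np.any(col > 0):
                raise ValueError(f"group {gj.name!r} has qb=0 but a nonzero diet")
            continue
        e = pb[j] / qb[j]
        for i in np.where(col > 0)[0]:
            if not model.groups[i].is_living:
                continue  # detritivory does not enter the living-group matrix
            qb_eff = qb[i] if literal_printed_aij else qb[j]
            aij = -(qb_eff * col[i]) / b[i]
            pi, pj = pos[i], pos[j]
            if pi == pj:
                continue  # cannibalism would break the zero diagonal
            a[pi, pj] += aij
            a[pj, pi] += -e * aij
            links[pi, pj] = True
    np.fill_diagonal(a, 0.0)
    return InteractionMatrix(a=a, names=[model.groups[i].name for i in live], links=links)


def local_stability(a: InteractionMatrix | np.ndarray) -> float:
    """-Re of the dominant eigenvalue of A; larger = more stable."""
    m = a.a if isinstance(a, InteractionMatrix) else np.asarray(a, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("interaction matrix must be square")
    if not np.all(np.isfinite(m)):
        raise ValueError("interaction matrix has non-finite entries")
    if m.size == 0:
        return 0.0
    return float(-np.max(np.linalg.eigvals(m).real))


def interaction_strength_stats(
    im: InteractionMatrix, *, scope: str = "both"
) -> dict[str, float]:
    """Mean and SD of interaction-strength magnitudes (ISI_mean, ISI_sd).

    ``scope='both'`` pools |a_ij| of both directions of every link;
    ``scope='predator'`` uses only the (negative) predator-on-prey entries.
    Returns NaNs when the web has no links.
    """
    if scope not in ("both", "predator"):
        raise ValueError(f"unknown scope {scope!r}")
    off = ~np.eye(im.n, dtype=bool)
    if scope == "both":
        vals = np.abs(im.a[off & (im.a != 0)])
    else:
        vals = np.abs(im.a[off & (im.a < 0)])
    if vals.size == 0:
        return {"ISI_mean": float("nan"), "ISI_sd": float("nan")}
    return {"ISI_mean": float(vals.mean()), "ISI_sd": float(vals.std(ddof=0))}
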