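"""Ecopath-style food web models and the static mass-balance solver.

A food web is a set of functional *groups* (living groups plus one or more
detritus pools) linked by a diet-composition matrix.  For every living group
``i`` the steady-state balance reads::

    (P/B)_i * B_i * EE_i  -  sum_j B_j * (Q/B)_j * DC_ij  -  Y_i - E_i - BA_i  =  0

where ``B`` is biomass (t/km^2), ``P/B`` and ``Q/B`` are production and
consumption per unit biomass (1/yr), ``EE`` the ecotrophic efficiency (the
fraction of production consumed within the system, exported or accumulated),
``DC_ij`` the proportion of prey ``i`` in the diet of predator ``j``, ``Y``
fisheries catch, ``E`` net emigration and ``BA`` biomass accumulation
(t/km^2/yr).  At most one of {B, P/B, Q/B, EE} may be unknown per living
group; the solver fills the unknowns so that every balance equation holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ECOSYSTEM_TYPES",
    "RESOLUTION_LEVELS",
    "Group",
    "FoodWebModel",
    "ValidationReport",
    "UnsolvableError",
    "InfeasibleError",
    "solve_mass_balance",
    "balance_residuals",
    "validate_model",
    "read_model",
    "write_model",
]

ECOSYSTEM_TYPES = (
    "bay",
    "coastal lagoon",
    "continental shelf",
    "estuary",
    "open ocean",
    "upwelling",
)

#: taxonomic species / family-class / trophic function / general name
RESOLUTION_LEVELS = (1.0, 0.7, 0.4, 0.1)

_BALANCE_FIELDS = ("biomass", "pb", "qb", "ee")


class UnsolvableError(ValueError):
    """The mass-balance system is over-/under-determined or singular."""


class InfeasibleError(ValueError):
    """The mass-balance solution is non-finite or physically impossible."""


@dataclass
class Group:
    """One functional group of a food web.

    ``None`` marks an unknown parameter to be estimated by the balance
    solver.  Detritus pools (``is_living=False``) do not use ``pb``, ``qb``
    or ``ee``; their biomass may still be given (it is needed by the dynamic
    simulation when detritivory is present).
    """

    name: str
    is_living: bool = True
    biomass: float | None = None
    pb: float | None = None
    qb: float | None = None
    ee: float | None = None
    catch: float = 0.0
    ba: float = 0.0
    emig: float = 0.0
    gs: float = 0.2  # unassimilated fraction of consumption
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.biomass is not None and not self.biomass > 0:
            raise ValueError(f"group {self.name!r}: biomass must be > 0")
        for fld in ("pb", "qb"):
            v = getattr(self, fld)
            if v is not None and v < 0:
                raise ValueError(f"group {self.name!r}: {fld} must be >= 0")
        if self.catch < 0:
            raise ValueError(f"group {self.name!r}: catch must be >= 0")
        if not 0.0 <= self.gs < 1.0:
            raise ValueError(f"group {self.name!r}: gs must be in [0, 1)")

    @property
    def is_producer(self) -> bool:
        return self.is_living and (self.qb == 0)

    @property
    def is_detritus(self) -> bool:
        return not self.is_living

    def unknowns(self) -> list[str]:
        if not self.is_living:
            return []
        return [f for f in _BALANCE_FIELDS if getattr(self, f) is None]


@dataclass
class FoodWebModel:
    """An ordered group list, a diet matrix and an ecosystem-type label.

    ``diet[i, j]`` is the proportion of prey ``i`` in the diet of predator
    ``j`` (columns are consumers).  Consumer columns may sum to less than 1;
    the shortfall is treated as diet import (feeding outside the system),
    never renormalized.
    """

    groups: list[Group]
    diet: np.ndarray
    ecosystem_type: str = "bay"
    name: str = "web"
    flags: list[str] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        self.diet = np.asarray(self.diet, dtype=float)
        n = len(self.groups)
        if self.diet.shape != (n, n):
            raise ValueError(
                f"diet matrix {self.diet.shape} does not match {n} groups"
            )
        if self.ecosystem_type not in ECOSYSTEM_TYPES:
            raise ValueError(f"unknown ecosystem type {self.ecosystem_type!r}")
        if np.any(self.diet < -1e-12) or np.any(self.diet > 1 + 1e-9):
            raise ValueError("diet proportions must lie in [0, 1]")
        sums = self.diet.sum(axis=0)
        for j, g in enumerate(self.groups):
            if g.is_detritus or g.qb == 0:
                if np.any(self.diet[:, j] != 0):
                    raise ValueError(
                        f"non-consumer column {g.name!r} must be all-zero"
                    )
            elif sums[j] > 1 + 1e-9:
                raise ValueError(
                    f"diet column {g.name!r} sums to {sums[j]:.6g} > 1"
                )
        if sum(g.is_living for g in self.groups) < 2:
            raise ValueError("a web needs at least 2 living groups")
        if not any(g.is_producer or g.is_detritus for g in self.groups):
            raise ValueError("a web needs a producer or detritus group")

    # -- indexing helpers ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def living(self) -> np.ndarray:
        return np.array([g.is_living for g in self.groups], dtype=bool)

    @property
    def detritus(self) -> np.ndarray:
        return ~self.living

    def index(self, name: str) -> int:
        return self.names.index(name)

    def copy(self) -> "FoodWebModel":
        return FoodWebModel(
            groups=[replace(g) for g in self.groups],
            diet=self.diet.copy(),
            ecosystem_type=self.ecosystem_type,
            name=self.name,
            flags=list(self.flags),
        )

    def param(self, fld: str, fill: float = np.nan) -> np.ndarray:
        """Vector of one group field with ``fill`` for unknown/detritus."""
        out = np.full(self.n, fill, dtype=float)
        for i, g in enumerate(self.groups):
            v = getattr(g, fld)
            if v is not None:
                out[i] = v
        return out

    def diet_import(self) -> np.ndarray:
        """Per-group diet shortfall (proportion of diet fed outside)."""
        imp = np.zeros(self.n)
        for j, g in enumerate(self.groups):
            if g.is_living and (g.qb or 0) > 0:
                imp[j] = max(0.0, 1.0 - float(self.diet[:, j].sum()))
        return imp


# ---------------------------------------------------------------------------
# mass balance


def _residual_vector(model: FoodWebModel, values: dict[tuple[int, str], float]) -> np.ndarray:
    """Balance residual per living group, with ``values`` overriding unknowns
    (unset unknowns are taken as 0)."""

    def get(i: int, fld: str) -> float:
        v = getattr(model.groups[i], fld)
        if v is None:
            v = values.get((i, fld), 0.0)
        return float(v)

    n = model.n
    res = np.zeros(n)
    cons = np.zeros(n)  # predation pressure on each prey
    for j, g in enumerate(model.groups):
        if not g.is_living:
            continue
        q = get(j, "biomass") * get(j, "qb")
        if q:
            cons += q * model.diet[:, j]
    for i, g in enumerate(model.groups):
        if not g.is_living:
            continue
        prod = get(i, "pb") * get(i, "biomass") * get(i, "ee")
        res[i] = prod - cons[i] - g.catch - g.emig - g.ba
    return res[model.living]


def balance_residuals(model: FoodWebModel) -> np.ndarray:
    """Left-hand side of the balance equation per living group (t/km^2/yr)."""
    missing = [g.name for g in model.groups if g.unknowns()]
    if missing:
        raise ValueError(f"missing parameters on groups: {missing}")
    return _residual_vector(model, {})


def solve_mass_balance(model: FoodWebModel) -> FoodWebModel:
    """Fill the unknown parameter of each living group from mass balance.

    The balance system with at most one unknown per group is affine in the
    unknowns, so all coupled unknowns are solved in one linear least-squares
    step; rank deficiency or an inconsistent over-determined system raises
    :class:`UnsolvableError`.  A solved ``EE`` outside [0, 1] raises
    :class:`InfeasibleError` if negative, or adds a warning flag if above 1.
    """
    unknowns: list[tuple[int, str]] = []
    for i, g in enumerate(model.groups):
        u = g.unknowns()
        if len(u) > 1:
            raise UnsolvableError(
                f"group {g.name!r} has {len(u)} unknowns ({u}); at most one "
                "of B, P/B, Q/B, EE may be missing"
            )
        unknowns.extend((i, fld) for fld in u)

    out = model.copy()
    if not unknowns:
        return out

    # affine system: residual(x) = c + M x over the unknown vector x
    c = _residual_vector(model, {})
    cols = []
    for key in unknowns:
        cols.append(_residual_vector(model, {key: 1.0}) - c)
    m = np.column_stack(cols)
    # keep only equations that actually involve an unknown
    involved = np.any(m != 0, axis=1)
    m_i, c_i = m[involved], c[involved]
    living_names = [g.name for g in model.groups if g.is_living]
    if np.linalg.matrix_rank(m_i) < len(unknowns) if m_i.size else True:
        names = sorted({model.groups[i].name for i, _ in unknowns})
        raise UnsolvableError(f"unsolvable balance system for groups: {names}")
    x, *_ = np.linalg.lstsq(m_i, -c_i, rcond=None)
    resid = m_i @ x + c_i
    scale = max(1.0, float(np.max(np.abs(c_i))) if c_i.size else 1.0)
    if np.max(np.abs(resid)) > 1e-8 * scale:
        bad = [living_names[k] for k in np.where(involved)[0][np.abs(resid) > 1e-8 * scale]]
        raise UnsolvableError(f"inconsistent balance equations for groups: {bad}")

    for (i, fld), v in zip(unknowns, x):
        g = out.groups[i]
        if not math.isfinite(v):
            raise InfeasibleError(f"group {g.name!r}: solved {fld} is not finite")
        if fld == "ee" and v < -1e-12:
            raise InfeasibleError(f"group {g.name!r}: solved EE = {v:.4g} < 0")
        if fld != "ee" and v <= 0:
            raise InfeasibleError(f"group {g.name!r}: solved {fld} = {v:.4g} <= 0")
        v = float(v)
        if fld == "ee":
            v = max(v, 0.0)
            if v > 1 + 1e-9:
                out.flags.append(f"{g.name}: solved EE = {v:.4g} > 1")
        setattr(g, fld, v)
    return out


# ---------------------------------------------------------------------------
# validation

_PQ_RANGE = (0.05, 0.35)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors


def validate_model(model: FoodWebModel) -> ValidationReport:
    """Lightweight pre-balance sanity checks (report-only, never raises).

    Checks EE in [0, 1], gross food-conversion efficiency P/Q in
    [0.05, 0.35] for consumers, diet column sums, and parameter positivity.
    """
    rep = ValidationReport()
    sums = model.diet.sum(axis=0)
    for j, g in enumerate(model.groups):
        if not g.is_living:
            continue
        if g.ee is not None:
            if g.ee < 0:
                rep.errors.append(f"{g.name}: EE = {g.ee:.4g} < 0")
            elif g.ee > 1 + 1e-9:
                rep.warnings.append(f"{g.name}: EE = {g.ee:.4g} > 1")
        if g.biomass is not None and g.biomass <= 0:
            rep.errors.append(f"{g.name}: non-positive biomass")
        if (g.qb or 0) > 0 and g.pb is not None and g.qb is not None:
            pq = g.pb / g.qb
            lo, hi = _PQ_RANGE
            if not lo <= pq <= hi:
                rep.warnings.append(
                    f"{g.name}: P/Q = {pq:.3g} out of range [{lo}, {hi}]"
                )
        if sums[j] > 1 + 1e-9:
            rep.errors.append(f"{g.name}: diet column sums to {sums[j]:.6g} > 1")
    return rep


# ---------------------------------------------------------------------------
# tabular I/O
#
# A model on disk is a directory with groups.csv (one row per group; empty
# cell = unknown), diet.csv (square matrix, header row/column = group names)
# and meta.yaml (name, ecosystem_type).  Rates are per year, biomass t/km^2.

_GROUP_COLS = [
    "name", "is_living", "B", "PB", "QB", "EE",
    "catch", "BA", "E", "GS", "resolution",
]


def write_model(model: FoodWebModel, path) -> None:
    from pathlib import Path

    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in model.groups:
        rows.append({
            "name": g.name,
            "is_living": int(g.is_living),
            "B": g.biomass, "PB": g.pb, "QB": g.qb, "EE": g.ee,
            "catch": g.catch, "BA": g.ba, "E": g.emig,
            "GS": g.gs, "resolution": g.resolution,
        })
    pd.DataFrame(rows, columns=_GROUP_COLS).to_csv(d / "groups.csv", index=False)
    pd.DataFrame(model.diet, index=model.names, columns=model.names).to_csv(
        d / "diet.csv"
    )
    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump(
            {"name": model.name, "ecosystem_type": model.ecosystem_type}, fh
        )


def read_model(path) -> FoodWebModel:
    from pathlib import Path

    d = Path(path)
    gdf = pd.read_csv(d / "groups.csv")
    missing = [c for c in _GROUP_COLS if c not in gdf.columns]
    if missing:
        raise ValueError(f"groups.csv: malformed header, missing {missing}")
    groups = []
    for _, r in gdf.iterrows():
        def opt(v):
            return None if pd.isna(v) else float(v)

        groups.append(Group(
            name=str(r["name"]),
            is_living=bool(int(r["is_living"])),
            biomass=opt(r["B"]), pb=opt(r["PB"]), qb=opt(r["QB"]), ee=opt(r["EE"]),
            catch=float(r["catch"]) if not pd.isna(r["catch"]) else 0.0,
            ba=float(r["BA"]) if not pd.isna(r["BA"]) else 0.0,
            emig=float(r["E"]) if not pd.isna(r["E"]) else 0.0,
            gs=float(r["GS"]) if not pd.isna(r["GS"]) else 0.2,
            resolution=float(r["resolution"]) if not pd.isna(r["resolution"]) else 1.0,
        ))
    ddf = pd.read_csv(d / "diet.csv", index_col=0)
    names = [g.name for g in groups]
    if ddf.shape[0] != ddf.shape[1] or ddf.shape[0] != len(names):
        raise ValueError(
            f"diet.csv: dimension mismatch, {ddf.shape} for {len(names)} groups"
        )
    if list(ddf.index) != names or list(ddf.columns) != names:
        raise ValueError("diet.csv: row/column names do not match groups.csv")
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    return FoodWebModel(
        groups=groups,
        diet=ddf.to_numpy(dtype=float),
        ecosystem_type=meta.get("ecosystem_type", "bay"),
        name=str(meta.get("name", d.name)),
    )
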