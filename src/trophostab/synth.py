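"""Synthetic food webs and statistical benchmarks.

Two generators feed the pipeline's validation:

* mechanistic webs — niche-model topologies (6-81 living groups,
  connectance 0.1-0.7) with a biomass pyramid, allometrically decreasing
  consumption rates, biomass-weighted Dirichlet-noise diets and one
  detritus pool, rejection-sampled until the mass balance yields
  ecotrophic efficiencies in [0, 1] and a non-deficient detritus budget;
* statistical benchmarks — linear/path-model data with known standardized
  coefficients and an ecosystem-type random intercept, the ground truth
  for the inference layer's recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ECOSYSTEM_TYPES, FoodWebModel, Group, solve_mass_balance, validate_model

__all__ = [
    "WebGenSpec",
    "BenchSpec",
    "generate_topology",
    "generate_balanced_web",
    "generate_ensemble",
    "generate_benchmark",
]

RESOLUTION_CHOICES = (1.0, 0.7, 0.4, 0.1)
RESOLUTION_PROBS = (0.3, 0.3, 0.25, 0.15)


@dataclass(frozen=True)
class WebGenSpec:
    """Study conditions for the mechanistic web generator.

    Producers get log-normal biomasses and algal-range P/B; consumer Q/B
    falls allometrically with niche position and consumer biomass follows
    from intake demand, so a biomass pyramid emerges.  Each consumer's
    intake is drawn as a fraction of the production still available in its
    prey pool (at most ``avail_frac`` of any group's production is exposed
    to predation), which keeps the solved ecotrophic efficiencies inside
    [0, 1] for almost every draw.
    """

    n_groups: tuple[int, int] = (6, 81)
    connectance: tuple[float, float] = (0.1, 0.7)
    ecosystem_types: tuple[str, ...] = ECOSYSTEM_TYPES
    producer_b_log10: tuple[float, float] = (1.5, 0.4)  # mean, sd
    producer_pb_log10: tuple[float, float] = (1.2, 2.2)  # uniform range
    qb_log10_intercept: float = 1.4
    qb_log10_slope: float = 1.1
    qb_log10_sigma: float = 0.15
    pq_range: tuple[float, float] = (0.05, 0.3)
    avail_frac: tuple[float, float] = (0.5, 0.95)
    demand_frac: tuple[float, float] = (0.05, 0.4)
    diet_noise_shape: float = 0.7
    detritus_pool_frac: float = 0.4
    fishing_prob: float = 0.3
    fishing_max_frac: float = 0.1
    gs: float = 0.2
    max_attempts: int = 200

    def __post_init__(self) -> None:
        for rng_fld in ("n_groups", "connectance", "pq_range"):
            lo, hi = getattr(self, rng_fld)
            if lo > hi:
                raise ValueError(f"{rng_fld}: range must be ordered")


@dataclass(frozen=True)
class BenchSpec:
    """Ground truth for statistical recovery benchmarks.

    ``effects`` describes a flat regression (predictor -> beta on one
    response); ``paths`` a causal chain/DAG as (response, predictor, beta)
    triples.  All coefficients are on the standardized scale; residual SDs
    are completed so every variable has (approximately) unit variance.
    """

    effects: dict = field(default_factory=dict)
    paths: tuple = ()
    response: str = "y"
    random_sd: float = 0.3
    resid_sd: float | None = None
    n: int = 500
    n_types: int = 6

    def __post_init__(self) -> None:
        n_pred = len(self.effects) or len({p for _, p, _ in self.paths})
        if n_pred and self.n < 10 * n_pred:
            raise ValueError("n must be at least 10x the predictor count")


# ---------------------------------------------------------------------------
# topology


def generate_topology(s: int, c_target: float, seed=None,
                      max_tries: int = 2000):
    """Niche-model link set over ``s`` living groups.

    Returns ``(links, niche)`` where ``links`` is a set of (prey, predator)
    index pairs (cannibalism excluded) and ``niche`` the sorted niche
    values.  Realized connectance L/s^2 lands within +-0.05 of the target;
    every group is connected and every consumer can reach a producer.
    """
    rng = np.random.default_rng(seed)
    if s < 2:
        raise ValueError("need at least 2 living groups")
    for _ in range(max_tries):
        niche = np.sort(rng.uniform(0, 1, s))
        if c_target < 0.45:
            beta = 1.0 / (2.0 * c_target) - 1.0
            ranges = niche * rng.beta(1.0, beta, s)
        else:
            # dense webs exceed what contiguity below the niche value allows
            ranges = rng.beta(10.0 * c_target, 10.0 * (1 - c_target), s)
        ranges = np.minimum(ranges, 0.95)
        ranges[0] = 0.0  # lowest-niche group is always a producer
        lo = np.array([rng.uniform(r / 2.0, max(min(n, 1 - r / 2.0), r / 2.0))
                       for n, r in zip(niche, ranges)]) - ranges / 2.0
        hi = lo + ranges
        links = set()
        for j in range(s):
            if ranges[j] <= 0:
                continue
            for i in range(s):
                if i != j and lo[j] <= niche[i] <= hi[j]:
                    links.add((i, j))
        if not links:
            continue
        realized = len(links) / s**2
        if abs(realized - c_target) > 0.05:
            continue
        preys = {j for _, j in links}
        producers = set(range(s)) - preys
        if not producers:
            continue
        degree = set()
        for i, j in links:
            degree.add(i)
            degree.add(j)
        if len(degree) < s:  # no isolated groups
            continue
        # every consumer must reach a producer through its prey
        reach = set(producers)
        changed = True
        prey_of = {j: {i for i, jj in links if jj == j} for j in preys}
        while changed:
            changed = False
            for j in preys - reach:
                if prey_of[j] & reach:
                    reach.add(j)
                    changed = True
        if preys - reach:
            continue
        return links, niche
    raise RuntimeError(
        f"could not realize connectance {c_target:.2f} for s={s}")


# ---------------------------------------------------------------------------
# balanced webs


def _draw_web(spec: WebGenSpec, s: int, niche, prey_of, rng):
    """One energetics-aware parameter/diet proposal.

    Consumers are processed in niche order; each draws its total intake as
    a fraction of the production still unclaimed in its prey pool (a
    per-prey ledger capped below production), and its diet column records
    the realized takes.  Biomass then follows as intake / (Q/B).
    Returns (b, pb, qb, diet over s+1 groups incl. detritus, b_det).
    """
    producers = sorted(i for i in range(s) if not prey_of.get(i))
    b = np.zeros(s)
    pb = np.zeros(s)
    qb = np.zeros(s)
    for i in producers:
        b[i] = 10.0 ** rng.normal(*spec.producer_b_log10)
        pb[i] = 10.0 ** rng.uniform(*spec.producer_pb_log10)

    det = s
    avail = np.zeros(s + 1)  # production still open to predation
    for i in producers:
        avail[i] = rng.uniform(*spec.avail_frac) * pb[i] * b[i]
    p_prod_total = float(np.sum(pb[producers] * b[producers]))
    # detritus standing stock is typically of the order of (or above) the
    # producer biomass; a large slow pool also keeps its turnover moderate
    b_det = float(np.sum(b[[i for i in producers]])) * rng.uniform(1.0, 5.0)
    avail[det] = spec.detritus_pool_frac * p_prod_total

    # consumers are processed once each of them has at least one prey whose
    # production ledger is already open (niche order breaks ties); consumers
    # caught in a pure loop with no open prey reject the draw
    pending = sorted(set(range(s)) - set(producers), key=lambda k: niche[k])
    consumers = []
    assigned = set(producers)
    ready_set = set(producers)
    while pending:
        pick = next((j for j in pending
                     if (set(prey_of[j]) & ready_set)
                     or min(niche[i] for i in prey_of[j]) < 0.1), None)
        if pick is None:
            return None
        pending.remove(pick)
        consumers.append(pick)
        ready_set.add(pick)
    takes: dict[tuple[int, int], float] = {}
    q_tot = np.zeros(s)
    deferred: list[tuple[int, int]] = []
    for j in consumers:
        prey = list(prey_of[j])
        if min(niche[i] for i in prey) < 0.1:
            prey.append(det)  # low-feeding consumers also take detritus
        ready = [i for i in prey if i == det or i in assigned]
        for i in prey:
            if i != det and i not in assigned:
                deferred.append((i, j))  # up-link into a loop; claimed later
        if not ready:
            return None
        pool = avail[ready]
        total = float(pool.sum())
        if total <= 0:
            return None  # prey pool exhausted; reject this draw
        demand = rng.uniform(*spec.demand_frac) * total
        w = pool * rng.gamma(spec.diet_noise_shape, 1.0, len(ready))
        if w.sum() <= 0:
            return None
        take = demand * w / w.sum()
        # never empty a pool completely: later consumers and loop links
        # must keep a positive claim
        take = np.minimum(take, 0.9 * pool)
        q_j = float(take.sum())
        if q_j <= 0:
            return None
        avail[ready] -= take
        for i, t in zip(ready, take):
            takes[(i, j)] = float(t)
        q_tot[j] = q_j
        qb[j] = 10.0 ** (spec.qb_log10_intercept
                         - spec.qb_log10_slope * niche[j]
                         + rng.normal(0, spec.qb_log10_sigma))
        pb[j] = rng.uniform(*spec.pq_range) * qb[j]
        b[j] = q_tot[j] / qb[j]
        # the consumer's own production joins the prey ledger (the estimate
        # predates any deferred top-up of its intake, hence conservative)
        avail[j] = rng.uniform(*spec.avail_frac) * pb[j] * b[j]
        assigned.add(j)

    for i, j in deferred:
        delta = rng.uniform(0.02, 0.15) * avail[i]
        if delta <= 0:
            return None  # would silently drop a topology link
        takes[(i, j)] = delta
        avail[i] -= delta
        q_tot[j] += delta
    for j in consumers:
        b[j] = q_tot[j] / qb[j]

    diet = np.zeros((s + 1, s + 1))
    for (i, j), t in takes.items():
        diet[i, j] = t / q_tot[j]
    return b, pb, qb, diet, b_det, producers


def generate_balanced_web(
    spec: WebGenSpec | None = None, seed=None, *,
    s: int | None = None, c_target: float | None = None,
    ecosystem_type: str | None = None, name: str = "web",
) -> FoodWebModel:
    """Draw one mass-balanced web; rejection-samples parameters until all
    solved EE lie in [0, 1] and the detritus budget is non-deficient."""
    spec = spec or WebGenSpec()
    rng = np.random.default_rng(seed)
    if s is None:
        s = int(rng.integers(spec.n_groups[0], spec.n_groups[1] + 1))
    if c_target is None:
        c_target = float(rng.uniform(*spec.connectance))
    if ecosystem_type is None:
        ecosystem_type = str(rng.choice(list(spec.ecosystem_types)))
    links, niche = generate_topology(s, c_target, rng)
    prey_of = {j: sorted(i for i, jj in links if jj == j) for j in range(s)}

    last_diag = ""
    for attempt in range(spec.max_attempts):
        if attempt and attempt % 25 == 0:  # pathological topology escape
            links, niche = generate_topology(s, c_target, rng)
            prey_of = {j: sorted(i for i, jj in links if jj == j)
                       for j in range(s)}
        drawn = _draw_web(spec, s, niche, prey_of, rng)
        if drawn is None:
            last_diag = "exhausted prey pool"
            continue
        b, pb, qb, diet, b_det, producers = drawn
        det = s
        if b.min() < 1e-6:  # degenerate group far below any real biomass
            last_diag = f"min biomass = {b.min():.2e}"
            continue

        catch = np.zeros(s)
        for i in range(s):
            if i not in producers and niche[i] > 0.5 and rng.uniform() < spec.fishing_prob:
                catch[i] = rng.uniform(0, spec.fishing_max_frac) * pb[i] * b[i]

        groups = [
            Group(
                name=f"grp_{i:03d}", is_living=True, biomass=float(b[i]),
                pb=float(pb[i]), qb=float(qb[i]), ee=None,
                catch=float(catch[i]), gs=spec.gs,
                resolution=float(rng.choice(RESOLUTION_CHOICES,
                                            p=RESOLUTION_PROBS)),
            )
            for i in range(s)
        ]
        groups.append(Group(name="detritus", is_living=False,
                            biomass=b_det, resolution=0.1))
        model = FoodWebModel(groups=groups, diet=diet,
                             ecosystem_type=ecosystem_type, name=name)
        try:
            solved = solve_mass_balance(model)
        except Exception as exc:  # infeasible draw
            last_diag = str(exc)
            continue
        ee = solved.param("ee")[:s]
        if np.any(ee > 1.0):
            last_diag = f"max EE = {ee.max():.3f}"
            continue
        # detritus budget: inflow must cover detritivory
        q_tot = b * qb
        inflow = float(np.sum(spec.gs * q_tot + (1 - ee) * pb * b))
        det_cons = float(np.sum(q_tot * diet[det, :s]))
        if det_cons > inflow:
            last_diag = "detritus deficit"
            continue
        rep = validate_model(solved)
        if rep.errors:
            last_diag = "; ".join(rep.errors)
            continue
        return solved
    raise RuntimeError(
        f"rejection budget exhausted for s={s}, C={c_target:.2f} "
        f"(last: {last_diag})")


def generate_ensemble(n: int, spec: WebGenSpec | None = None,
                      seed=None) -> list[FoodWebModel]:
    """Reproducible list of ``n`` balanced webs spanning the ecosystem-type mix."""
    spec = spec or WebGenSpec()
    children = np.random.SeedSequence(seed).spawn(n)
    types = list(spec.ecosystem_types)
    models = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        etype = types[k % len(types)]
        models.append(generate_balanced_web(
            spec, rng, ecosystem_type=etype, name=f"web_{k:03d}"))
    return models


# ---------------------------------------------------------------------------
# statistical benchmarks


def generate_benchmark(bench: BenchSpec, seed=None) -> pd.DataFrame:
    """Data with known standardized coefficients and a type random intercept.

    Exogenous variables are standard normal; each endogenous variable is the
    stated linear combination of its parents plus a type-level intercept
    (sd ``random_sd``) and Gaussian noise whose sd is completed so the
    variable has unit variance (floored at 0.05 when the stated effects are
    too large for that).
    """
    rng = np.random.default_rng(seed)
    n, n_types = bench.n, bench.n_types
    types = np.array([f"type_{k % n_types}" for k in range(n)])
    rng.shuffle(types)

    if bench.paths:
        parents: dict[str, list[tuple[str, float]]] = {}
        nodes: list[str] = []
        for resp, pred, beta in bench.paths:
            parents.setdefault(resp, []).append((pred, beta))
            for v in (pred, resp):
                if v not in nodes:
                    nodes.append(v)
        import networkx as nx

        g = nx.DiGraph((p, r) for r, p, _ in bench.paths)
        order = list(nx.topological_sort(g))
        data: dict[str, np.ndarray] = {}
        for v in order:
            if v not in parents:
                data[v] = rng.standard_normal(n)
                continue
            mu = np.zeros(n)
            ss = 0.0
            for pred, beta in parents[v]:
                mu += beta * data[pred]
                ss += beta**2
            u = rng.normal(0, bench.random_sd, n_types)
            intercepts = u[[int(t.split("_")[1]) for t in types]]
            resid = (bench.resid_sd if bench.resid_sd is not None else
                     np.sqrt(max(1.0 - ss - bench.random_sd**2, 0.05**2)))
            data[v] = mu + intercepts + rng.normal(0, resid, n)
        frame = pd.DataFrame(data)
    else:
        preds = list(bench.effects)
        frame = pd.DataFrame({p: rng.standard_normal(n) for p in preds})
        mu = np.zeros(n)
        ss = 0.0
        for p, beta in bench.effects.items():
            mu += beta * frame[p].to_numpy()
            ss += beta**2
        u = rng.normal(0, bench.random_sd, n_types)
        intercepts = u[[int(t.split("_")[1]) for t in types]]
        resid = (bench.resid_sd if bench.resid_sd is not None else
                 np.sqrt(max(1.0 - ss - bench.random_sd**2, 0.05**2)))
        frame[bench.response] = mu + intercepts + rng.normal(0, resid, n)
    frame["ecosystem_type"] = types
    return frame
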