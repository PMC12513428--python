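"""End-to-end pipeline: models -> balance -> indicators + local stability
-> disturbance simulations -> stability table -> inference tables.

Every stochastic stage derives its seed from ``RunConfig.seed``; a rerun
with the same configuration is bit-identical for deterministic stages.  The
expensive simulation stage is cached on a hash of the configuration fields
it depends on.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indices, perturbation, stats, synth
from .core import FoodWebModel, read_model, solve_mass_balance, validate_model
from .dynamics import ScenarioConfig, scenario_grid

__all__ = ["RunConfig", "run_pipeline", "analysis_frame"]

STABILITY_RESPONSES = ("log_resistance", "log_resilience", "local_stability")
INDICATOR_PREDICTORS = (
    "log_NLG", "log_CI", "log_ISI_mean", "log_ISI_sd",
    "log_SOI", "log_FCI", "log_PCI", "log_FML",
)


@dataclass
class RunConfig:
    out_dir: str = "runs/run"
    input_dir: str | None = None     # directory containing model sub-dirs
    n_webs: int = 40                 # synthetic ensemble size when no input
    scenario_selection: str = "grid"  # "grid" (3x3) or "main" (25%, 10 yr)
    seed: int = 0
    ye_rule: str = "max_deviation"
    press_target: str = "M0"
    ci_threshold: float = 0.0
    isi_scope: str = "both"
    soi_weighting: str = "log_q"
    literal_printed_aij: bool = False
    mediation_boot: int = 200
    web_spec: synth.WebGenSpec = field(default_factory=synth.WebGenSpec)

    def sim_key(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("mediation_boot")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_models(cfg: RunConfig) -> list[FoodWebModel]:
    if cfg.input_dir is not None:
        root = Path(cfg.input_dir)
        dirs = sorted(p for p in root.iterdir() if (p / "groups.csv").exists())
        models = []
        for p in dirs:
            m = read_model(p)
            if any(g.unknowns() for g in m.groups):
                m = solve_mass_balance(m)
            models.append(m)
        return models
    return synth.generate_ensemble(cfg.n_webs, cfg.web_spec, seed=cfg.seed)


def analysis_frame(indicator_df: pd.DataFrame,
                   stability_df: pd.DataFrame) -> pd.DataFrame:
    """Merge per-web indicators with main-scenario stability; resistance and
    resilience are natural-log transformed, local stability (which is <= 0
    by construction) stays on its linear scale."""
    main = stability_df[stability_df["is_main"]] if stability_df["is_main"].any() \
        else stability_df
    main = main.drop_duplicates("web")
    df = indicator_df.merge(
        main[["web", "resistance", "resilience", "local_stability"]], on="web")
    df["log_resistance"] = np.log(df["resistance"])
    df["log_resilience"] = np.log(df["resilience"])
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write all tables; returns paths and frames."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # stage 1: models
    try:
        models = _load_models(cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'models' failed: {exc}") from exc
    for m in models:
        rep = validate_model(m)
        if not rep.passed:
            raise RuntimeError(
                f"stage 'validate' failed for web {m.name!r}: {rep.errors}")

    # stage 2: indicators
    ind = indices.indicator_table(
        models, ci_threshold=cfg.ci_threshold, isi_scope=cfg.isi_scope,
        soi_weighting=cfg.soi_weighting)
    ind.to_csv(out / "indicators.csv", index=False)

    # stage 3: simulations (cached on the config hash)
    key = cfg.sim_key()
    stab_path = out / "stability.csv"
    pg_path = out / "stability_per_group.csv"
    cache_tag = out / ".sim_cache_key"
    if stab_path.exists() and cache_tag.exists() and cache_tag.read_text() == key:
        summary = pd.read_csv(stab_path)
        per_group = pd.read_csv(pg_path)
    else:
        scenarios = scenario_grid(press_target=cfg.press_target)
        if cfg.scenario_selection == "main":
            scenarios = [s for s in scenarios if s.is_main]
        table = perturbation.run_scenario_grid(
            models, scenarios, base_seed=cfg.seed, ye_rule=cfg.ye_rule,
            press_target=cfg.press_target)
        summary, per_group = table.summary, table.per_group
        summary.to_csv(stab_path, index=False)
        per_group.to_csv(pg_path, index=False)
        cache_tag.write_text(key)

    # stage 4: analysis frame and statistics
    frame = analysis_frame(ind, summary).dropna(
        subset=list(STABILITY_RESPONSES))
    frame.to_csv(out / "analysis_frame.csv", index=False)
    preds = [p for p in INDICATOR_PREDICTORS if frame[p].std(ddof=0) > 0]
    if len(frame) < len(preds) + 3:  # tiny desk runs keep the core drivers
        core = ["log_NLG", "log_CI", "log_ISI_sd", "log_FCI"]
        preds = [p for p in core if p in preds]
    vif = stats.vif_screen(frame, preds)
    vif.to_csv(out / "vif.csv", index=False)

    glmm_tables, sem_models, mediations, rf_tables, letters = {}, {}, [], {}, {}
    for resp in STABILITY_RESPONSES:
        try:
            res = stats.fit_glmm(frame, resp, preds)
            res.table.to_csv(out / f"glmm_{resp}.csv")
            glmm_tables[resp] = res
        except Exception as exc:
            raise RuntimeError(f"stage 'glmm' failed for {resp}: {exc}") from exc
        rf = stats.rf_importance(frame, resp, preds, n_trees=500, seed=cfg.seed)
        rf.to_csv(out / f"rf_{resp}.csv", index=False)
        rf_tables[resp] = rf
        dag = stats.default_dag(resp)
        sem = stats.fit_piecewise_sem(frame, dag)
        sem.coefficients.to_csv(out / f"sem_{resp}_coefficients.csv", index=False)
        sem.r2.to_csv(out / f"sem_{resp}_r2.csv", index=False)
        sem_models[resp] = sem
        for mediator in ("log_CI", "log_ISI_sd", "log_FCI"):
            med = stats.mediation(sem, frame, "log_NLG", mediator, resp,
                                  n_boot=cfg.mediation_boot, seed=cfg.seed)
            mediations.append({"response": resp, "mediator": mediator, **{
                k: (v if not isinstance(v, tuple) else None) for k, v in med.items()
            }, **{f"{k}_lo": v[0] for k, v in med.items() if isinstance(v, tuple)},
                **{f"{k}_hi": v[1] for k, v in med.items() if isinstance(v, tuple)}})
        letters[resp] = stats.group_compare(frame[resp], frame["ecosystem_type"])
        letters[resp].to_csv(out / f"letters_{resp}.csv", index=False)
    med_df = pd.DataFrame(mediations)
    med_df.to_csv(out / "mediation.csv", index=False)

    # manifest
    files = sorted(p for p in out.iterdir()
                   if p.is_file() and p.suffix in (".csv", ".yaml"))
    manifest = {
        "seed": cfg.seed,
        "n_webs": len(models),
        "sim_cache_key": key,
        "rows": {"indicators": len(ind), "stability": len(summary),
                 "analysis_frame": len(frame)},
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    cfg_d = dataclasses.asdict(cfg)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(cfg_d, default=str)), fh)

    artifacts.update(
        models=models, indicators=ind, stability=summary,
        per_group=per_group, frame=frame, vif=vif, glmm=glmm_tables,
        rf=rf_tables, sem=sem_models, mediation=med_df, letters=letters,
        out_dir=str(out), manifest=manifest,
    )
    return artifacts
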