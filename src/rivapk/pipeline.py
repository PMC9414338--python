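"""End-to-end analysis pipeline with provenance and resumable checkpoints.

Stages: simulate-cohort -> fit -> scm -> bootstrap -> vpc -> dose-sim.
Every artifact directory carries a provenance.json with the full
configuration, its hash and the master seed; stage sub-seeds derive from the
master seed, so a rerun with the same config is numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import dosing
from .cohort import CohortConfig, simulate_study
from .data import EventDataset
from .diagnostics import bootstrap, residual_table, vpc
from .estimate import FitConfig, PriorSpec, fit
from .model import PopParams
from .scm import scm

log = logging.getLogger("rivapk")

STAGES = ("simulate-cohort", "fit", "scm", "bootstrap", "vpc", "dose-sim")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (seed is mandatory)."""

    seed: int | None = None
    outdir: str = "rivapk_run"
    n_patients: int = 60
    error_model: str = "log-additive"
    sim_params: dict = field(default_factory=dict)  # overrides for PopParams
    prior: dict = field(default_factory=dict)  # overrides for PriorSpec
    run_scm: bool = True
    bootstrap_n: int = 1000
    vpc_n: int = 1000
    dose_n: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("bootstrap_n", "vpc_n", "dose_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sub_seeds(master: int) -> dict:
    state = np.random.SeedSequence(master).generate_state(len(STAGES))
    return {stage: int(s) for stage, s in zip(STAGES, state)}


def run_pipeline(cfg: RunConfig, resume: bool = False) -> Path:
    """Execute all stages, writing one artifact (file) per stage.

    With ``resume=True`` stages whose artifact already exists are not
    re-written; a failed run leaves checkpoint.json recording the completed
    stages.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(cfg.seed)
    truth = PopParams(**cfg.sim_params)
    prior = PriorSpec(**cfg.prior)
    fit_cfg = FitConfig(error_model=cfg.error_model)
    provenance = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
                  "seed": cfg.seed, "stage_seeds": seeds}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    done: list[str] = []
    try:
        # ---- simulate-cohort ----------------------------------------
        ds_path = out / "dataset.csv"
        if not (resume and ds_path.exists()):
            cohort_cfg = CohortConfig(n_patients=cfg.n_patients,
                                      seed=seeds["simulate-cohort"])
            ds = simulate_study(cohort_cfg, truth,
                                error_model=cfg.error_model)
            ds.write(ds_path)
            log.info("simulate-cohort: wrote %s (%d observations)",
                     ds_path, ds.n_observations)
        ds = EventDataset.read(ds_path)
        done.append("simulate-cohort")

        # ---- fit ----------------------------------------------------
        fr = fit(ds, prior=prior, config=fit_cfg)
        fit_path = out / "fit.txt"
        if not (resume and fit_path.exists()):
            fr.save(fit_path)
            residual_table(fr, ds).to_csv(out / "residuals.csv", index=False)
            log.info("fit: ofv=%.3f converged=%s", fr.ofv, fr.converged)
        done.append("fit")

        # ---- scm ----------------------------------------------------
        scm_path = out / "scm_trace.txt"
        if cfg.run_scm and not (resume and scm_path.exists()):
            trace = scm(ds, prior=prior,
                        config=replace(fit_cfg, effects=()))
            trace.save(scm_path)
            log.info("scm: final effects %s",
                     [e.name for e in trace.final_effects])
        done.append("scm")

        # ---- bootstrap ----------------------------------------------
        bs_path = out / "bootstrap.txt"
        if not (resume and bs_path.exists()):
            bs = bootstrap(ds, prior=prior, n=cfg.bootstrap_n,
                           seed=seeds["bootstrap"], config=fit_cfg,
                           base_fit=fr)
            bs.save(bs_path)
            log.info("bootstrap: %d resamples, %d failed",
                     bs.n_resamples, bs.n_failed)
        done.append("bootstrap")

        # ---- vpc ----------------------------------------------------
        vpc_path = out / "vpc.txt"
        if not (resume and vpc_path.exists()):
            summary = vpc(fr, ds, n_sim=cfg.vpc_n, seed=seeds["vpc"])
            summary.save(vpc_path)
            log.info("vpc: %d simulations", summary.n_simulations)
        done.append("vpc")

        # ---- dose-sim -----------------------------------------------
        dose_path = out / "dose_recommendations.csv"
        if not (resume and dose_path.exists()):
            params = fr.estimates if fr.estimates is not None else truth
            table = dosing.dose_recommendation_table(
                params, n_virtual=cfg.dose_n, seed=seeds["dose-sim"])
            table.to_csv(dose_path, index=False)
            log.info("dose-sim: wrote %s", dose_path)
        done.append("dose-sim")
    except Exception:
        (out / "checkpoint.json").write_text(
            json.dumps({"completed_stages": done}, indent=2))
        raise
    cp = out / "checkpoint.json"
    if cp.exists():
        cp.unlink()
    return out
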