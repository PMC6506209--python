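"""End-to-end orchestration: simulate -> fit -> analyze.

Each stage reads/writes the CSV/JSON formats defined by the owning
modules and records a manifest with the seeds and settings needed for
exact re-execution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hba_fit import DUAL_ALPHA, SINGLE_ALPHA, fit_hba, fit_mle
from .mediation import MediationSpec, mediate
from .model_selection import protected_pxp, subject_evidence
from .prospect_model import ChoiceDataset
from .roi_glm import RoiTimeSeries, EventSchedule, fit_roi_glm, neural_loss_aversion
from .synthetic_data import CohortSpec, generate_cohort
from .task_design import TaskSet
from .trait_stats import (build_trait_table, one_sample_t, partial_r,
                          pearson_r)

log = logging.getLogger("lossaversion")


class ValidationError(ValueError):
    """Bad inputs or outputs that already exist without --force."""


class ConvergenceError(RuntimeError):
    """MCMC chains failed the R-hat convergence criterion."""


@dataclasses.dataclass
class PipelineConfig:
    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    n_chains: int = 4
    n_warmup: int = 12000
    n_samples: int = 6000
    fit_seed: int = 0
    with_bold: bool = True
    bold_noise_sd: float = 0.5
    rhat_threshold: float = 1.01
    mediation_n_boot: int = 5000
    mediation_seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        cohort_raw = raw.pop("cohort", {})
        from .synthetic_data import Coupling
        for key in ("gpt_coupling", "ipt_coupling", "nla_coupling"):
            if key in cohort_raw:
                cohort_raw[key] = Coupling(*cohort_raw[key])
        for key in ("group_means", "group_sds"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        return cls(cohort=CohortSpec(**cohort_raw), **raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: PipelineConfig, stage: str) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, default=str))


def run_simulate(config: PipelineConfig, outdir: str | Path,
                 force: bool = False) -> Path:
    """Generate and write a synthetic cohort (task, traits, choices, BOLD)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ValidationError(f"{outdir} is not empty (use force to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.cohort, with_bold=config.with_bold,
                             bold_noise_sd=config.bold_noise_sd)
    cohort.write(outdir)
    _write_manifest(outdir, config, "simulate")
    log.info("wrote cohort with %d subjects to %s",
             config.cohort.n_subjects, outdir)
    return outdir


def run_fit(config: PipelineConfig, indir: str | Path, outdir: str | Path,
            models: tuple[str, ...] = ("single", "dual"),
            mle: bool = False) -> dict:
    """Fit the hierarchical model(s) to a choices file; compare if both fit.

    Writes per-subject estimates, group summaries, the R-hat table, DIC
    values, and — when both models are fitted — the random-effects model
    comparison (expected frequencies, EP, BOR, PXP).  A fit whose worst
    R-hat exceeds the threshold is written but flagged.
    """
    indir, outdir = Path(indir), Path(outdir)
    choices_path = indir / "choices.csv"
    if not choices_path.exists():
        raise ValidationError(f"missing {choices_path}")
    data = ChoiceDataset.from_csv(choices_path)
    outdir.mkdir(parents=True, exist_ok=True)

    if mle:
        rows = []
        for sid in data.subjects:
            res = fit_mle(data.for_subject(sid))
            rows.append({"subject_id": sid, "alpha": res.params.alpha,
                         "lam": res.params.lam, "tau": res.params.tau,
                         "ln_lam": np.log(res.params.lam),
                         "nll": res.nll, "at_bound": res.at_bound})
        pd.DataFrame(rows).to_csv(outdir / "mle_subjects.csv", index=False)
        _write_manifest(outdir, config, "fit")
        return {"mle": str(outdir / "mle_subjects.csv")}

    specs = {"single": SINGLE_ALPHA, "dual": DUAL_ALPHA}
    fits = {}
    for name in models:
        fit = fit_hba(data, model=specs[name], n_chains=config.n_chains,
                      n_warmup=config.n_warmup, n_samples=config.n_samples,
                      seed=config.fit_seed)
        fits[name] = fit
        fit.write(outdir, stem=name)
        if not fit.converged(config.rhat_threshold):
            log.warning("%s model: max R-hat %.4f exceeds %.2f",
                        name, fit.max_rhat, config.rhat_threshold)
    summary = {
        name: {"dic": fit.dic.dic, "p_d": fit.dic.p_d,
               "max_rhat": fit.max_rhat,
               "converged": fit.converged(config.rhat_threshold)}
        for name, fit in fits.items()
    }
    if len(fits) == 2:
        L = subject_evidence(fits["single"].dic, fits["dual"].dic)
        bms = protected_pxp(L, seed=config.fit_seed)
        summary["bms"] = {
            "models": list(fits), "frequencies": bms.frequencies.tolist(),
            "ep": bms.ep.tolist(), "bor": bms.bor, "pxp": bms.pxp.tolist(),
        }
    (outdir / "fit_summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(outdir, config, "fit")
    if any(not fits[m].converged(config.rhat_threshold) for m in fits):
        summary["converged"] = False
    return summary


def compute_nla(indir: str | Path, task: TaskSet) -> pd.DataFrame:
    """ROI GLM per subject from a bold.csv, returning neural loss aversion."""
    bold = pd.read_csv(Path(indir) / "bold.csv")
    schedule = EventSchedule.from_task(task)
    rows = []
    for sid, grp in bold.groupby("subject_id"):
        ts = RoiTimeSeries(grp.sort_values("t_index")["bold"].to_numpy())
        betas = fit_roi_glm(schedule, ts)
        rows.append({"subject_id": sid, "nla": neural_loss_aversion(betas),
                     "beta_gain": betas.beta_gain,
                     "beta_loss": betas.beta_loss})
    return pd.DataFrame(rows)


def run_analyze(config: PipelineConfig, indir: str | Path,
                outdir: str | Path, estimates_csv: str | Path | None = None
                ) -> dict:
    """Correlation battery, t-tests and both mediations on a cohort.

    Correlations with greed control impulsivity as a covariate of no
    interest (the simple correlations are reported alongside).
    """
    indir, outdir = Path(indir), Path(outdir)
    for fname in ("traits.csv", "choices.csv"):
        if not (indir / fname).exists():
            raise ValidationError(f"missing {indir / fname}")
    traits = pd.read_csv(indir / "traits.csv")
    choices = ChoiceDataset.from_csv(indir / "choices.csv")
    outdir.mkdir(parents=True, exist_ok=True)

    estimates = None
    if estimates_csv is not None:
        estimates = pd.read_csv(estimates_csv)
    else:
        # fall back to generating parameters when no fit is supplied
        estimates = traits.rename(columns={
            "true_alpha": "alpha", "true_lam": "lam"})[
                ["subject_id", "alpha", "lam"]].copy()
        estimates["ln_lam"] = np.log(estimates["lam"])

    nla = None
    if (indir / "bold.csv").exists():
        task = TaskSet.from_csv(indir / "task.csv")
        nla = compute_nla(indir, task)
    table = build_trait_table(traits, choices, estimates=estimates, nla=nla)
    table.to_csv(outdir / "trait_table.csv", index=False)

    def corr_pair(xcol, ycol, control_ipt=True):
        cols = list(dict.fromkeys([xcol, ycol, "ipt"]))
        sub = table[cols].dropna()
        simple = pearson_r(sub[xcol], sub[ycol])
        out = {"r": simple.r, "p": simple.p, "n": simple.n}
        if control_ipt:
            part = partial_r(sub[xcol], sub[ycol], sub[["ipt"]])
            out.update({"partial_r": part.r, "partial_p": part.p})
        return out

    results = {"correlations": {}, "t_tests": {}, "mediations": {}}
    pairs = [("gpt", "ipt", False), ("gpt", "pct_risky_mixed", True),
             ("gpt", "pct_risky_gain", True), ("gpt", "pct_risky_loss", True),
             ("gpt", "lam", True), ("gpt", "alpha", True),
             ("gpt", "ln_lam", True)]
    if nla is not None:
        pairs += [("nla", "ln_lam", True), ("nla", "gpt", True)]
    for xcol, ycol, ctl in pairs:
        results["correlations"][f"{xcol}~{ycol}"] = corr_pair(xcol, ycol, ctl)

    t, p = one_sample_t(table["lam"], 1.0)
    results["t_tests"]["lam_vs_1"] = {"t": t, "p": p}
    t, p = one_sample_t(table["alpha"], 1.0)
    results["t_tests"]["alpha_vs_1"] = {"t": t, "p": p}

    behavioral = mediate(table, MediationSpec(
        x="gpt", m="ln_lam", y="pct_risky_all", covariates=("ipt",),
        n_boot=config.mediation_n_boot, seed=config.mediation_seed))
    results["mediations"]["gpt->ln_lam->risky_pct"] = behavioral.to_dict()
    if nla is not None:
        neural = mediate(table, MediationSpec(
            x="gpt", m="nla", y="ln_lam", covariates=("ipt",),
            n_boot=config.mediation_n_boot, seed=config.mediation_seed))
        results["mediations"]["gpt->nla->ln_lam"] = neural.to_dict()

    (outdir / "analysis.json").write_text(json.dumps(results, indent=2))
    _write_manifest(outdir, config, "analyze")
    return results
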