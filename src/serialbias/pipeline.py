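"""End-to-end analysis runner: data -> summaries -> hierarchical fits -> tables.

The pipeline executes, in order: load or simulate a dataset; bin circular
mean errors and fit the three-level hierarchical DoG model; preprocess
trajectories and fit the model to both AUC variants; build time-resolved
deviation profiles and fit the four-level model on all trials and on the
movement-onset median-split halves; finally summarize posteriors and the
cross-report amplitude correlations. Every output table carries a
provenance header (config hash, seed, package version) and regenerates
byte-identically from the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import correlate_alphas, prepare_condition_summaries
from .hbm import HierarchicalSpec, Priors, fit_hbm3, fit_hbm4, participant_alpha_means, posterior_summary
from .io import read_trials, read_trajectories, write_trials, write_trajectories
from .simulate import SimConfig, simulate_experiment
from .trajectory import (
    auc_condition_summaries,
    deviation_profiles,
    median_split_by_onset,
    trajectory_features,
)

__all__ = ["RunConfig", "ResultBundle", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("serialbias")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one data source must be set: either ``simulation`` (a
    :class:`SimConfig`) or ``trials_path`` (+ ``trajectories_path`` for the
    trajectory stages).
    """

    simulation: SimConfig | None = None
    trials_path: str | None = None
    trajectories_path: str | None = None
    flip_sign: bool = False          # flip the relative-color sign convention
    edge_variant: str = "mean"       # +/-180 bin synthesis: "mean" or "odd"
    auc_scale: float = 1.0           # unit scale for AUC values
    median_split: bool = True
    traj_prior_scale: float = 5.0    # widen amplitude priors for px-valued fits
    spec3: HierarchicalSpec = field(default_factory=lambda: HierarchicalSpec(levels=3))
    spec4: HierarchicalSpec = field(default_factory=lambda: HierarchicalSpec(levels=4))
    outdir: str | None = None
    seed: int = 0
    write_inputs: bool = False       # persist the simulated trials/trajectories

    def __post_init__(self):
        if (self.simulation is None) == (self.trials_path is None):
            raise ValueError(
                "exactly one of 'simulation' and 'trials_path' must be set"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # the hash covers the analysis-relevant configuration; the output
        # location must not change it (reruns into different directories
        # should produce identical tables)
        blob = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(blob, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ResultBundle:
    """All tables a pipeline run produces, plus provenance."""

    condition_summaries: pd.DataFrame
    auc_summaries: pd.DataFrame | None
    posterior_errors: pd.DataFrame
    posterior_auc_with: pd.DataFrame | None
    posterior_auc_without: pd.DataFrame | None
    posterior_time_all: pd.DataFrame | None
    posterior_time_early: pd.DataFrame | None
    posterior_time_late: pd.DataFrame | None
    participant_alphas: pd.DataFrame
    alpha_correlations: pd.DataFrame
    diagnostics: dict
    provenance: dict

    def posterior_tables(self) -> dict:
        return {
            "posterior_errors": self.posterior_errors,
            "posterior_auc_with": self.posterior_auc_with,
            "posterior_auc_without": self.posterior_auc_without,
            "posterior_time_all": self.posterior_time_all,
            "posterior_time_early": self.posterior_time_early,
            "posterior_time_late": self.posterior_time_late,
        }


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineStageError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def _spec_with_seed(spec: HierarchicalSpec, seed: int) -> HierarchicalSpec:
    return HierarchicalSpec(
        levels=spec.levels, n_chains=spec.n_chains, n_warmup=spec.n_warmup,
        n_samples=spec.n_samples, priors=spec.priors, share_w=spec.share_w,
        seed=seed,
    )


def _write_table(df: pd.DataFrame, path: Path, provenance: dict):
    with open(path, "w") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full analysis; returns (and optionally writes) all tables."""
    provenance = {
        "schema": "serialbias-results v1.0",
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    @_stage("load")
    def load():
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            ds = simulate_experiment(sim)
            return ds.trials, ds.trajectories
        trials = read_trials(config.trials_path)
        trajectories = (
            read_trajectories(config.trajectories_path, trials)
            if config.trajectories_path else {}
        )
        return trials, trajectories

    trials, trajectories = load()

    @_stage("error_summaries")
    def errors_stage():
        summaries = prepare_condition_summaries(
            trials, flip_sign=config.flip_sign, edge_variant=config.edge_variant
        )
        n_excl = int((~prepare_exclusions(trials)).sum())
        return summaries, n_excl

    def prepare_exclusions(tr):
        from .errors import assign_condition
        return assign_condition(tr, flip_sign=config.flip_sign)["included"]

    summaries, n_excluded = errors_stage()
    log.info("excluded %d trial records from binned analysis", n_excluded)

    @_stage("fit_errors")
    def fit_errors():
        spec = _spec_with_seed(config.spec3, config.seed + 1)
        return fit_hbm3(summaries, spec)

    post_err, diag_err = fit_errors()
    tab_err = posterior_summary(post_err, diag_err)
    alphas = participant_alpha_means(post_err)
    try:
        corr = correlate_alphas(alphas)
    except ValueError as exc:  # e.g. < 3 participants: correlation undefined
        log.warning("alpha correlations unavailable: %s", exc)
        corr = pd.DataFrame(columns=["pair", "r", "df", "p"])

    auc_summaries = tab_with = tab_without = None
    tab_all = tab_early = tab_late = None
    diagnostics = {"errors": _diag_dict(diag_err)}

    if trajectories:
        @_stage("trajectory_features")
        def features_stage():
            feats = trajectory_features(trajectories, auc_scale=config.auc_scale)
            n_unusable = int((~feats["usable"]).sum())
            log.info("unusable trajectories: %d", n_unusable)
            return feats

        feats = features_stage()

        @_stage("fit_auc")
        def fit_auc():
            aucs = auc_condition_summaries(
                feats, trials, flip_sign=config.flip_sign,
                edge_variant=config.edge_variant,
            )
            priors = (config.spec3.priors or Priors()).scaled(config.traj_prior_scale)
            base = dataclasses.replace(config.spec3, priors=priors)
            pw, dw = fit_hbm3(aucs, _spec_with_seed(base, config.seed + 2),
                              value_col="auc_with")
            po, do = fit_hbm3(aucs, _spec_with_seed(base, config.seed + 3),
                              value_col="auc_without")
            return aucs, (pw, dw), (po, do)

        auc_summaries, (post_w, diag_w), (post_o, diag_o) = fit_auc()
        tab_with = posterior_summary(post_w, diag_w)
        tab_without = posterior_summary(post_o, diag_o)
        diagnostics["auc_with"] = _diag_dict(diag_w)
        diagnostics["auc_without"] = _diag_dict(diag_o)

        @_stage("fit_time_resolved")
        def fit_time():
            priors = (config.spec4.priors or Priors()).scaled(config.traj_prior_scale)
            base = dataclasses.replace(config.spec4, priors=priors)
            prof_all = deviation_profiles(feats, trials, flip_sign=config.flip_sign,
                                          edge_variant=config.edge_variant)
            pa, da = fit_hbm4(prof_all, _spec_with_seed(base, config.seed + 4))
            out = {"all": (pa, da)}
            if config.median_split:
                split = median_split_by_onset(feats)
                for half, offset in (("early", 5), ("late", 6)):
                    sub = split[split["onset_half"] == half]
                    prof = deviation_profiles(sub, trials, flip_sign=config.flip_sign,
                                              edge_variant=config.edge_variant)
                    out[half] = fit_hbm4(prof, _spec_with_seed(base, config.seed + offset))
            return out

        time_fits = fit_time()
        pa, da = time_fits["all"]
        tab_all = posterior_summary(pa, da)
        diagnostics["time_all"] = _diag_dict(da)
        if "early" in time_fits:
            pe, de = time_fits["early"]
            pl, dl = time_fits["late"]
            tab_early = posterior_summary(pe, de)
            tab_late = posterior_summary(pl, dl)
            diagnostics["time_early"] = _diag_dict(de)
            diagnostics["time_late"] = _diag_dict(dl)

    bundle = ResultBundle(
        condition_summaries=summaries,
        auc_summaries=auc_summaries,
        posterior_errors=tab_err,
        posterior_auc_with=tab_with,
        posterior_auc_without=tab_without,
        posterior_time_all=tab_all,
        posterior_time_early=tab_early,
        posterior_time_late=tab_late,
        participant_alphas=alphas.reset_index(),
        alpha_correlations=corr,
        diagnostics=diagnostics,
        provenance=provenance,
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_table(summaries, outdir / "condition_summaries.csv", provenance)
        if auc_summaries is not None:
            _write_table(auc_summaries, outdir / "auc_summaries.csv", provenance)
        for name, tab in bundle.posterior_tables().items():
            if tab is not None:
                _write_table(tab, outdir / f"{name}.csv", provenance)
        _write_table(bundle.participant_alphas, outdir / "participant_alphas.csv", provenance)
        _write_table(corr, outdir / "alpha_correlations.csv", provenance)
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump({"provenance": provenance, **diagnostics}, fh, indent=2)
        if config.write_inputs and config.simulation is not None:
            write_trials(trials, outdir / "trials.csv")
            if trajectories:
                write_trajectories(trajectories, outdir / "trajectories.csv")
    return bundle


def _diag_dict(diag) -> dict:
    return {
        "max_rhat": diag.max_rhat,
        "converged": diag.converged,
        "messages": diag.messages,
    }
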