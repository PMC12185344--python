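"""End-to-end pipeline: simulate -> fit -> model-free -> group stats -> mood.

A single :class:`PipelineConfig` (YAML-serialisable) drives every stage;
each stochastic stage gets its own seed derived from the one master seed,
and a manifest records the config hash and the stage seeds so that a
rerun with the same config reproduces every CSV output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .fitting import PriorSpec, fit_sessions
from .inference import drug_time_interaction, fit_location_scale
from .modelfree import bin_choice_curve, dimension_sensitivity, outcome_history_contrast, predictive_accuracy
from .mood import happiness_outcome_regression, mood_instability, mood_instability_gradient, mood_noisiness_coupling
from .synth import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "fit", "modelfree", "groupstats", "mood", "report")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a full run needs; every stochastic stage is seeded."""

    seed: int
    cohort: CohortConfig = field(default_factory=CohortConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    fit_method: str = "map"
    n_bins: int = 7
    extreme_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ValueError("config must declare an integer master seed")
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if isinstance(self.priors, dict):
            self.priors = PriorSpec(**self.priors)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return clean(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "seed" not in d:
            raise ValueError("config must declare an integer master seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGES))
        return {s: int(v % (2**31)) for s, v in zip(STAGES, state)}


def _summary_rows(summary, outcome: str, analysis: str) -> pd.DataFrame:
    t = summary.table.reset_index(names="coefficient")
    t.insert(0, "analysis", analysis)
    t.insert(1, "outcome", outcome)
    t["converged"] = summary.converged
    return t


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] | None = None,
    fast: bool | None = None,
) -> Path:
    """Execute the requested stages, writing all artifacts under ``out_dir``.

    Stages not requested must have run before (their outputs are read back
    from ``out_dir``).  Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages) if stages else STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    seeds = config.stage_seeds()
    method = "map" if fast else config.fit_method

    for stage in [s for s in STAGES if s in stages]:
        try:
            _run_stage(stage, config, out, seeds, method)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineStageError(stage, exc) from exc

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stages_run": list(stages),
        "fit_method": method,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _run_stage(stage, config, out, seeds, method):
    if stage == "simulate":
        cohort_cfg = dataclasses.replace(config.cohort, rng_seed=seeds["simulate"])
        cohort, truth = generate_cohort(cohort_cfg)
        rio.write_trials(cohort.trials, out / "trials.csv")
        rio.write_mood(cohort.mood, out / "mood.csv")
        rio.write_table(cohort.participants, out / "participants.csv")
        rio.write_table(truth, out / "truth.csv")

    elif stage == "fit":
        trials = rio.read_trials(out / "trials.csv")
        fits = fit_sessions(
            trials, priors=config.priors, method=method, random_state=seeds["fit"]
        )
        rio.write_table(fits, out / "session_fits.csv")

    elif stage == "modelfree":
        trials = rio.read_trials(out / "trials.csv")
        curve = bin_choice_curve(trials, n_bins=config.n_bins)
        curves, slopes = dimension_sensitivity(trials, n_bins=config.n_bins)
        frames = [curve.to_frame(), curves["win"].to_frame(), curves["loss"].to_frame()]
        rio.write_table(pd.concat(frames, ignore_index=True), out / "choice_curves.csv")
        rio.write_table(slopes, out / "dimension_slopes.csv")
        contrast = outcome_history_contrast(trials, config.extreme_fraction)
        rio.write_table(contrast, out / "history_contrast.csv")
        fits_path = out / "session_fits.csv"
        if fits_path.exists():
            fits = rio.read_table(fits_path)
            acc = predictive_accuracy(trials, fits, by_group=True)
            rio.write_table(
                acc.rename("accuracy").reset_index(), out / "predictive_accuracy.csv"
            )

    elif stage == "groupstats":
        fits = rio.read_table(out / "session_fits.csv")
        participants = rio.read_table(out / "participants.csv")
        df = fits.merge(
            participants[["participant_id", "age", "gender", "n_baseline_days"]],
            on="participant_id",
        )
        rows = []
        for outcome in ("lam_mean", "gamma_mean", "log_beta_mean"):
            rows.append(_summary_rows(fit_location_scale(df, outcome), outcome, "gradient"))
        bd = df[df["group"] == "bd"]
        if set(bd["arm"].unique()) >= {"lithium", "placebo"}:
            for outcome in ("lam_mean", "gamma_mean", "log_beta_mean"):
                rows.append(
                    _summary_rows(drug_time_interaction(bd, outcome), outcome, "drug_time")
                )
        rio.write_table(pd.concat(rows, ignore_index=True), out / "group_summary.csv")

    elif stage == "mood":
        mood = rio.read_mood(out / "mood.csv")
        trials = rio.read_trials(out / "trials.csv")
        fits = rio.read_table(out / "session_fits.csv")
        participants = rio.read_table(out / "participants.csv")
        rio.write_table(mood_instability(mood), out / "mood_instability.csv")
        rows = [
            _summary_rows(
                mood_instability_gradient(mood, participants, scale=s),
                f"sd_panas_{s}", "instability_gradient",
            )
            for s in ("pos", "neg")
        ]
        rows.append(
            _summary_rows(
                happiness_outcome_regression(mood, trials, participants),
                "dvas", "happiness_outcome",
            )
        )
        nois = mood_noisiness_coupling(mood, fits, participants)
        rows.append(_summary_rows(nois["daily"], "log_beta_mean", "noisiness_daily_mood"))
        rows.append(
            _summary_rows(nois["instability"], "mean_log_beta", "noisiness_instability")
        )
        rio.write_table(pd.concat(rows, ignore_index=True), out / "mood_summary.csv")

    elif stage == "report":
        _write_report(config, out)


def _write_report(config, out) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = rio.read_table(out / "choice_curves.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, dim in zip(axes, ("total", "win", "loss")):
        sub = curves[curves["dimension"] == dim]
        mid = 0.5 * (sub["bin_low"] + sub["bin_high"])
        ax.plot(mid, sub["frac_left"], "o-")
        ax.axhline(0.5, color="grey", lw=0.5)
        ax.set_title(f"{dim} utility difference")
        ax.set_xlabel("left - right (points)")
    axes[0].set_ylabel("fraction choosing left")
    fig.tight_layout()
    fig.savefig(out / "fig_choice_curves.png", dpi=120)
    plt.close(fig)

    fits_path = out / "session_fits.csv"
    lines = ["# Pipeline report", "", f"Config hash: `{config.config_hash()}`", ""]
    if fits_path.exists():
        fits = rio.read_table(fits_path)
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax, p in zip(axes, ("lam_mean", "gamma_mean", "log_beta_mean")):
            for grp, sub in fits.groupby("group"):
                ax.hist(sub[p], bins=40, alpha=0.5, label=grp, density=True)
            ax.set_title(p)
        axes[0].legend()
        fig.tight_layout()
        fig.savefig(out / "fig_params_by_group.png", dpi=120)
        plt.close(fig)
        by_group = fits.groupby("group")[["lam_mean", "gamma_mean", "log_beta_mean"]].mean()
        lines += ["## Session-wise parameter means by group", "", by_group.to_markdown(), ""]
    gs_path = out / "group_summary.csv"
    if gs_path.exists():
        gs = rio.read_table(gs_path)
        key = gs[gs["coefficient"].isin(["grad_linear", "arm:phase"])]
        lines += ["## Key group coefficients", "", key.to_markdown(index=False), ""]
    (out / "report.md").write_text("\n".join(lines))
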