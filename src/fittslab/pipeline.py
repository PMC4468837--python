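"""End-to-end pipeline: simulate -> reduce -> metrics -> slopes -> anova.

Every stage exchanges flat comma-separated tables so intermediate results are
inspectable and diff-able; a run is deterministic given its configuration and
seed (re-running produces byte-identical tables).  Stage row counts and
dropped-trial counts are logged, keeping the exclusion rule auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitts_metrics, inferential, kinematics, slopes, synthetic_data
from .kinematics import ReductionConfig
from .synthetic_data import ACCURACY_PRONE, SPEED_PRONE, SimParams, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "fittslab_out"
    seed: int = 1
    simulate: bool = True
    trajectories_path: str | None = None   # input when simulate is False
    design: StudyDesign = field(default_factory=StudyDesign)
    params_accuracy: SimParams = field(
        default_factory=synthetic_data.default_accuracy_params)
    params_speed: SimParams = field(
        default_factory=synthetic_data.default_speed_params)
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    strategy_cutoff: float = fitts_metrics.STRATEGY_CUTOFF
    bases: tuple[str, ...] = ("nominal", "effective")


_DESIGN_KEYS = {f.name for f in dataclasses.fields(StudyDesign)}
_PARAM_KEYS = {f.name for f in dataclasses.fields(SimParams)}
_REDUCTION_KEYS = {f.name for f in dataclasses.fields(ReductionConfig)}


def load_config(path) -> PipelineConfig:
    """Read a flat YAML-style key-value file into a :class:`PipelineConfig`.

    Keys matching design / reduction fields are routed to the nested configs;
    simulation-parameter keys may be prefixed ``accuracy_`` or ``speed_`` to
    target one group (unprefixed parameter keys apply to both).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat mapping")
    design_kw, red_kw, acc_kw, spd_kw, top_kw = {}, {}, {}, {}, {}
    for key, value in raw.items():
        if key in _DESIGN_KEYS:
            design_kw[key] = tuple(value) if isinstance(value, list) else value
        elif key in _REDUCTION_KEYS and key != "sample_rate":
            red_kw[key] = value
        elif key.startswith("accuracy_") and key[9:] in _PARAM_KEYS:
            acc_kw[key[9:]] = value
        elif key.startswith("speed_") and key[6:] in _PARAM_KEYS:
            spd_kw[key[6:]] = value
        elif key in _PARAM_KEYS and key != "seed":
            acc_kw.setdefault(key, value)
            spd_kw.setdefault(key, value)
        elif key in {"out_dir", "seed", "simulate", "trajectories_path",
                     "strategy_cutoff", "bases"}:
            top_kw[key] = tuple(value) if key == "bases" else value
        else:
            raise ValueError(f"unknown config key: {key}")
    design = StudyDesign(**design_kw)
    reduction = ReductionConfig(sample_rate=design.sample_rate, **red_kw)
    acc = dataclasses.replace(synthetic_data.default_accuracy_params(), **acc_kw)
    spd = dataclasses.replace(synthetic_data.default_speed_params(), **spd_kw)
    return PipelineConfig(design=design, reduction=reduction,
                          params_accuracy=acc, params_speed=spd, **top_kw)


def _write(df: pd.DataFrame, path: Path, name: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    logger.info("%s: wrote %d rows -> %s", name, len(df), path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Returns a dict of the in-memory tables.  A stage failure raises with the
    failing stage named; outputs of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    stage = "simulate"
    try:
        if config.simulate:
            traj, truth = synthetic_data.simulate_study(
                config.design, config.params_accuracy, config.params_speed,
                seed=config.seed)
            _write(traj, out / "trajectories.csv", stage)
            _write(truth["participants"], out / "truth_participants.csv", stage)
            _write(truth["trials"], out / "truth_trials.csv", stage)
            results["truth"] = truth
        else:
            if not config.trajectories_path:
                raise ValueError("trajectories_path required when simulate=False")
            traj = pd.read_csv(config.trajectories_path)
        results["trajectories"] = traj

        stage = "reduce"
        measures = kinematics.reduce_frame(traj, config.reduction)
        _write(measures, out / "measures.csv", stage)
        dropped = kinematics.invalid_counts(measures)
        if len(dropped):
            _write(dropped, out / "dropped_trials.csv", stage)
        logger.info("reduce: %d trials, %d invalid", len(measures),
                    int((~measures["valid"]).sum()))
        results["measures"] = measures

        stage = "metrics"
        summaries = fitts_metrics.condition_summaries(measures)
        profiles = fitts_metrics.participant_profiles(
            measures, config.strategy_cutoff)
        grid = fitts_metrics.id_grid(config.design.amplitudes,
                                     config.design.widths)
        _write(summaries, out / "condition_summaries.csv", stage)
        _write(profiles, out / "participant_profiles.csv", stage)
        grid_fmt = fitts_metrics.format_id_grid(grid)
        grid_fmt.to_csv(out / "id_grid.csv", float_format="%.2f")
        results.update(summaries=summaries, profiles=profiles, id_grid=grid)

        stage = "slopes"
        slope_tables = [slopes.component_slopes(summaries, basis)
                        for basis in config.bases]
        slope_records = pd.concat(slope_tables, ignore_index=True)
        _write(slope_records, out / "slopes.csv", stage)
        slope_summary = slopes.summarize_slopes(slope_records)
        _write(slope_summary, out / "slope_summary.csv", stage)
        results.update(slopes=slope_records, slope_summary=slope_summary)

        stage = "anova"
        anovas = run_anovas(summaries, profiles, slope_records)
        for name, table in anovas.items():
            table.to_csv(out / f"anova_{name}.csv", index=False,
                         float_format="%.10g")
        results["anovas"] = anovas
        report = "\n\n".join(
            inferential.format_anova(t, title=name)
            for name, t in anovas.items())
        (out / "anova_report.txt").write_text(report + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results


def run_anovas(summaries: pd.DataFrame, profiles: pd.DataFrame,
               slope_records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The study's ANOVA suite on a summary/slope bundle.

    Primary: TF x Amplitude x Width within-subject ANOVAs on MT, CE and VE,
    and TF x Component x Average-ID ANOVAs on each slope basis.  Secondary
    (when both strategy groups have >= 2 members): the same designs with the
    observed Strategy factor between subjects.
    """
    data = summaries.merge(profiles[["participant", "strategy"]],
                           on="participant", how="left")
    multi_session = data["session"].nunique() > 1
    within_primary = (["session", "amplitude_mm", "width_mm"] if multi_session
                      else ["amplitude_mm", "width_mm"])
    out: dict[str, pd.DataFrame] = {}
    for dv, name in (("mean_mt_ms", "mt"), ("ce_mm", "ce"), ("ve_mm", "ve")):
        out[name] = inferential.rm_anova(data, dv, within_primary,
                                         subject="participant")
        if _two_groups(data):
            out[f"{name}_strategy"] = inferential.rm_anova(
                data, dv, within_primary, subject="participant",
                between="strategy", observed="strategy")

    sdata = slope_records.merge(profiles[["participant", "strategy"]],
                                on="participant", how="left")
    # Average-ID enters as a 4-level factor; its level values differ between
    # components (row vs column margins), so levels are matched by rank.
    sdata = sdata.copy()
    sdata["avg_id_rank"] = (sdata.groupby(["basis", "component"])
                            ["average_id_bits"].rank(method="dense"))
    swithin = (["session", "component", "avg_id_rank"] if multi_session
               else ["component", "avg_id_rank"])
    for basis in sdata["basis"].unique():
        sub = sdata[sdata["basis"] == basis]
        out[f"slopes_{basis}"] = inferential.rm_anova(
            sub, "slope_ms_per_bit", swithin, subject="participant")
        if _two_groups(sub.merge(sdata[["participant", "strategy"]]
                                 .drop_duplicates(), on="participant")):
            out[f"slopes_{basis}_strategy"] = inferential.rm_anova(
                sub, "slope_ms_per_bit", swithin, subject="participant",
                between="strategy", observed="strategy")
    return out


def _two_groups(data: pd.DataFrame) -> bool:
    if "strategy" not in data.columns:
        return False
    counts = data.drop_duplicates("participant")["strategy"].value_counts()
    return len(counts) == 2 and counts.min() >= 2


# ---------------------------------------------------------------------------
# Fixtures


def make_fixtures(size: str = "tiny", seed: int = 7, out_dir=None):
    """Generate a test dataset: ``"tiny"`` (2 participants, 2x2 grid, 3
    trials, near-zero noise) or ``"paper-scale"`` (the full default design).

    Returns ``(trajectories, truth)`` and writes CSVs when ``out_dir`` given.
    """
    if size == "tiny":
        design = StudyDesign(amplitudes=(155.0, 380.0), widths=(20.0, 50.0),
                             trials_per_condition=3, n_accuracy=1, n_speed=1)
        quiet = dict(mt_trial_sd_ms=0.0, participant_sd_ms=0.0,
                     endpoint_bias_mm=0.0, noise_base_mm=0.0,
                     noise_amp_gain=0.0, width_utilization=1e-9)
        acc = synthetic_data.default_accuracy_params().replace(**quiet)
        spd = synthetic_data.default_speed_params().replace(**quiet)
    elif size == "paper-scale":
        design = StudyDesign()
        acc = synthetic_data.default_accuracy_params()
        spd = synthetic_data.default_speed_params()
    else:
        raise ValueError("size must be 'tiny' or 'paper-scale'")
    traj, truth = synthetic_data.simulate_study(design, acc, spd, seed=seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(traj, out / "trajectories.csv", "fixtures")
        _write(truth["participants"], out / "truth_participants.csv", "fixtures")
        _write(truth["trials"], out / "truth_trials.csv", "fixtures")
    return traj, truth
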