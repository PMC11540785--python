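"""End-to-end pipeline: simulate -> extract -> metrics -> model -> validate.

Every stage reads only on-disk inputs from the previous stage and writes
plain-text artifacts into the working directory, so each is re-runnable
in isolation. A single master seed fans out to stable per-stage child
seeds (CRC-32 of the stage name mixed with the master seed), giving
stage-level reproducibility without seed collisions.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .muscle_parameters import (
    COMPOSITE_VARS,
    CohortStandardizer,
    cohort_frame,
    fit_standardizer,
)
from .performance_metrics import (
    SessionInputs,
    build_metric_table,
    build_mvic_reference,
    mvic_envelopes,
    metric_columns,
)
from .protocols import CONDITIONS, EXERCISES, PROTOCOLS, get_protocol
from .session_io import (
    read_repetition_series,
    read_session,
    session_filename,
    write_repetition_series,
    write_session,
)
from .signal_processing import MvicReference, detect_rep_peaks
from .stats_pipeline import (
    BootstrapSpec,
    RegressionModel,
    SelectionCriteria,
    bootstrap_validate,
    fit_ols,
    normality_test,
    select_variables,
)
from .synthetic_data import (
    SimulationConfig,
    generate_cohort,
    generate_muscle_parameters,
    generate_rest_recording,
    generate_session,
)

log = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_GRID = (
    (100, 0.10),
    (100, 0.30),
    (300, 0.10),
    (300, 0.30),
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable child seed for a named stage (< 2^31)."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31 - 1)


@dataclass
class PipelineConfig:
    workdir: Path = Path("exostrength_run")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    target: str = "total_performance"
    exercises: tuple[str, ...] = EXERCISES
    conditions: tuple[str, ...] = CONDITIONS
    bootstrap_grid: tuple[tuple[int, float], ...] = DEFAULT_BOOTSTRAP_GRID
    bootstrap_repeats: int = 50
    include_demographics: bool = True
    make_figures: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)
        self.simulation.master_seed = stage_seed(self.master_seed, "simulate")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        crit = SelectionCriteria(**raw.pop("criteria", {}))
        grid = raw.pop("bootstrap_grid", None)
        kwargs = dict(simulation=sim, criteria=crit, **raw)
        if grid is not None:
            kwargs["bootstrap_grid"] = tuple((int(n), float(f)) for n, f in grid)
        return cls(**kwargs)


@dataclass
class ReportBundle:
    workdir: Path
    cohort_path: Path | None = None
    metrics_path: Path | None = None
    models: dict[str, RegressionModel] = field(default_factory=dict)
    selection_audit: list = field(default_factory=list)
    bootstrap: pd.DataFrame | None = None
    figures: list[Path] = field(default_factory=list)
    report_path: Path | None = None


def simulate(config: PipelineConfig) -> Path:
    """Stage 1: cohort, muscle parameters, sessions, rest recordings."""
    wd = config.workdir
    wd.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    profiles = generate_cohort(sim)
    log.info("simulate: %d participants, seed %d", len(profiles), sim.master_seed)
    params = [generate_muscle_parameters(p, sim) for p in profiles]
    std = fit_standardizer(params)
    std.save(wd / "standardizer.csv")
    cohort = cohort_frame(params, std)
    demo = pd.DataFrame(
        {
            "participant_id": [p.id for p in profiles],
            "latent_strength": [p.latent_strength for p in profiles],
            "height": [p.height for p in profiles],
            "age": [p.age for p in profiles],
            "sex": [p.sex for p in profiles],
        }
    )
    cohort = cohort.merge(demo, on="participant_id")
    cohort_path = wd / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)

    sess_dir = wd / "sessions"
    sess_dir.mkdir(exist_ok=True)
    from .session_io import write_session  # local alias for clarity

    for profile in profiles:
        rest = generate_rest_recording(profile, sim)
        _write_traces(rest, sess_dir / f"{profile.id}_rest.csv")
        for ex in config.exercises:
            for cond in config.conditions:
                proto = get_protocol(ex, cond)
                bundle = generate_session(profile, proto, config=sim)
                write_session(bundle, sess_dir)
    return cohort_path


def _write_traces(traces: dict, path: Path) -> None:
    rate = next(iter(traces.values())).rate
    channels = list(traces)
    data = np.column_stack([traces[ch].samples for ch in channels])
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={rate:g}\n# channels={','.join(channels)}\n")
        np.savetxt(fh, data, fmt="%.6g", delimiter=",")


def _read_traces(path: Path) -> dict:
    from .signal_processing import SignalTrace

    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    data = np.loadtxt(path, delimiter=",", skiprows=n_header)
    if data.ndim == 1:
        data = data[:, None]
    rate = float(meta["rate_hz"])
    channels = meta["channels"].split(",")
    return {
        ch: SignalTrace(data[:, i], rate, channel=ch, kind="semg_raw")
        for i, ch in enumerate(channels)
    }


def extract(config: PipelineConfig) -> Path:
    """Stage 2: repetition series and MVIC references from session files."""
    wd = config.workdir
    sess_dir = wd / "sessions"
    reps_dir = wd / "reps"
    reps_dir.mkdir(exist_ok=True)
    cohort = pd.read_csv(wd / "cohort.csv")
    ref_rows = []
    for pid in cohort["participant_id"]:
        semg_sets = []
        for ex in config.exercises:
            for cond in config.conditions:
                key = f"{ex}:{cond}"
                path = sess_dir / session_filename(pid, key)
                if not path.exists():
                    log.warning("extract: missing session %s", path.name)
                    continue
                bundle = read_session(path)
                series = detect_rep_peaks(bundle.torque, bundle.protocol)
                write_repetition_series(
                    series, reps_dir / session_filename(pid, key)
                )
                semg_sets.append(bundle.semg)
        rest_path = sess_dir / f"{pid}_rest.csv"
        rest = _read_traces(rest_path) if rest_path.exists() else {}
        if semg_sets and rest:
            ref = build_mvic_reference(
                semg_sets, rest, mains_freq=config.simulation.mains_freq
            )
            for ch in ref.semg_max:
                ref_rows.append(
                    {"participant_id": pid, "channel": ch,
                     "semg_max": ref.semg_max[ch], "semg_rest": ref.semg_rest[ch]}
                )
    ref_path = wd / "mvic_refs.csv"
    pd.DataFrame(ref_rows).to_csv(ref_path, index=False)
    return ref_path


def _load_refs(path: Path) -> dict[str, MvicReference]:
    df = pd.read_csv(path)
    refs = {}
    for pid, grp in df.groupby("participant_id"):
        refs[str(pid)] = MvicReference(
            semg_max=dict(zip(grp["channel"], grp["semg_max"])),
            semg_rest=dict(zip(grp["channel"], grp["semg_rest"])),
        )
    return refs


def metrics(config: PipelineConfig) -> Path:
    """Stage 3: the participants x 27 metric table."""
    wd = config.workdir
    cohort = pd.read_csv(wd / "cohort.csv")
    refs = _load_refs(wd / "mvic_refs.csv")
    sessions: dict[str, dict[str, SessionInputs]] = {}
    for pid in cohort["participant_id"]:
        by_proto = {}
        for ex in config.exercises:
            for cond in config.conditions:
                key = f"{ex}:{cond}"
                sess_path = wd / "sessions" / session_filename(pid, key)
                reps_path = wd / "reps" / session_filename(pid, key)
                if not (sess_path.exists() and reps_path.exists() and pid in refs):
                    continue
                bundle = read_session(sess_path)
                series = read_repetition_series(reps_path)
                envs = mvic_envelopes(
                    bundle.semg, refs[pid], mains_freq=config.simulation.mains_freq
                )
                by_proto[key] = SessionInputs(torque_series=series, envelopes=envs)
        sessions[pid] = by_proto
    table = build_metric_table(sessions)
    metrics_path = wd / "metrics.csv"
    table.to_csv(metrics_path)
    return metrics_path


def analysis_table(config: PipelineConfig) -> pd.DataFrame:
    """Join the metric table with the dependent-variable columns."""
    wd = config.workdir
    table = pd.read_csv(wd / "metrics.csv", index_col="participant_id")
    cohort = pd.read_csv(wd / "cohort.csv").set_index("participant_id")
    keep = ["total_performance", *COMPOSITE_VARS, "age", "sex"]
    joined = table.join(cohort[[c for c in keep if c in cohort.columns]])
    if "sex" in joined.columns:
        joined["sex_male"] = (joined.pop("sex") == "male").astype(float)
    return joined


def model(config: PipelineConfig) -> tuple[dict[str, RegressionModel], list]:
    """Stage 4: variable selection and the regression models.

    Fits the screened multivariable model ("selected") plus the
    squat-only ablation on the same cohort; each report mirrors the
    coefficient-table layout (term, B, SE, beta) with a JSON summary.
    """
    wd = config.workdir
    table = analysis_table(config)
    candidates = [c for c in metric_columns() if c in table.columns]
    predictors, audit = select_variables(
        table, config.target, config.criteria, candidates=candidates
    )
    models: dict[str, RegressionModel] = {}
    n_ok = table[[config.target]].dropna().shape[0]
    if predictors:
        if n_ok > len(predictors) + 1:
            models["selected"] = fit_ols(table, config.target, predictors)
        else:
            log.warning("model: insufficient n=%d for %d predictors",
                        n_ok, len(predictors))
    else:
        log.warning("model: no admissible predictors after screening")
    if "Squat_IS_Max" in table.columns and table["Squat_IS_Max"].notna().sum() > 3:
        models["squat_only"] = fit_ols(table, config.target, ["Squat_IS_Max"])
    for name, m in models.items():
        m.summary_frame().to_csv(wd / f"model_{name}.csv", index=False)
        summary = {
            "target": m.target_name, "predictors": m.predictor_names,
            "R": m.R, "r2": m.r2, "adj_r2": m.adj_r2, "f2": m.f2,
            "power": m.power, "p_overall": m.p_overall, "n": m.n,
        }
        (wd / f"model_{name}.json").write_text(json.dumps(summary, indent=2))
    audit_df = pd.DataFrame([asdict(a) for a in audit])
    audit_df.to_csv(wd / "selection_audit.csv", index=False)
    return models, audit


def validate(config: PipelineConfig, model_name: str = "squat_only") -> pd.DataFrame:
    """Stage 5: bootstrap-with-noise grid for one fitted model."""
    wd = config.workdir
    spec_path = wd / f"model_{model_name}.json"
    if not spec_path.exists():
        raise FileNotFoundError(f"model stage has not produced {spec_path.name}")
    predictors = json.loads(spec_path.read_text())["predictors"]
    table = analysis_table(config)
    std = CohortStandardizer.load(wd / "standardizer.csv").freeze()
    rows = []
    for demo in ([False, True] if config.include_demographics else [False]):
        for n_res, frac in config.bootstrap_grid:
            spec = BootstrapSpec(
                n_resamples=n_res,
                noise_fraction=frac,
                n_repeats=config.bootstrap_repeats,
                include_demographics=demo,
                seed=stage_seed(config.master_seed, f"validate:{n_res}:{frac}:{demo}"),
            )
            res = bootstrap_validate(table, config.target, predictors, spec, std)
            rows.append(
                {"model": model_name, "demographics": demo,
                 "n_resamples": n_res, "noise_fraction": frac,
                 "mean_R": res.mean_R, "sd_R": res.sd_R,
                 "mean_adj_r2": res.mean_adj_r2, "sd_adj_r2": res.sd_adj_r2}
            )
    grid = pd.DataFrame(rows)
    grid.to_csv(wd / "bootstrap.csv", index=False)
    return grid


def make_figures(config: PipelineConfig) -> list[Path]:
    """Correlation heatmap and clustering dendrogram of the metrics."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy as sch

    from .stats_pipeline import cluster_metrics, correlation_matrix

    wd = config.workdir
    table = analysis_table(config)
    cols = [
        c for c in metric_columns()
        if c in table.columns and table[c].notna().sum() > 2
        and table[c].nunique() > 1  # constant metrics have no correlation
    ]
    out: list[Path] = []
    if len(cols) < 2:
        return out
    corr = correlation_matrix(table[cols]).abs()
    incomplete = corr.columns[corr.isna().any()]
    corr = corr.drop(index=incomplete, columns=incomplete)
    cols = list(corr.columns)
    if len(cols) < 2:
        return out
    fig, ax = plt.subplots(figsize=(9, 8))
    im = ax.imshow(corr.to_numpy(), vmin=0, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
    ax.set_yticks(range(len(cols)), cols, fontsize=6)
    fig.colorbar(im, ax=ax, label="|Pearson r|")
    fig.tight_layout()
    p1 = wd / "correlation_heatmap.png"
    fig.savefig(p1, dpi=120)
    plt.close(fig)
    out.append(p1)

    clust = cluster_metrics(corr, config.criteria)
    fig, ax = plt.subplots(figsize=(9, 4))
    sch.dendrogram(clust.linkage_matrix, labels=clust.columns, ax=ax,
                   color_threshold=1 - config.criteria.linearity_threshold)
    ax.axhline(1 - config.criteria.linearity_threshold, ls="--", c="gray")
    ax.set_ylabel("1 - |r|")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=6)
    fig.tight_layout()
    p2 = wd / "dendrogram.png"
    fig.savefig(p2, dpi=120)
    plt.close(fig)
    out.append(p2)
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and render the report."""
    bundle = ReportBundle(workdir=config.workdir)
    bundle.cohort_path = simulate(config)
    extract(config)
    bundle.metrics_path = metrics(config)
    bundle.models, bundle.selection_audit = model(config)
    if "squat_only" in bundle.models:
        bundle.bootstrap = validate(config, "squat_only")
    if config.make_figures:
        bundle.figures = make_figures(config)
    bundle.report_path = render_report(bundle, config)
    return bundle


def render_report(bundle: ReportBundle, config: PipelineConfig) -> Path:
    """Human-readable markdown summary of every produced artifact."""
    wd = bundle.workdir
    lines = ["# Strength-estimation pipeline report", ""]

    if bundle.cohort_path and bundle.cohort_path.exists():
        cohort = pd.read_csv(bundle.cohort_path)
        lines += ["## Muscle parameters (cohort summary)", ""]
        lines.append("| parameter | mean | SD | Shapiro-Wilk p |")
        lines.append("|---|---|---|---|")
        for col in ("vj", "rm_le_lc_weight", "iso_le_lc_weight", "total_performance"):
            if col in cohort.columns:
                vals = cohort[col].dropna()
                try:
                    _, p = normality_test(vals)
                    ptxt = f"{p:.3f}"
                except ValueError:
                    ptxt = "-"
                lines.append(
                    f"| {col} | {vals.mean():.3f} | {vals.std(ddof=1):.3f} | {ptxt} |"
                )
        lines.append("")
    else:
        lines.append("cohort table: absent\n")

    if bundle.metrics_path and bundle.metrics_path.exists():
        table = pd.read_csv(bundle.metrics_path, index_col=0)
        present = [c for c in table.columns if table[c].notna().any()]
        lines += ["## Performance metrics", "",
                  f"{len(table)} participants, {len(present)} populated metrics.", ""]
        lines.append("| metric | mean | SD |")
        lines.append("|---|---|---|")
        for col in present:
            vals = table[col].dropna()
            lines.append(f"| {col} | {vals.mean():.3f} | {vals.std(ddof=1):.3f} |")
        lines.append("")
    else:
        lines.append("metric table: absent\n")

    if bundle.models:
        lines.append("## Regression models\n")
        for name, m in bundle.models.items():
            lines.append(
                f"### {name}: R = {m.R:.3f} (adj R2 = {m.adj_r2:.3f}), "
                f"f2 = {m.f2:.2f}, power = {m.power:.3f}, n = {m.n}\n"
            )
            lines.append("| term | B | SE | beta |")
            lines.append("|---|---|---|---|")
            for _, row in m.summary_frame().iterrows():
                beta = "-" if pd.isna(row["beta"]) else f"{row['beta']:.3f}"
                lines.append(
                    f"| {row['term']} | {row['B']:.3f} | {row['SE']:.3f} | {beta} |"
                )
            lines.append("")
    else:
        lines.append("regression models: no admissible predictors\n")

    if bundle.bootstrap is not None:
        lines.append("## Bootstrap validation\n")
        lines.append("| demographics | n_resamples | noise | mean R (adj R2) |")
        lines.append("|---|---|---|---|")
        for _, row in bundle.bootstrap.iterrows():
            lines.append(
                f"| {bool(row['demographics'])} | {int(row['n_resamples'])} "
                f"| {row['noise_fraction']:.0%} "
                f"| {row['mean_R']:.3f} ({row['mean_adj_r2']:.3f}) |"
            )
        lines.append("")
    else:
        lines.append("bootstrap validation: absent\n")

    path = wd / "report.md"
    path.write_text("\n".join(lines))
    return path
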