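"""End-to-end orchestration of the synthetic rehearsal study.

`run_synthetic_study` wires the stages together: generate stimulus
scatterplots, simulate drawers with known latent styles, process the raw
traces onto the fixed grid, fit the GP measurement model per function,
cluster the log-hyperparameters per problem, fit the linear style
classifier against the known simulated styles, and run the condition-level
statistics. Every stage draws its randomness from a seed derived from the
master seed and the stage name, so stages are reproducible in isolation
and two runs with the same config produce identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, dpmm, stats, stimuli, traces
from .exceptions import InvalidArgumentError
from .gp import FitConfig, GPHyperParams, fit_hyperparams
from .stimuli import DesignCell, DrawerProfile

__all__ = [
    "StudyConfig",
    "StudyResult",
    "stage_seed",
    "run_synthetic_study",
    "run_cluster_count_anova",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _default_problems() -> list[DesignCell]:
    # A compact 4-problem battery spanning both point counts and scales.
    return [
        DesignCell("linear", 6, "large", 1),
        DesignCell("linear", 24, "small", 1),
        DesignCell("quadratic", 6, "small", 1),
        DesignCell("cubic", 24, "large", 1),
    ]


@dataclass
class StudyConfig:
    """Configuration of one synthetic study run.

    The two latent drawer styles differ in their GP profile: smooth drawers
    have a large length scale and attribute deviations to noise; tracking
    drawers have a tiny length scale and near-zero noise variance, so their
    trace threads through every stimulus point. Per-participant style
    parameters are jittered in log space to create individual variation.
    """

    seed: int = 0
    problems: list[DesignCell] = field(default_factory=_default_problems)
    n_participants: int = 30
    smooth_fraction: float = 0.5
    stimulus_noise_sd: float = 0.15
    smooth_theta: GPHyperParams = field(
        default_factory=lambda: GPHyperParams(2.0, 1.0, 0.1)
    )
    tracking_theta: GPHyperParams = field(
        default_factory=lambda: GPHyperParams(0.05, 1.0, 1e-6)
    )
    style_jitter_sd: float = 0.15
    motor_sd: float = 0.01
    backtrack_prob: float = 0.0
    n_raw_points: int = 200
    fit: FitConfig = field(default_factory=FitConfig)
    dpmm_alpha: float = 1.0
    dpmm_sweeps: int = 300
    dpmm_burn_in: int = 150
    drop: list = field(default_factory=list)  # (participant_id, problem_id) pairs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["problems"] = [dataclasses.asdict(c) for c in self.problems]
        d["smooth_theta"] = dataclasses.asdict(self.smooth_theta)
        d["tracking_theta"] = dataclasses.asdict(self.tracking_theta)
        d["fit"] = dataclasses.asdict(self.fit)
        d["drop"] = [list(p) for p in self.drop]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "problems" in d:
            d["problems"] = [DesignCell(**c) for c in d["problems"]]
        for key in ("smooth_theta", "tracking_theta"):
            if key in d and isinstance(d[key], dict):
                d[key] = GPHyperParams(**d[key])
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = FitConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["fit"].items()})
        if "drop" in d:
            d["drop"] = [tuple(p) for p in d["drop"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Bundle of every intermediate and final table of a study run."""

    config: StudyConfig
    stimuli_table: pd.DataFrame
    traces_table: pd.DataFrame
    functions_table: pd.DataFrame
    records: pd.DataFrame
    partitions: pd.DataFrame
    cluster_counts: pd.DataFrame
    boundary_2d: classify.LinearBoundary
    boundary_3d: classify.LinearBoundary
    condition_means: pd.DataFrame
    correlations: pd.DataFrame
    consistency: list
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "stimuli_table",
            "traces_table",
            "functions_table",
            "records",
            "partitions",
            "cluster_counts",
            "condition_means",
            "correlations",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        for name in ("boundary_2d", "boundary_3d"):
            b = getattr(self, name)
            with open(out / f"{name}.json", "w") as fh:
                json.dump(
                    {
                        "features": list(b.features),
                        "weights": b.weights.tolist(),
                        "bias": b.bias,
                        "positive_label": b.positive_label,
                        "training_accuracy": b.training_accuracy,
                    },
                    fh,
                    indent=2,
                )
        with open(out / "consistency.json", "w") as fh:
            json.dump([dataclasses.asdict(c) for c in self.consistency], fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _participant_profiles(config: StudyConfig) -> dict[str, tuple[str, DrawerProfile]]:
    """Assign each participant a latent style and a jittered GP profile."""
    rng = np.random.default_rng(stage_seed(config.seed, "profiles"))
    n_smooth = int(round(config.smooth_fraction * config.n_participants))
    profiles = {}
    for i in range(config.n_participants):
        style = "smooth" if i < n_smooth else "tracking"
        base = config.smooth_theta if style == "smooth" else config.tracking_theta
        jitter = rng.normal(0.0, config.style_jitter_sd, size=3)
        theta = GPHyperParams.from_log_params(base.log_params + jitter)
        pid = f"p{i:03d}"
        profiles[pid] = (
            style,
            DrawerProfile(
                theta_true=theta,
                motor_sd=config.motor_sd,
                backtrack_prob=config.backtrack_prob,
            ),
        )
    return profiles


def run_synthetic_study(config: StudyConfig, out_dir=None) -> StudyResult:
    """Run the full synthetic study; optionally write all tables."""
    dropped = {tuple(p) for p in config.drop}

    # --- stimuli ---------------------------------------------------------
    stim_seed = stage_seed(config.seed, "stimuli")
    stim_by_problem = {}
    stim_rows = []
    for cell in config.problems:
        # One shared seed per (generator, n_points, replicate) so the
        # small/large members of a pair share relative point positions.
        seed = stage_seed(stim_seed, f"{cell.generator}-{cell.n_points}-{cell.replicate}")
        sp = stimuli.make_stimulus(
            cell,
            stimuli.default_coefficients(cell.generator),
            config.stimulus_noise_sd,
            seed,
        )
        stim_by_problem[cell.problem_id] = sp
        for j, (x, y) in enumerate(zip(sp.x, sp.y)):
            stim_rows.append(
                {"problem_id": cell.problem_id, "point_index": j, "x": x, "y": y}
            )
    stimuli_table = pd.DataFrame(stim_rows)

    # --- simulated drawers ----------------------------------------------
    profiles = _participant_profiles(config)
    draw_seed = stage_seed(config.seed, "drawers")
    trace_rows = []
    raw_traces = []
    for pid, (style, profile) in profiles.items():
        for problem_id, sp in stim_by_problem.items():
            if (pid, problem_id) in dropped:
                continue
            tr = stimuli.simulate_drawer(
                sp,
                profile,
                n_raw_points=config.n_raw_points,
                seed=stage_seed(draw_seed, f"{pid}-{problem_id}"),
                participant_id=pid,
            )
            raw_traces.append((pid, style, tr))
            for j, (x, y) in enumerate(zip(tr.x, tr.y)):
                trace_rows.append(
                    {
                        "participant_id": pid,
                        "problem_id": problem_id,
                        "point_index": j,
                        "x": x,
                        "y": y,
                    }
                )
    traces_table = pd.DataFrame(trace_rows)

    # --- trace processing -----------------------------------------------
    functions = []
    fn_rows = []
    for pid, style, tr in raw_traces:
        rf = traces.process_trace(tr)
        functions.append((pid, style, rf))
        for j, (x, y) in enumerate(zip(rf.grid_x, rf.y)):
            fn_rows.append(
                {
                    "participant_id": pid,
                    "problem_id": rf.problem_id,
                    "point_index": j,
                    "x": x,
                    "y": y,
                    "processed": True,
                }
            )
    functions_table = pd.DataFrame(fn_rows)

    # --- GP fits ---------------------------------------------------------
    design = {cell.problem_id: cell for cell in config.problems}
    recs = []
    styles = {}
    for pid, style, rf in functions:
        styles[(pid, rf.problem_id)] = style
        recs.append(fit_hyperparams(rf, config.fit))
    records = stats.records_to_frame(recs, design)
    records["style"] = [
        styles[(r.participant_id, r.problem_id)] for r in recs
    ]

    # --- DPMM clustering per problem -------------------------------------
    clus_seed = stage_seed(config.seed, "dpmm")
    part_rows = []
    count_rows = []
    for problem_id, cell in design.items():
        sub = records[records["problem_id"] == problem_id]
        data = sub[list(stats.LOG_PARAM_COLUMNS)].to_numpy()
        partition, _ = dpmm.run_dpmm(
            data,
            alpha=config.dpmm_alpha,
            n_sweeps=config.dpmm_sweeps,
            burn_in=config.dpmm_burn_in,
            seed=stage_seed(clus_seed, problem_id),
            problem_id=problem_id,
        )
        for pid, lab in zip(sub["participant_id"], partition.assignments):
            part_rows.append(
                {"problem_id": problem_id, "participant_id": pid, "cluster_label": int(lab)}
            )
        count_rows.append(
            {
                "problem_id": problem_id,
                "generator": cell.generator,
                "n_points": cell.n_points,
                "scale": cell.scale,
                "replicate": cell.replicate,
                "n_clusters": partition.n_clusters,
            }
        )
    partitions = pd.DataFrame(part_rows)
    cluster_counts = pd.DataFrame(count_rows)

    # --- classifier against the known latent styles ----------------------
    style_labels = records["style"].map(
        {"smooth": "linear", "tracking": "data_tracking"}
    )
    feats = records.rename(
        columns={
            "log_lambda": "log_length_scale",
            "log_signal_var": "log_signal_var",
            "log_noise_var": "log_noise_var",
        }
    )
    boundary_2d = classify.fit_linear_boundary(
        feats, style_labels, feature_subset=("log_length_scale", "log_noise_var")
    )
    boundary_3d = classify.fit_linear_boundary(feats, style_labels)

    # --- statistics -------------------------------------------------------
    cond_means = stats.condition_means(records)
    correlations = stats.parameter_correlations(records)
    consistency = (
        stats.consistency_analysis(records) if len(design) >= 2 else []
    )

    incomplete = sorted({pid for pid, _ in dropped})
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("profiles", "stimuli", "drawers", "dpmm")
        },
        "n_participants": config.n_participants,
        "n_problems": len(design),
        "n_traces": len(raw_traces),
        "n_records": len(records),
        "n_nonconverged_fits": int((~records["converged"]).sum()),
        "participants_partially_missing": incomplete,
    }

    result = StudyResult(
        config=config,
        stimuli_table=stimuli_table,
        traces_table=traces_table,
        functions_table=functions_table,
        records=records,
        partitions=partitions,
        cluster_counts=cluster_counts,
        boundary_2d=boundary_2d,
        boundary_3d=boundary_3d,
        condition_means=cond_means,
        correlations=correlations,
        consistency=consistency,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def run_cluster_count_anova(cluster_counts: pd.DataFrame | None = None) -> stats.AnovaTable:
    """The 3 x 2 x 2 fixed-effects ANOVA on per-problem cluster counts.

    With no argument, runs on the shipped reference counts (24 problems,
    2 replicates per cell).
    """
    if cluster_counts is None:
        from .datasets import reference_cluster_counts

        cluster_counts = reference_cluster_counts()
    if len(cluster_counts) != 24:
        raise InvalidArgumentError("expected 24 per-problem counts")
    return stats.factorial_anova(
        cluster_counts["n_clusters"].to_numpy(), cluster_counts
    )
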