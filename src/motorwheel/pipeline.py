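"""Configuration and orchestration of the full analysis.

``RunConfig`` collects every stage parameter with defaults matching the
standard experimental conventions (2-min blocks, 15-s transition windows,
5000 shuffles, 99.95th percentile, 5-px rendering SD and matching tolerance,
search half-width 40).  ``run_pipeline`` executes the stages in order —
kinematics, events, transition response, connectivity, registration,
persistence — on provided input files or, when a stage's input is absent,
on synthetic data generated from the run seed.  Outputs are per-stage
delimited tables plus a JSON manifest (parameters, seed, package version)
sufficient to reproduce the run; identical config and seed give identical
outputs.

The single run seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``: stage k always receives child k,
so a stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import connectivity as conn
from . import events as ev
from . import io as mio
from . import kinematics as kin
from . import persistence as pers
from . import registration as reg
from . import synthetic as syn
from . import transitions as tr
from .profile import SpeedProfile

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

STAGES = (
    "kinematics",
    "events",
    "transitions",
    "connectivity",
    "registration",
    "persistence",
)


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters."""

    out_dir: str = "motorwheel_out"
    seed: int = 0
    # inputs (None -> simulate with the stage seed)
    paw_path: str | None = None
    traces_path: str | None = None
    rois_path: str | None = None
    # speed profile
    speeds: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0, 0.0)
    block_duration_s: float = 120.0
    # kinematics
    alpha_mm_per_px: float = 0.1
    cutoff: float = 0.2
    paw_frame_rate: float = 71.5
    # events
    k_mad: float = 2.5
    min_duration_frames: int = 2
    calcium_frame_rate: float = syn.CALCIUM_FRAME_RATE
    # transition response
    window_s: float = 15.0
    percentile: float = 99.95
    n_shuffles: int = 5000
    shuffle_mode: str = "window"
    # connectivity
    shrinkage: float = 0.05
    near_um: float = 100.0
    far_um: float = 200.0
    # registration
    ws: int = 40
    tol_px: float = 5.0
    sd_px: float = 5.0
    field_px: int = 512
    n_days: int = 4
    # simulation sizes
    sim_n_neurons: int = 60
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        if not 0 <= self.percentile <= 100:
            raise ValueError(f"percentile must lie in [0, 100], got {self.percentile}")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie strictly between 0 and 1")
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must lie in [0, 1]")
        if self.n_shuffles < 1 or self.ws < 0 or self.tol_px < 0 or self.sd_px <= 0:
            raise ValueError("invalid stage parameter")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @property
    def profile(self) -> SpeedProfile:
        return SpeedProfile(self.speeds, self.block_duration_s)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("speeds", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage child of the run seed."""
    return np.random.SeedSequence(seed).spawn(len(STAGES))[STAGES.index(stage)]


def _stage_rng_seed(seed: int, stage: str) -> int:
    # small deterministic integer for APIs that take a plain seed
    return int(stage_seed(seed, stage).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write report tables plus a manifest.

    Returns a dict of the in-memory stage results keyed by stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = config.profile
    results: dict = {}

    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    try:
        if "kinematics" in config.stages:
            results["kinematics"] = _run_kinematics(config, profile, out)
        traces = None
        truth = None
        if {"events", "transitions", "connectivity"} & set(config.stages):
            traces, truth = _load_or_simulate_traces(config, profile)
        if "events" in config.stages:
            results["events"] = _run_events(config, profile, traces, out)
        if "transitions" in config.stages:
            results["transitions"] = _run_transitions(config, profile, traces, truth, out)
        if "connectivity" in config.stages:
            results["connectivity"] = _run_connectivity(config, traces, out)
        if "registration" in config.stages or "persistence" in config.stages:
            regmap = _run_registration(config, out)
            results["registration"] = regmap
            if "persistence" in config.stages:
                results["persistence"] = _run_persistence(config, regmap, out)

        manifest = {
            "package": "motorwheel",
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    finally:
        logger.removeHandler(fh)
        fh.close()
    return results


def _run_kinematics(config: RunConfig, profile: SpeedProfile, out: Path) -> dict:
    if config.paw_path:
        left, right = mio.read_paws(config.paw_path, config.paw_frame_rate)
    else:
        left, right, _ = syn.gen_paw_trajectories(
            profile,
            coordination=0.8,
            noise_sd_mm=0.2,
            seed=_stage_rng_seed(config.seed, "kinematics"),
            frame_rate=config.paw_frame_rate,
            alpha=config.alpha_mm_per_px,
        )
    a = config.alpha_mm_per_px
    lx = kin.center_paw(left.x_raw, a, left.frame_rate)
    ly = kin.center_paw(left.y_raw, a, left.frame_rate)
    rx = kin.center_paw(right.x_raw, a, right.frame_rate)
    for t in (lx, ly, rx):
        t.values_mm = kin.smooth_trace(t.values_mm, cutoff=config.cutoff)
    strides = kin.detect_strides(lx, ly)
    stats = kin.block_stride_stats(strides, profile)

    running = [i for i, s in enumerate(profile.speeds) if s == max(profile.speeds)]
    block = profile.block_slices(config.paw_frame_rate)[running[0]]
    coord = kin.coordination_index(lx, rx, block)

    strides.strides.to_csv(out / "strides.csv", index=False)
    stats.assign(coordination_index_top_speed=coord).to_csv(
        out / "stride_blocks.csv", index=False
    )
    return {"strides": strides, "block_stats": stats, "coordination_index": coord}


def _load_or_simulate_traces(config: RunConfig, profile: SpeedProfile):
    if config.traces_path:
        if str(config.traces_path).endswith((".h5", ".hdf5")):
            loaded = mio.read_session_h5(config.traces_path)
            return loaded["traces"], loaded.get("truth")
        return (
            mio.read_traces_csv(config.traces_path, config.calcium_frame_rate),
            None,
        )
    traces, truth = syn.gen_transition_responders(
        profile,
        config.sim_n_neurons,
        seed=_stage_rng_seed(config.seed, "events"),
        frame_rate=config.calcium_frame_rate,
        noise_sd=0.05,
    )
    # attach plausible metadata so connectivity scopes and distances work
    rng = np.random.default_rng(_stage_rng_seed(config.seed, "connectivity"))
    n = traces.n_neurons
    traces.layer = np.where(np.arange(n) < n // 2, "L2/3", "L5a")
    traces.centroids = rng.uniform(20, config.field_px - 20, (n, 2))
    traces.pixel_size_um = 0.8
    return traces, truth


def _run_events(config, profile, traces, out: Path) -> dict:
    raster = ev.detect_events(traces, config.k_mad, config.min_duration_frames)
    rates = ev.block_event_rate(raster, profile)
    states = ev.state_rates(raster, profile)
    change = ev.transition_rate_change(raster, profile)
    width = ev.rate_distribution_width(
        rates.groupby("neuron")["rate_hz"].mean().to_numpy()
    )
    rates.to_csv(out / "block_rates.csv", index=False)
    states.to_csv(out / "state_rates.csv", index=False)
    change.to_csv(out / "transition_rates.csv", index=False)
    return {"raster": raster, "block_rates": rates, "state_rates": states,
            "transition_rates": change, "rate_fwhm": width}


def _run_transitions(config, profile, traces, truth, out: Path) -> dict:
    res = tr.classify_transition_active(
        traces,
        profile,
        config.percentile,
        config.n_shuffles,
        seed=_stage_rng_seed(config.seed, "transitions"),
        window_s=config.window_s,
        mode=config.shuffle_mode,
    )
    table = pd.DataFrame(
        {
            "neuron": np.arange(len(res.similarity)),
            "similarity": res.similarity,
            "null_percentile": res.threshold,
            "transition_active": res.active,
        }
    )
    if truth is not None and truth.responder_labels is not None:
        table["planted_responder"] = truth.responder_labels
    table.to_csv(out / "transition_active.csv", index=False)
    return {"result": res, "table": table}


def _run_connectivity(config, traces, out: Path) -> dict:
    pairs = conn.pair_table(traces, shrinkage=config.shrinkage)
    pairs.to_csv(out / "pairs.csv", index=False)
    summary_rows = []
    for scope, grp in pairs.groupby("scope"):
        row = {
            "scope": scope,
            "n_pairs": len(grp),
            "mean_abs_r": float(np.abs(grp["r"]).mean()),
            "mean_abs_dcc": float(np.abs(grp["dcc"]).mean()),
            "n_strong_r": int(grp["strong_r"].sum()),
            "n_strong_dcc": int(grp["strong_dcc"].sum()),
        }
        try:
            row["proximity_ratio"] = conn.proximity_ratio(
                grp, config.near_um, config.far_um
            )
        except ValueError:
            row["proximity_ratio"] = np.nan
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "connectivity_summary.csv", index=False)
    return {"pairs": pairs, "summary": summary}


def _run_registration(config, out: Path) -> reg.RegistrationMap:
    if config.rois_path:
        tables = mio.read_rois(config.rois_path, config.field_px)
    else:
        tables, _ = syn.gen_roi_sessions(
            config.sim_n_neurons,
            config.n_days,
            config.field_px,
            max_shift_px=min(config.ws, 20),
            jitter_px=1.0,
            dropout=0.1,
            seed=_stage_rng_seed(config.seed, "registration"),
        )
    regmap = reg.track_across_days(
        tables, config.ws, config.tol_px, config.sd_px, config.field_px
    )
    regmap.identity.to_csv(out / "identity_map.csv")
    pd.DataFrame(
        {
            "day": range(1, regmap.n_days + 1),
            "dx": [s[0] for s in regmap.shifts],
            "dy": [s[1] for s in regmap.shifts],
            "score": regmap.scores,
        }
    ).to_csv(out / "day_shifts.csv", index=False)
    return regmap


def _run_persistence(config, regmap: reg.RegistrationMap, out: Path) -> dict:
    # per-day DCC over the tracked id space from per-day simulated traces
    tracked = regmap.identity.notna().all(axis=1)
    ids = regmap.identity.index[tracked].to_numpy()
    n = len(ids)
    if n < 4:
        raise ValueError("fewer than 4 neurons tracked on all days")
    sets = []
    base = syn.random_coupling(
        n, 0.1, 0.3, seed=_stage_rng_seed(config.seed, "persistence")
    )
    for day in range(regmap.n_days):
        traces, _ = syn.gen_network_traces(
            n,
            base,
            frames=1000,
            seed=_stage_rng_seed(config.seed, "persistence") + day + 1,
            mode="precision",
            condition=True,
        )
        mat = conn.dcc_matrix(traces, shrinkage=config.shrinkage)
        mat.neuron_ids = ids[mat.neuron_ids]
        sets.append(pers.detected_pairs_per_day([mat])[0])
    profile_ = pers.persistence_histogram(sets, regmap.n_days)
    kurt = pers.histogram_kurtosis(profile_)
    table = profile_.to_frame().assign(kurtosis=kurt, n_pairs=profile_.n_pairs)
    table.to_csv(out / "persistence.csv", index=False)
    return {"profile": profile_, "kurtosis": kurt}
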