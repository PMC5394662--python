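"""File I/O, configuration and the end-to-end pipeline runner.

The interchange format is CSV with a one-line schema header comment.
``visits.csv`` columns: device_id, device_type (puzzlebox|feeder),
subpop, replicate, bird_id, arrive_s, depart_s, opened (0/1, empty for
feeders); times are decimal seconds since the experiment epoch on the
1/16-s grid. All stage parameters and seeds live in a YAML config; a run
manifest records the config echo, seeds, package version and SHA-256 of
every output so identical inputs and seeds reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import events as ev
from . import inference, network, tactics
from .gatherings import build_gbi, detect_gatherings
from .simulate import SimConfig, simulate_population

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
VISIT_COLUMNS = [
    "device_id", "device_type", "subpop", "replicate", "bird_id",
    "arrive_s", "depart_s", "opened",
]

__all__ = [
    "PipelineConfig", "RunManifest", "read_visits", "write_visits",
    "load_config", "run_pipeline",
]


def write_visits(visits: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# psforage schema={SCHEMA_VERSION} kind=visits\n")
        visits[VISIT_COLUMNS].to_csv(fh, index=False)


def read_visits(path) -> pd.DataFrame:
    """Read and validate a visits table.

    Malformed rows (negative duration, unknown device type) are reported
    with their line numbers. Records come back sorted by device and
    arrival time.
    """
    path = Path(path)
    df = pd.read_csv(
        path, comment="#",
        dtype={"device_id": str, "device_type": str, "subpop": str,
               "replicate": str, "bird_id": str},
    )
    missing = set(VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_type = ~df["device_type"].isin(["puzzlebox", "feeder"])
    if bad_type.any():
        rows = df.index[bad_type].tolist()[:5]
        raise ValueError(f"{path}: bad device_type at rows {rows}")
    bad_iv = df["depart_s"].to_numpy(float) < df["arrive_s"].to_numpy(float)
    if bad_iv.any():
        rows = df.index[bad_iv].tolist()[:5]
        raise ValueError(f"{path}: depart_s < arrive_s at rows {rows}")
    return df.sort_values(
        ["subpop", "device_id", "arrive_s", "bird_id"], kind="stable"
    ).reset_index(drop=True)


def _write_csv(df: pd.DataFrame, path: Path, kind: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# psforage schema={SCHEMA_VERSION} kind={kind}\n")
        df.to_csv(fh, index=index)


@dataclass
class PipelineConfig:
    """Validated parameters for every stage of the pipeline."""

    out_dir: str = "psforage_run"
    visits_path: str | None = None  # None -> simulate
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    window_s: float = 1.0
    max_scrounges: int = 3
    min_visits: int = 50
    bin_hours: float = 2.0
    k: int = 2
    n_starts: int = 10
    max_components: int | None = None
    n_perm: int = 1000
    burn_in: int = 1000
    perm_metric: str | None = "strength"
    n_boot: int = 0  # bootstrap draws for the repeatability CI
    log_level: str = "INFO"

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.max_scrounges < 1 or self.min_visits < 0:
            raise ValueError("invalid event-engine parameters")
        if self.bin_hours <= 0 or self.k < 1:
            raise ValueError("invalid tactic-clustering parameters")
        if self.n_perm < 0 or self.burn_in < 0:
            raise ValueError("permutation counts must be non-negative")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict[str, str]  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute simulate (optional) -> events -> gatherings -> network ->
    tactics -> inference, writing every stage output under ``out_dir``.

    Deterministic: all randomness flows from ``config.seed``. Returns the
    manifest (also written as ``manifest.json``) whose output hashes are
    identical across reruns with the same inputs and seed.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if config.visits_path is None:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        sim = simulate_population(sim_cfg)
        visits = sim.visits
        write_visits(visits, out / "visits.csv")
        _write_csv(sim.truth, out / "truth.csv", "truth")
        outputs["visits.csv"] = out / "visits.csv"
        outputs["truth.csv"] = out / "truth.csv"
    else:
        visits = read_visits(config.visits_path)

    # --- events -----------------------------------------------------------
    puzzle = visits[visits["device_type"] == "puzzlebox"]
    events, chains = ev.classify_all(
        puzzle, window_s=config.window_s, max_scrounges=config.max_scrounges
    )
    summaries = ev.exposure_summaries(events, min_visits=config.min_visits)
    _write_csv(
        events.assign(
            chain_position=events["chain_position"].astype("Int64")
        )[["bird_id", "time", "kind", "chain_id", "chain_position"]],
        out / "events.csv", "events",
    )
    _write_csv(summaries, out / "summaries.csv", "summaries", index=True)
    outputs["events.csv"] = out / "events.csv"
    outputs["summaries.csv"] = out / "summaries.csv"

    # --- gatherings & network, per subpopulation --------------------------
    feeder = visits[visits["device_type"] == "feeder"]
    metrics_frames = []
    for subpop, grp in feeder.groupby("subpop", sort=True):
        gevents = detect_gatherings(
            grp, max_components=config.max_components, seed=config.seed
        )
        if not gevents:
            continue
        gbi = build_gbi(gevents)
        A = network.association_matrix(gbi)
        nm = network.node_metrics(A, gevents)
        nm.insert(0, "subpop", subpop)
        metrics_frames.append(nm)
    if metrics_frames:
        metrics = pd.concat(metrics_frames)
        _write_csv(metrics, out / "metrics.csv", "node-metrics", index=True)
        outputs["metrics.csv"] = out / "metrics.csv"

    # --- tactics ----------------------------------------------------------
    traj = tactics.build_trajectories(
        events, bin_hours=config.bin_hours, min_visits=config.min_visits
    )
    assign = tactics.longitudinal_kmeans(
        traj, k=config.k, n_starts=config.n_starts, seed=config.seed
    )
    tact = pd.DataFrame(
        {"tactic": assign.labels, "final_proportion": traj.values[:, -1]}
    )
    _write_csv(traj.to_frame(), out / "trajectories.csv", "trajectories", index=True)
    _write_csv(tact, out / "tactics.csv", "tactics", index=True)
    outputs["trajectories.csv"] = out / "trajectories.csv"
    outputs["tactics.csv"] = out / "tactics.csv"
    (out / "clusters.json").write_text(
        json.dumps(
            {
                "k": assign.k,
                "cluster_means": assign.cluster_means.tolist(),
                "cluster_sds": assign.cluster_sds.tolist(),
                "inertia": assign.inertia,
            },
            indent=2,
        )
    )
    outputs["clusters.json"] = out / "clusters.json"

    # --- inference --------------------------------------------------------
    rep_of_bird = puzzle.groupby("bird_id")["replicate"].first()
    results: dict = {}

    rewarded = events[events["kind"].isin([ev.SOLVE, ev.SCROUNGE])].copy()
    rewarded = rewarded[
        rewarded["bird_id"].isin(summaries.index[summaries["passes_min_visits"]])
    ]
    rewarded["is_scrounge"] = (rewarded["kind"] == ev.SCROUNGE).astype(int)
    from ._calendar import day_index

    rewarded["date"] = day_index(rewarded["time"].to_numpy())
    rewarded["replicate"] = rewarded["bird_id"].map(rep_of_bird)
    fixed = ["date"]
    if rewarded["replicate"].nunique() > 1:
        fixed.append("replicate")
    rep = inference.repeatability(
        rewarded,
        fixed=fixed,
        n_boot=config.n_boot,
        rng=np.random.default_rng(config.seed + 1),
    )
    results["repeatability"] = {
        "R": rep.R, "CI": [rep.CI_low, rep.CI_high], "V_ind": rep.V_ind,
        "V_e": rep.V_e, "scale": rep.scale,
    }

    props = tactics.proportion_scroungers(assign.labels, rep_of_bird)
    sizes = puzzle.groupby("replicate")["bird_id"].nunique()
    table = pd.DataFrame(
        {"proportion_scroungers": props, "subpop_size": sizes}
    ).dropna()
    if len(table) >= 3 and table["subpop_size"].std() > 0:
        reg = inference.subpop_regression(table, year_col=None)
        results["subpop_regression"] = {
            "slope": reg.slope, "t": reg.t, "p": reg.p, "r2": reg.r2,
            "n": reg.n,
        }
    (out / "inference.json").write_text(json.dumps(results, indent=2))
    outputs["inference.json"] = out / "inference.json"

    manifest = RunManifest(
        config={**asdict(config)},
        seed=config.seed,
        version=_version,
        outputs={name: _sha256(p) for name, p in sorted(outputs.items())},
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
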