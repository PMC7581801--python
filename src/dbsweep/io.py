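"""File I/O and the end-to-end paradigm runner.

All tabular artifacts are plain delimiter-separated text with unit-suffixed
headers; protocols and configs are YAML. A run writes a manifest with a
SHA-256 checksum per file, so the manifest alone re-verifies the bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    EXCLUDED,
    AngularTrajectory,
    AnimalModel,
    CohortConfig,
    sample_animal,
    simulate_session,
    titrate_I0,
)
from .errors import ParseError, TitrationError
from .protocols import (
    AMPLITUDE_MULTIPLIERS,
    CHARGE_MULTIPLIERS,
    FREQUENCY_LEVELS_HZ,
    WAVEFORM_SHAPE_ORDER,
    SessionProtocol,
    build_amplitude_protocol,
    build_frequency_protocol,
    build_waveform_protocol,
    save_protocol,
)
from .rotometry import session_features
from .similarity import SimilarityMatrix, condition_trace, ed_matrix
from .stats import level_means, pearson, waveform_ttest
from .waveforms import PulseShape, PulseTrainSpec, charge_per_phase

__all__ = [
    "RunConfig",
    "RunBundle",
    "read_trajectory",
    "write_trajectory",
    "run_paradigm",
]

PARADIGMS = ("amplitude", "frequency", "waveform")


# ---------------------------------------------------------------------------
# trajectory files


def write_trajectory(path, traj: AngularTrajectory) -> None:
    """Write ``time_s,angle_deg[,x_cm,y_cm]`` columns plus a YAML meta sidecar."""
    path = Path(path)
    cols = {"time_s": traj.time_s, "angle_deg": np.asarray(traj.angle_deg, dtype=float)}
    if traj.has_position:
        cols["x_cm"] = np.asarray(traj.x_cm, dtype=float)
        cols["y_cm"] = np.asarray(traj.y_cm, dtype=float)
    # %.17g keeps the round trip exact at double precision
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    if traj.meta:
        with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
            yaml.safe_dump(traj.meta, fh, sort_keys=False)


def read_trajectory(path) -> AngularTrajectory:
    """Read and validate a trajectory table.

    Requires strictly increasing, uniformly spaced ``time_s`` and finite
    ``angle_deg``; violations are reported with their 1-based data row
    number. ``x_cm``/``y_cm`` are optional (distances downstream come back
    missing without them).
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "angle_deg"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    angle = df["angle_deg"].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(angle))[0]
    if bad.size:
        raise ParseError(f"{path.name}: non-finite angle_deg at row {bad[0] + 1}")
    if t.size < 2:
        raise ParseError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    nonmono = np.nonzero(dt <= 0)[0]
    if nonmono.size:
        raise ParseError(
            f"{path.name}: time_s not strictly increasing at row {nonmono[0] + 2}"
        )
    if np.max(np.abs(dt - dt[0])) > 1e-6 * max(dt[0], 1.0):
        raise ParseError(f"{path.name}: time_s is not uniformly sampled")
    x = df["x_cm"].to_numpy(dtype=float) if "x_cm" in df.columns else None
    y = df["y_cm"].to_numpy(dtype=float) if "y_cm" in df.columns else None
    if (x is None) != (y is None):
        raise ParseError(f"{path.name}: x_cm and y_cm must come together")
    meta = {}
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    return AngularTrajectory(dt_s=float(dt[0]), angle_deg=angle, x_cm=x, y_cm=y, meta=meta)


# ---------------------------------------------------------------------------
# run configuration and bundle


@dataclass
class RunConfig:
    """Everything needed to reproduce one paradigm run."""

    paradigm: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_include: int = 6  # animals enrolled after titration/exclusion
    grid_step_ua: float = 1.0  # titration grid; fine enough for small thresholds
    grid_n: int = 30  # similarity resampling grid
    units: str = "rotations"
    with_position: bool = True

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ParseError(f"paradigm must be one of {PARADIGMS}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunBundle:
    """In-memory artifacts of one paradigm run."""

    config: RunConfig
    animals: list[AnimalModel]
    thresholds_ua: dict[str, float]
    excluded_ids: list[str]
    protocols: dict[str, SessionProtocol]
    trajectories: dict[str, AngularTrajectory]
    features: pd.DataFrame
    correlations: pd.DataFrame
    similarity: SimilarityMatrix
    ttests: pd.DataFrame | None = None
    manifest: dict[str, str] = field(default_factory=dict)


def _titration_template(paradigm: str) -> PulseTrainSpec:
    if paradigm == "frequency":
        # thresholds for this paradigm are titrated at the 15 Hz baseline
        return PulseTrainSpec(PulseShape.RECT, 1.0, 65.0, 15.0, 100.0)
    pw = 100.0 if paradigm == "waveform" else 65.0
    return PulseTrainSpec(PulseShape.RECT, 1.0, pw, 130.0, 100.0)


def _protocol_for(paradigm: str, I0_ua: float) -> SessionProtocol:
    if paradigm == "amplitude":
        return build_amplitude_protocol(I0_ua)
    if paradigm == "frequency":
        return build_frequency_protocol(I0_ua)
    q0 = charge_per_phase(PulseShape.RECT, I0_ua, 100.0)
    return build_waveform_protocol(q0, pw_us=100.0)


def _condition_levels(paradigm: str) -> list[tuple[str, float]]:
    """(label, physical level) pairs in protocol order."""
    if paradigm == "amplitude":
        return [(f"{m:g}xI0", m) for m in AMPLITUDE_MULTIPLIERS]
    if paradigm == "frequency":
        return [(f"{f:g}Hz", f) for f in FREQUENCY_LEVELS_HZ]
    return [
        (f"{m:g}xQ0_{shape.display}", m)
        for m in CHARGE_MULTIPLIERS
        for shape in WAVEFORM_SHAPE_ORDER
    ]


def _session_seed(root_seed: int, animal_index: int) -> list[int]:
    return [int(root_seed), int(animal_index), 7]


def enroll_cohort(
    config: RunConfig,
) -> tuple[list[tuple[int, AnimalModel, float]], list[str]]:
    """Titrate candidate animals in index order until ``n_include`` qualify.

    Dyskinesia-prone (EXCLUDED) and titration-failure animals are skipped
    and recorded; candidate supply is capped at 30 x ``n_include``.
    """
    template = _titration_template(config.paradigm)
    included: list[tuple[int, AnimalModel, float]] = []
    dropped: list[str] = []
    for index in range(30 * config.n_include):
        if len(included) == config.n_include:
            break
        animal = sample_animal(config.cohort, index)
        try:
            i0 = titrate_I0(
                animal, config.cohort, template, grid_step_ua=config.grid_step_ua
            )
        except TitrationError:
            dropped.append(animal.id)
            continue
        if i0 is EXCLUDED:
            dropped.append(animal.id)
            continue
        included.append((index, animal, float(i0)))
    if len(included) < config.n_include:
        raise TitrationError(
            f"could not enroll {config.n_include} animals "
            f"(got {len(included)}, dropped {len(dropped)})"
        )
    return included, dropped


def _correlations(
    features: pd.DataFrame, paradigm: str
) -> pd.DataFrame:
    """Per-feature Pearson correlation of condition level vs cohort mean."""
    level_pairs = _condition_levels(paradigm)
    rows = []
    feature_cols = [
        ("max_rotation", "total_rotation"),
        ("auc_rot_s", "area_under_curve"),
        ("distance_cm", "total_distance"),
    ]
    if paradigm == "waveform":
        # one correlation per shape across the five charge multipliers
        for shape in WAVEFORM_SHAPE_ORDER:
            labels = [
                (lab, m) for lab, m in level_pairs if lab.endswith("_" + shape.display)
            ]
            for col, name in feature_cols:
                x, y = _level_mean_xy(features, labels, col)
                if np.any(np.isnan(y)):  # e.g. distance without position data
                    continue
                res = pearson(x, y)
                rows.append(
                    {
                        "test": shape.display,
                        "feature": name,
                        "rho": res.rho,
                        "n": res.n,
                        "t": res.t_stat,
                        "df": res.df,
                        "p": res.p_two_tailed,
                    }
                )
    else:
        for col, name in feature_cols:
            x, y = _level_mean_xy(features, level_pairs, col)
            if np.any(np.isnan(y)):
                continue
            res = pearson(x, y)
            rows.append(
                {
                    "test": paradigm,
                    "feature": name,
                    "rho": res.rho,
                    "n": res.n,
                    "t": res.t_stat,
                    "df": res.df,
                    "p": res.p_two_tailed,
                }
            )
    return pd.DataFrame(rows)


def _level_mean_xy(features, labels, value_col):
    sub = features[features["episode_label"].isin([lab for lab, _ in labels])]
    means = level_means(
        sub, level_col="episode_label", value_col=value_col, order=[lab for lab, _ in labels]
    )
    x = [lvl for _, lvl in labels]
    return x, means["mean"].to_numpy()


def _waveform_ttests(features: pd.DataFrame) -> pd.DataFrame:
    """Paired Rect-vs-alternative tests at matched and offset charge levels."""
    rows = []
    pivot = {}
    for label, grp in features.groupby("episode_label"):
        pivot[label] = grp.sort_values("animal")

    def per_animal(label, col):
        return pivot[label][col].to_numpy()

    comparisons = [(m, m) for m in (1.0, 1.5, 2.0)] + [(1.5, 2.0)]
    for rect_m, other_m in comparisons:
        for shape in WAVEFORM_SHAPE_ORDER[1:]:
            a_lab = f"{rect_m:g}xQ0_Rect"
            b_lab = f"{other_m:g}xQ0_{shape.display}"
            for col, name in (
                ("max_rotation", "total_rotation"),
                ("auc_rot_s", "area_under_curve"),
                ("distance_cm", "total_distance"),
            ):
                res = waveform_ttest(per_animal(a_lab, col), per_animal(b_lab, col))
                rows.append(
                    {
                        "comparison": f"Rect@{rect_m:g}xQ0 vs {shape.display}@{other_m:g}xQ0",
                        "feature": name,
                        "t": res.t_stat,
                        "df": res.df,
                        "p": res.p_two_tailed,
                    }
                )
    return pd.DataFrame(rows)


def run_paradigm(config: RunConfig, out_dir=None) -> RunBundle:
    """Execute one full paradigm: cohort, titration, sessions, features,
    correlations and the similarity matrix; optionally persist the bundle."""
    included, dropped = enroll_cohort(config)
    protocols: dict[str, SessionProtocol] = {}
    trajectories: dict[str, AngularTrajectory] = {}
    thresholds: dict[str, float] = {}
    feature_frames = []
    items = []
    for index, animal, i0 in included:
        protocol = _protocol_for(config.paradigm, i0)
        traj = simulate_session(
            animal,
            protocol,
            config.cohort,
            seed=_session_seed(config.cohort.seed, index),
            with_position=config.with_position,
        )
        traj.meta.update({"I0_ua": i0, "animal_index": index})
        protocols[animal.id] = protocol
        trajectories[animal.id] = traj
        thresholds[animal.id] = i0
        feature_frames.append(session_features(traj, protocol))
        items.append((traj, protocol))
    features = pd.concat(feature_frames, ignore_index=True)

    labels = [lab for lab, _ in _condition_levels(config.paradigm)]
    traces = [
        condition_trace(items, lab, grid_n=config.grid_n, units=config.units)
        for lab in labels
    ]
    similarity = ed_matrix(traces)
    correlations = _correlations(features, config.paradigm)
    ttests = _waveform_ttests(features) if config.paradigm == "waveform" else None

    bundle = RunBundle(
        config=config,
        animals=[animal for _, animal, _ in included],
        thresholds_ua=thresholds,
        excluded_ids=dropped,
        protocols=protocols,
        trajectories=trajectories,
        features=features,
        correlations=correlations,
        similarity=similarity,
        ttests=ttests,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: RunBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "trajectories").mkdir(exist_ok=True)
    (out_dir / "protocols").mkdir(exist_ok=True)
    for aid, traj in bundle.trajectories.items():
        write_trajectory(out_dir / "trajectories" / f"{aid}.csv", traj)
    for aid, protocol in bundle.protocols.items():
        save_protocol(out_dir / "protocols" / f"{aid}.yaml", protocol)
    bundle.features.to_csv(out_dir / "features.csv", index=False, float_format="%.9g")
    bundle.correlations.to_csv(
        out_dir / "correlations.csv", index=False, float_format="%.9g"
    )
    bundle.similarity.to_dataframe().to_csv(
        out_dir / "ed_matrix.csv", float_format="%.9g"
    )
    if bundle.ttests is not None:
        bundle.ttests.to_csv(out_dir / "ttests.csv", index=False, float_format="%.9g")
    cfg = bundle.config.to_dict()
    cfg["excluded_ids"] = bundle.excluded_ids
    cfg["thresholds_ua"] = bundle.thresholds_ua
    with open(out_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    manifest = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(out_dir))] = digest
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle.manifest = manifest
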