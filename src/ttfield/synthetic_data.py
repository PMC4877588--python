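"""Seeded generator of synthetic nuclei tables and image stacks.

The generator emulates the three biological preparations the device
hosts, with the statistical structure the analysis pipeline assumes:

* **Cancer aggregates** (40–100 μm diameter spheroids in collagen gel):
  nuclei start uniform in a sphere, then follow an hourly random walk
  with an outward radial drift (dispersion), divide with a per-hour
  probability (proliferation) and die with a per-hour probability
  (apoptosis; dead nuclei are retained in place, mirroring a
  cell-impermeant dead-nucleus dye).
* **Dispersed single cancer cells** seeded uniformly in a gel slab at
  300 cells/mm³ (3 × 10⁵ cells/ml), with the same birth–death dynamics;
  the readout is cell density per region of interest.
* **An endothelial monolayer** lining the media channel, a planar band
  of nuclei scored only for marker fractions.

Marker channels (Ki-67, caspase-3/7) are Bernoulli flags drawn per
nucleus at each output timepoint with per-condition, per-cell-type
probabilities.  ``default_calibration`` sets those probabilities and the
division rates so that the *expected* pipeline outputs equal the
reference study's printed means (proliferation 50.77 % stimulated vs
142.10 % control at 72 h, Ki-67 2.38 % vs 37.54 % for the cancer
aggregates, 72 h densities ≈ 1000 vs 2000 cells/mm³, ...).

The within-gel motility model (random walk + radial drift) is a
deliberately simple stand-in: it is the least-structured process that
produces a progressive, condition-dependent increase in dispersion.  It
is labelled as such in every ``truth`` record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .imaging import ImageStack

__all__ = [
    "ConditionParams",
    "GeneratorConfig",
    "SimulatedExperiment",
    "default_calibration",
    "dispersed_calibration",
    "division_rate_for_target",
    "simulate_aggregate_timecourse",
    "simulate_dispersed_culture",
    "simulate_monolayer",
    "simulate_experiment",
    "render_stack",
]

CONDITIONS = ("stimulated", "control", "dmso")
TABLE_COLUMNS = [
    "id", "t_h", "x_um", "y_um", "z_um", "condition", "cell_type",
    "ki67", "caspase", "dead",
]


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition kinetics of one preparation.

    step_sigma: isotropic random-walk step scale, μm per √h.
    drift: outward radial drift, μm/h.
    p_div: division probability per cell per hour.
    p_die: death probability per cell per hour.
    """

    step_sigma: float
    drift: float
    p_div: float
    p_die: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_div <= 1 and 0 <= self.p_die <= 1):
            raise ValueError("p_div and p_die must be probabilities in [0, 1]")
        if self.step_sigma < 0 or self.drift < 0:
            raise ValueError("step_sigma and drift must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of one simulated study.

    ``aggregate`` / ``dispersed`` map condition name → ConditionParams
    for the spheroid and single-cell preparations; ``marker_p`` maps
    marker → cell_type → condition → Bernoulli probability.
    """

    seed: int = 0
    n0: int = 80
    r0: float = 30.0  # μm; initial aggregate radius (40-100 μm diameter range)
    timepoints: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    aggregate: dict[str, ConditionParams] = field(default_factory=dict)
    dispersed: dict[str, ConditionParams] = field(default_factory=dict)
    marker_p: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    n_devices: int = 3
    n_rois: int = 3
    seeding_density: float = 300.0  # cells/mm³ for the dispersed culture
    gel_box_um: tuple[float, float, float] = (1300.0, 3000.0, 120.0)
    roi_size_um: tuple[float, float, float] = (350.0, 350.0, 120.0)
    monolayer_n: int = 400
    daughter_offset_um: float = 5.0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be at least 1")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not self.timepoints or self.timepoints[0] != 0.0:
            raise ValueError("timepoints must start at 0 h")
        for block in (self.aggregate, self.dispersed):
            for name, params in block.items():
                if not isinstance(params, ConditionParams):
                    raise TypeError(f"condition {name!r} must be ConditionParams")
        for marker, by_type in self.marker_p.items():
            for cell_type, by_cond in by_type.items():
                for cond, p in by_cond.items():
                    if not 0 <= p <= 1:
                        raise ValueError(
                            f"marker_p[{marker}][{cell_type}][{cond}] = {p} not in [0, 1]"
                        )


@dataclass
class SimulatedExperiment:
    """Tables per (device, condition) plus the generating ground truth."""

    tables: dict[tuple[int, str], pd.DataFrame]
    truth: dict

    def combined(self) -> pd.DataFrame:
        frames = []
        for (device, condition), table in sorted(self.tables.items()):
            t = table.copy()
            t["device"] = device
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def to_csv_dir(self, out_dir: str | Path) -> None:
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (device, condition), table in sorted(self.tables.items()):
            table.to_csv(out / f"device{device}_{condition}.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def division_rate_for_target(target_pct: float, hours: float) -> float:
    """Per-hour division probability giving an expected proliferation
    rate of ``target_pct`` % after ``hours`` h: (1+p)^t − 1 = target."""
    if hours <= 0:
        raise ValueError("hours must be positive")
    if target_pct <= -100:
        raise ValueError("target proliferation must exceed -100%")
    return (1.0 + target_pct / 100.0) ** (1.0 / hours) - 1.0


def default_calibration(seed: int = 0) -> GeneratorConfig:
    """Study-calibrated generator for the lung-carcinoma aggregate
    co-culture (200 kHz arm).

    Division rates are solved from the printed 72 h proliferation rates
    (50.77 % stimulated, 142.10 % control); marker probabilities are the
    printed positivity fractions / 100; the dispersion drift makes the
    control normalized dispersion exceed the stimulated one at 72 h, and
    the cytotoxic (DMSO) arm neither divides nor disperses.
    """
    p_div_stim = division_rate_for_target(50.77, 72.0)
    p_div_ctrl = division_rate_for_target(142.10, 72.0)
    aggregate = {
        "stimulated": ConditionParams(step_sigma=0.8, drift=0.12, p_div=p_div_stim, p_die=0.0),
        "control": ConditionParams(step_sigma=0.8, drift=0.35, p_div=p_div_ctrl, p_die=0.0),
        "dmso": ConditionParams(step_sigma=0.1, drift=0.0, p_div=0.0, p_die=0.05),
    }
    # dispersed-culture growth solved from the 72 h densities
    # (~1000 vs ~2000 cells/mm³ from a 300 cells/mm³ seed)
    g_stim = division_rate_for_target(100.0 * (1000.0 / 300.0 - 1.0), 72.0)
    g_ctrl = division_rate_for_target(100.0 * (2000.0 / 300.0 - 1.0), 72.0)
    dispersed = {
        "stimulated": ConditionParams(step_sigma=0.5, drift=0.0, p_div=g_stim, p_die=0.0),
        "control": ConditionParams(step_sigma=0.5, drift=0.0, p_div=g_ctrl, p_die=0.0),
        "dmso": ConditionParams(step_sigma=0.1, drift=0.0, p_div=0.0, p_die=0.05),
    }
    marker_p = {
        "ki67": {
            "cancer": {"stimulated": 0.0238, "control": 0.3754, "dmso": 0.0},
            "endothelial": {"stimulated": 0.0640, "control": 0.0765, "dmso": 0.0},
        },
        "caspase": {
            "cancer": {"stimulated": 0.4920, "control": 0.2388, "dmso": 0.95},
            "endothelial": {"stimulated": 0.1304, "control": 0.1147, "dmso": 0.95},
        },
    }
    return GeneratorConfig(
        seed=seed, aggregate=aggregate, dispersed=dispersed, marker_p=marker_p
    )


def dispersed_calibration(seed: int = 0) -> GeneratorConfig:
    """Calibration for the breast-carcinoma mono/co-culture (150 kHz arm):
    identical kinetics but the printed MDA-MB-231 Ki-67 fractions
    (27.37 % stimulated, 25.94 % control) and the 150 kHz endothelial
    Ki-67 fractions (6.69 % vs 6.63 %)."""
    cfg = default_calibration(seed)
    marker_p = {
        "ki67": {
            "cancer": {"stimulated": 0.2737, "control": 0.2594, "dmso": 0.0},
            "endothelial": {"stimulated": 0.0669, "control": 0.0663, "dmso": 0.0},
        },
        "caspase": cfg.marker_p["caspase"],
    }
    return replace(cfg, marker_p=marker_p)


# --------------------------------------------------------------------------
# core birth-death random-walk engine
# --------------------------------------------------------------------------

def _draw_markers(
    rng: np.random.Generator,
    n: int,
    alive: np.ndarray,
    cell_type: str,
    condition: str,
    marker_p: dict,
) -> dict[str, np.ndarray]:
    """Bernoulli marker flags; dead nuclei never stain for activity markers."""
    flags = {}
    for marker, by_type in marker_p.items():
        p = by_type.get(cell_type, {}).get(condition, 0.0)
        draw = rng.random(n) < p
        flags[marker] = (draw & alive).astype(int)
    return flags


def _snapshot(
    t: float,
    ids: np.ndarray,
    pos: np.ndarray,
    alive: np.ndarray,
    condition: str,
    cell_type: str,
    marker_p: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    flags = _draw_markers(rng, len(ids), alive, cell_type, condition, marker_p)
    table = pd.DataFrame(
        {
            "id": ids,
            "t_h": t,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "condition": condition,
            "cell_type": cell_type,
            "ki67": flags.get("ki67", np.zeros(len(ids), dtype=int)),
            "caspase": flags.get("caspase", np.zeros(len(ids), dtype=int)),
            "dead": (~alive).astype(int),
        }
    )
    return table[TABLE_COLUMNS]


def _evolve(
    pos: np.ndarray,
    alive: np.ndarray,
    next_id: int,
    ids: np.ndarray,
    params: ConditionParams,
    rng: np.random.Generator,
    *,
    radial_center: np.ndarray | None,
    daughter_offset: float,
    box: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Advance one hour: move, die, divide.  Dead nuclei stay in place."""
    n = len(pos)
    if alive.any():
        live_idx = np.flatnonzero(alive)
        step = rng.normal(0.0, params.step_sigma, size=(len(live_idx), 3))
        pos[live_idx] += step
        if params.drift > 0 and radial_center is not None:
            rel = pos[live_idx] - radial_center
            norm = np.linalg.norm(rel, axis=1, keepdims=True)
            unit = np.divide(rel, norm, out=np.zeros_like(rel), where=norm > 0)
            pos[live_idx] += params.drift * unit
        # deaths
        dies = rng.random(len(live_idx)) < params.p_die
        alive[live_idx[dies]] = False
        # divisions among the still-living
        live_idx = np.flatnonzero(alive)
        divides = rng.random(len(live_idx)) < params.p_div
        parents = live_idx[divides]
        if len(parents):
            direction = rng.normal(size=(len(parents), 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            daughters = pos[parents] + daughter_offset * direction
            pos = np.vstack([pos, daughters])
            alive = np.concatenate([alive, np.ones(len(parents), dtype=bool)])
            ids = np.concatenate([ids, np.arange(next_id, next_id + len(parents))])
            next_id += len(parents)
    if box is not None:
        # reflect at the slab faces; clipping would pile cells exactly on
        # the boundary, where half-open ROIs no longer count them
        b = np.asarray(box)
        pos = np.abs(pos)
        pos = np.mod(pos, 2 * b)
        pos = np.where(pos > b, 2 * b - pos, pos)
    return pos, alive, ids, next_id


def simulate_aggregate_timecourse(
    config: GeneratorConfig,
    condition: str,
    *,
    rng: np.random.Generator | None = None,
    cell_type: str = "cancer",
) -> tuple[pd.DataFrame, dict]:
    """Simulate one aggregate through the configured timepoints.

    Returns a long-format nuclei table (one block per output timepoint)
    and a truth record with the generating parameters and per-timepoint
    ground-truth counts.
    """
    if condition not in config.aggregate:
        raise ValueError(f"no aggregate parameters for condition {condition!r}")
    params = config.aggregate[condition]
    rng = np.random.default_rng(config.seed) if rng is None else rng

    # uniform points in a sphere of radius r0
    direction = rng.normal(size=(config.n0, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = config.r0 * rng.random(config.n0) ** (1.0 / 3.0)
    pos = direction * radius[:, None]
    alive = np.ones(config.n0, dtype=bool)
    ids = np.arange(config.n0)
    next_id = config.n0
    center = np.zeros(3)

    snapshots = []
    counts = {}
    t_now = 0.0
    for t_out in config.timepoints:
        hours = int(round(t_out - t_now))
        for _ in range(hours):
            pos, alive, ids, next_id = _evolve(
                pos, alive, next_id, ids, params, rng,
                radial_center=center,
                daughter_offset=config.daughter_offset_um,
            )
        t_now = t_out
        snapshots.append(
            _snapshot(t_out, ids, pos, alive, condition, cell_type, config.marker_p, rng)
        )
        counts[t_out] = len(ids)

    table = pd.concat(snapshots, ignore_index=True)
    truth = {
        "kind": "aggregate",
        "motility_model": "synthetic stand-in: isotropic random walk + radial drift",
        "condition": condition,
        "params": vars(params).copy() if hasattr(params, "__dict__") else {
            "step_sigma": params.step_sigma,
            "drift": params.drift,
            "p_div": params.p_div,
            "p_die": params.p_die,
        },
        "n0": config.n0,
        "r0_um": config.r0,
        "counts": counts,
        "expected_proliferation_pct": {
            t: 100.0 * ((1.0 + params.p_div) ** t - 1.0) for t in config.timepoints
        },
        "marker_p": {
            m: config.marker_p[m].get("cancer", {}).get(condition, 0.0)
            for m in config.marker_p
        },
    }
    return table, truth


def simulate_dispersed_culture(
    config: GeneratorConfig,
    condition: str,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate single cancer cells seeded uniformly in a gel slab.

    The initial count is Poisson with mean seeding_density × slab
    volume; cells then follow the condition's birth–death random walk.
    """
    if condition not in config.dispersed:
        raise ValueError(f"no dispersed-culture parameters for condition {condition!r}")
    params = config.dispersed[condition]
    rng = np.random.default_rng(config.seed) if rng is None else rng

    box = np.asarray(config.gel_box_um, dtype=float)
    volume_mm3 = box.prod() / 1e9
    n0 = int(rng.poisson(config.seeding_density * volume_mm3))
    n0 = max(n0, 1)
    pos = rng.random((n0, 3)) * box
    alive = np.ones(n0, dtype=bool)
    ids = np.arange(n0)
    next_id = n0

    snapshots = []
    counts = {}
    t_now = 0.0
    for t_out in config.timepoints:
        for _ in range(int(round(t_out - t_now))):
            pos, alive, ids, next_id = _evolve(
                pos, alive, next_id, ids, params, rng,
                radial_center=None,
                daughter_offset=config.daughter_offset_um,
                box=tuple(box),
            )
        t_now = t_out
        snapshots.append(
            _snapshot(t_out, ids, pos, alive, condition, "cancer", config.marker_p, rng)
        )
        counts[t_out] = len(ids)

    table = pd.concat(snapshots, ignore_index=True)
    truth = {
        "kind": "dispersed",
        "motility_model": "synthetic stand-in: isotropic random walk",
        "condition": condition,
        "seeding_density_per_mm3": config.seeding_density,
        "slab_volume_mm3": float(volume_mm3),
        "counts": counts,
        "expected_density_per_mm3": {
            t: config.seeding_density * (1.0 + params.p_div) ** t
            for t in config.timepoints
        },
        "marker_p": {
            m: config.marker_p[m].get("cancer", {}).get(condition, 0.0)
            for m in config.marker_p
        },
    }
    return table, truth


def simulate_monolayer(
    config: GeneratorConfig,
    condition: str,
    *,
    rng: np.random.Generator | None = None,
    t_h: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Endothelial monolayer at the gel–channel interface.

    A planar band of nuclei (10 μm thick) along the channel; only the
    marker fractions of this table are meaningful readouts.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t_h = config.timepoints[-1] if t_h is None else t_h
    n = config.monolayer_n
    length, height = config.gel_box_um[1], config.gel_box_um[2]
    pos = np.column_stack(
        [
            rng.random(n) * 10.0,  # thin band across x
            rng.random(n) * length,
            rng.random(n) * height,
        ]
    )
    alive = np.ones(n, dtype=bool)
    table = _snapshot(
        t_h, np.arange(n), pos, alive, condition, "endothelial", config.marker_p, rng
    )
    truth = {
        "kind": "monolayer",
        "condition": condition,
        "n": n,
        "marker_p": {
            m: config.marker_p[m].get("endothelial", {}).get(condition, 0.0)
            for m in config.marker_p
        },
    }
    return table, truth


def simulate_experiment(
    config: GeneratorConfig,
    *,
    experiment: str = "aggregate",
    conditions: tuple[str, ...] = ("stimulated", "control"),
) -> SimulatedExperiment:
    """Simulate the full study design: n_devices devices per condition,
    each with one cancer preparation and one endothelial monolayer.

    ``experiment`` selects the preparation: "aggregate" (spheroid
    timecourse) or "dispersed" (single cells in gel).  Each device gets
    an independent child RNG derived from the config seed, so the whole
    experiment is reproducible and device tables are independent.
    """
    if experiment not in ("aggregate", "dispersed"):
        raise ValueError(f"unknown experiment {experiment!r}")
    root = np.random.SeedSequence(config.seed)
    tables: dict[tuple[int, str], pd.DataFrame] = {}
    truth: dict = {
        "experiment": experiment,
        "seed": config.seed,
        "n_devices": config.n_devices,
        "n_rois": config.n_rois,
        "devices": {},
    }
    children = root.spawn(config.n_devices * len(conditions))
    k = 0
    for device in range(config.n_devices):
        for condition in conditions:
            rng = np.random.default_rng(children[k])
            k += 1
            if experiment == "aggregate":
                cancer_table, cancer_truth = simulate_aggregate_timecourse(
                    config, condition, rng=rng
                )
            else:
                cancer_table, cancer_truth = simulate_dispersed_culture(
                    config, condition, rng=rng
                )
            endo_table, endo_truth = simulate_monolayer(config, condition, rng=rng)
            # monolayer ids must not collide with cancer ids at shared timepoints
            endo_table = endo_table.assign(id=endo_table["id"] + 1_000_000)
            tables[(device, condition)] = pd.concat(
                [cancer_table, endo_table], ignore_index=True
            )
            truth["devices"][f"{device}/{condition}"] = {
                "cancer": cancer_truth,
                "endothelial": endo_truth,
            }
    return SimulatedExperiment(tables=tables, truth=truth)


# --------------------------------------------------------------------------
# stack rendering (fixture generator for the imaging front-end)
# --------------------------------------------------------------------------

def render_stack(
    table: pd.DataFrame,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    nucleus_radius: float = 4.0,
    noise_sd: float = 2.0,
    *,
    amplitude: float = 100.0,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Render a nuclei table into a synthetic multi-channel image stack.

    Each nucleus becomes a Gaussian blob (σ = nucleus_radius/2) in the
    ``nuclei`` channel; marker channels are painted only at marker-true
    nuclei.  Additive Gaussian noise is applied to every channel.
    Nuclei outside the stack are clipped with a warning.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    nz, ny, nx = shape
    dx, dy, dz = voxel_size
    markers = [c for c in ("ki67", "caspase", "dead") if c in table.columns]
    channels = {name: np.zeros(shape) for name in ["nuclei", *markers]}

    extent = np.array([nx * dx, ny * dy, nz * dz])
    sigma = nucleus_radius / 2.0
    zc = (np.arange(nz) + 0.5) * dz
    yc = (np.arange(ny) + 0.5) * dy
    xc = (np.arange(nx) + 0.5) * dx

    n_clipped = 0
    for row in table.itertuples(index=False):
        p = np.array([row.x_um, row.y_um, row.z_um])
        if (p < 0).any() or (p > extent).any():
            n_clipped += 1
            continue
        gz = np.exp(-0.5 * ((zc - p[2]) / sigma) ** 2)
        gy = np.exp(-0.5 * ((yc - p[1]) / sigma) ** 2)
        gx = np.exp(-0.5 * ((xc - p[0]) / sigma) ** 2)
        blob = amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        channels["nuclei"] += blob
        for m in markers:
            if getattr(row, m):
                channels[m] += blob
    if n_clipped:
        warnings.warn(f"{n_clipped} nuclei outside the stack bounds were clipped")
    if noise_sd > 0:
        for name in channels:
            channels[name] = channels[name] + rng.normal(0.0, noise_sd, size=shape)
    return ImageStack(channels=channels, voxel_size=voxel_size)
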