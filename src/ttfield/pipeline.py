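"""End-to-end orchestration of a simulated stimulation study.

A run mirrors the study design: design the electrical stimulation for
the requested frequency and target field (equivalent-circuit model),
simulate the biological preparations per device and condition, quantify
the image-derived statistics, compare stimulated vs control arms
(pooled-variance t for imaging endpoints, Welch for ELISA-like cytokine
endpoints), and write a reproducible report bundle with a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import device_model as dm
from . import quantify as q
from . import synthetic_data as sd
from .config import parse_device_config

__all__ = [
    "design_stimulation",
    "quantify_aggregate_experiment",
    "quantify_dispersed_experiment",
    "compare_conditions",
    "run",
]

log = logging.getLogger("ttfield.pipeline")


# --------------------------------------------------------------------------
# stage 1: stimulation design
# --------------------------------------------------------------------------

def design_stimulation(raw_config: dict) -> dict:
    """Solve the equivalent circuit for the configured operating point."""
    geometry, materials, stim = parse_device_config(raw_config)
    network = dm.build_network(geometry, materials)
    f = stim.frequency_hz
    ratio = dm.transfer_ratio(network, f)
    if stim.v_in_volts is not None:
        v_in = stim.v_in_volts * stim.amplitude_scale
        field = dm.gel_field(v_in, network, f, geometry.gel_width)
    else:
        field = stim.target_field_v_per_cm * stim.amplitude_scale
        v_in = dm.required_input_voltage(field, network, f, geometry.gel_width)
    return {
        "frequency_hz": f,
        "elements": [
            {"label": e.label, "kind": e.kind, "R_ohm": e.R, "C_farad": e.C,
             "is_gel": e.is_gel}
            for e in network.elements
        ],
        "transfer_ratio_abs": abs(ratio),
        "transfer_ratio_phase_rad": float(np.angle(ratio)),
        "resistive_divider_limit": dm.resistive_divider_limit(network),
        "gel_field_v_per_cm": field,
        "required_v_in_volts": v_in,
        "gel_width_m": geometry.gel_width,
    }


# --------------------------------------------------------------------------
# stage 2: quantification
# --------------------------------------------------------------------------

def _random_rois(
    config: sd.GeneratorConfig, rng: np.random.Generator
) -> list[q.ROI]:
    """n_rois random axis-aligned boxes inside the gel slab."""
    box = np.asarray(config.gel_box_um, dtype=float)
    size = np.asarray(config.roi_size_um, dtype=float)
    if (size > box).any():
        raise ValueError("ROI size exceeds the gel slab")
    rois = []
    for _ in range(config.n_rois):
        origin = rng.random(3) * (box - size)
        rois.append(
            q.ROI(
                x_min=origin[0], x_max=origin[0] + size[0],
                y_min=origin[1], y_max=origin[1] + size[1],
                z_min=origin[2], z_max=origin[2] + size[2],
            )
        )
    return rois


def quantify_aggregate_experiment(
    exp: sd.SimulatedExperiment,
    *,
    markers: tuple[str, ...] = ("ki67", "caspase"),
    min_nuclei: int = 3,
) -> pd.DataFrame:
    """Per-device, per-condition readouts of the aggregate study.

    Returns a tidy frame with one row per device × condition ×
    timepoint: nucleus count, proliferation %, dispersion Δ, normalized
    Δ/Δ₀, and final-timepoint marker positivity per cell type.
    Aggregates with fewer than ``min_nuclei`` nuclei at any timepoint
    are excluded from dispersion summaries (logged).
    """
    rows = []
    for (device, condition), table in sorted(exp.tables.items()):
        cancer = table[table["cell_type"] == "cancer"]
        endo = table[table["cell_type"] == "endothelial"]
        n0 = int((cancer["t_h"] == cancer["t_h"].min()).sum())
        counts_ok = (cancer.groupby("t_h").size() >= min_nuclei).all()
        disp = None
        if counts_ok:
            disp = {r.t_h: r for r in q.normalized_dispersion(cancer)}
        else:
            log.warning(
                "device %s/%s: aggregate below %d nuclei, dispersion skipped",
                device, condition, min_nuclei,
            )
        t_final = cancer["t_h"].max()
        for t in sorted(cancer["t_h"].unique()):
            sub = cancer[cancer["t_h"] == t]
            row = {
                "device": device,
                "condition": condition,
                "t_h": float(t),
                "n_nuclei": len(sub),
                "proliferation_pct": q.proliferation_rate(len(sub), n0),
                "delta_um": disp[t].delta if disp else np.nan,
                "normalized_dispersion": disp[t].normalized if disp else np.nan,
            }
            for marker in markers:
                row[f"{marker}_cancer_pct"] = (
                    q.positivity_fraction(sub, marker) if t == t_final else np.nan
                )
                row[f"{marker}_endothelial_pct"] = (
                    q.positivity_fraction(endo, marker)
                    if (t == t_final and len(endo)) else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def quantify_dispersed_experiment(
    exp: sd.SimulatedExperiment,
    config: sd.GeneratorConfig,
    *,
    markers: tuple[str, ...] = ("ki67", "caspase"),
    roi_seed: int = 0,
) -> pd.DataFrame:
    """Per-device, per-ROI, per-timepoint density (and final-timepoint
    positivity) for the dispersed-culture study."""
    rng = np.random.default_rng(roi_seed)
    rois = _random_rois(config, rng)
    rows = []
    for (device, condition), table in sorted(exp.tables.items()):
        cancer = table[table["cell_type"] == "cancer"]
        endo = table[table["cell_type"] == "endothelial"]
        t_final = cancer["t_h"].max()
        for t in sorted(cancer["t_h"].unique()):
            sub = cancer[cancer["t_h"] == t]
            for i, roi in enumerate(rois):
                inside = sub[roi.contains(sub)]
                row = {
                    "device": device,
                    "condition": condition,
                    "roi": i,
                    "t_h": float(t),
                    "count": len(inside),
                    "density_per_mm3": q.cell_density(len(inside), roi),
                }
                for marker in markers:
                    row[f"{marker}_cancer_pct"] = (
                        q.positivity_fraction(sub, marker) if t == t_final else np.nan
                    )
                    row[f"{marker}_endothelial_pct"] = (
                        q.positivity_fraction(endo, marker)
                        if (t == t_final and len(endo)) else np.nan
                    )
                rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stage 3: group comparisons
# --------------------------------------------------------------------------

def compare_conditions(
    summary: pd.DataFrame,
    endpoints: list[str],
    *,
    a: str = "stimulated",
    b: str = "control",
    t_h: float | None = None,
    welch: bool = False,
    pool_rois: bool = False,
) -> dict[str, q.GroupComparison]:
    """Device-level t-tests between two arms for each endpoint column.

    The unit of replication is the device: per-device values are
    averaged over ROIs first unless ``pool_rois`` is set, in which case
    every ROI enters the test as an observation.
    """
    sub = summary
    if t_h is not None:
        sub = sub[sub["t_h"] == t_h]
    out = {}
    group_cols = ["device"] if not pool_rois else ["device", "roi"]
    for endpoint in endpoints:
        values = {}
        for name in (a, b):
            arm = sub[sub["condition"] == name]
            per_unit = arm.groupby(group_cols)[endpoint].mean().dropna()
            values[name] = per_unit.to_list()
        out[endpoint] = q.compare_groups(values[a], values[b], welch=welch)
    return out


# --------------------------------------------------------------------------
# optional figures
# --------------------------------------------------------------------------

def plot_dispersion_timecourse(summary: pd.DataFrame, path: str | Path) -> None:
    """Mean ± SEM normalized dispersion per condition over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for condition, sub in summary.groupby("condition"):
        per_t = sub.groupby("t_h")["normalized_dispersion"]
        mean = per_t.mean()
        sem = per_t.sem()
        ax.errorbar(mean.index, mean, yerr=sem, marker="o", capsize=3,
                    label=condition)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized dispersion Δ/Δ₀")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# stage 4: full run
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(raw_config: dict, seed: int, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write a report bundle.

    Returns the manifest.  Stages: circuit design, simulation of the
    aggregate and dispersed studies, quantification, stimulated-vs-
    control comparisons, ELISA-like Welch comparison, manifest with
    per-file SHA-256 hashes.  Deterministic given (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "design"
    try:
        circuit = design_stimulation(raw_config)
        with open(out / "circuit.json", "w") as fh:
            json.dump(circuit, fh, indent=2)

        stage = "generate"
        gen_raw = raw_config.get("generator", {})
        config = sd.default_calibration(seed)
        if "n_devices" in gen_raw or "n_rois" in gen_raw or "n0" in gen_raw:
            from dataclasses import replace

            config = replace(
                config,
                n_devices=int(gen_raw.get("n_devices", config.n_devices)),
                n_rois=int(gen_raw.get("n_rois", config.n_rois)),
                n0=int(gen_raw.get("n0", config.n0)),
            )
        conditions = tuple(gen_raw.get("conditions", ("stimulated", "control")))
        agg_exp = sd.simulate_experiment(config, experiment="aggregate", conditions=conditions)
        disp_cfg = sd.dispersed_calibration(seed + 1)
        from dataclasses import replace as _replace

        disp_cfg = _replace(
            disp_cfg, n_devices=config.n_devices, n_rois=config.n_rois
        )
        disp_exp = sd.simulate_experiment(disp_cfg, experiment="dispersed", conditions=conditions)

        stage = "quantify"
        agg_summary = quantify_aggregate_experiment(agg_exp)
        disp_summary = quantify_dispersed_experiment(disp_exp, disp_cfg, roi_seed=seed + 2)
        agg_summary.to_csv(out / "aggregate_summary.csv", index=False)
        disp_summary.to_csv(out / "dispersed_summary.csv", index=False)

        stage = "compare"
        t_final = float(max(config.timepoints))
        comparisons = {}
        comparisons["aggregate"] = compare_conditions(
            agg_summary,
            [
                "proliferation_pct",
                "normalized_dispersion",
                "ki67_cancer_pct",
                "ki67_endothelial_pct",
                "caspase_endothelial_pct",
            ],
            t_h=t_final,
        )
        comparisons["dispersed"] = compare_conditions(
            disp_summary,
            ["density_per_mm3", "ki67_cancer_pct", "caspase_cancer_pct"],
            t_h=t_final,
        )
        # ELISA-like cytokine endpoint: two-group Gaussian samples, Welch test
        elisa_raw = raw_config.get("elisa", {})
        rng = np.random.default_rng(seed + 3)
        n_dev = config.n_devices
        elisa = {}
        for cytokine in elisa_raw.get("cytokines", ["il6", "il8"]):
            mu = elisa_raw.get("mean_pg_ml", 50.0)
            sigma = elisa_raw.get("sd_pg_ml", 10.0)
            stim_sample = rng.normal(mu, sigma, n_dev)
            ctrl_sample = rng.normal(mu, sigma, n_dev)
            elisa[cytokine] = q.compare_groups(stim_sample, ctrl_sample, welch=True)
        comparisons["elisa"] = elisa

        if raw_config.get("plots", False):
            stage = "plots"
            plot_dispersion_timecourse(agg_summary, out / "dispersion_timecourse.png")

        comp_json = {
            block: {name: asdict(c) for name, c in tests.items()}
            for block, tests in comparisons.items()
        }
        with open(out / "comparisons.json", "w") as fh:
            json.dump(comp_json, fh, indent=2)

        stage = "manifest"
        files = sorted(
            p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "seed": seed,
            "config": raw_config,
            "stages": ["design", "generate", "quantify", "compare"],
            "files": {p.name: _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise
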