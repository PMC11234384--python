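"""End-to-end analysis tracks: colocalization, PLA and calcium.

Each pipeline simulates (or loads) its inputs, runs the corresponding
analysis modules, and writes deterministic CSV/JSON reports.  Every report
embeds the config hash, the global seed and the package version; excluded
cells or fields are logged with a reason.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calcium import quantify_trace_frame
from .config import (
    STREAM_CA,
    STREAM_PLA,
    STREAM_PUNCTA,
    STREAM_RAND,
    STREAM_RENDER,
    STREAM_SCENE,
    config_hash,
    stage_seed,
)
from .core import Image, Mask, PunctaField
from .object_coloc import (
    nearest_neighbour_distances,
    nnd_histogram,
    nnd_to_frame,
    subset_by_mask,
)
from .pla import PLAParams, analyze_field, compare_conditions, fields_to_frame
from .randomization import chance_corrected_fraction, randomization_test
from .segmentation import PunctaParams, detect_puncta, make_organelle_mask
from .simulate import (
    CalciumTraceSpec,
    NoiseModel,
    SceneSpec,
    make_calcium_trace_pair,
    make_cell_and_mito_masks,
    make_pla_scene,
    place_puncta,
    render_channel,
)
from .stats import compare_groups

log = logging.getLogger("mcsquant")


def _scene_spec(cfg: dict, seed: int) -> SceneSpec:
    s = cfg["scene"]
    return SceneSpec(
        width_px=s["width_px"],
        height_px=s["height_px"],
        pixel_size_nm=s["pixel_size_nm"],
        psf_sigma_nm=s["psf_sigma_nm"],
        noise_model=NoiseModel(
            gaussian_sd=s["gaussian_sd"], poisson_scaling=s["poisson_scaling"]
        ),
        seed=seed,
    )


def _report_header(cfg: dict) -> dict:
    return {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "version": __version__,
    }


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=float))


def simulate_coloc_cell(cfg: dict, cell_index: int):
    """One simulated cell: masks, ground-truth puncta and rendered channels."""
    c = cfg["coloc"]
    spec = _scene_spec(cfg, stage_seed(cfg, STREAM_SCENE, cell_index))
    cell, mito = make_cell_and_mito_masks(
        spec, mito_area_fraction=cfg["scene"]["mito_area_fraction"]
    )
    truth = place_puncta(
        cell,
        mito,
        n_ref=c["n_ref"],
        n_partner=c["n_partner"],
        f_coloc=c["f_coloc"],
        f_mito=c["f_mito"],
        offset_sigma_nm=c["offset_sigma_nm"],
        min_spacing_nm=c["min_spacing_nm"],
        seed=stage_seed(cfg, STREAM_PUNCTA, cell_index),
    )
    rseed = stage_seed(cfg, STREAM_RENDER, cell_index)
    ref_img = render_channel(
        truth.ref_points, spec, amplitudes=c["amplitude"], seed=rseed, channel="IP3R"
    )
    partner_img = render_channel(
        truth.partner_points, spec, amplitudes=c["amplitude"], seed=rseed + 1, channel="KRAP"
    )
    mito_img = render_channel(
        np.column_stack(np.nonzero(mito.data))[:, ::-1] * spec.pixel_size_nm,
        spec,
        amplitudes=50.0,
        seed=rseed + 2,
        channel="mito",
    )
    return spec, cell, mito, truth, ref_img, partner_img, mito_img


def run_coloc_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Fig.4-style track: per-cell mito-associated vs non-associated
    colocalization fractions with a shuffle null."""
    c = cfg["coloc"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_cell = []
    per_punctum = []
    hist_frames = []
    for i in range(c["n_cells"]):
        spec, cell, mito, truth, ref_img, partner_img, mito_img = simulate_coloc_cell(cfg, i)
        if c["detect_from_images"]:
            bg = Mask(~cell.data, pixel_size_nm=spec.pixel_size_nm)
            params = PunctaParams(sigma_nm=spec.psf_sigma_nm)
            ref = detect_puncta(ref_img.with_data(ref_img.data, background_corrected=True), params)
            partner = detect_puncta(
                partner_img.with_data(partner_img.data, background_corrected=True), params
            )
            mito_mask = make_organelle_mask(
                mito_img.with_data(mito_img.data, background_corrected=True),
                cell_mask=cell,
            )
        else:
            ref = PunctaField(truth.ref_points, pixel_size_nm=spec.pixel_size_nm)
            partner = PunctaField(truth.partner_points, pixel_size_nm=spec.pixel_size_nm)
            mito_mask = mito
        if len(ref) == 0 or len(partner) == 0:
            log.info("cell %d excluded: no puncta detected", i)
            continue
        if c["direction"] == "partner_to_ref":
            ref, partner = partner, ref
        inside, outside = subset_by_mask(ref, mito_mask, dilation_px=c["dilation_px"])
        rows = {"cell": i, "n_ref": len(ref), "n_partner": len(partner)}
        rows["fraction_mito_associated"] = len(inside) / len(ref)
        rand_seed = stage_seed(cfg, STREAM_RAND, i)
        for label, sub in (("mito", inside), ("nonmito", outside)):
            if len(sub) == 0:
                log.info("cell %d: no %s-associated puncta", i, label)
                rows[f"fraction_coloc_{label}"] = np.nan
                continue
            nnd = nearest_neighbour_distances(sub, partner, c["threshold_nm"])
            rt = randomization_test(
                sub,
                partner,
                cell,
                threshold_nm=c["threshold_nm"],
                n_iter=c["n_iter"],
                seed=rand_seed + (0 if label == "mito" else 1),
                observed=nnd,
            )
            rows[f"fraction_coloc_{label}"] = rt.observed_fraction
            rows[f"null_mean_{label}"] = rt.null_mean
            rows[f"ci_low_{label}"] = rt.ci_low
            rows[f"ci_high_{label}"] = rt.ci_high
            rows[f"significant_{label}"] = bool(rt.significant)
            rows[f"chance_corrected_{label}"] = chance_corrected_fraction(
                rt.observed_fraction, rt.null_mean
            )
            if label == "mito":
                h = nnd_histogram(nnd, bin_width_nm=50.0)
                h.insert(0, "cell", i)
                hist_frames.append(h)
                df = nnd_to_frame(nnd)
                df.insert(0, "cell", i)
                per_punctum.append(df)
        per_cell.append(rows)
    cells = pd.DataFrame(per_cell)
    cells.to_csv(out / "coloc_cells.csv", index=False)
    if per_punctum:
        pd.concat(per_punctum).to_csv(out / "coloc_puncta.csv", index=False)
    if hist_frames:
        pd.concat(hist_frames).to_csv(out / "coloc_nnd_histogram.csv", index=False)
    report = _report_header(cfg) | {
        "direction": c["direction"],
        "threshold_nm": c["threshold_nm"],
        "n_cells": int(len(cells)),
        "mean_fraction_coloc_mito": float(cells["fraction_coloc_mito"].mean()),
        "mean_null_mito": float(cells["null_mean_mito"].mean()),
        "n_significant_mito": int(cells["significant_mito"].sum()),
    }
    _write_json(out / "coloc_report.json", report)
    if cfg["make_plots"] and hist_frames:
        _plot_nnd_histogram(pd.concat(hist_frames), out / "coloc_nnd_histogram.png")
    return report


def _plot_nnd_histogram(hist: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = hist.groupby("bin_left_nm")["count"].sum()
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(agg.index, agg.values, width=45, align="edge", color="0.4")
    ax.axvline(233, color="red", lw=1)
    ax.set_xlabel("centre-to-centre distance (nm)")
    ax.set_ylabel("puncta")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pla_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Fig.5-style track: spots per cell per field, compared across conditions."""
    p = cfg["pla"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = PLAParams(
        threshold_k=p["threshold_k"],
        min_area_px=p["min_area_px"],
        max_area_px=p["max_area_px"],
    )
    fields = []
    k = 0
    for cond in p["conditions"]:
        for j in range(cond["n_fields"]):
            seed = stage_seed(cfg, STREAM_PLA, k)
            k += 1
            spec = _scene_spec(cfg, seed)
            spots, dapi, truth = make_pla_scene(
                n_cells=cond["n_cells"],
                spots_per_cell_mean=cond["spots_per_cell_mean"],
                spec=spec,
                seed=seed,
            )
            try:
                fr = analyze_field(
                    spots,
                    dapi,
                    params,
                    field_id=f"{cond['name']}_{j}",
                    condition=cond["name"],
                )
            except ValueError as e:
                log.info("field %s excluded: %s", f"{cond['name']}_{j}", e)
                continue
            fields.append(fr)
    df = fields_to_frame(fields)
    df.to_csv(out / "pla_fields.csv", index=False)
    stats = compare_conditions(fields, design=p["design"])
    stats.summaries.to_csv(out / "pla_summary.csv", index=False)
    stats.pairwise.to_csv(out / "pla_comparisons.csv", index=False)
    report = _report_header(cfg) | {
        "design": p["design"],
        "omnibus_p": stats.omnibus_p,
        "n_fields": len(fields),
        "group_means": {
            r["group"]: r["mean"] for _, r in stats.summaries.iterrows()
        },
    }
    _write_json(out / "pla_report.json", report)
    return report


def run_calcium_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Figs 1-3-style track: per-cell peak dF/F_max by channel and condition."""
    ca = cfg["calcium"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    k = 0
    for cond in ca["conditions"]:
        for j in range(cond["n_cells"]):
            seed = stage_seed(cfg, STREAM_CA, k)
            k += 1
            common = dict(
                n_frames=ca["n_frames"],
                baseline_frac=ca["baseline_frac"],
                stim_frame=ca["stim_frame"],
                fmax_frame=ca["fmax_frame"],
                noise_sd_frac=ca["noise_sd_frac"],
            )
            cyto = CalciumTraceSpec(peak_frac=cond["cyto_peak_frac"], seed=seed, **common)
            mito = CalciumTraceSpec(peak_frac=cond["mito_peak_frac"], seed=seed + 1, **common)
            tc, tm = make_calcium_trace_pair(cyto, mito)
            pair = pd.DataFrame(
                {
                    "frame": tc["frame"],
                    "time_s": tc["time_s"],
                    "F_cyto": tc["F"],
                    "F_mito": tm["F"],
                }
            )
            q = quantify_trace_frame(
                pair, ca["stim_frame"], ca["fmax_frame"], cell_id=f"{cond['name']}_{j}"
            )
            q.insert(0, "condition", cond["name"])
            q["true_delta"] = np.where(
                q["channel"] == "cytosolic", cyto.true_delta, mito.true_delta
            )
            rows.append(q)
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(out / "calcium_cells.csv", index=False)
    report = _report_header(cfg) | {"channels": {}}
    for channel in ("cytosolic", "mitochondrial"):
        sub = df[df["channel"] == channel]
        groups = {
            c: sub.loc[sub["condition"] == c, "delta_f_over_fmax"].to_numpy()
            for c in sub["condition"].unique()
        }
        design = ca["design"] if len(groups) == 2 else "oneway_tukey"
        stats = compare_groups(groups, design=design)
        stats.summaries.to_csv(out / f"calcium_summary_{channel}.csv", index=False)
        report["channels"][channel] = {
            "omnibus_p": stats.omnibus_p,
            "group_means": {r["group"]: r["mean"] for _, r in stats.summaries.iterrows()},
        }
    _write_json(out / "calcium_report.json", report)
    return report


def run_all(cfg: dict, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    return {
        "coloc": run_coloc_pipeline(cfg, out / "coloc"),
        "pla": run_pla_pipeline(cfg, out / "pla"),
        "calcium": run_calcium_pipeline(cfg, out / "calcium"),
    }
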