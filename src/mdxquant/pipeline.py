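"""Study orchestration: run all stages per sample, summarise per group.

A study configuration lists samples (either phantom presets to simulate or
image files to load) plus per-stage parameter blocks. The pipeline runs the
stages in dependency order, records per-sample failures without aborting
the study, and emits tidy per-sample metric tables, mean ± SD group
summaries and a reproducibility manifest. Inferential statistics are
deliberately left to external tools; the exported tables are their input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mdxquant import __version__, centronucleation, markers, morphometry, qpcr, segmentation, stainsep, synthdata
from mdxquant.io_core import ChannelImage, config_hash, read_image

__all__ = ["run_pipeline", "analyze_sample", "summarize_groups"]

METRIC_COLUMNS = [
    "sample_id",
    "group",
    "n_fibers",
    "n_fibers_retained",
    "cnf_percent",
    "min_feret_mean_um",
    "min_feret_sd_um",
    "collagen_percent",
    "necrotic_percent",
    "igm_positive_fraction",
    "emyhc_per_mm2",
    "error",
]


def _load_sample_images(sample: dict) -> tuple[dict[str, ChannelImage], dict[str, np.ndarray]]:
    if "preset" in sample:
        spec = synthdata.preset(sample["preset"], **sample.get("overrides", {}))
        if "seed" in sample:
            from dataclasses import replace

            spec = replace(spec, seed=int(sample["seed"]))
        channels, brightfield, _ = synthdata.generate_phantom(spec)
        return channels, brightfield
    images = sample.get("images", {})
    ps = sample.get("pixel_size_um")
    channels = {}
    for name, path in images.get("channels", {}).items():
        channels[name] = read_image(path, channel_spec=name, pixel_size_um=ps)
    brightfield = {}
    for key in ("sirius_fastgreen", "he"):
        if key in images:
            rgb, _ = read_image(images[key], pixel_size_um=ps)
            brightfield[key] = rgb
    return channels, brightfield


def analyze_sample(
    channels: dict[str, ChannelImage],
    brightfield: dict[str, np.ndarray],
    stages: dict,
) -> dict:
    """Run segmentation → morphometry → CNF → fibrosis → necrosis → markers
    on one sample's images; return a flat metric dict."""
    seg_cfg = stages.get("segmentation", {})
    params = segmentation.SegmentationParams(**seg_cfg)
    out: dict = {}

    laminin = channels["laminin"]
    tissue = segmentation.tissue_mask(laminin)
    fibers = segmentation.segment_fibers(laminin, params, tissue)
    metrics = morphometry.compute_morphometry(fibers)
    thr = stages.get("morphometry", {}).get(
        "circularity_threshold", morphometry.CIRCULARITY_THRESHOLD
    )
    metrics = morphometry.apply_circularity_filter(metrics, thr)
    retained = set(metrics.loc[~metrics["excluded"], "fiber_id"].astype(int))
    out["n_fibers"] = int(len(metrics))
    out["n_fibers_retained"] = len(retained)
    size = morphometry.fiber_size_summary(metrics)
    out["min_feret_mean_um"] = size["mean_um"]
    out["min_feret_sd_um"] = size["sd_um"]

    if "DAPI" in channels:
        cnf_cfg = stages.get("cnf", {})
        rule = centronucleation.CNFRule(
            mode=cnf_cfg.get("mode", "relative"),
            alpha=cnf_cfg.get("alpha", 0.3),
            absolute_um=cnf_cfg.get("absolute_um", 5.0),
        )
        _, nuc_table = segmentation.segment_nuclei(channels["DAPI"], params)
        records = centronucleation.assign_nuclei(nuc_table, fibers)
        centronucleation.compute_border_distances(records, fibers)
        summary = centronucleation.classify_cnf(records, fibers, retained, rule)
        out["cnf_percent"] = summary.cnf_percent

    if "sirius_fastgreen" in brightfield:
        rgb = brightfield["sirius_fastgreen"]
        bf_tissue = segmentation.tissue_mask(rgb=rgb, pixel_size_um=laminin.pixel_size_um)
        fib = stainsep.collagen_fraction(
            rgb, bf_tissue, laminin.pixel_size_um, **stages.get("fibrosis", {})
        )
        out["collagen_percent"] = fib.collagen_percent

    if "he" in brightfield:
        rgb = brightfield["he"]
        bf_tissue = segmentation.tissue_mask(rgb=rgb, pixel_size_um=laminin.pixel_size_um)
        _, necrotic = stainsep.infiltrate_mask(
            rgb, bf_tissue, laminin.pixel_size_um, **stages.get("necrosis", {})
        )
        out["necrotic_percent"] = necrotic

    if "IgM" in channels:
        score = markers.positive_fiber_fraction(channels["IgM"], fibers, retained)
        out["igm_positive_fraction"] = score.value
    if "eMyHC" in channels:
        score = markers.positive_fiber_density(channels["eMyHC"], fibers, tissue, retained)
        out["emyhc_per_mm2"] = score.value
    return out


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute a full study from a configuration mapping.

    Returns ``{"metrics": per-sample DataFrame, "summary": group summary,
    "qpcr": qPCR outputs or None, "manifest": provenance dict}`` and, when
    ``out_dir`` is given, writes them as CSV/JSON. A stage failure is
    recorded in the sample's ``error`` column; the study continues.
    """
    if "samples" not in config and "qpcr" not in config:
        raise ValueError("config must define 'samples' and/or 'qpcr'")
    stages = config.get("stages", {})
    seed = int(config.get("seed", 0))

    rows = []
    for i, sample in enumerate(config.get("samples", [])):
        row = {c: np.nan for c in METRIC_COLUMNS}
        row["sample_id"] = sample.get("id", f"sample_{i + 1}")
        row["group"] = sample.get("group", "")
        row["error"] = ""
        try:
            sample = dict(sample)
            sample.setdefault("seed", (seed + 7919 * i) % 2**31)
            channels, brightfield = _load_sample_images(sample)
            row.update(analyze_sample(channels, brightfield, stages))
        except Exception as exc:  # record, do not abort the study
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)

    summary = summarize_groups(metrics) if not metrics.empty else pd.DataFrame()

    qpcr_out = None
    if "qpcr" in config:
        qcfg = config["qpcr"]
        plate = pd.read_csv(qcfg["plate_csv"])
        qtable = qpcr.quantity_table(qpcr.validate_plate(plate))
        norm, fold = qpcr.normalization_and_fold_change(
            qtable, list(qcfg.get("references", [])), qcfg["control_group"]
        )
        qpcr_out = {"quantities": qtable, "normalized": norm, "fold_changes": fold}

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "n_samples": len(rows),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        summary.to_csv(out_dir / "group_summary.csv", index=False)
        if qpcr_out is not None:
            for name, df in qpcr_out.items():
                df.to_csv(out_dir / f"qpcr_{name}.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"metrics": metrics, "summary": summary, "qpcr": qpcr_out, "manifest": manifest}


def summarize_groups(
    metrics: pd.DataFrame, keys: tuple[str, ...] = ("group",)
) -> pd.DataFrame:
    """Long-format mean, SD and n per (group, metric).

    SD is missing (NaN) when a group has a single sample. Raises on an
    empty table — an explicit empty signal rather than a headerless file.
    """
    if metrics.empty:
        raise ValueError("empty metric table; nothing to summarise")
    numeric = metrics.select_dtypes(include=[np.number]).columns
    long = metrics.melt(
        id_vars=list(keys), value_vars=list(numeric), var_name="metric"
    ).dropna(subset=["value"])
    g = long.groupby(list(keys) + ["metric"])["value"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan, n="count")
    return out.reset_index()
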