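"""Reproducible pipeline runs: config validation, seeding, provenance.

A run is described by a YAML/dict config with a global ``seed`` and an
ordered list of stages.  Every stage's parameters are validated against
its signature before anything executes (unknown keys and out-of-range
values fail fast), per-stage seeds are expanded deterministically from the
global seed via ``numpy.random.SeedSequence(seed).spawn``, and the
resolved config plus provenance are serialized next to the outputs so any
result can be regenerated.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import imaging, io, mea, smlm, spt, synthetic

__all__ = ["validate_config", "run_pipeline", "STAGES"]

logger = logging.getLogger("polyquant")


def _stage_simulate_smlm(ctx, out, seed, **params):
    locs, truth = synthetic.simulate_smlm_field(seed=seed, **params)
    ctx["locs"], ctx["smlm_truth"] = locs, truth
    io.write_localizations_csv(locs, out / "localizations.csv")
    io.write_json(
        {
            "n_detections": len(locs),
            "n_clusters_true": len(truth.cluster_centers_nm),
            "cluster_centers_nm": truth.cluster_centers_nm,
            "detection_cluster_label": truth.detection_cluster_label,
        },
        out / "smlm_truth.json",
    )


def _stage_simulate_spt(ctx, out, seed, **params):
    traj, truth = synthetic.simulate_trajectories(seed=seed, **params)
    ctx["traj"], ctx["spt_truth"] = traj, truth
    io.write_trajectories_csv(traj, out / "trajectories.csv")
    io.write_json(
        {
            "D_um2_s": truth.D_um2_s,
            "transition_matrix": truth.transition_matrix,
            "initial_distribution": truth.initial_distribution,
            "state_fractions": truth.state_fractions(),
        },
        out / "spt_truth.json",
    )


def _stage_simulate_image(ctx, out, seed, **params):
    pair = synthetic.simulate_two_channel_image(seed=seed, **params)
    ctx["image_pair"] = pair
    io.write_tiff(pair.channel_a, out / "channel_a.tif")
    io.write_tiff(pair.channel_b, out / "channel_b.tif")
    io.write_json(
        {
            "centers_a": pair.centers_a,
            "centers_b": pair.centers_b,
            "n_overlap": len(pair.overlap_pairs),
        },
        out / "image_truth.json",
    )


def _stage_simulate_mea(ctx, out, seed, **params):
    rec = synthetic.simulate_mea_recording(seed=seed, **params)
    ctx["mea_rec"] = rec
    io.write_mea_h5(rec, out / "recording.h5")
    io.write_json(
        {"true_spike_counts": [len(t) for t in rec.true_spike_times_s]},
        out / "mea_truth.json",
    )


def _stage_merge(ctx, out, seed, input=None, merge_radius_nm=20.0, max_frame_gap=1):
    locs = io.read_localizations_csv(input) if input else ctx["locs"]
    merged = smlm.merge_consecutive_detections(locs, merge_radius_nm, max_frame_gap)
    ctx["locs"] = merged
    io.write_localizations_csv(merged, out / "localizations_merged.csv")


def _stage_cluster(ctx, out, seed, input=None, eps_nm=20.0, min_pts=20):
    locs = io.read_localizations_csv(input) if input else ctx["locs"]
    cs = smlm.dbscan_cluster(locs, eps_nm=eps_nm, min_pts=min_pts)
    metrics = smlm.cluster_metrics(cs)
    ctx["cluster_set"], ctx["cluster_metrics"] = cs, metrics
    metrics["per_cluster"].to_csv(out / "clusters.csv", index=False)
    locs.to_dataframe().assign(cluster_label=cs.labels).to_csv(
        out / "localization_labels.csv", index=False
    )
    io.write_json(
        {
            "n_clusters": metrics["n_clusters"],
            "detections_per_um2": metrics["detections_per_um2"],
            "fraction_in_clusters": metrics["fraction_in_clusters"],
        },
        out / "cluster_metrics.json",
    )


def _stage_render(ctx, out, seed, input=None, pixel_size_nm=10.0, kernel_sigma_nm=10.0):
    locs = io.read_localizations_csv(input) if input else ctx["locs"]
    img = smlm.render_storm(locs, pixel_size_nm, kernel_sigma_nm)
    io.write_tiff(img.image.astype(np.float32), out / "rendered.tif")


def _stage_spt_hmm(
    ctx,
    out,
    seed,
    input=None,
    dt_s=None,
    kmax=3,
    prior_D_um2_s=0.1,
    prior_dwell_frames=50.0,
    n_restarts=10,
    max_iter=500,
    tol=1e-6,
):
    traj = io.read_trajectories_csv(input, dt_s=dt_s) if input else ctx["traj"]
    ds = spt.displacements(traj)
    priors = spt.HMMPriors(prior_D_um2_s=prior_D_um2_s, prior_dwell_frames=prior_dwell_frames)
    model, bounds = spt.select_model(
        ds,
        priors=priors,
        candidate_K=range(1, kmax + 1),
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
    )
    metrics = spt.state_metrics(model, ds)
    ctx["hmm_model"] = model
    io.write_json(
        {
            "K": model.K,
            "D_um2_s": model.D_um2_s,
            "A": model.A,
            "pi": model.pi,
            "evidence_bound": model.evidence_bound,
            "per_K_bounds": {str(k): v for k, v in bounds.items()},
            "dwell_time_ms": metrics.dwell_time_ms,
            "occupancy": metrics.occupancy,
            "converged": model.converged,
            "n_dropped_trajectories": ds.n_dropped,
        },
        out / "hmm_model.json",
    )


def _stage_segment(
    ctx,
    out,
    seed,
    input=None,
    channel="a",
    n_scales=2,
    threshold_k=4.0,
    min_size_px=4,
    pixel_size_nm=None,
):
    if input:
        image = io.read_tiff(input)
        px = pixel_size_nm or 100.0
    else:
        pair = ctx["image_pair"]
        image = pair.channel_a if channel == "a" else pair.channel_b
        px = pixel_size_nm or pair.pixel_size_nm
    mask = imaging.wavelet_segment(image, n_scales, threshold_k, min_size_px, px)
    ctx[f"mask_{channel}"] = mask
    io.write_tiff(mask.label_image, out / f"labels_{channel}.tif")
    mask.table.to_csv(out / f"structures_{channel}.csv", index=False)
    io.write_json(imaging.structure_metrics(mask), out / f"segment_metrics_{channel}.json")


def _stage_coloc(ctx, out, seed, mode="overlap"):
    res = imaging.colocalize(ctx["mask_a"], ctx["mask_b"], mode=mode)
    io.write_json(
        {
            "fraction_a_coloc": res.fraction_a_coloc,
            "n_a": res.n_a,
            "n_b": res.n_b,
            "n_coloc": res.n_coloc,
            "mode": res.mode,
        },
        out / "colocalization.json",
    )


def _stage_endocytosis(ctx, out, seed, green="a", red="b"):
    res = imaging.classify_endocytosed(ctx[f"mask_{green}"], ctx[f"mask_{red}"])
    io.write_json(
        {
            "n_total_green": res.n_total_green,
            "n_surface": res.n_surface,
            "n_internal": res.n_internal,
            "fraction_internal": res.fraction_internal,
            "undefined": res.undefined,
        },
        out / "endocytosis.json",
    )


def _stage_mea(
    ctx,
    out,
    seed,
    input=None,
    threshold_sd=6.0,
    highpass_hz=300.0,
    sd_estimator="robust",
    dead_time_ms=1.0,
    min_rate_hz=0.1,
):
    rec = io.read_mea_h5(input) if input else ctx["mea_rec"]
    st = mea.detect_all_channels(rec, threshold_sd, highpass_hz, sd_estimator, dead_time_ms)
    rates = mea.channel_rates(st, min_rate_hz=min_rate_hz)
    ctx["spike_trains"], ctx["channel_rates"] = st, rates
    rows = [
        {"channel": ch, "t_s": t}
        for ch, times in enumerate(st.times_s)
        for t in times
    ]
    import pandas as pd

    pd.DataFrame(rows, columns=["channel", "t_s"]).to_csv(out / "spikes.csv", index=False)
    pd.DataFrame(
        {"channel": np.arange(len(rates.rates_hz)), "rate_hz": rates.rates_hz, "active": rates.active}
    ).to_csv(out / "rates.csv", index=False)
    io.write_json(
        {
            "network_mean_hz": rates.network_mean_hz,
            "n_active": rates.n_active,
            "n_channels": len(rates.rates_hz),
        },
        out / "mea_metrics.json",
    )


STAGES = {
    "simulate_smlm": (
        _stage_simulate_smlm,
        {
            "n_clusters",
            "detections_per_cluster_mean",
            "cluster_radius_nm",
            "background_density_per_um2",
            "localization_sigma_nm",
            "n_frames",
            "blink_repeat_mean",
            "field_width_nm",
            "field_height_nm",
        },
    ),
    "simulate_spt": (
        _stage_simulate_spt,
        {
            "D_um2_s",
            "transition_matrix",
            "n_trajectories",
            "lengths",
            "dt_s",
            "localization_sigma_um",
        },
    ),
    "simulate_image": (
        _stage_simulate_image,
        {
            "shape",
            "pixel_size_nm",
            "n_puncta_a",
            "n_puncta_b",
            "overlap_fraction",
            "psf_sigma_px",
            "amplitude",
            "background_rate",
            "min_separation_px",
        },
    ),
    "simulate_mea": (
        _stage_simulate_mea,
        {
            "n_channels",
            "rates_hz",
            "duration_s",
            "sampling_rate_hz",
            "spike_amplitude_sd_units",
            "noise_sd",
        },
    ),
    "merge": (_stage_merge, {"input", "merge_radius_nm", "max_frame_gap"}),
    "cluster": (_stage_cluster, {"input", "eps_nm", "min_pts"}),
    "render": (_stage_render, {"input", "pixel_size_nm", "kernel_sigma_nm"}),
    "spt_hmm": (
        _stage_spt_hmm,
        {
            "input",
            "dt_s",
            "kmax",
            "prior_D_um2_s",
            "prior_dwell_frames",
            "n_restarts",
            "max_iter",
            "tol",
        },
    ),
    "segment": (
        _stage_segment,
        {"input", "channel", "n_scales", "threshold_k", "min_size_px", "pixel_size_nm"},
    ),
    "coloc": (_stage_coloc, {"mode"}),
    "endocytosis": (_stage_endocytosis, {"green", "red"}),
    "mea": (
        _stage_mea,
        {"input", "threshold_sd", "highpass_hz", "sd_estimator", "dead_time_ms", "min_rate_hz"},
    ),
}

_POSITIVE_PARAMS = {
    "eps_nm",
    "min_pts",
    "merge_radius_nm",
    "pixel_size_nm",
    "kernel_sigma_nm",
    "threshold_k",
    "min_size_px",
    "threshold_sd",
    "highpass_hz",
    "duration_s",
    "sampling_rate_hz",
    "prior_D_um2_s",
    "prior_dwell_frames",
    "tol",
    "dt_s",
    "psf_sigma_px",
    "n_scales",
}


def validate_config(config: dict) -> dict:
    """Validate a run config and return it with defaults resolved.

    Unknown top-level keys, unknown stages, unknown stage parameters, and
    non-positive values of strictly positive parameters are all rejected
    before any stage runs.
    """
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    allowed_top = {"seed", "stages", "out"}
    unknown = set(config) - allowed_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages")
    if not stages:
        raise ValueError("config must declare a non-empty 'stages' list")
    resolved = {"seed": int(config.get("seed", 0)), "stages": []}
    for entry in stages:
        entry = dict(entry)
        name = entry.pop("stage", None)
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        _, allowed = STAGES[name]
        bad = set(entry) - allowed
        if bad:
            raise ValueError(f"stage {name!r}: unknown parameters {sorted(bad)}")
        for key in set(entry) & _POSITIVE_PARAMS:
            if entry[key] is not None and not (float(entry[key]) > 0):
                raise ValueError(f"stage {name!r}: parameter {key!r} must be positive")
        resolved["stages"].append({"stage": name, **entry})
    return resolved


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages in order into ``out_dir``.

    Writes the resolved config, a run log, and a provenance record
    (package version, global seed, per-stage seeds and parameters).  With a
    fixed seed and config the metric outputs are byte-identical between
    runs.
    """
    resolved = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed_seq = np.random.SeedSequence(resolved["seed"])
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(resolved["stages"]))]

    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    provenance = {"version": __version__, "seed": resolved["seed"], "stages": []}
    ctx: dict = {}
    try:
        for i, entry in enumerate(resolved["stages"]):
            name = entry["stage"]
            params = {k: v for k, v in entry.items() if k != "stage"}
            logger.info("stage %d: %s %s", i, name, params)
            func, _ = STAGES[name]
            try:
                func(ctx, out, stage_seeds[i], **params)
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            provenance["stages"].append(
                {"index": i, "stage": name, "seed": stage_seeds[i], "params": params}
            )
        io.write_json(provenance, out / "provenance.json")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
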