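"""End-to-end pipeline driver: filter → ROI → detect → link → QC → analyses.

A single YAML config names the inputs (a TIFF movie or a pre-tracked CSV),
the acquisition metadata, and which downstream analyses to run. Outputs
are deterministic given the seed; a run manifest (package version,
parameters, seed, input hashes) is written alongside the results.

Presets: ``fast`` SMT = continuous 12 ms frames, 6 lags, max jump 6 px;
``slow`` SMT = 10 ms exposures every 200 ms, max jump 4 px.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__, anisotropy, dwell, io, jump_kinetics, pem_states, qc, rl_msd
from .core import AcquisitionParams, LinkingParams
from .detect import DetectionParams, detect_movie
from .link import link_tracks

log = logging.getLogger(__name__)

PRESETS = {
    "fast": {
        "acquisition": {"frame_interval_s": 0.012, "exposure_s": 0.012},
        "linking": {"max_jump_px": 6.0, "gaps_to_close": 1, "shortest_track": 2},
        "n_lags": 6,
    },
    "slow": {
        "acquisition": {"frame_interval_s": 0.2, "exposure_s": 0.01},
        "linking": {"max_jump_px": 4.0, "gaps_to_close": 1, "shortest_track": 2},
        "n_lags": 6,
    },
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the workflow described by a config dict or YAML file path.

    Config keys: ``tiff`` or ``tracks`` (input path), ``preset``
    (fast/slow), ``acquisition``, ``detection``, ``linking``, ``roi``
    (polygon JSON path), ``analyses`` (subset of kinetics, rl, anisotropy,
    dwell, pem), ``seed``, ``qc_gate`` (optional {snr: 0.05, nn2: 0.05}),
    plus per-analysis option blocks. Returns a dict of result paths.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    preset = PRESETS.get(config.get("preset", "fast"), PRESETS["fast"])
    acq = AcquisitionParams(**{**preset["acquisition"], **config.get("acquisition", {})})
    lparams = LinkingParams(**{**preset["linking"], **config.get("linking", {})})
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "smtkit_out"))
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {
        "smtkit_version": __version__,
        "seed": seed,
        "acquisition": asdict(acq),
        "linking": asdict(lparams),
        "inputs": {},
    }

    detections = None
    if "tiff" in config:
        tiff_path = Path(config["tiff"])
        if not tiff_path.exists():
            raise FileNotFoundError(f"input TIFF not found: {tiff_path}")
        manifest["inputs"][str(tiff_path)] = io.file_sha256(tiff_path)
        movie = io.read_tiff_stack(tiff_path)
        roi = io.read_roi_json(config["roi"]) if "roi" in config else None
        dparams = DetectionParams(**config.get("detection", {}))
        manifest["detection"] = asdict(dparams)
        detections = detect_movie(movie, dparams, roi=roi, acq=acq)
        detections.to_csv(out / "detections.csv", index=False)
        results["detections"] = out / "detections.csv"
        table = link_tracks(detections, lparams, acq=acq)
    elif "tracks" in config:
        tracks_path = Path(config["tracks"])
        if not tracks_path.exists():
            raise FileNotFoundError(f"input track CSV not found: {tracks_path}")
        manifest["inputs"][str(tracks_path)] = io.file_sha256(tracks_path)
        table = io.read_track_csv(tracks_path, acq=acq)
    else:
        raise ValueError("config must name either 'tiff' or 'tracks'")

    io.write_track_csv(table, out / "tracks.csv", linking=lparams)
    results["tracks"] = out / "tracks.csv"

    # QC + optional gate
    qc_result = {}
    if detections is not None and len(detections) and detections["snr"].notna().any():
        report = qc.qc_report(detections, table, mj_px=lparams.max_jump_px)
        qc_result = report.to_dict()
        io.write_json(out / "qc.json", qc_result)
        results["qc"] = out / "qc.json"
        gate = config.get("qc_gate")
        if gate:
            snr_bad = qc_result["fraction_snr_below"] > gate.get("snr", 0.05)
            nn_frac = qc_result.get("fraction_2nn_within_mj")
            nn_bad = nn_frac is not None and nn_frac > gate.get("nn2", 0.05)
            if snr_bad or nn_bad:
                io.write_json(out / "manifest.json", manifest)
                raise RuntimeError(
                    f"QC gate failed (snr_below={qc_result['fraction_snr_below']:.3f}, "
                    f"2nn_within_mj={nn_frac}); analyses aborted"
                )

    analyses = config.get("analyses", [])
    if "kinetics" in analyses:
        opts = config.get("kinetics", {})
        hist = jump_kinetics.jump_histograms(
            table, n_lags=opts.get("n_lags", preset["n_lags"]),
            bin_width_um=opts.get("bin_width_um", 0.01),
        )
        variant = opts.get("model", "kinetic")
        if opts.get("n_boot", 0):
            fit, sd = jump_kinetics.bootstrap_fit(
                table, variant=variant, n_boot=opts["n_boot"], seed=seed,
                n_lags=opts.get("n_lags", preset["n_lags"]),
            )
        else:
            fit_fn = (jump_kinetics.fit_two_state_kinetic if variant == "kinetic"
                      else jump_kinetics.fit_two_state_spoton)
            fit = fit_fn(hist, acq, seed=seed)
        io.write_json(out / "kinetics.json", {**fit.as_dict(), "model_variant": fit.model_variant,
                                              "bootstrap_sd": fit.bootstrap_sd})
        results["kinetics"] = out / "kinetics.json"

    if "rl" in analyses:
        opts = config.get("rl", {})
        lag = int(round(opts.get("lag_ms", 120) / 1000.0 / acq.frame_interval_s)) or 1
        vhc = rl_msd.van_hove(table, lag)
        pm = rl_msd.rl_invert(vhc)
        bnd = rl_msd.find_group_boundaries(pm)
        groups = rl_msd.classify_tracks(table, bnd, lag, seed=seed)
        fits, curves = rl_msd.group_msd_powerlaw(table, groups)
        io.write_json(out / "rl.json", {
            "m_um2": pm.m_um2, "p": pm.p, "boundaries_um2": bnd,
            "fractions": groups.fractions, "fractions_sd": groups.fractions_sd,
            "alpha": fits,
        })
        groups.labels.rename("rl_group").reset_index().to_csv(out / "rl_groups.csv", index=False)
        results["rl"] = out / "rl.json"

    if "anisotropy" in analyses:
        opts = config.get("anisotropy", {})
        pairs = anisotropy.angles_pooled(table, n_lags=opts.get("n_lags", 6))
        ac, sd = anisotropy.anisotropy_coefficient(pairs["theta_deg"], seed=seed)
        spatial = anisotropy.spatial_anisotropy(pairs, seed=seed)
        anisotropy.polar_histogram(pairs["theta_deg"]).to_csv(out / "angles_polar.csv", index=False)
        io.write_json(out / "anisotropy.json", {"ac": ac, "ac_sd": sd, "spatial": spatial})
        results["anisotropy"] = out / "anisotropy.json"

    if "dwell" in analyses:
        opts = config.get("dwell", {})
        ref = io.read_track_csv(opts["reference_tracks"], acq=acq)
        params = dwell.calibrate_bound_call(ref, d_free_um2s=opts.get("d_free_um2s", 5.0))
        ref_surv = dwell.survival(dwell.call_bound_segments(ref, params), seed=seed)
        k_pb = dwell.fit_triple_exponential(ref_surv, seed=seed).k_pb
        segs = dwell.call_bound_segments(table, params)
        raw = dwell.survival(segs, seed=seed)
        corr = dwell.photobleach_correct(raw, k_pb)
        curves = [raw, corr]
        if "f_bound" in opts:
            curves.append(dwell.normalize_to_bound_fraction(corr, opts["f_bound"]))
        rows = []
        for c in curves:
            for t, s, lo_, hi_ in zip(c.t_s, c.s, c.ci_low, c.ci_high):
                rows.append({"t_s": t, "s": s, "ci_low": lo_, "ci_high": hi_, "variant": c.variant})
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "survival.csv", index=False)
        io.write_json(out / "dwell.json", {"k_pb": k_pb, "bound_call": asdict(params),
                                           "n_segments": int(len(segs))})
        results["dwell"] = out / "dwell.json"

    if "pem" in analyses:
        opts = config.get("pem", {})
        subs = pem_states.split_subtracks(table, split_length=opts.get("split_length", 7))
        model = pem_states.select_model(
            subs,
            k_range=range(1, opts.get("k_max", 15) + 1),
            n_reinit=opts.get("n_reinit", 50),
            n_perturb=opts.get("n_perturb", 200),
            n_runs=opts.get("n_runs", 5),
            seed=seed,
        )
        labels = pem_states.assign_states(model)
        payload = {
            "k": model.k, "d_um2s": model.d_um2s, "sigma_um": model.sigma_um,
            "pi": model.pi, "bic": model.bic,
            "msd": pem_states.state_msd(subs, labels),
        }
        if "f_bound" in opts:
            payload["normalized_fractions"] = pem_states.normalized_state_fractions(
                labels, model.k, opts["f_bound"], seed=seed)
        io.write_json(out / "pem.json", payload)
        subs.meta.assign(pem_state=labels).to_csv(out / "pem_labels.csv", index=False)
        results["pem"] = out / "pem.json"

    io.write_json(out / "manifest.json", manifest)
    results["manifest"] = out / "manifest.json"
    return {k: str(v) for k, v in results.items()}
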