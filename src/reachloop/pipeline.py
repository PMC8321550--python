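"""Run all analysis stages over one or many sessions and collect
machine-readable results.

Stages run in dependency order (prep happens inside each stage);
stages whose inputs are absent are skipped with a logged reason, and
a stage failure does not abort the remaining stages. With a fixed
seed the result bundle is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, cca, condition_compare, decoding, entrainment, event_glm, response_stats

from .data_model import Session, read_session
from .signal_prep import align_to_event, zscore_to_baseline

log = logging.getLogger("reachloop")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonify(payload), indent=1, sort_keys=True) + "\n")


def run_glm_stage(session: Session, out_dir: Path) -> dict:
    units = session.units(region="PN", multiunit=False)
    if not units:
        raise RuntimeError("no PN single units")
    trials = session.trials[np.isfinite(session.trials.cue_time)]
    fits = [event_glm.fit_unit(u, trials) for u in units]
    comparison = event_glm.compare_event_weights(fits) if len(fits) >= 2 else None
    df = pd.DataFrame(
        {
            "unit_id": [f.unit_id for f in fits],
            "r2": [f.r2 for f in fits],
            "modeled": [f.modeled for f in fits],
            "norm_k_cue": [float(np.linalg.norm(f.k_cue)) for f in fits],
            "norm_k_reach": [float(np.linalg.norm(f.k_reach)) for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    df.to_csv(out_dir / "glm.csv", index=False)
    return {
        "n_units": len(fits),
        "n_modeled": int(df.modeled.sum()),
        "p_cue_vs_reach": None if comparison is None else comparison["p_signed_rank"],
    }


def run_tag_stage(session: Session, out_dir: Path) -> dict:
    pulses = np.asarray(session.meta.get("pulse_times", []), dtype=float)
    units = session.units(region="PN", multiunit=False)
    if not units or pulses.size < 10:
        raise RuntimeError("tagging needs PN units and >= 10 pulses")
    tag = response_stats.paired_window_test(units, pulses, (-0.020, 0.0), (0.0, 0.020))
    latency = response_stats.sliding_window_latency(units, pulses)
    onsets = session.trials.laser_on.to_numpy(dtype=float)
    laser = response_stats.classify_laser_response(units, onsets[np.isfinite(onsets)])
    df = pd.DataFrame(
        {
            "unit_id": tag.unit_ids,
            "tag_p": tag.p,
            "tag_q": tag.q,
            "tagged": tag.modulated,
            "first_lag_ms": latency.first_lag_ms,
            "laser_class": laser["classes"],
        }
    )
    df.to_csv(out_dir / "tags.csv", index=False)
    return {
        "n_tagged": int(tag.modulated.sum()),
        "n_responsive_latency": latency.n_responsive,
        "laser_class_counts": {
            c: int(laser["classes"].count(c)) for c in response_stats.LASER_CLASSES
        },
    }


def run_entrain_stage(session: Session, out_dir: Path) -> dict:
    trials = session.trials
    onsets = trials.laser_on.to_numpy(dtype=float)
    onsets = onsets[np.isfinite(onsets)]
    freqs = trials.laser_freq_hz.to_numpy(dtype=float)
    freqs = freqs[np.isfinite(freqs)]
    if onsets.size == 0:
        raise RuntimeError("no laser stimulation epochs")
    freq = float(freqs[0])
    rows = []
    groups = {}
    for region in ("PKJ", "DCN"):
        units = session.units(region=region, multiunit=False)
        if not units:
            continue
        results = entrainment.analyze_units(
            units, onsets, freq, session.config.entrain_window_s,
            fdr_alpha=session.config.fdr_alpha,
        )
        groups[region] = results
        for r in results:
            rows.append(
                dict(unit_id=r.unit_id, region=region, n_spikes=r.n_spikes_used,
                     mrl=r.mrl, pref_phase=r.pref_phase, rayleigh_p=r.rayleigh_p,
                     q=r.q, entrained=r.entrained)
            )
    if not rows:
        raise RuntimeError("no PKJ or DCN single units")
    pd.DataFrame(rows).to_csv(out_dir / "entrain.csv", index=False)
    out = {
        region: {
            "n_units": len(res),
            "n_entrained": int(sum(r.entrained for r in res)),
            "mean_mrl": float(np.mean([r.mrl for r in res if not r.empty])),
        }
        for region, res in groups.items()
    }
    if "PKJ" in groups and "DCN" in groups:
        out["population"] = entrainment.population_entrainment(
            groups["PKJ"], groups["DCN"], freq
        )
    return out


def run_behavior_stage(session: Session, out_dir: Path) -> dict:
    if session.hand is None:
        raise RuntimeError("no hand trajectory")
    summary = behavior.analyze_session(session)
    behavior.summarize_sessions([summary], session.config.fdr_alpha)
    payload = {
        "session_id": summary.session_id,
        "endpoint_diff_mm": summary.endpoint["diff_mm"],
        "duration_diff_s": summary.duration["diff_s"],
        "initiation": [summary.initiation["prob_control"], summary.initiation["prob_laser"]],
        "success": [summary.success["rate_control"], summary.success["rate_laser"]],
        "summed_sd_mm": [summary.dispersion["summed_sd_control_mm"],
                         summary.dispersion["summed_sd_laser_mm"]],
        "q": summary.q,
        "effects": summary.effects,
        "any_effect": summary.any_effect,
    }
    _write_json(out_dir / "behavior.json", payload)
    return payload


def run_compare_stage(session: Session, out_dir: Path, region: str = "DCN") -> dict:
    units = session.units(region=region, multiunit=False)
    if not units:
        raise RuntimeError(f"no {region} single units")
    window = (-1.0, 1.0)
    tensors = {}
    for cond in ("control", "laser_cue"):
        aligned = align_to_event(session, units, "lift_time", window, condition=cond,
                                 sigma_s=session.config.rate_kernel_sigma_s)
        z, _, _, _ = zscore_to_baseline(aligned.values, aligned.t, (-1.0, -0.4))
        tensors[cond] = z.mean(axis=2)
    tp = condition_compare.timepoint_correlation(tensors["control"], tensors["laser_cue"])
    pu = condition_compare.per_unit_correlation(tensors["control"], tensors["laser_cue"])
    payload = {
        "region": region,
        "median_timepoint_rho": float(np.nanmedian(tp["rho"])),
        "per_unit_median_rho": pu["median_rho"],
        "per_unit_n_positive": pu["n_positive"],
        "per_unit_n_defined": pu["n_defined"],
    }
    _write_json(out_dir / f"compare_{region}.json", payload)
    return payload


def run_decode_stage(session: Session, out_dir: Path) -> dict:
    if session.hand is None:
        raise RuntimeError("no hand trajectory")
    out = {}
    for region in ("CTX", "DCN"):
        has = region in session.rates or bool(session.units(region=region, multiunit=True))
        if not has:
            continue
        res = decoding.fit_standard_decoder(session, region)
        diff = decoding.decoded_observed_difference(res, session)
        out[region] = {
            "n_dims": res.model.n_dims,
            "r2_control_test": res.r2_control_test,
            "r2_laser": res.r2_laser,
            "diff_rho_by_axis": diff["rho_by_axis"],
        }
    if not out:
        raise RuntimeError("no multiunit activity in CTX or DCN")
    _write_json(out_dir / "decode.json", out)
    return out


def run_cca_stage(session: Session, out_dir: Path) -> dict:
    for region in ("CTX", "DCN"):
        if region not in session.rates and not session.units(region=region, multiunit=True):
            raise RuntimeError("CCA needs simultaneous CTX and DCN activity")
    res = cca.session_cca(session)
    comp = cca.compare_laser_control_cca(session)
    payload = {
        "canonical_corrs": res.canonical_corrs,
        "total_opp_ctx": res.total_opposite_a,
        "total_opp_dcn": res.total_opposite_b,
        "laser_vs_control": comp,
    }
    _write_json(out_dir / "cca.json", payload)
    return payload


STAGES = (
    ("glm", run_glm_stage),
    ("tag", run_tag_stage),
    ("entrain", run_entrain_stage),
    ("behavior", run_behavior_stage),
    ("compare", run_compare_stage),
    ("decode", run_decode_stage),
    ("cca", run_cca_stage),
)


def run_all(
    session_dirs: list[str | Path] | None = None,
    out_dir: str | Path = "reachloop_out",
    sessions: list[Session] | None = None,
) -> dict:
    """Execute every stage on every session; returns the report bundle.

    Stage failures are logged (with the reason) and recorded in the
    bundle; remaining stages continue. ``bundle['ok']`` is False if
    any stage raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if sessions is None:
        sessions = [read_session(d) for d in (session_dirs or [])]
    bundle = {"sessions": {}, "ok": True}
    for session in sessions:
        sdir = out_dir / session.session_id
        sdir.mkdir(parents=True, exist_ok=True)
        report = {}
        for name, fn in STAGES:
            try:
                report[name] = {"status": "ok", "result": fn(session, sdir)}
            except (RuntimeError, ValueError) as exc:
                log.info("session %s: stage %s skipped/failed: %s",
                         session.session_id, name, exc)
                report[name] = {"status": "skipped", "reason": str(exc)}
            except Exception as exc:  # unexpected failure: record, continue
                log.error("session %s stage %s error:\n%s", session.session_id,
                          name, traceback.format_exc())
                report[name] = {"status": "error", "reason": repr(exc)}
                bundle["ok"] = False
        bundle["sessions"][session.session_id] = report
        _write_json(sdir / "report.json", report)
    bundle["study"] = summarize_study(bundle)
    _write_json(out_dir / "study.json", bundle["study"])
    return bundle


def summarize_study(bundle: dict) -> dict:
    """Cross-session tallies of effects, entrainment, decoding, CCA."""
    n_any = 0
    n_behavior = 0
    r2_control, r2_laser, cca_totals = [], [], []
    entrained = {"PKJ": [0, 0], "DCN": [0, 0]}
    for rep in bundle["sessions"].values():
        beh = rep.get("behavior", {})
        if beh.get("status") == "ok":
            n_behavior += 1
            n_any += bool(beh["result"]["any_effect"])
        ent = rep.get("entrain", {})
        if ent.get("status") == "ok":
            for region in ("PKJ", "DCN"):
                if region in ent["result"]:
                    entrained[region][0] += ent["result"][region]["n_entrained"]
                    entrained[region][1] += ent["result"][region]["n_units"]
        dec = rep.get("decode", {})
        if dec.get("status") == "ok":
            for region_res in dec["result"].values():
                r2_control.append(region_res["r2_control_test"])
                r2_laser.append(region_res["r2_laser"])
        cc = rep.get("cca", {})
        if cc.get("status") == "ok":
            cca_totals.append(
                [cc["result"]["total_opp_ctx"], cc["result"]["total_opp_dcn"]]
            )
    return {
        "n_sessions": len(bundle["sessions"]),
        "n_behavior_sessions": n_behavior,
        "n_sessions_any_effect": n_any,
        "entrained_fraction": {
            k: (v[0] / v[1] if v[1] else None) for k, v in entrained.items()
        },
        "decoder_r2_control": r2_control,
        "decoder_r2_laser": r2_laser,
        "cca_totals": cca_totals,
    }
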