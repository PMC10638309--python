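"""Delimited-text and structured-text I/O for tables, parameters and traces."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .emg import EMGTrace
from .exgauss import RunnerParams
from .sis import SISParams


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("ssd_ms", "rt_ms", "rt_left_ms", "rt_right_ms"):
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def params_to_dict(params: SISParams) -> dict:
    out = {"gf": params.gf, "tf": params.tf, "eps_wrong": params.eps_wrong,
           "p_floor": params.p_floor, "runners": {}}
    for runner in ("dual_go", "dual_stop", "sel_left", "sel_right"):
        out["runners"][runner] = {
            cond: {"mu": rp.mu, "sigma": rp.sigma, "tau": rp.tau}
            for cond, rp in getattr(params, runner).items()
        }
    return out


def params_from_dict(d: dict) -> SISParams:
    runners = {
        runner: {
            cond: RunnerParams(v["mu"], v["sigma"], v["tau"])
            for cond, v in conds.items()
        }
        for runner, conds in d["runners"].items()
    }
    return SISParams(
        dual_go=runners["dual_go"], dual_stop=runners["dual_stop"],
        sel_left=runners["sel_left"], sel_right=runners["sel_right"],
        gf=d.get("gf", 0.0), tf=d.get("tf", 0.0),
        eps_wrong=d.get("eps_wrong", 0.0), p_floor=d.get("p_floor", 1e-10),
    )


def write_params(params: SISParams | Sequence[SISParams], path) -> None:
    if isinstance(params, SISParams):
        payload = params_to_dict(params)
    else:
        payload = [params_to_dict(p) for p in params]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_params(path):
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, list):
        return [params_from_dict(d) for d in payload]
    return params_from_dict(payload)


def write_traces(traces: Sequence[EMGTrace], out_dir) -> None:
    """One tab-separated file per trial (left/right channel columns, mV) plus
    a JSON sidecar with sampling rate and event markers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar = {}
    for tr in traces:
        name = f"trace_p{tr.participant}_t{tr.trial}.tsv"
        pd.DataFrame({"left_mv": tr.left, "right_mv": tr.right}).to_csv(
            out_dir / name, sep="\t", index=False, float_format="%.6g"
        )
        sidecar[name] = {
            "fs_hz": tr.fs_hz,
            "go_time_ms": tr.go_time_ms,
            "stop_time_ms": tr.stop_time_ms,
            "press_left_ms": tr.press_left_ms,
            "press_right_ms": tr.press_right_ms,
            "participant": tr.participant,
            "trial": tr.trial,
            "condition": tr.condition,
        }
    (out_dir / "traces.json").write_text(json.dumps(sidecar, indent=1))


def read_traces(in_dir) -> list[EMGTrace]:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "traces.json").read_text())
    traces = []
    for name, meta in sidecar.items():
        tab = pd.read_csv(in_dir / name, sep="\t")
        traces.append(
            EMGTrace(
                left=tab["left_mv"].to_numpy(float),
                right=tab["right_mv"].to_numpy(float),
                fs_hz=meta["fs_hz"],
                go_time_ms=meta["go_time_ms"],
                stop_time_ms=meta["stop_time_ms"],
                press_left_ms=meta["press_left_ms"],
                press_right_ms=meta["press_right_ms"],
                participant=meta["participant"],
                trial=meta["trial"],
                condition=meta["condition"],
            )
        )
    return traces


def save_posterior(samples, path, extra: Optional[dict] = None) -> None:
    """Persist retained draws plus metadata in a compressed array container."""
    meta = {
        "variant": samples.variant.id,
        "param_names": samples.param_names,
        "subject_ids": [int(s) for s in samples.subject_ids],
        "seed": samples.seed,
        "burnin_iterations": samples.burnin_iterations,
    }
    if extra:
        meta.update(extra)
    np.savez_compressed(
        path,
        theta=samples.theta,
        phi_loc=samples.phi_loc,
        phi_scale=samples.phi_scale,
        loglik=samples.loglik,
        meta=json.dumps(meta),
    )


def load_posterior(path):
    """Load persisted draws; returns a PosteriorSamples suitable for
    diagnostics and contrasts (the trial data are not stored, so BPIC must be
    read from the saved metadata or recomputed against the data)."""
    from .hierfit import (Hyperprior, ParameterSpace, PosteriorSamples,
                          SamplerConfig, VARIANTS)

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        variant = VARIANTS[meta["variant"]]
        priors = Hyperprior()
        samples = PosteriorSamples(
            variant=variant,
            param_names=meta["param_names"],
            subject_ids=meta["subject_ids"],
            theta=z["theta"],
            phi_loc=z["phi_loc"],
            phi_scale=z["phi_scale"],
            loglik=z["loglik"],
            seed=meta.get("seed"),
            config=SamplerConfig(),
            priors=priors,
            burnin_iterations=meta.get("burnin_iterations", 0),
            space=ParameterSpace(variant, priors),
            prepared={},
        )
    return samples, meta
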