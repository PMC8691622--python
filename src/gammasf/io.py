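"""HDF5 container for recordings and JSON serialization of fit results.

Layout::

    /lfp          (n_trials, n_samples) float64; attrs: rate, pre, stim, post
    /spikes/t0000 ... one ragged float64 dataset per trial (optional)
    /conditions   UTF-8 strings, one per trial (floats stored as repr)
    /meta         attrs: site_id, region, depth_mm (optional), config_digest

Native vendor formats (Blackrock NEV/NSx, Plexon) are not parsed; convert
them to this layout upstream.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .model import (
    BaselineParams,
    ComponentParams,
    FitResult,
    ModelParams,
)
from .synthetic import Recording


def _encode_condition(c) -> str:
    return c if isinstance(c, str) else repr(float(c))


def _decode_condition(s: str):
    try:
        return float(s)
    except ValueError:
        return s


def write_recording(rec: Recording, path, config_digest: str = "") -> None:
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("lfp", data=rec.lfp)
        d.attrs["rate"] = rec.rate
        d.attrs["pre"] = rec.pre
        d.attrs["stim"] = rec.stim
        d.attrs["post"] = rec.post
        fh.create_dataset(
            "conditions",
            data=np.array([_encode_condition(c) for c in rec.conditions], dtype=object),
            dtype=h5py.string_dtype(),
        )
        if rec.spikes is not None:
            g = fh.create_group("spikes")
            for i, tr in enumerate(rec.spikes):
                g.create_dataset(f"t{i:04d}", data=np.asarray(tr, dtype=float))
        meta = fh.create_group("meta")
        meta.attrs["site_id"] = rec.site_id
        meta.attrs["region"] = rec.region
        if rec.depth_mm is not None:
            meta.attrs["depth_mm"] = rec.depth_mm
        if config_digest:
            meta.attrs["config_digest"] = config_digest


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as fh:
        for group in ("lfp", "conditions", "meta"):
            if group not in fh:
                raise ValueError(f"missing {group} group in {path}")
        lfp = fh["lfp"][...]
        attrs = fh["lfp"].attrs
        conditions = [_decode_condition(s.decode() if isinstance(s, bytes) else s)
                      for s in fh["conditions"][...]]
        if len(conditions) != lfp.shape[0]:
            raise ValueError("trial count mismatch between /lfp and /conditions")
        spikes = None
        if "spikes" in fh:
            keys = sorted(fh["spikes"].keys())
            if len(keys) != lfp.shape[0]:
                raise ValueError("trial count mismatch between /lfp and /spikes")
            spikes = [fh["spikes"][k][...] for k in keys]
        meta = fh["meta"].attrs
        return Recording(
            lfp=lfp, rate=float(attrs["rate"]), conditions=conditions,
            spikes=spikes, pre=float(attrs["pre"]), stim=float(attrs["stim"]),
            post=float(attrs["post"]), site_id=str(meta.get("site_id", "site0")),
            depth_mm=float(meta["depth_mm"]) if "depth_mm" in meta else None,
            region=str(meta.get("region", "V1")),
        )


def fit_result_to_dict(fit: FitResult) -> dict:
    p = fit.params
    return {
        "baseline": dataclasses.asdict(p.baseline),
        "components": [dataclasses.asdict(c) for c in p.components],
        "sf0_cpd": p.sf0,
        "band_windows_hz": {k: list(v) for k, v in p.band_windows.items()},
        "gof": fit.gof,
        "component_snr": None if fit.component_snr is None else list(map(float, fit.component_snr)),
        "n_components": fit.n_components,
        "mse": fit.mse,
        "n_restarts": fit.n_restarts,
        "converged": fit.converged,
        "best_restart": fit.best_restart,
    }


def fit_result_from_dict(d: dict) -> ModelParams:
    comps = tuple(ComponentParams(**c) for c in d["components"])
    return ModelParams(
        baseline=BaselineParams(**d["baseline"]),
        components=comps,
        sf0=d["sf0_cpd"],
        band_windows={k: tuple(v) for k, v in d["band_windows_hz"].items()},
    )


def write_fit_result(fit: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(fit), fh, indent=2)


def read_model_params(path) -> ModelParams:
    with open(path) as fh:
        return fit_result_from_dict(json.load(fh))
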