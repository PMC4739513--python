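"""Readers, writers, run configuration and the end-to-end pipeline.

Time series travel as delimited text (one row per sample, one column per
channel, sampling rate in a ``# fs <Hz>`` header line) or as a small
little-endian binary format; segment boundaries and event markers live in
companion delimited files with 0-based half-open sample indices.  Fits and
spectral estimates are serialised to HDF5.  ``run_pipeline`` ties the
modules together in the standard workflow order: sign flip, fit, statewise
spectra, time-frequency maps and statistics.

Binary matrix format (extension-agnostic): 8-byte magic ``HMMARTS1``,
little-endian ``int64 T``, ``int64 N``, ``float64 fs``, then ``T*N``
``float64`` values row-major.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import yaml

from .datatypes import TimeSeriesData
from .inference import FitResult, HMMMARPosterior, StatePosterior, StateTimeCourse, fit
from .model import (
    ClampingPlan,
    HMMMARConfig,
    LagSet,
    PriorConfig,
    TrainingConfig,
    build_lag_set,
)
from .spectral import SpectralEstimate, TaperConfig

logger = logging.getLogger(__name__)

_MAGIC = b"HMMARTS1"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Time-series IO


def _companion(path: Path, kind: str) -> Path:
    return path.with_suffix(path.suffix + f".{kind}")


def write_timeseries(data: TimeSeriesData, path, format: str = "text") -> None:
    """Write values plus companion ``.segments`` / ``.events`` files."""
    path = Path(path)
    if format == "text":
        with open(path, "w") as fh:
            fh.write(f"# fs {data.fs!r}\n")
            np.savetxt(fh, data.values, fmt="%.12g")
    elif format == "binary":
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            np.array([data.n_samples, data.n_channels], dtype="<i8").tofile(fh)
            np.array([data.fs], dtype="<f8").tofile(fh)
            data.values.astype("<f8").tofile(fh)
    else:
        raise ValueError(f"unknown format {format!r}")
    np.savetxt(_companion(path, "segments"), np.asarray(data.segments, int), fmt="%d")
    if data.events:
        np.savetxt(_companion(path, "events"), np.asarray(data.events, int), fmt="%d")


def read_timeseries(path, format: str = "text", fs: Optional[float] = None) -> TimeSeriesData:
    """Read a time series and its companion segment/event files.

    ``fs`` overrides/supplies the sampling rate; for text files it otherwise
    comes from the ``# fs`` header and for binary files from the header.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "text":
        header_fs = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            parts = first[1:].split()
            if len(parts) >= 2 and parts[0] == "fs":
                header_fs = float(parts[1])
        try:
            values = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        fs = fs if fs is not None else header_fs
        if fs is None:
            raise ParseError(f"{path}: sampling rate missing (no '# fs' header)")
    elif format == "binary":
        with open(path, "rb") as fh:
            magic = fh.read(8)
            if magic != _MAGIC:
                raise ParseError(f"{path}: bad magic {magic!r}")
            T, N = np.fromfile(fh, dtype="<i8", count=2)
            file_fs = float(np.fromfile(fh, dtype="<f8", count=1)[0])
            values = np.fromfile(fh, dtype="<f8").reshape(-1, N)
            if values.shape[0] != T:
                raise ParseError(
                    f"{path}: header promises {T} samples, found {values.shape[0]}"
                )
        fs = fs if fs is not None else file_fs
    else:
        raise ValueError(f"unknown format {format!r}")
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(f"{path}: non-finite value at row {r}, column {c}")
    segments, events = [], []
    seg_path = _companion(path, "segments")
    if seg_path.exists():
        segs = np.loadtxt(seg_path, ndmin=2, dtype=int)
        segments = [tuple(s) for s in segs]
    ev_path = _companion(path, "events")
    if ev_path.exists():
        evs = np.loadtxt(ev_path, ndmin=2, dtype=int)
        events = [tuple(e) for e in evs]
    try:
        return TimeSeriesData(values=values, fs=fs, segments=segments, events=events)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Config (de)serialisation helpers


def config_to_dict(config: HMMMARConfig) -> dict:
    d = {
        "K": config.K,
        "lags": {
            "P": config.lagset.P,
            "P0": config.lagset.P0,
            "Q": config.lagset.Q,
        },
        "noise_cov": config.noise_cov,
        "noise_shared": config.noise_shared,
        "symmetric_sigma": config.symmetric_sigma,
        "observation": config.observation,
        "priors": dataclasses.asdict(config.priors),
        "training": dataclasses.asdict(config.training),
    }
    if config.priors.wishart_scale is not None:
        d["priors"]["wishart_scale"] = np.asarray(
            config.priors.wishart_scale
        ).tolist()
    if config.clamping is not None:
        d["clamping"] = {"mode": config.clamping.mode}
    return d


def config_from_dict(d: dict) -> HMMMARConfig:
    lags = d["lags"]
    lagset = (
        build_lag_set(lags["P"], lags["P0"], lags["Q"])
        if lags["P"] > 0
        else LagSet(lags=(), P=0, P0=0, Q="uniform")
    )
    priors = dict(d.get("priors", {}))
    if priors.get("wishart_scale") is not None:
        priors["wishart_scale"] = np.asarray(priors["wishart_scale"])
    return HMMMARConfig(
        K=d["K"],
        lagset=lagset,
        noise_cov=d.get("noise_cov", "diagonal"),
        noise_shared=d.get("noise_shared", False),
        symmetric_sigma=d.get("symmetric_sigma", False),
        observation=d.get("observation", "mar"),
        priors=PriorConfig(**priors),
        training=TrainingConfig(**d.get("training", {})),
    )


# ---------------------------------------------------------------------------
# HDF5 containers


def save_fit(result: FitResult, path) -> None:
    """Serialise a fit (posterior arrays, gamma, trace, config echo, seeds)."""
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "hmmar-fit"
        f.attrs["config"] = json.dumps(config_to_dict(result.config))
        f.attrs["restart_id"] = result.restart_id
        f.attrs["seed"] = result.seed
        f.attrs["converged"] = result.converged
        f.create_dataset("gamma", data=result.stc.gamma)
        if result.stc.xi is not None:
            f.create_dataset("xi", data=result.stc.xi)
            f.create_dataset("xi_from", data=result.stc.xi_from)
        f.create_dataset("free_energy_trace", data=result.free_energy_trace)
        f.create_dataset("trans_counts", data=result.posterior.trans_counts)
        f.create_dataset("init_counts", data=result.posterior.init_counts)
        for k, st in enumerate(result.posterior.states):
            g = f.create_group(f"state{k}")
            g.create_dataset("W_mean", data=st.W_mean)
            for name in (
                "noise_shape",
                "noise_rate",
                "sigma_shape",
                "sigma_rate",
                "alpha_shape",
                "alpha_rate",
            ):
                v = getattr(st, name)
                if v is not None:
                    g.create_dataset(name, data=v)
            if st.wishart_dof is not None:
                g.attrs["wishart_dof"] = st.wishart_dof
                g.create_dataset("wishart_scale", data=st.wishart_scale)


def load_fit(path) -> FitResult:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "hmmar-fit":
            raise ParseError(f"{path}: not a fit container")
        config = config_from_dict(json.loads(f.attrs["config"]))
        states = []
        k = 0
        while f"state{k}" in f:
            g = f[f"state{k}"]

            def get(name):
                return np.asarray(g[name]) if name in g else None

            states.append(
                StatePosterior(
                    W_mean=np.asarray(g["W_mean"]),
                    W_cov=[],
                    free_cols=[],
                    noise_shape=get("noise_shape"),
                    noise_rate=get("noise_rate"),
                    wishart_dof=g.attrs.get("wishart_dof"),
                    wishart_scale=get("wishart_scale"),
                    sigma_shape=get("sigma_shape"),
                    sigma_rate=get("sigma_rate"),
                    alpha_shape=get("alpha_shape"),
                    alpha_rate=get("alpha_rate"),
                )
            )
            k += 1
        posterior = HMMMARPosterior(
            states=states,
            trans_counts=np.asarray(f["trans_counts"]),
            init_counts=np.asarray(f["init_counts"]),
            lagset=config.lagset,
            n_channels=states[0].W_mean.shape[1] if states else 0,
        )
        stc = StateTimeCourse(
            gamma=np.asarray(f["gamma"]),
            xi=np.asarray(f["xi"]) if "xi" in f else None,
            xi_from=np.asarray(f["xi_from"]) if "xi_from" in f else None,
        )
        return FitResult(
            posterior=posterior,
            stc=stc,
            free_energy_trace=np.asarray(f["free_energy_trace"]),
            config=config,
            restart_id=int(f.attrs["restart_id"]),
            seed=int(f.attrs["seed"]),
            converged=bool(f.attrs["converged"]),
        )


def save_spectra(est: SpectralEstimate, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "hmmar-spectra"
        f.attrs["provenance"] = est.provenance
        f.create_dataset("freqs", data=est.freqs)
        f.create_dataset("csd", data=est.csd)
        f.create_dataset("psd", data=est.psd)
        f.create_dataset("coherence", data=est.coherence)
        if est.pdc is not None:
            f.create_dataset("pdc", data=est.pdc)
        if est.taper is not None:
            f.attrs["taper"] = json.dumps(
                {
                    "R": est.taper.R,
                    "NW": est.taper.NW,
                    "window_length": est.taper.window_length,
                    "window_step": est.taper.window_step,
                }
            )


def load_spectra(path) -> SpectralEstimate:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "hmmar-spectra":
            raise ParseError(f"{path}: not a spectra container")
        taper = None
        if "taper" in f.attrs:
            taper = TaperConfig(**json.loads(f.attrs["taper"]))
        return SpectralEstimate(
            freqs=np.asarray(f["freqs"]),
            csd=np.asarray(f["csd"]),
            psd=np.asarray(f["psd"]),
            coherence=np.asarray(f["coherence"]),
            pdc=np.asarray(f["pdc"]) if "pdc" in f else None,
            provenance=str(f.attrs["provenance"]),
            taper=taper,
        )


# ---------------------------------------------------------------------------
# Run configuration


_SCHEMA: dict[str, set] = {
    "": {"seed", "out_dir", "stages", "data", "simulate", "signflip", "fit",
         "spectra", "tf", "test"},
    "data": {"path", "format", "fs", "standardize"},
    "simulate": {"preset", "n_trials", "seed", "trial_seconds", "fs",
                 "osc_radius", "lifetime_shape", "lifetime_rate", "noise_std"},
    "signflip": {"n_restarts", "max_iter", "seed"},
    "fit": {"K", "P", "P0", "Q", "noise_cov", "noise_shared", "symmetric_sigma",
            "variant", "n_restarts", "max_cycles", "tol", "seed"},
    "spectra": {"method", "NW", "R", "window_length", "window_step",
                "fmin", "fmax", "pdc"},
    "tf": {"window", "baseline", "measures"},
    "test": {"mode", "cluster_threshold", "alpha", "n_perm", "seed"},
}


def load_run_config(path) -> dict:
    """Parse and validate a structured-text (YAML) run configuration.

    Unknown keys are rejected; the parsed mapping round-trips to an
    identical file via :func:`dump_run_config`.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_run_config(cfg)
    return cfg


def validate_run_config(cfg: dict) -> None:
    unknown = set(cfg) - _SCHEMA[""]
    if unknown:
        raise ParseError(f"unknown configuration keys: {sorted(unknown)}")
    for section, keys in _SCHEMA.items():
        if not section or section not in cfg:
            continue
        sub = cfg[section] or {}
        bad = set(sub) - keys
        if bad:
            raise ParseError(f"unknown keys in [{section}]: {sorted(bad)}")


def dump_run_config(cfg: dict, path) -> None:
    validate_run_config(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Execute the standard workflow: simulate/load, sign flip, fit,
    statewise spectra, T-F maps and cluster statistics.

    Stages are taken from ``cfg["stages"]`` (default: everything configured)
    and run in the canonical order; every intermediate artefact is written
    to ``out_dir`` and a structured log records seeds, the free-energy trace
    and diagnostics (including the state-time-course spectrum check).
    Failures abort with the failing stage named; artefacts already written
    are kept.
    """
    from . import spectral, taskstats
    from .signflip import find_sign_flips
    from .simulate import paper2016_preset
    from .simulate import simulate as run_simulation

    validate_run_config(cfg)
    out = Path(out_dir or cfg.get("out_dir", "hmmar_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages") or [
        s for s in ("simulate", "signflip", "fit", "spectra", "tf", "test")
        if s in cfg or s == "fit"
    ]
    artefacts: dict = {"out_dir": str(out), "stages": stages}
    log_path = out / "run_log.yaml"
    log: dict = {"stages": {}}
    data = None
    truth = None
    seed = int(cfg.get("seed", 0))

    def fail(stage, exc):
        log["stages"][stage] = {"status": "failed", "error": str(exc)}
        yaml.safe_dump(log, open(log_path, "w"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if "simulate" in stages:
        try:
            s = dict(cfg.get("simulate", {}))
            s.pop("preset", None)
            s.setdefault("seed", seed)
            simcfg = paper2016_preset(**s)
            truth = run_simulation(simcfg)
            data = truth.data
            write_timeseries(data, out / "data.txt")
            np.savetxt(out / "true_state_path.txt", truth.state_path, fmt="%d")
            log["stages"]["simulate"] = {
                "status": "ok",
                "seed": simcfg.seed,
                "samples": int(data.n_samples),
            }
        except Exception as exc:  # noqa: BLE001
            fail("simulate", exc)
    elif "data" in cfg:
        d = cfg["data"]
        data = read_timeseries(d["path"], d.get("format", "text"), d.get("fs"))
        if d.get("standardize"):
            v = data.values - data.values.mean(0)
            data = data.copy_with(v / v.std(0))

    if data is None:
        raise RuntimeError("pipeline has no data: configure 'simulate' or 'data'")

    if "signflip" in stages:
        try:
            sf = cfg.get("signflip", {})
            trials = [data.values[a:b] for a, b in data.segments]
            sol, flipped = find_sign_flips(
                trials,
                n_restarts=sf.get("n_restarts", 10),
                max_iter=sf.get("max_iter", 1000),
                seed=sf.get("seed", seed),
            )
            data = data.copy_with(np.concatenate(flipped))
            np.savetxt(out / "sign_flips.txt", sol.signs, fmt="%d")
            log["stages"]["signflip"] = {
                "status": "ok",
                "objective": sol.objective,
            }
        except Exception as exc:  # noqa: BLE001
            fail("signflip", exc)

    result = None
    if "fit" in stages:
        try:
            fc = cfg.get("fit", {})
            lagset = build_lag_set(fc.get("P", 35), fc.get("P0", 0), fc.get("Q", "uniform"))
            mcfg = HMMMARConfig(
                K=fc.get("K", 3),
                lagset=lagset,
                noise_cov=fc.get("noise_cov", "diagonal"),
                noise_shared=fc.get("noise_shared", False),
                symmetric_sigma=fc.get("symmetric_sigma", False),
                training=TrainingConfig(
                    max_cycles=fc.get("max_cycles", 100),
                    tol=fc.get("tol", 1e-5),
                    n_restarts=fc.get("n_restarts", 1),
                    seed=fc.get("seed", seed),
                ),
            )
            variant = fc.get("variant", "full")
            if variant != "full":
                from .inference import make_variant

                mcfg = make_variant(mcfg, variant, data=data)
            result = fit(data, mcfg)
            save_fit(result, out / "fit.h5")
            log["stages"]["fit"] = {
                "status": "ok",
                "seed": result.seed,
                "free_energy": [float(x) for x in result.free_energy_trace],
                "converged": result.converged,
                "low_occupancy_states": result.low_occupancy_states,
            }
        except Exception as exc:  # noqa: BLE001
            fail("fit", exc)

    est = None
    if "spectra" in stages:
        try:
            if result is None:
                raise RuntimeError("spectra stage requires a fit (missing input stage)")
            sp = cfg.get("spectra", {})
            tcfg = spectral.TaperConfig(
                R=sp.get("R", 7),
                NW=sp.get("NW", 4),
                window_length=sp.get("window_length"),
                window_step=sp.get("window_step"),
            )
            frange = (sp.get("fmin", 1.0), sp.get("fmax", min(48.0, data.fs / 2)))
            if sp.get("method", "multitaper") == "multitaper":
                est = spectral.statewise_multitaper(
                    data, result.stc, tcfg, freq_range=frange,
                    compute_pdc=sp.get("pdc", False),
                )
            else:
                from .model import parametric_spectra

                freqs = np.linspace(frange[0], frange[1], 200)
                W = [st.W_mean for st in result.posterior.states]
                S = [
                    result.posterior.expected_noise_covariance(k)
                    for k in range(result.posterior.K)
                ]
                est = parametric_spectra(W, S, result.config.lagset, freqs, data.fs)
            save_spectra(est, out / "spectra.h5")
            diag = spectral.gamma_spectrum_diagnostic(
                result.stc, data.fs, band=frange, segments=data.segments
            )
            log["stages"]["spectra"] = {
                "status": "ok",
                "gamma_band_fraction": [float(x) for x in diag["band_fraction"]],
                "gamma_flagged": [bool(x) for x in diag["flagged"]],
            }
        except Exception as exc:  # noqa: BLE001
            fail("spectra", exc)

    if "tf" in stages:
        try:
            if result is None or est is None:
                raise RuntimeError("tf stage requires fit and spectra stages")
            tfc = cfg.get("tf", {})
            window = tuple(tfc.get("window", (-2.0, 2.0)))
            baseline = tfc.get("baseline")
            events = np.asarray([s for _, s in data.events], int)
            maps = taskstats.tf_reconstruct(
                result.stc, est, events, window, data.fs,
                baseline_s=tuple(baseline) if baseline else None,
                measures=tuple(tfc.get("measures", ("psd",))),
                segments=data.segments,
            )
            with h5py.File(out / "tfmaps.h5", "w") as f:
                f.attrs["container"] = "hmmar-tf"
                for name, m in maps.items():
                    g = f.create_group(name)
                    g.create_dataset("times", data=m.times)
                    g.create_dataset("freqs", data=m.freqs)
                    g.create_dataset("values", data=m.values)
                    g.create_dataset("per_trial", data=m.per_trial)
            artefacts["tf_measures"] = list(maps)
            log["stages"]["tf"] = {"status": "ok", "n_events": len(events)}
            if "test" in stages:
                tc = cfg.get("test", {})
                first = maps[next(iter(maps))]
                obs = first.per_trial
                obs2 = obs.reshape(obs.shape[0], obs.shape[1], obs.shape[2], -1)[..., 0]
                res = taskstats.cluster_permutation_test(
                    obs2,
                    mode=tc.get("mode", "2d"),
                    cluster_threshold=tc.get("cluster_threshold", 3.0),
                    alpha=tc.get("alpha", 0.05),
                    n_perm=tc.get("n_perm", 1000),
                    seed=tc.get("seed", seed),
                )
                np.savetxt(out / "tf_sig_mask.txt", res["mask"].astype(int), fmt="%d")
                log["stages"]["test"] = {
                    "status": "ok",
                    "n_significant": int(res["mask"].sum()),
                }
        except Exception as exc:  # noqa: BLE001
            fail("tf", exc)

    yaml.safe_dump(log, open(log_path, "w"))
    artefacts["log"] = str(log_path)
    artefacts["result"] = result
    artefacts["spectra"] = est
    artefacts["truth"] = truth
    return artefacts
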