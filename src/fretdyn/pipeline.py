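"""End-to-end pipeline orchestration: simulate -> correlate -> fit -> classify.

A :class:`PipelineConfig` (built in code or from a YAML file) selects stages
and their parameter blocks; :func:`run_pipeline` executes them in dependency
order and writes an inspectable bundle into the output directory:

- ``photons.h5``           simulated photon stream (HDF5)
- ``trajectories.csv``     simulated binned trajectories (+ JSON sidecar)
- ``curves.csv``           correlation curves of all four pairs
- ``separate_report.json`` per-curve separate fits with rel.N / Delta tau_D
- ``global_fit.json``      shared-parameter global fit
- ``populations.json``     two-Gaussian decomposition + per-trajectory classes
- ``kinetics.json``        rates derived from tau_I and the populations
- ``provenance.json``      seed, config echo/hash, package version

Every output embeds the global seed and the config hash; a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .correlator import PAIRS, multitau_correlate, read_curves_csv, write_curves_csv
from .fcsmodels import (
    GlobalFitParams,
    build_separate_report,
    fit_global,
    fit_separate,
)
from .kinetics import rates_from_relaxation
from .photons import read_photons_hdf5, write_photons_hdf5
from .smfret import (
    FretCorrections,
    analyze_cohort,
    read_trajectories_csv,
    write_trajectories_csv,
)
from .synthetic import (
    DiffusionSimConfig,
    TrajectorySimConfig,
    simulate_fret_trajectories,
    simulate_photon_stream,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

_STAGES = (
    "simulate_photons",
    "simulate_trajectories",
    "correlate",
    "fit_separate",
    "fit_global",
    "fret_hist",
    "kinetics",
)


class PipelineError(RuntimeError):
    """Stage failure with context about the failing stage."""


@dataclass
class PipelineConfig:
    """Stage selection and per-stage parameter blocks.

    ``stages`` lists the stages to run (subset of the canonical order);
    unspecified parameter blocks use the generator/model defaults.  The
    global ``seed`` feeds every stage's randomness.  Input files may replace
    upstream stages (``photons_file``, ``curves_file``, ``trajectories_file``).
    """

    stages: tuple = _STAGES
    out_dir: str = "fretdyn_out"
    seed: int = 0
    photons: dict = field(default_factory=dict)
    trajectories: dict = field(default_factory=dict)
    correlate: dict = field(default_factory=dict)
    corrections: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    photons_file: str | None = None
    curves_file: str | None = None
    trajectories_file: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {_STAGES}")
        self.stages = tuple(s for s in _STAGES if s in self.stages)
        for name in ("photons_file", "curves_file", "trajectories_file"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValueError(f"{name} {path!r} does not exist")

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "out_dir": self.out_dir,
            "seed": self.seed,
            "photons": self.photons,
            "trajectories": self.trajectories,
            "correlate": self.correlate,
            "corrections": self.corrections,
            "fit": self.fit,
            "photons_file": self.photons_file,
            "curves_file": self.curves_file,
            "trajectories_file": self.trajectories_file,
        }

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded,
        so reruns into different directories stay byte-identical)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return PipelineConfig(**data)


def _write_json(path: Path, payload: dict, stamp: dict) -> None:
    payload = {"provenance": stamp, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages in dependency order.

    Returns a report bundle dict mapping artifact names to file paths plus
    the in-memory results.  A stage failure raises :class:`PipelineError`
    naming the stage; artifacts written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "fretdyn_version": _version,
    }
    bundle: dict = {"out_dir": str(out)}
    stream = None
    curves = None
    trajs = None

    def fail(stage, exc):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if config.photons_file:
        stream = read_photons_hdf5(config.photons_file)
    if config.curves_file:
        curves = read_curves_csv(config.curves_file)
    if config.trajectories_file:
        trajs = read_trajectories_csv(config.trajectories_file)

    for stage in config.stages:
        try:
            if stage == "simulate_photons":
                sim = DiffusionSimConfig(**{"seed": config.seed, **config.photons})
                stream = simulate_photon_stream(sim)
                path = out / "photons.h5"
                write_photons_hdf5(stream, path)
                bundle["photons"] = str(path)
            elif stage == "simulate_trajectories":
                sim = TrajectorySimConfig(
                    **{"seed": config.seed, **config.trajectories}
                )
                trajs = simulate_fret_trajectories(sim)
                path = out / "trajectories.csv"
                write_trajectories_csv(
                    trajs, path, sidecar_config={**sim.to_dict(), **stamp}
                )
                bundle["trajectories"] = str(path)
            elif stage == "correlate":
                if stream is None:
                    raise PipelineError(
                        "no photon stream: run 'simulate_photons' first or "
                        "provide photons_file"
                    )
                curves = {
                    pair: multitau_correlate(stream, pair, **config.correlate)
                    for pair in PAIRS
                }
                path = out / "curves.csv"
                write_curves_csv(curves, path)
                bundle["curves"] = str(path)
            elif stage == "fit_separate":
                if curves is None:
                    raise PipelineError(
                        "no correlation curves: run 'correlate' first or "
                        "provide curves_file"
                    )
                results = {
                    pair: fit_separate(curves[pair], seed=config.seed)
                    for pair in curves
                }
                report = build_separate_report(results)
                bundle["separate_results"] = results
                path = out / "separate_report.json"
                _write_json(path, {"separate_fit": report.to_dict()}, stamp)
                bundle["separate_report"] = str(path)
            elif stage == "fit_global":
                if curves is None:
                    raise PipelineError(
                        "no correlation curves: run 'correlate' first or "
                        "provide curves_file"
                    )
                init = None
                fit_kw = dict(config.fit)
                if "init" in fit_kw:
                    init = GlobalFitParams(**fit_kw.pop("init"))
                res = fit_global(curves, init=init, seed=config.seed, **fit_kw)
                bundle["global_results"] = res
                path = out / "global_fit.json"
                _write_json(
                    path,
                    {
                        "global_fit": res.params.to_dict(microseconds=True),
                        "std_errors": {
                            k: (v if np.isfinite(v) else None)
                            for k, v in res.bse.items()
                        },
                        "ssr": res.ssr,
                        "converged": res.converged,
                        "tau_i_identifiable": res.tau_i_identifiable,
                    },
                    stamp,
                )
                bundle["global_fit"] = str(path)
            elif stage == "fret_hist":
                if trajs is None:
                    raise PipelineError(
                        "no trajectories: run 'simulate_trajectories' first "
                        "or provide trajectories_file"
                    )
                corr = FretCorrections(**config.corrections)
                cohort = analyze_cohort(trajs, corr)
                bundle["cohort"] = cohort
                path = out / "populations.json"
                _write_json(
                    path,
                    {
                        "mixture": cohort["pair"].to_dict(),
                        "closed_population_pct": cohort["closed_population_pct"],
                        "classes": [
                            {"label": c.label, "n_closed": c.n_closed,
                             "n_open": c.n_open}
                            for c in cohort["classes"]
                        ],
                        "tally": cohort["tally"],
                        "n_bins_pooled": cohort["n_bins_pooled"],
                    },
                    stamp,
                )
                bundle["populations"] = str(path)
            elif stage == "kinetics":
                if "global_results" not in bundle:
                    raise PipelineError(
                        "no global fit: run 'fit_global' first (kinetics "
                        "needs the fitted tau_I)"
                    )
                if "cohort" not in bundle:
                    raise PipelineError(
                        "no population analysis: run 'fret_hist' first "
                        "(kinetics needs the open fraction)"
                    )
                tau_i = bundle["global_results"].params.tau_i
                p_open = 1.0 - bundle["cohort"]["pair"].weights[0]
                kin = rates_from_relaxation(tau_i, p_open)
                bundle["kinetics_result"] = kin
                path = out / "kinetics.json"
                _write_json(path, {"kinetics": kin.to_dict()}, stamp)
                bundle["kinetics"] = str(path)
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context
            fail(stage, exc)

    prov = out / "provenance.json"
    prov.write_text(
        json.dumps({**stamp, "config": config.to_dict()}, indent=2, sort_keys=True)
    )
    bundle["provenance"] = str(prov)
    return bundle
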