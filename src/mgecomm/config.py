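"""Experiment configuration and reproducible experiment runner.

An experiment is described by a small structured config (YAML or JSON, or a
plain dict): an experiment ``kind``, a model (inline document, packaged
fixture name, or sampler spec), run parameters, and a mandatory ``seed``.
:func:`run_experiment` dispatches to the corresponding library operation,
writes CSV results plus a JSON manifest sufficient to replay the run
bit-compatibly, and removes partial outputs on failure.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import CommunityModel
from .metacommunity import MetacommunityModel, diversity_vs_eta, integrate_metacommunity, sample_metacommunity
from .sampling import FIXTURES, SamplerSpec, sample_model
from .simulate import integrate
from .stability import bistability_fraction, cluster_attractors, eta_scan, phase_diagram, run_ensemble

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment"]

log = logging.getLogger("mgecomm")

CONFIG_SCHEMA = "mgecomm/experiment-v1"

KINDS = ("simulate", "ensemble", "phase_diagram", "eta_scan", "bistability_fraction", "metacommunity")


class ConfigError(ValueError):
    """A configuration document failed validation; the message names the field."""


@dataclass
class ExperimentConfig:
    """Validated description of one reproducible experiment."""

    kind: str
    seed: int
    outdir: str = "results"
    model: Optional[dict] = None  # inline CommunityModel document
    fixture: Optional[str] = None  # packaged fixture name
    sampler: Optional[dict] = None  # SamplerSpec document
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        schema = d.pop("schema", CONFIG_SCHEMA)
        if schema != CONFIG_SCHEMA:
            raise ConfigError(f"schema: unsupported value {schema!r}")
        if "kind" not in d or d["kind"] not in KINDS:
            raise ConfigError(f"kind: must be one of {KINDS}")
        if "seed" not in d or d["seed"] is None:
            raise ConfigError("seed: required field is missing")
        try:
            d["seed"] = int(d["seed"])
        except (TypeError, ValueError):
            raise ConfigError("seed: must be an integer")
        known = {"kind", "seed", "outdir", "model", "fixture", "sampler", "params"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        return cls.from_dict(doc)

    def validate(self) -> None:
        if self.fixture is not None and self.fixture not in FIXTURES:
            raise ConfigError(f"fixture: unknown name {self.fixture!r}; available: {sorted(FIXTURES)}")
        sources = [x is not None for x in (self.model, self.fixture, self.sampler)]
        if self.kind in ("simulate", "ensemble", "phase_diagram", "metacommunity") and not any(sources[:2]) and self.sampler is None:
            raise ConfigError("model: one of model/fixture/sampler is required")
        if self.kind in ("eta_scan", "bistability_fraction") and self.sampler is None:
            raise ConfigError("sampler: required for this experiment kind")
        if self.kind == "phase_diagram" and not (
            "mu1_values" in self.params and "mu2_values" in self.params
        ) and "mu_grid" not in self.params:
            raise ConfigError("params.mu1_values/mu2_values (or mu_grid) required for phase_diagram")
        if self.kind == "eta_scan" and "eta_values" not in self.params:
            raise ConfigError("params.eta_values: required for eta_scan")

    def to_dict(self) -> dict:
        d = {"schema": CONFIG_SCHEMA, "kind": self.kind, "seed": self.seed, "outdir": self.outdir, "params": self.params}
        for k in ("model", "fixture", "sampler"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    # ------------------------------------------------------------------
    def build_model(self) -> CommunityModel:
        if self.model is not None:
            return CommunityModel.from_dict(self.model)
        if self.fixture is not None:
            kwargs = self.params.get("fixture_args", {})
            return FIXTURES[self.fixture](**kwargs)
        if self.sampler is not None:
            spec = SamplerSpec.from_dict(self.sampler)
            return sample_model(spec, np.random.default_rng(self.seed))
        raise ConfigError("model: no model source configured")

    def build_sampler(self):
        spec = SamplerSpec.from_dict(self.sampler)

        def sampler(rng):
            return sample_model(spec, rng)

        return sampler


def _write_csv(df: pd.DataFrame, path: str, written: list) -> None:
    df.to_csv(path, index=False, float_format="%.12g")
    written.append(path)


def run_experiment(config: ExperimentConfig, outdir: Optional[str] = None) -> dict:
    """Run one experiment and write results + manifest under ``outdir``.

    Returns a summary dict (also stored in the manifest).  On failure all
    files written so far are removed before the error propagates.
    """
    outdir = outdir or config.outdir
    os.makedirs(outdir, exist_ok=True)
    written: list = []
    p = config.params
    seed = config.seed
    t_start = time.time()
    timings = {}
    try:
        if config.kind == "simulate":
            model = config.build_model()
            from .stability import sample_initial_conditions, default_carrier_mode
            inits, _ = sample_initial_conditions(
                model.m, 1, seed, carrier_mode=default_carrier_mode(model), donor_index=model.donor_index
            )
            traj = integrate(model, inits[0], p.get("t_end", 2000.0),
                             t_eval=np.linspace(0, p.get("t_end", 2000.0), p.get("n_points", 201)))
            _write_csv(traj.to_frame(), os.path.join(outdir, "trajectory.csv"), written)
            summary = {"t_end": float(traj.times[-1])}
        elif config.kind == "ensemble":
            model = config.build_model()
            if "eta" in p:
                model = model.with_eta(p["eta"])
            n_init = p.get("n_init", 500 if model.m > 2 else 200)
            threshold = p.get("threshold", 0.05 if model.m > 2 else 0.01)
            ens = run_ensemble(model, n_init=n_init, seed=seed, horizon=p.get("horizon", 2000.0))
            aset = cluster_attractors(ens, threshold=threshold)
            _write_csv(ens.to_frame(), os.path.join(outdir, "steady_states.csv"), written)
            _write_csv(aset.to_frame(), os.path.join(outdir, "attractors.csv"), written)
            summary = {"n_attractors": int(aset.n_attractors), "chi": aset.chi,
                       "n_converged": int(aset.n_converged), "n_init": n_init, "threshold": threshold}
        elif config.kind == "phase_diagram":
            model = config.build_model()
            if "eta" in p:
                model = model.with_eta(p["eta"])
            if "mu_grid" in p:
                g = p["mu_grid"]
                mu1 = mu2 = np.linspace(g["low"], g["high"], g["n"])
            else:
                mu1, mu2 = p["mu1_values"], p["mu2_values"]
            pd_ = phase_diagram(model, mu1, mu2, n_init=p.get("n_init", 200),
                                threshold=p.get("threshold", 0.01), seed=seed)
            _write_csv(pd_.to_frame(), os.path.join(outdir, "phase_diagram.csv"), written)
            summary = {"bistable_area_fraction": pd_.bistable_area_fraction}
        elif config.kind == "eta_scan":
            res = eta_scan(config.build_sampler(), p["eta_values"],
                           n_replicates=p.get("n_replicates", 10), n_init=p.get("n_init", 500),
                           threshold=p.get("threshold", 0.05), seed=seed)
            _write_csv(res.table, os.path.join(outdir, "eta_scan.csv"), written)
            _write_csv(res.summary, os.path.join(outdir, "eta_scan_summary.csv"), written)
            summary = {"onset_eta": res.onset_eta, "promotion_threshold": res.promotion_threshold}
        elif config.kind == "bistability_fraction":
            frac = bistability_fraction(config.build_sampler(), n_draws=p.get("n_draws", 500),
                                        n_init=p.get("n_init", 200), threshold=p.get("threshold", 0.01),
                                        seed=seed)
            _write_csv(pd.DataFrame([{"fraction": frac}]), os.path.join(outdir, "fraction.csv"), written)
            summary = {"fraction": frac}
        elif config.kind == "metacommunity":
            model = config.build_model()
            meta = MetacommunityModel(u=p.get("u", 10), v=p.get("v", 10),
                                      patch_model=model, omega=p.get("omega", 0.001))
            if "eta_values" in p:
                df = diversity_vs_eta(meta, p["eta_values"], seed=seed, t_end=p.get("t_end", 2000.0))
                _write_csv(df, os.path.join(outdir, "diversity.csv"), written)
                summary = {"regional_range": [float(df.regional.min()), float(df.regional.max())]}
            else:
                init = sample_metacommunity(meta, seed=seed)
                final, conv, res_, tf = integrate_metacommunity(meta, init, t_end=p.get("t_end", 2000.0))
                _write_csv(final.to_frame(), os.path.join(outdir, "final_state.csv"), written)
                from .metacommunity import regional_and_local_diversity
                regional, locals_ = regional_and_local_diversity(final)
                summary = {"regional": regional, "mean_local": float(np.nanmean(locals_)),
                           "converged": bool(conv), "t_final": tf}
        else:  # pragma: no cover - guarded by validate()
            raise ConfigError(f"kind: unknown {config.kind!r}")
        timings["total_s"] = time.time() - t_start
        manifest = {
            "config": config.to_dict(),
            "package_version": __version__,
            "numpy_version": np.__version__,
            "summary": summary,
            "timings": timings,
            "outputs": [os.path.basename(f) for f in written],
        }
        mpath = os.path.join(outdir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
        written.append(mpath)
        log.info("experiment %s finished in %.1fs -> %s", config.kind, timings["total_s"], outdir)
        return summary
    except Exception:
        for f in written:
            try:
                os.remove(f)
            except OSError:
                pass
        raise
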