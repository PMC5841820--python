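"""Run configuration, experiment dispatch and result serialisation.

A run is described by a hierarchical YAML configuration (see
``params/defaults.yaml``); every run writes its resolved configuration
next to the outputs so results carry full provenance.  Tabular outputs
are TSV with ``#``-prefixed header metadata stating units, sign
conventions and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hormones import TransferFunctions
from .metabolic import EnzymeParameterSet, glucose_exchange_flux, set_point
from .microcirculation import STUGeometry, SystemicParams, perfused_systemic
from .species import REACTION_INDEX
from .stu import (assemble_stu, half_life_decay, indicator_dilution,
                  steady_state_stu)
from .zonation import ZonationProfile, endpoint_params

log = logging.getLogger("hepstu")

EXPERIMENTS = ("cell-gef", "set-point", "dilution", "stu-steady", "refeed",
               "sensitivity", "montecarlo", "functiogram", "export-sbml")

SIGN_NOTE = ("positive glucose flux = hepatic uptake; "
             "dGlu_PV = portal minus venous (positive = uptake); "
             "axial position 1 = periportal pole")


class ConfigError(ValueError):
    """Invalid or unknown configuration entry (message carries the path)."""


def default_config() -> dict:
    with resources.files("hepstu.params").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, override: dict, path="") -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration field {here!r}")
        if isinstance(base[key], dict) and not key.endswith("overrides") \
                and key not in ("vmax", "alpha"):
            if not isinstance(val, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Resolved configuration of one run."""

    raw: dict

    @classmethod
    def load(cls, path=None, overrides: dict | None = None) -> "RunConfig":
        cfg = default_config()
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            cfg = _merge(cfg, user)
        if overrides:
            cfg = _merge(cfg, overrides)
        return cls(cfg)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def geometry(self) -> STUGeometry:
        g = self.raw["geometry"]
        return STUGeometry(radius=g["radius"], length=g["length"],
                           disse=g["disse"], hepatocyte=g["hepatocyte"],
                           n_cells=int(g["n_cells"]),
                           fenestration=g["fenestration"])

    def systemic(self) -> SystemicParams:
        s = self.raw["systemic"]
        preset = s.get("preset", "in_vivo")
        if preset == "in_vivo":
            base = SystemicParams()
        elif preset == "perfused":
            base = perfused_systemic()
        else:
            raise ConfigError(f"systemic.preset must be in_vivo or perfused, "
                              f"got {preset!r}")
        if s.get("overrides"):
            base = replace(base, **s["overrides"])
        return base

    def transfer(self) -> TransferFunctions:
        over = self.raw["hormones"].get("overrides") or {}
        return replace(TransferFunctions(), **over) if over \
            else TransferFunctions()

    def params_mh(self) -> EnzymeParameterSet:
        p = EnzymeParameterSet.default()
        vmax = self.raw["model"].get("vmax") or {}
        return p.with_vmax(vmax) if vmax else p

    def profile(self) -> ZonationProfile:
        prof = ZonationProfile.default(
            n_cells=int(self.raw["geometry"]["n_cells"]),
            params_mh=self.params_mh())
        over = self.raw["model"].get("alpha") or {}
        if over:
            alpha = dict(prof.alpha)
            alpha.update(over)
            prof = ZonationProfile(params_mh=prof.params_mh, alpha=alpha,
                                   sd=dict(prof.sd), n_cells=prof.n_cells)
        return prof

    def system(self):
        return assemble_stu(self.geometry(), self.profile(), self.systemic(),
                            self.transfer())


def write_results(df: pd.DataFrame, path, metadata: dict) -> Path:
    """TSV with '#'-prefixed header metadata; every quantity self-describes
    its units through the metadata and a ``units`` row requirement."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {key}: {value}" for key, value in metadata.items()]
    lines.append(f"# sign_conventions: {SIGN_NOTE}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_results(path):
    """Inverse of :func:`write_results`: returns (DataFrame, metadata)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition(": ")
            meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Execute the configured experiment; writes result tables and a
    resolved-config copy, returns {name: path} of everything written."""
    proto = config.raw["protocol"]
    name = proto["experiment"]
    if name not in EXPERIMENTS:
        raise ConfigError(
            f"unknown experiment {name!r}; valid names: {', '.join(EXPERIMENTS)}")
    out_dir = Path(out_dir or config.raw["output"]["directory"])
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    resolved = out_dir / "resolved_config.yaml"
    with open(resolved, "w") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=False)
    written["config"] = resolved
    meta = {"experiment": name, "seed": config.seed}

    if name == "cell-gef":
        grid = np.asarray(proto["glucose_grid"], dtype=float)
        prof = config.profile()
        pph, pch = endpoint_params(prof)
        rows = {"plasma_glucose_mM": grid}
        for label, ps in [("PPH", pph), ("MH", prof.params_mh), ("PCH", pch)]:
            rows[f"gef_{label}_mM_per_min"] = glucose_exchange_flux(
                ps, grid, proto["portal_lactate"])
        df = pd.DataFrame(rows)
        meta["units"] = "glucose mM; GEF mM/min on the cytosolic-volume basis"
        written["gef"] = write_results(df, out_dir / "cell_gef.tsv", meta)

    elif name == "set-point":
        prof = config.profile()
        pph, pch = endpoint_params(prof)
        df = pd.DataFrame({
            "cell": ["PPH", "MH", "PCH"],
            "set_point_mM": [set_point(pph), set_point(prof.params_mh),
                             set_point(pch)],
        })
        meta["units"] = "set-point mM plasma glucose"
        written["set_point"] = write_results(df, out_dir / "set_points.tsv", meta)

    elif name == "dilution":
        system = config.system()
        frames = []
        for tracer in ("rbc", "albumin", "water"):
            t, c = indicator_dilution(system, tracer,
                                      t_max=config.raw["dilution"]["t_max"])
            frames.append(pd.DataFrame({
                "time_s": t, "tracer": tracer, "outflow_normalized": c}))
            log.info("dilution %s: half-life %.1f s", tracer,
                     half_life_decay(t, c))
        df = pd.concat(frames, ignore_index=True)
        meta["units"] = "time s; outflow concentration normalised to unit bolus peak"
        written["dilution"] = write_results(df, out_dir / "dilution.tsv", meta)

    elif name == "stu-steady":
        system = config.system()
        r = steady_state_stu(system, proto["portal_glucose"],
                             proto["portal_lactate"])
        log.info("steady state residual %.2e", r.residual)
        df = pd.DataFrame({
            "cell_index": np.arange(1, system.n_cells + 1),
            "sinusoid_glucose_mM": r.sinusoid_glucose,
            "disse_glucose_mM": r.disse_glucose,
            "cell_glucose_mM": r.cell_glucose,
            "gef_mM_per_min": r.per_cell_gef,
            "glycogen_mM": r.glycogen,
        })
        meta["units"] = "concentrations mM; GEF mM/min cytosolic basis"
        meta["venous_glucose_mM"] = f"{r.venous_glucose:.6f}"
        meta["dGlu_PV_mM"] = f"{r.delta_glu_pv:.6f}"
        meta["insulin_extraction"] = f"{r.insulin_extraction:.4f}"
        meta["glucagon_extraction"] = f"{r.glucagon_extraction:.4f}"
        written["profiles"] = write_results(df, out_dir / "stu_profiles.tsv", meta)

    elif name == "refeed":
        from .experiments import starvation_refeeding_stu
        system = config.system()
        t, glyc = starvation_refeeding_stu(system)
        df = pd.DataFrame(glyc, columns=[f"cell_{i+1}"
                                         for i in range(glyc.shape[1])])
        df.insert(0, "time_h", t)
        meta["units"] = "time h; glycogen mM glucosyl units per cell"
        written["refeed"] = write_results(df, out_dir / "refeed_glycogen.tsv",
                                          meta)

    elif name == "sensitivity":
        from .experiments import sensitivity
        system = config.system()
        res = sensitivity(system, proto["parameter"], proto["portal_glucose"],
                          proto["epsilon"])
        df = pd.DataFrame([{"parameter": res.parameter,
                            "portal_glucose_mM": res.portal_glucose,
                            "S": res.value, "epsilon": res.epsilon}])
        meta["units"] = "S dimensionless (normalised central difference)"
        written["sensitivity"] = write_results(df, out_dir / "sensitivity.tsv",
                                               meta)

    elif name == "montecarlo":
        from .experiments import monte_carlo_porto_venous
        mc = monte_carlo_porto_venous(proto["glucose_grid"],
                                      n=int(proto["n_samples"]),
                                      seed=config.seed)
        log.info("Monte-Carlo: %d failures excluded", mc["failures"])
        df = pd.DataFrame({"portal_glucose_mM": mc["portal"],
                           "dGlu_PV_mean_mM": mc["mean"],
                           "dGlu_PV_sd_mM": mc["sd"]})
        meta["units"] = "glucose mM"
        meta["excluded_failures"] = mc["failures"]
        written["montecarlo"] = write_results(df, out_dir / "montecarlo.tsv",
                                              meta)

    elif name == "functiogram":
        from .experiments import functiogram, synthetic_perfusion_map
        pmap = synthetic_perfusion_map(proto["map_mean"], proto["map_sd"],
                                       tuple(proto["map_shape"]),
                                       seed=config.seed)
        flux, summary = functiogram(pmap, proto["portal_glucose"],
                                    system=config.system())
        df = pd.DataFrame({"flow_ml_100ml_min": pmap.flow.ravel(),
                           "flux_umol_g_h": flux.ravel()})
        meta["units"] = "flow ml/100ml/min; flux umol/g/h (negative = release)"
        for key, value in summary.items():
            meta[key] = f"{value:.4f}"
        written["functiogram"] = write_results(df, out_dir / "functiogram.tsv",
                                               meta)

    elif name == "export-sbml":
        from .sbml import export_sbml, validate_sbml
        doc = export_sbml(config.params_mh())
        issues = validate_sbml(doc)
        if issues:
            raise ConfigError("SBML validation failed: " + "; ".join(issues))
        path = out_dir / "hepatocyte_model.xml"
        path.write_bytes(doc)
        written["sbml"] = path

    return written
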