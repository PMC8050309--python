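"""Sensorgram I/O, configuration and deterministic fixture generation.

CSV dialect: comma-separated, UTF-8, time column first, one column per curve.
Metadata travels in '#'-prefixed header lines of the form ``# key = value``;
per-curve metadata and the provenance block are JSON-encoded under the keys
``curve.<i>`` and ``provenance``.  The dialect is close to common instrument
exports while remaining trivially parseable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core_models import KineticConstants
from .ode_simulator import (
    InjectionProgram,
    kt_from_response_scaled,
    simulate_two_compartment,
    simulate_rebinding_dissociation,
)
from .sensorgram import Sensorgram

__all__ = [
    "read_sensorgram_csv",
    "write_sensorgram_csv",
    "write_field_snapshot",
    "load_config",
    "default_config",
    "FIXTURES",
    "generate_fixture",
]


class SensorgramParseError(ValueError):
    """Malformed sensorgram file; the message names the offending row/column."""


def write_sensorgram_csv(sg: Sensorgram, path: str | Path) -> None:
    """Write a sensorgram with its metadata; round-trips losslessly."""
    path = Path(path)
    lines = ["# rebindkin sensorgram v1"]
    if sg.provenance:
        lines.append(f"# provenance = {json.dumps(sg.provenance, sort_keys=True)}")
    for i, meta in enumerate(sg.metadata):
        lines.append(f"# curve.{i} = {json.dumps(meta, sort_keys=True)}")
    header = ",".join(["time"] + sg.labels())

    def fmt(v: float) -> str:
        return format(float(v), ".17g")

    body = "\n".join(
        ",".join([fmt(t)] + [fmt(v) for v in row])
        for t, row in zip(sg.time, sg.response))
    path.write_text("\n".join(lines + [header, body]) + "\n", encoding="utf-8")


def read_sensorgram_csv(path: str | Path) -> Sensorgram:
    """Read the CSV dialect above (tolerates plain comment header lines)."""
    path = Path(path)
    provenance: dict[str, Any] = {}
    curve_meta: dict[int, dict] = {}
    data_lines: list[str] = []
    header: list[str] | None = None
    for ln, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            content = line.lstrip("#").strip()
            if "=" in content:
                key, _, val = content.partition("=")
                key, val = key.strip(), val.strip()
                if key == "provenance":
                    provenance = json.loads(val)
                elif key.startswith("curve."):
                    curve_meta[int(key.split(".", 1)[1])] = json.loads(val)
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            continue
        data_lines.append(line)
    if header is None or not data_lines:
        raise SensorgramParseError(f"{path}: no data found")
    ncol = len(header)
    rows = []
    for ln, line in enumerate(data_lines, 1):
        parts = line.split(",")
        if len(parts) != ncol:
            raise SensorgramParseError(
                f"{path}: data row {ln} has {len(parts)} columns, expected {ncol}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise SensorgramParseError(f"{path}: data row {ln}: {exc}") from exc
    arr = np.asarray(rows)
    time, resp = arr[:, 0], arr[:, 1:]
    if np.any(np.diff(time) <= 0):
        bad = int(np.flatnonzero(np.diff(time) <= 0)[0]) + 2
        raise SensorgramParseError(
            f"{path}: time not strictly increasing at data row {bad}")
    metadata = [dict(curve_meta.get(i, {}), label=header[i + 1])
                for i in range(resp.shape[1])]
    return Sensorgram(time, resp, metadata, provenance)


def write_field_snapshot(field: np.ndarray, path: str | Path,
                         metadata: dict | None = None) -> None:
    """Plain-matrix field snapshot with a JSON sidecar (``<path>.meta.json``)."""
    path = Path(path)
    np.savetxt(path, np.asarray(field), delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(metadata or {}, sort_keys=True, indent=1),
                       encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = {
    "kinetics": {"ka": 1e6, "kd": 1e-3, "ka_p": 1e7, "kd_p": 0.05, "kinact": 0.0},
    "transport": {"nu_c": 0.1, "D_A": 5e-10},
    "surface": {"P": 1e-3, "G": 100.0, "Mr_B": 30000.0, "Mr_A": 200.0},
    "geometry": {"h": 20e-6, "l_channel": 0.5e-3, "gel_length": 0.2e-3,
                 "Hgel": 200e-9},
    "hydrogel": {"p_nominal": 1e-3, "density_steepness": 100.0,
                 "viscosity_factor": 2.0},
    "injection": {"contact_time": 300.0, "conc_target": 0.0,
                  "conc_inhibitor": 1e-3},
    "detection": {"sample_rate": 1.0, "noise_rms": 0.03, "seed": 0},
    "mesh": {"nx": 96, "n_gel": 20, "n_bulk": 32},
}


def default_config() -> dict:
    """Full default configuration (deep copy), dumpable as YAML."""
    return {sec: dict(vals) for sec, vals in _CONFIG_SECTIONS.items()}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    """Load a sectioned YAML config, validating every key against defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if section not in cfg:
            raise ConfigError(f"unknown config section [{section}]")
        if not isinstance(values, dict):
            raise ConfigError(f"section [{section}] must map keys to values")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ConfigError(f"unknown config key [{section}] {key}")
            cfg[section][key] = val
    return cfg


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _fixture_two_compartment_da_series(seed: int, overrides: dict) -> tuple[dict, dict]:
    """Mass-transport-limited 1:1 binding at Da = 100, 10, 1.

    Three association/dissociation curves of 10 nM target on a 20 RU surface
    (ka' = 5e7, kd' = 0.05) at response-scaled transport coefficients
    1e7, 1e8 and 1e9.
    """
    params = {"ka_p": 5e7, "kd_p": 0.05, "rmax": 20.0, "conc": 10e-9,
              "kt_resp": [1e7, 1e8, 1e9], "mr_b": 30000.0, "g": 100.0,
              "contact_time": 600.0, "dissociation_time": 600.0}
    params.update(overrides)
    k = KineticConstants(ka_p=params["ka_p"], kd_p=params["kd_p"])
    prog = InjectionProgram.pulse(params["contact_time"], params["conc"],
                                  params["dissociation_time"])
    parts = []
    for kt_resp in params["kt_resp"]:
        kt = kt_from_response_scaled(kt_resp, params["g"], params["mr_b"])
        sg = simulate_two_compartment(k, kt, params["rmax"], prog,
                                      g=params["g"], mr_b=params["mr_b"])
        da = params["ka_p"] * params["rmax"] / kt_resp
        sg.metadata[0].update(label=f"Da_{da:g}", Da=da, kt_resp=kt_resp,
                              conc=params["conc"],
                              contact_time=params["contact_time"])
        parts.append(sg)
    sg = Sensorgram.concat(parts)
    sg.provenance.update(generator="fixture:two_compartment_da_series", seed=seed)
    return {"curves": sg}, params


def _fixture_synthetic_rebinding_workflow(seed: int, overrides: dict) -> tuple[dict, dict]:
    """Closed-form rebinding workflow curve set (synthetic stand-in for an
    experimental inhibitor dose series; all constants are fit-derived values
    of a probe/target pair, not measured data)."""
    from .core_models import (probe_concentration_from_rmax,
                              rebinding_factor_alpha, rebinding_response)

    params = {"ka": 3.07e6, "kd": 0.125, "ka_p": 8.5e4, "kd_p": 0.075,
              "kt": 10.55, "rmax": 1025.0, "r0": 118.0, "mr_b": 22000.0,
              "a_series": [0.0, 0.016e-6, 0.6e-6, 4e-6],
              "duration": 120.0, "noise_rms": 0.0}
    params.update(overrides)
    p = probe_concentration_from_rmax(params["rmax"], 100.0, params["mr_b"])
    k = KineticConstants(ka=params["ka"], kd=params["kd"],
                         ka_p=params["ka_p"], kd_p=params["kd_p"])
    t = np.arange(0.0, params["duration"] + 1.0)
    curves, metas = [], []
    for a in params["a_series"]:
        alpha, _, _ = rebinding_factor_alpha(k, params["kt"], p, a)
        curves.append(rebinding_response(params["r0"], params["kd_p"], alpha, t))
        metas.append({"A": a, "label": f"A_{a:g}", "Mr_B": params["mr_b"],
                      "Rmax": params["rmax"]})
    resp = np.column_stack(curves)
    if params["noise_rms"] > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, params["noise_rms"], resp.shape)
    sg = Sensorgram(t, resp, metas,
                    {"generator": "fixture:synthetic_rebinding_workflow",
                     "seed": seed, **{k_: v for k_, v in params.items()
                                      if not isinstance(v, list)}})
    return {"curves": sg}, params


def _fixture_transient_grid(seed: int, overrides: dict) -> tuple[dict, dict]:
    """Inhibition curves over a (ka, kd, kinact) grid.

    Default grid: 6 ka x 4 kd x 2 kinact = 48 curves, generated with the
    two-compartment rebinding simulator (fast, deterministic); the flow-cell
    simulator can regenerate any subset for spatially resolved checks.
    """
    params = {"ka_grid": [1e4, 1e5, 1e6, 1e7, 1e8, 1e9],
              "kd_grid": [0.0, 0.1, 1.0, 10.0],
              "kinact_grid": [0.0, 1.0],
              "ka_p": 1e7, "kd_p": 0.05, "kt": 300.0, "rmax": 3000.0,
              "r0": 300.0, "a": 1e-3, "duration": 300.0, "mr_b": 30000.0}
    params.update(overrides)
    k0 = dict(ka_p=params["ka_p"], kd_p=params["kd_p"])
    parts = []
    for ka in params["ka_grid"]:
        for kd in params["kd_grid"]:
            for kinact in params["kinact_grid"]:
                k = KineticConstants(ka=ka, kd=kd, kinact=kinact, **k0)
                sg = simulate_rebinding_dissociation(
                    k, params["kt"], params["rmax"], params["r0"],
                    params["a"], params["duration"], mr_b=params["mr_b"])
                sg.metadata[0].update(
                    label=f"ka{ka:g}_kd{kd:g}_ki{kinact:g}",
                    ka=ka, kd=kd, kinact=kinact)
                parts.append(sg)
    sg = Sensorgram.concat(parts)
    sg.provenance.update(generator="fixture:transient_grid", seed=seed)
    return {"curves": sg}, params


def _fixture_inhibition_ladder(seed: int, overrides: dict) -> tuple[dict, dict]:
    """Flow-cell inhibition ladder study table (see studies module)."""
    from .studies import SurrogateStudyConfig, inhibition_ladder_study
    from .flowcell_sim import FlowCellGeometry

    params = {"n_rungs": 6, "ka_start": 3e5, "ladder_step": 3.375,
              "a": 0.5e-3, "kd": 1e-3}
    params.update(overrides)
    cfg = SurrogateStudyConfig(geometry=FlowCellGeometry(h=10e-6),
                               duration=300.0, noise_rms=0.03)
    table = inhibition_ladder_study(
        cfg, ka_start=params["ka_start"], ladder_step=params["ladder_step"],
        n_rungs=params["n_rungs"], a=params["a"], kd=params["kd"], seed=seed)
    return {"table": table}, params


def _fixture_montecarlo_recovery(seed: int, overrides: dict) -> tuple[dict, dict]:
    """Small Monte-Carlo recovery table for both assay formats."""
    from .studies import RecoveryStudySpec, run_recovery_study

    params = {"n_draws": 25}
    params.update(overrides)
    out = {}
    for fmt in ("rebinding", "competitive"):
        spec = RecoveryStudySpec(assay_format=fmt, n_draws=params["n_draws"],
                                 seed=seed)
        out[fmt] = run_recovery_study(spec)
    return out, params


FIXTURES = {
    "two_compartment_da_series": _fixture_two_compartment_da_series,
    "synthetic_rebinding_workflow": _fixture_synthetic_rebinding_workflow,
    "transient_grid": _fixture_transient_grid,
    "inhibition_ladder": _fixture_inhibition_ladder,
    "montecarlo_recovery": _fixture_montecarlo_recovery,
}


def generate_fixture(name: str, seed: int = 0,
                     overrides: dict | None = None) -> tuple[dict, dict]:
    """Generate a named fixture deterministically.

    Returns ``(objects, manifest)`` where ``objects`` maps names to
    Sensorgrams or DataFrames and ``manifest`` lists every parameter used.
    The same name and seed always produce identical output.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}")
    objects, params = FIXTURES[name](seed, dict(overrides or {}))
    manifest = {"fixture": name, "seed": seed, "parameters": params}
    return objects, manifest


def write_fixture(name: str, out_dir: str | Path, seed: int = 0,
                  overrides: dict | None = None) -> list[Path]:
    """Generate a fixture and write its artifacts under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    objects, manifest = generate_fixture(name, seed, overrides)
    written = []
    for key, obj in objects.items():
        if isinstance(obj, Sensorgram):
            p = out_dir / f"{name}_{key}.csv"
            write_sensorgram_csv(obj, p)
        elif isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}_{key}.csv"
            obj.to_csv(p, index=False)
        else:  # pragma: no cover
            continue
        written.append(p)
    mp = out_dir / f"{name}_manifest.json"
    mp.write_text(json.dumps(manifest, sort_keys=True, indent=1, default=str),
                  encoding="utf-8")
    written.append(mp)
    return written
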