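"""YAML/JSON serialisation of process chains.

Schema (YAML or JSON): top-level keys ``cqas``, ``parameters`` and
``unit_operations`` (in process order).  Each unit operation carries a
``models`` mapping CQA name → model document with a ``kind`` of ``doe``,
``load``, ``both`` or ``fixed``; absent CQAs are pass-through.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .process_chain import (DoEModel, FixedClearance, LoadModel, ProcessChain,
                            ProcessParameter, QualityAttribute, UnitOperation)

__all__ = ["chain_to_dict", "chain_from_dict", "save_chain", "load_chain"]


def _doe_to_dict(m: DoEModel) -> dict:
    return {"terms": list(m.terms), "beta": list(m.beta), "beta0": m.beta0,
            "rmse": m.rmse, "n_runs": m.n_runs, "n_params": m.n_params}


def _load_to_dict(m: LoadModel) -> dict:
    return {"beta_slc": m.beta_slc, "beta0": m.beta0, "rmse": m.rmse,
            "mean_slc_doe": m.mean_slc_doe}


def chain_to_dict(chain: ProcessChain) -> dict:
    doc: dict = {"cqas": [], "parameters": [], "unit_operations": []}
    for c in chain.cqas:
        doc["cqas"].append({
            "name": c.name, "kind": c.kind, "lsl": c.lsl, "usl": c.usl,
            "start_mean": c.start_mean, "start_sd": c.start_sd})
    for p in chain.parameters:
        doc["parameters"].append({
            "name": p.name, "uo": p.uo, "set_point": p.set_point,
            "nor": [p.nor_low, p.nor_high], "sr": [p.sr_low, p.sr_high]})
    for uo in chain.ordered_uos():
        models = {}
        for cqa, spec in uo.models.items():
            kind = uo.model_kind(cqa)
            if kind == "doe":
                models[cqa] = {"kind": "doe", **_doe_to_dict(spec)}
            elif kind == "load":
                models[cqa] = {"kind": "load", **_load_to_dict(spec)}
            elif kind == "both":
                models[cqa] = {"kind": "both",
                               "doe": _doe_to_dict(spec[0]),
                               "load": _load_to_dict(spec[1])}
            else:
                models[cqa] = {"kind": "fixed", "sc_mean": spec.sc_mean,
                               "sc_sd": spec.sc_sd}
        doc["unit_operations"].append({"name": uo.name, "models": models})
    return doc


def _doe_from_dict(uo: str, cqa: str, d: dict) -> DoEModel:
    return DoEModel(uo=uo, cqa=cqa, terms=tuple(d["terms"]),
                    beta=tuple(d["beta"]), beta0=float(d["beta0"]),
                    rmse=float(d["rmse"]), n_runs=int(d["n_runs"]),
                    n_params=int(d.get("n_params", len(d["terms"]))))


def _load_from_dict(uo: str, cqa: str, d: dict) -> LoadModel:
    return LoadModel(uo=uo, cqa=cqa, beta_slc=float(d["beta_slc"]),
                     beta0=float(d["beta0"]), rmse=float(d["rmse"]),
                     mean_slc_doe=float(d["mean_slc_doe"]))


def chain_from_dict(doc: dict) -> ProcessChain:
    try:
        cqas = [QualityAttribute(
            name=c["name"], kind=c["kind"],
            lsl=None if c.get("lsl") is None else float(c["lsl"]),
            usl=None if c.get("usl") is None else float(c["usl"]),
            start_mean=float(c["start_mean"]), start_sd=float(c["start_sd"]))
            for c in doc["cqas"]]
        params = [ProcessParameter(
            name=p["name"], uo=p["uo"], set_point=float(p["set_point"]),
            nor_low=float(p["nor"][0]), nor_high=float(p["nor"][1]),
            sr_low=float(p["sr"][0]), sr_high=float(p["sr"][1]))
            for p in doc["parameters"]]
        uos = []
        for order, u in enumerate(doc["unit_operations"], start=1):
            models = {}
            for cqa, m in (u.get("models") or {}).items():
                kind = m["kind"]
                if kind == "doe":
                    models[cqa] = _doe_from_dict(u["name"], cqa, m)
                elif kind == "load":
                    models[cqa] = _load_from_dict(u["name"], cqa, m)
                elif kind == "both":
                    models[cqa] = (_doe_from_dict(u["name"], cqa, m["doe"]),
                                   _load_from_dict(u["name"], cqa, m["load"]))
                elif kind == "fixed":
                    models[cqa] = FixedClearance(
                        uo=u["name"], cqa=cqa, sc_mean=float(m["sc_mean"]),
                        sc_sd=float(m["sc_sd"]))
                else:
                    raise ConfigurationError(f"unknown model kind {kind!r}")
            uos.append(UnitOperation(name=u["name"], order=order, models=models))
    except (KeyError, TypeError, IndexError) as exc:
        raise ConfigurationError(f"malformed chain document: {exc!r}") from exc
    return ProcessChain(unit_operations=uos, parameters=params, cqas=cqas)


def save_chain(chain: ProcessChain, path: str | Path) -> None:
    path = Path(path)
    doc = chain_to_dict(chain)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_chain(path: str | Path) -> ProcessChain:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"chain file not found: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return chain_from_dict(doc)
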