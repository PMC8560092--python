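"""CSV / JSON / YAML interchange for traces, networks, priors and ensembles."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .inference import PosteriorEnsemble, PriorEntry, PriorSpec
from .network import Condition, ReactionNetwork
from .simulate import EmissionTrace

__all__ = [
    "traces_to_csv",
    "traces_from_csv",
    "network_to_json",
    "prior_to_yaml",
    "prior_from_yaml",
    "ensemble_to_csv",
    "write_manifest",
]

_COND_FIELDS = ("camp_dose", "with_cn", "with_akap", "rii_variant", "label")


def traces_to_csv(traces: list[EmissionTrace], path: str | Path) -> None:
    """Long-format CSV: one row per sample, condition fields repeated."""
    rows = []
    for i, tr in enumerate(traces):
        cond = tr.condition
        for t, r, p in zip(tr.times, tr.ratio, tr.percent_full_scale):
            row = {"trace": i, "time_s": t, "ratio": r, "percent_full_scale": p,
                   "gain": tr.gain, "baseline_ratio": tr.baseline_ratio}
            if cond is not None:
                for f in _COND_FIELDS:
                    row[f] = getattr(cond, f)
                for k, v in cond.totals.items():
                    row[f"total_{k}"] = v
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def traces_from_csv(path: str | Path) -> list[EmissionTrace]:
    df = pd.read_csv(path)
    traces = []
    for _, g in df.groupby("trace", sort=True):
        cond = None
        if "camp_dose" in g.columns:
            totals = {
                c.removeprefix("total_"): float(g[c].iloc[0])
                for c in g.columns if c.startswith("total_")
            }
            cond = Condition(
                totals, float(g["camp_dose"].iloc[0]),
                bool(g["with_cn"].iloc[0]), bool(g["with_akap"].iloc[0]),
                str(g["rii_variant"].iloc[0]),
                label=str(g["label"].iloc[0]),
            )
        traces.append(EmissionTrace(
            g["time_s"].to_numpy(), g["ratio"].to_numpy(),
            g["percent_full_scale"].to_numpy(), cond,
            float(g["gain"].iloc[0]), float(g["baseline_ratio"].iloc[0]),
        ))
    return traces


def network_to_json(network: ReactionNetwork, path: str | Path | None = None) -> dict:
    doc = {
        "variant": network.variant,
        "species": [
            {"id": s.id, "name": s.name, "pool": s.pool} for s in network.species
        ],
        "reactions": [
            {
                "name": r.name, "kind": r.kind,
                "reactants": list(r.reactants), "products": list(r.products),
                "kf": r.kf, "kr": r.kr,
            }
            for r in network.reactions
        ],
        "conserved_moieties": {
            name: vec.tolist() for name, vec in network.conserved_moieties
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def prior_to_yaml(prior: PriorSpec, path: str | Path) -> None:
    doc = [
        {"parameter": name, "default": e.default, "low": e.low,
         "high": e.high, "frozen": e.frozen}
        for name, e in prior.entries.items()
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def prior_from_yaml(path: str | Path) -> PriorSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return PriorSpec({
        d["parameter"]: PriorEntry(
            float(d["default"]), float(d["low"]), float(d["high"]),
            bool(d.get("frozen", False)),
        )
        for d in doc
    })


def ensemble_to_csv(
    ensemble: PosteriorEnsemble, path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    ensemble.to_frame().to_csv(path, index=False)
    if manifest_path is not None:
        write_manifest(manifest_path, {
            "seed": ensemble.seed,
            "n_draws": ensemble.n_draws,
            "n_accepted": ensemble.n_accepted,
            "n_failed": ensemble.n_failed,
            "threshold": ensemble.threshold,
            "akap_mode": ensemble.akap_mode,
        })


def write_manifest(path: str | Path, payload: dict) -> None:
    from . import __version__

    doc = {"package": "pkacn", "version": __version__, **payload}
    Path(path).write_text(json.dumps(doc, indent=1, default=str))
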