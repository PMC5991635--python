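"""Tidy-CSV serialization of trajectories/ensembles and run manifests."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .adapt import Ensemble, ParameterTrajectory

__all__ = [
    "ensemble_to_csv",
    "ensemble_from_csv",
    "trajectory_to_frame",
    "write_manifest",
]

_KINDS = ("state", "flux", "param")


def trajectory_to_frame(traj: ParameterTrajectory,
                        member: int | None = None) -> pd.DataFrame:
    """Long-format frame: member, day, kind, name, value."""
    frames = []
    for kind, arr, names in (
            ("state", traj.states, traj.pool_names),
            ("flux", traj.fluxes, traj.flux_names),
            ("param", traj.params, traj.param_names)):
        if arr.size == 0:
            continue
        df = pd.DataFrame(arr, columns=list(names))
        df["day"] = traj.days
        long = df.melt(id_vars="day", var_name="name", value_name="value")
        long["kind"] = kind
        frames.append(long)
    meta = pd.DataFrame([
        {"day": 0.0, "name": "wsse_total", "value": traj.wsse_total,
         "kind": "meta"},
        {"day": 0.0, "name": "penalty", "value": traj.penalty,
         "kind": "meta"},
    ])
    frames.append(meta)
    out = pd.concat(frames, ignore_index=True)
    out["member"] = traj.seed if member is None else member
    return out[["member", "day", "kind", "name", "value"]]


def ensemble_to_csv(ensemble: Ensemble, path) -> None:
    frames = [trajectory_to_frame(m) for m in ensemble.members]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def ensemble_from_csv(path) -> Ensemble:
    """Rebuild an ensemble from its tidy CSV (analysis-grade: only the
    stored kinds are populated)."""
    df = pd.read_csv(path)
    members = []
    for seed, mdf in df.groupby("member", sort=True):
        days = np.array(
            sorted(mdf.loc[mdf["kind"] != "meta", "day"].unique()))
        data = {}
        names = {}
        for kind in _KINDS:
            kdf = mdf[mdf["kind"] == kind]
            if kdf.empty:
                data[kind] = np.zeros((len(days), 0))
                names[kind] = ()
                continue
            wide = kdf.pivot_table(index="day", columns="name",
                                   values="value", sort=True)
            data[kind] = wide.to_numpy()
            names[kind] = tuple(wide.columns)
        meta = dict(zip(mdf.loc[mdf["kind"] == "meta", "name"],
                        mdf.loc[mdf["kind"] == "meta", "value"]))
        members.append(ParameterTrajectory(
            days=days, params=data["param"], states=data["state"],
            fluxes=data["flux"], data_error=np.zeros(len(days)),
            penalty=float(meta.get("penalty", 0.0)),
            wsse_total=float(meta.get("wsse_total", np.nan)),
            seed=int(seed), param_names=names["param"],
            pool_names=names["state"], flux_names=names["flux"]))
    return Ensemble(members)


def write_manifest(path, command: str, seed: int | None,
                   settings: dict) -> None:
    """Reproducibility record written alongside every CLI output."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "settings": settings,
        "package_version": __version__,
        "python": platform.python_version(),
        "created": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
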