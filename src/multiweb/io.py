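"""Serialization of networks, results and run manifests.

Everything is plain text: species tables and edge lists as headered CSV
(0-based integer species ids, floats at 12 significant digits), manifests
as JSON.  A saved multiplex network round-trips losslessly.
"""

from __future__ import annotations

import json
import platform

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig
from .generation import MultiplexNetwork, NTILayer, SpeciesTraits, TrophicWeb

__all__ = [
    "species_table",
    "save_network",
    "load_network",
    "write_table",
    "read_table",
    "make_manifest",
    "save_manifest",
]

FLOAT_FORMAT = "%.12g"


def species_table(network: MultiplexNetwork) -> pd.DataFrame:
    """Per-species table: id, plant/sessile flags, trophic levels, mass."""
    tr = network.traits
    web = network.web
    return pd.DataFrame({
        "id": np.arange(web.S),
        "is_plant": web.is_plant.astype(int),
        "is_sessile": tr.is_sessile.astype(int),
        "TL": tr.TL,
        "TL_shortest": (tr.TL_shortest if tr.TL_shortest is not None
                        else np.full(web.S, np.nan)),
        "mass": tr.mass,
        "niche_value": web.niche_values,
    })


def _edge_table(matrix: np.ndarray, cols: tuple[str, str]) -> pd.DataFrame:
    src, tgt = np.nonzero(matrix)
    return pd.DataFrame({cols[0]: src, cols[1]: tgt})


def save_network(network: MultiplexNetwork, directory: str | Path) -> None:
    """Write species table, trophic edge list and NTI layer edge lists."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    species_table(network).to_csv(d / "species.csv", index=False,
                                  float_format=FLOAT_FORMAT)
    _edge_table(network.web.adjacency, ("consumer_id", "resource_id")).to_csv(
        d / "trophic_edges.csv", index=False)
    rows = []
    meta = []
    for t, layer in network.layers.items():
        src, tgt = np.nonzero(layer.presence)
        rows.append(pd.DataFrame({
            "nti_type": t, "source_id": src, "target_id": tgt}))
        meta.append({"nti_type": t, "probability": layer.probability,
                     "intensity": layer.intensity})
    edges = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["nti_type", "source_id", "target_id"]))
    edges.to_csv(d / "nti_edges.csv", index=False)
    pd.DataFrame(meta, columns=["nti_type", "probability", "intensity"]).to_csv(
        d / "nti_layers.csv", index=False, float_format=FLOAT_FORMAT)


def load_network(directory: str | Path) -> MultiplexNetwork:
    """Inverse of :func:`save_network`."""
    d = Path(directory)
    try:
        sp = pd.read_csv(d / "species.csv")
        te = pd.read_csv(d / "trophic_edges.csv")
        ne = pd.read_csv(d / "nti_edges.csv")
        nl = pd.read_csv(d / "nti_layers.csv")
    except (pd.errors.ParserError, FileNotFoundError) as exc:
        raise ValueError(f"cannot read network from {d}: {exc}") from exc
    S = len(sp)
    for col in ("id", "is_plant", "is_sessile", "TL", "mass"):
        if col not in sp.columns:
            raise ValueError(f"species.csv: missing column {col!r}")
    adjacency = np.zeros((S, S), dtype=bool)
    adjacency[te["consumer_id"].to_numpy(), te["resource_id"].to_numpy()] = True
    web = TrophicWeb(
        S=S, adjacency=adjacency,
        is_plant=sp["is_plant"].to_numpy(dtype=bool),
        niche_values=(sp["niche_value"].to_numpy(dtype=float)
                      if "niche_value" in sp.columns else np.full(S, np.nan)),
    )
    sTL = (sp["TL_shortest"].to_numpy(dtype=float)
           if "TL_shortest" in sp.columns else None)
    traits = SpeciesTraits(
        is_sessile=sp["is_sessile"].to_numpy(dtype=bool),
        TL=sp["TL"].to_numpy(dtype=float),
        mass=sp["mass"].to_numpy(dtype=float),
        TL_shortest=sTL,
    )
    layers = {}
    for _, row in nl.iterrows():
        t = row["nti_type"]
        presence = np.zeros((S, S), dtype=bool)
        sel = ne[ne["nti_type"] == t]
        presence[sel["source_id"].to_numpy(), sel["target_id"].to_numpy()] = True
        layers[t] = NTILayer(nti_type=t, presence=presence,
                             probability=float(row["probability"]),
                             intensity=float(row["intensity"]))
    return MultiplexNetwork(web=web, traits=traits, layers=layers)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def make_manifest(config: ModelConfig, seed: int, stage: str,
                  tallies: dict | None = None, extra: dict | None = None) -> dict:
    """Run manifest: config snapshot, seed, code version, tallies.

    Re-running the same manifest reproduces all outputs bit-for-bit.
    """
    return {
        "stage": stage,
        "seed": int(seed),
        "multiweb_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "tallies": dict(tallies or {}),
        **(extra or {}),
    }


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
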