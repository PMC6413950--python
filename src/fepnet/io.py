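"""Plain-text file formats of the pipeline.

Everything external is columnar text (TSV/CSV) or JSON, serialized at
full precision with a fixed column order so outputs diff reproducibly.
External free energies are always kcal/mol.

Formats
-------
network spec        JSON: ligands, directed edges, reference ligand
reduced potentials  TSV: leg_id, repeat, origin_state, sample_index, u_0..u_{K-1}
leg estimates       CSV: edge_id, source, target, environment, repeat,
                    value_kcal_mol, sigma_kcal_mol
edge estimates      CSV: aggregated directed edges
ligand estimates    CSV: absolute per-ligand dG
experimental table  CSV: ligand_id plus ki_molar and/or dg_kcal_mol
cycle report        JSON: cycle closures, flags, ligand ranking
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from .diagnostics import CycleReport, FlagReport
from .estimators import ReducedPotentialMatrix
from .network import (
    EdgeEstimate,
    Ligand,
    PerturbationNetwork,
    ki_to_dg,
)
from .values import FreeEnergyValue, ValueKind

__all__ = [
    "write_network_spec", "read_network_spec",
    "write_reduced_potentials", "read_reduced_potentials",
    "write_leg_estimates", "read_leg_estimates",
    "write_edge_estimates", "read_edge_estimates",
    "write_ligand_estimates", "read_ligand_estimates",
    "write_experimental", "read_experimental",
    "write_cycle_report", "load_table3_closures",
]


# --- network spec ----------------------------------------------------------

def write_network_spec(network_or_parts, path: str | Path) -> None:
    """Write ligands/edges/reference as JSON.

    Accepts a :class:`PerturbationNetwork` or a dict with keys
    ``ligands`` (list of Ligand), ``edges`` (list of (source, target) or
    (source, target, protocol)), ``reference_id``.
    """
    if isinstance(network_or_parts, PerturbationNetwork):
        net = network_or_parts
        ligands = list(net.ligands.values())
        edges = [(s, t, net.edges[(s, t)].protocol) for s, t in sorted(net.edges)]
        reference_id = net.reference_id
    else:
        ligands = network_or_parts["ligands"]
        edges = [tuple(e) for e in network_or_parts["edges"]]
        reference_id = network_or_parts["reference_id"]
    doc = {
        "reference_id": reference_id,
        "ligands": [
            {
                "id": l.id, "batch": l.batch, "charge": l.charge,
                "ki_molar": l.ki, "is_racemate": l.is_racemate,
                "enantiomer_ids": list(l.enantiomer_ids) if l.enantiomer_ids else None,
            }
            for l in ligands
        ],
        "edges": [
            {"source": e[0], "target": e[1],
             "protocol": e[2] if len(e) > 2 else ""}
            for e in edges
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_network_spec(path: str | Path) -> dict:
    """Parse a network spec JSON into ligands, edge tuples, reference id."""
    doc = json.loads(Path(path).read_text())
    ligands = [
        Ligand(
            id=d["id"], batch=d.get("batch", "batch1"),
            charge=int(d.get("charge", 0)), ki=d.get("ki_molar"),
            is_racemate=bool(d.get("is_racemate", False)),
            enantiomer_ids=tuple(d["enantiomer_ids"]) if d.get("enantiomer_ids") else None,
        )
        for d in doc["ligands"]
    ]
    edges = [(e["source"], e["target"], e.get("protocol", ""))
             for e in doc["edges"]]
    return {"ligands": ligands, "edges": edges,
            "reference_id": doc["reference_id"]}


# --- reduced potentials ----------------------------------------------------

def write_reduced_potentials(
    matrices: dict[tuple[str, int], ReducedPotentialMatrix], path: str | Path
) -> None:
    """TSV of reduced-potential samples keyed by (leg_id, repeat)."""
    frames = []
    for (leg_id, repeat), m in sorted(matrices.items()):
        origin = np.repeat(np.arange(m.n_states), m.counts)
        df = pd.DataFrame(m.u.T, columns=[f"u_{k}" for k in range(m.n_states)])
        df.insert(0, "sample_index", np.arange(m.n_samples))
        df.insert(0, "origin_state", origin)
        df.insert(0, "repeat", repeat)
        df.insert(0, "leg_id", leg_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_reduced_potentials(
    path: str | Path, expected_states: int | None = None
) -> dict[tuple[str, int], ReducedPotentialMatrix]:
    """Parse the reduced-potential TSV back into matrices, validating the
    state count and per-state sample tallies."""
    df = pd.read_csv(path, sep="\t")
    ucols = sorted(
        (c for c in df.columns if c.startswith("u_")),
        key=lambda c: int(c.split("_")[1]),
    )
    k = len(ucols)
    if expected_states is not None and k != expected_states:
        raise ValueError(f"expected {expected_states} states, file has {k}")
    out: dict[tuple[str, int], ReducedPotentialMatrix] = {}
    for (leg_id, repeat), grp in df.groupby(["leg_id", "repeat"], sort=True):
        grp = grp.sort_values("sample_index")
        counts = np.bincount(grp["origin_state"].to_numpy(), minlength=k)
        if counts.sum() != len(grp):
            raise ValueError(f"leg {leg_id!r} repeat {repeat}: sample tally mismatch")
        out[(str(leg_id), int(repeat))] = ReducedPotentialMatrix(
            u=grp[ucols].to_numpy().T, counts=counts, leg_id=str(leg_id)
        )
    return out


# --- leg / edge / ligand tables --------------------------------------------

def write_leg_estimates(legs: list[dict], path: str | Path) -> None:
    """CSV of per-leg free energies. Each entry: edge_id, source, target,
    environment, repeat, value_kcal_mol, sigma_kcal_mol."""
    cols = ["edge_id", "source", "target", "environment", "repeat",
            "value_kcal_mol", "sigma_kcal_mol"]
    pd.DataFrame(legs)[cols].to_csv(path, index=False, float_format="%.17g")


def read_leg_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"source": str, "target": str, "edge_id": str})
    required = {"edge_id", "source", "target", "environment", "repeat",
                "value_kcal_mol", "sigma_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"leg CSV missing columns: {sorted(missing)}")
    return df


def write_edge_estimates(network: PerturbationNetwork, path: str | Path) -> None:
    rows = []
    for (s, t), e in sorted(network.edges.items()):
        rows.append({
            "source": s, "target": t,
            "value_kcal_mol": e.ddg.value, "sigma_kcal_mol": e.ddg.sigma,
            "n_repeats": len(e.repeat_values) or 1,
            "repeat_values": ";".join(f"{v.value:.17g}" for v in e.repeat_values),
            "charge_mismatch": e.charge_mismatch,
            "protocol": e.protocol,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_edge_estimates(path: str | Path) -> list[EdgeEstimate]:
    df = pd.read_csv(path, dtype={"source": str, "target": str},
                     keep_default_na=False, na_values=[])
    out = []
    for row in df.itertuples(index=False):
        reps = tuple(
            FreeEnergyValue(float(v), 0.0, ValueKind.EDGE_REPEAT)
            for v in str(getattr(row, "repeat_values", "")).split(";") if v
        )
        out.append(EdgeEstimate(
            source=row.source, target=row.target,
            ddg=FreeEnergyValue(float(row.value_kcal_mol),
                                float(row.sigma_kcal_mol),
                                ValueKind.EDGE_MEAN, f"{row.source}~{row.target}"),
            repeat_values=reps,
            protocol=str(getattr(row, "protocol", "")),
            charge_mismatch=str(getattr(row, "charge_mismatch", "False")) == "True",
        ))
    return out


def write_ligand_estimates(dgs: dict[str, FreeEnergyValue], path: str | Path) -> None:
    rows = [{"ligand_id": lid, "dg_kcal_mol": v.value, "sigma_kcal_mol": v.sigma}
            for lid, v in sorted(dgs.items())]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_ligand_estimates(path: str | Path) -> dict[str, FreeEnergyValue]:
    df = pd.read_csv(path, dtype={"ligand_id": str})
    return {
        row.ligand_id: FreeEnergyValue(float(row.dg_kcal_mol),
                                       float(row.sigma_kcal_mol),
                                       ValueKind.LIGAND_DG, row.ligand_id)
        for row in df.itertuples(index=False)
    }


def write_experimental(dg: dict[str, float], path: str | Path,
                       ki: dict[str, float] | None = None) -> None:
    rows = []
    for lid in sorted(dg):
        row = {"ligand_id": lid, "dg_kcal_mol": dg[lid]}
        if ki is not None and lid in ki:
            row["ki_molar"] = ki[lid]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_experimental(path: str | Path,
                      temperature: float = DEFAULT_TEMPERATURE) -> dict[str, float]:
    """Experimental table as ligand -> dG (kcal/mol); a ki_molar column is
    converted when no dG column is present."""
    df = pd.read_csv(path, dtype={"ligand_id": str})
    if "dg_kcal_mol" in df.columns:
        return {r.ligand_id: float(r.dg_kcal_mol) for r in df.itertuples(index=False)}
    if "ki_molar" in df.columns:
        return {r.ligand_id: ki_to_dg(float(r.ki_molar), temperature)
                for r in df.itertuples(index=False)}
    raise ValueError("experimental CSV needs a dg_kcal_mol or ki_molar column")


# --- reports ---------------------------------------------------------------

def write_cycle_report(report: FlagReport, path: str | Path) -> None:
    doc = {
        "threshold_kcal_mol": report.threshold,
        "n_flagged": report.n_flagged,
        "cycles": [
            {
                "cycle": list(r.cycle), "label": r.label,
                "closure_kcal_mol": r.closure.value,
                "sigma_kcal_mol": r.closure.sigma,
                "flagged": r.flagged, "protocol": r.protocol,
            }
            for r in report.reports
        ],
        "ligand_ranking": [
            {"ligand_id": lig, "n_flagged_cycles": n} for lig, n in report.ranking
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_table3_closures() -> dict[str, list[CycleReport]]:
    """Packaged printed cycle-closure table: protocol label -> reports.

    Cycles not run under a protocol (null entries) are omitted from that
    protocol's list.
    """
    text = resources.files("fepnet.data").joinpath("table3_closures.json").read_text()
    doc = json.loads(text)
    threshold = float(doc["threshold"])
    out: dict[str, list[CycleReport]] = {p: [] for p in doc["protocols"]}
    for entry in doc["cycles"]:
        cycle = tuple(entry["cycle"])
        for proto, pair in entry["closures"].items():
            if pair is None:
                continue
            value, sigma = float(pair[0]), float(pair[1])
            out[proto].append(CycleReport(
                cycle, FreeEnergyValue(value, sigma, ValueKind.EDGE_MEAN,
                                       "-".join(cycle)),
                abs(value) >= threshold, proto,
            ))
    return out
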