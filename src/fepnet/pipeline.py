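"""End-to-end assembly: leg free energies -> edge ddGs -> network.

Glue between data sources (the synthetic generator, or leg tables read
from disk) and the analysis layers. Per-leg free energies come from MBAR
when a leg carries a sampled reduced-potential matrix, or from stored
values otherwise; repeats combine into per-edge means; edges incident to
a racemic parent are collapsed over its enantiomers with the Boltzmann
mixture rule; the result is a :class:`PerturbationNetwork` ready for
reconstruction, diagnostics and benchmarking.
"""

from __future__ import annotations

from collections import defaultdict

from .constants import DEFAULT_TEMPERATURE
from .estimators import leg_free_energy
from .network import (
    EdgeEstimate,
    Ligand,
    PerturbationNetwork,
    aggregate_repeats,
    combine_racemate,
    ddg_from_legs,
)
from .synthetic import ScenarioData
from .values import FreeEnergyValue, ValueKind

__all__ = ["leg_values_from_scenario", "network_from_leg_values", "build_network"]

#: leg table type: (source, target, repeat) -> {"free": value, "complex": value}
LegValues = dict[tuple[str, str, int], dict[str, FreeEnergyValue]]


def leg_values_from_scenario(
    scenario: ScenarioData,
    tolerance: float = 1e-10,
    max_iterations: int = 10_000,
) -> LegValues:
    """Estimate (or read off) every leg's free energy, in kcal/mol.

    Sampled legs go through MBAR at the scenario temperature; analytic
    legs carry their exact stored targets. Keys still use enantiomer ids.
    """
    out: LegValues = defaultdict(dict)
    t = scenario.config.temperature
    for rec in scenario.legs:
        if rec.matrix is not None:
            value = leg_free_energy(rec.matrix, t, tolerance, max_iterations)
        else:
            value = rec.exact_value()
        out[(rec.source, rec.target, rec.repeat)][rec.environment] = value
    return dict(out)


def network_from_leg_values(
    leg_values: LegValues,
    ligands: list[Ligand],
    reference_id: str,
    reference_dg: float,
    temperature: float = DEFAULT_TEMPERATURE,
    protocol: str = "",
) -> PerturbationNetwork:
    """Assemble a perturbation network from per-leg free energies.

    Each (source, target, repeat) needs both a free and a complex leg;
    repeats aggregate to an edge mean. Directed edges whose endpoint is an
    enantiomer of a declared racemate are folded into the parent edge by
    combining enantiomer repeats pairwise with the racemic mixture rule.
    Edges between ligands of unequal net charge carry a warning flag.
    """
    enantiomer_parent: dict[str, str] = {}
    for lig in ligands:
        if lig.is_racemate:
            for e in lig.enantiomer_ids:
                enantiomer_parent[e] = lig.id

    def to_parent(node: str) -> str:
        return enantiomer_parent.get(node, node)

    ddgs: dict[tuple[str, str], list[FreeEnergyValue]] = defaultdict(list)
    for (s, t, r), envs in sorted(leg_values.items()):
        missing = {"free", "complex"} - set(envs)
        if missing:
            raise ValueError(
                f"edge {s}~{t} repeat {r} missing legs {sorted(missing)}"
            )
        ddgs[(s, t)].append(
            ddg_from_legs(envs["complex"], envs["free"], tag=f"{s}~{t}#r{r}")
        )

    grouped: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)
    for key in ddgs:
        grouped[(to_parent(key[0]), to_parent(key[1]))].append(key)

    net = PerturbationNetwork(
        ligands=ligands, reference_id=reference_id,
        reference_dg=reference_dg, temperature=temperature,
    )
    charges = {l.id: l.charge for l in ligands}
    for (s, t), subkeys in sorted(grouped.items()):
        if len(subkeys) == 1:
            repeats = ddgs[subkeys[0]]
        elif len(subkeys) == 2:
            a, b = sorted(subkeys)
            rep_a, rep_b = ddgs[a], ddgs[b]
            if len(rep_a) != len(rep_b):
                raise ValueError(f"enantiomer repeat mismatch on {s}~{t}")
            if s in enantiomer_parent.values() and t not in enantiomer_parent.values():
                # racemate as source: the mixture rule as published
                repeats = [combine_racemate(x, y, temperature)
                           for x, y in zip(rep_a, rep_b)]
            else:
                # racemate as target: negate into the source convention,
                # combine, negate back — both directions then imply the
                # same effective racemate affinity
                repeats = [-combine_racemate(-x, -y, temperature)
                           for x, y in zip(rep_a, rep_b)]
        else:
            raise ValueError(
                f"edge {s}~{t} maps to {len(subkeys)} sub-edges; at most one "
                "racemate endpoint is supported"
            )
        mean = aggregate_repeats(repeats, tag=f"{s}~{t}")
        net.add_edge(EdgeEstimate(
            source=s, target=t, ddg=mean,
            repeat_values=tuple(v.with_kind(ValueKind.EDGE_REPEAT) for v in repeats),
            protocol=protocol,
            charge_mismatch=charges.get(s, 0) != charges.get(t, 0),
        ))
    return net


def build_network(
    scenario: ScenarioData,
    tolerance: float = 1e-10,
    max_iterations: int = 10_000,
) -> PerturbationNetwork:
    """Scenario -> assembled perturbation network (MBAR per sampled leg)."""
    leg_values = leg_values_from_scenario(scenario, tolerance, max_iterations)
    return network_from_leg_values(
        leg_values, scenario.ligands, scenario.reference_id,
        scenario.reference_dg, scenario.config.temperature,
        scenario.config.protocol,
    )
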