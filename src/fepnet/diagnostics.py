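"""Hysteresis and thermodynamic-cycle-closure diagnostics.

If every computed edge ddG were exact, the sum of oriented ddG values
around any closed cycle of ligands would vanish, and a forward and a
reverse perturbation of the same pair would cancel. Non-zero cycle
closures and hysteresis therefore flag problematic perturbations —
typically mis-modelled binding poses or missing binding-site waters —
without any reference to experimental affinities. Cycles whose mean
closure reaches the flagging threshold (default 0.8 kcal/mol) are
reported, and ligands are ranked by how many flagged cycles they appear
in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .network import PerturbationNetwork
from .values import FreeEnergyValue, quadrature

__all__ = [
    "EdgeHysteresis",
    "CycleReport",
    "FlagReport",
    "hysteresis",
    "edge_hysteresis",
    "enumerate_cycles",
    "canonical_cycle",
    "cycle_closure",
    "closure_from_dgs",
    "flag_cycles",
    "diagnose_network",
    "DEFAULT_THRESHOLD",
]

#: Flagging threshold for |cycle closure|, kcal/mol.
DEFAULT_THRESHOLD = 0.8


@dataclass(frozen=True)
class EdgeHysteresis:
    """Forward/reverse discrepancy of one perturbation pair.

    ``h`` is the 2-cycle closure ddG(X->Y) + ddG(Y->X); zero for perfectly
    self-consistent runs.
    """

    source: str
    target: str
    h: FreeEnergyValue
    flagged: bool


@dataclass
class CycleReport:
    """An oriented simple cycle with its closure and flag status."""

    cycle: tuple[str, ...]
    closure: FreeEnergyValue
    flagged: bool = False
    protocol: str = ""

    def __post_init__(self) -> None:
        if len(set(self.cycle)) != len(self.cycle):
            raise ValueError(f"cycle has repeated ligands: {self.cycle}")
        if len(self.cycle) < 2:
            raise ValueError("a cycle needs at least two ligands")

    @property
    def label(self) -> str:
        return "-".join(self.cycle)


@dataclass
class FlagReport:
    """Threshold-flagged cycles plus the per-ligand implication ranking."""

    threshold: float
    reports: list[CycleReport]
    flagged: list[CycleReport] = field(init=False)
    ranking: list[tuple[str, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.flagged = [r for r in self.reports if r.flagged]
        counts: dict[str, int] = {}
        for rep in self.flagged:
            for lig in rep.cycle:
                counts[lig] = counts.get(lig, 0) + 1
        self.ranking = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    def top_implicated(self) -> str | None:
        return self.ranking[0][0] if self.ranking else None


# ---------------------------------------------------------------------------


def hysteresis(forward: FreeEnergyValue, reverse: FreeEnergyValue,
               source: str = "", target: str = "",
               threshold: float = DEFAULT_THRESHOLD) -> EdgeHysteresis:
    """Hysteresis of a perturbation measured in both directions.

    h = ddG(X->Y) + ddG(Y->X), with quadrature uncertainty; ideal value 0.
    """
    h = FreeEnergyValue(forward.value + reverse.value,
                        quadrature(forward.sigma, reverse.sigma),
                        forward.kind, f"{source}~{target}")
    return EdgeHysteresis(source, target, h, abs(h.value) >= threshold)


def edge_hysteresis(network: PerturbationNetwork,
                    threshold: float = DEFAULT_THRESHOLD) -> list[EdgeHysteresis]:
    """Hysteresis for every pair measured in both directions. Pairs with a
    single measured direction yield no entry (not a zero)."""
    out = []
    seen: set[frozenset[str]] = set()
    for (s, t) in sorted(network.edges):
        pair = frozenset((s, t))
        if pair in seen:
            continue
        fwd = network.edge(s, t)
        rev = network.edge(t, s)
        if fwd is None or rev is None:
            continue
        seen.add(pair)
        out.append(hysteresis(fwd.ddg, rev.ddg, s, t, threshold))
    return out


def canonical_cycle(cycle: tuple[str, ...]) -> tuple[str, ...]:
    """Canonical representative under rotation and reflection: the
    lexicographically smallest of all equivalent orderings."""
    n = len(cycle)
    candidates = []
    for seq in (cycle, tuple(reversed(cycle))):
        for i in range(n):
            candidates.append(seq[i:] + seq[:i])
    return min(candidates)


def enumerate_cycles(network: PerturbationNetwork,
                     max_length: int = 4) -> list[tuple[str, ...]]:
    """All simple undirected cycles of length 3..max_length over pairs with
    at least one measured direction, canonicalized and sorted."""
    if max_length not in (3, 4):
        raise ValueError("max_length must be 3 or 4")
    g = nx.Graph()
    g.add_nodes_from(network.ligands)
    for pair in network.undirected_pairs():
        g.add_edge(*sorted(pair))
    cycles = {
        canonical_cycle(tuple(c))
        for c in nx.simple_cycles(g, length_bound=max_length)
        if len(c) >= 3
    }
    return sorted(cycles)


def _hop_value(network: PerturbationNetwork, x: str, y: str,
               policy: str) -> FreeEnergyValue:
    """Oriented ddG for traversing x -> y under the direction policy."""
    fwd = network.edge(x, y)   # measured along the traversal
    rev = network.edge(y, x)   # measured against the traversal
    if fwd is None and rev is None:
        raise ValueError(f"no measured edge between {x!r} and {y!r}")
    if policy == "as_measured":
        if fwd is not None and rev is not None:
            return FreeEnergyValue(
                0.5 * (fwd.ddg.value - rev.ddg.value),
                0.5 * quadrature(fwd.ddg.sigma, rev.ddg.sigma),
                fwd.ddg.kind, f"{x}~{y}")
        return fwd.ddg if fwd is not None else -rev.ddg
    if policy == "forward_only":
        return fwd.ddg if fwd is not None else -rev.ddg
    if policy == "reverse_only":
        return -rev.ddg if rev is not None else fwd.ddg
    raise ValueError(f"unknown direction_policy {policy!r}")


def cycle_closure(cycle: tuple[str, ...] | list[str],
                  network: PerturbationNetwork,
                  direction_policy: str = "as_measured",
                  threshold: float = DEFAULT_THRESHOLD,
                  protocol: str = "") -> CycleReport:
    """Closure of one oriented cycle: the sum of oriented edge ddGs along
    consecutive hops (the last ligand closes back to the first).

    ``direction_policy`` controls how each hop's value is read:
    ``as_measured`` averages the along-traversal value with the negated
    against-traversal value when both directions were measured;
    ``forward_only`` uses only the along-traversal measurement (falling
    back to the negated reverse when it is the only one); ``reverse_only``
    the mirror image. With ``forward_only``, the closure of the 2-cycle
    (X, Y) is exactly the edge hysteresis.
    """
    cycle = tuple(cycle)
    vals = []
    for i, x in enumerate(cycle):
        y = cycle[(i + 1) % len(cycle)]
        vals.append(_hop_value(network, x, y, direction_policy))
    total = sum(v.value for v in vals)
    sigma = quadrature(*(v.sigma for v in vals))
    closure = FreeEnergyValue(total, sigma, vals[0].kind, "-".join(cycle))
    return CycleReport(cycle, closure, abs(total) >= threshold, protocol)


def closure_from_dgs(cycle: tuple[str, ...],
                     dgs: dict[str, float]) -> float:
    """Closure implied by a per-ligand potential; identically zero up to
    float rounding, useful as a consistency check on fitted values."""
    total = 0.0
    for i, x in enumerate(cycle):
        y = cycle[(i + 1) % len(cycle)]
        total += dgs[y] - dgs[x]
    return total


def diagnose_network(network: PerturbationNetwork,
                     threshold: float = DEFAULT_THRESHOLD,
                     direction_policy: str = "as_measured",
                     include_hysteresis: bool = True,
                     cycles: list[tuple[str, ...]] | None = None) -> FlagReport:
    """Full pose-problem screen of a network.

    Computes closures for every simple 3-/4-cycle (or an explicit curated
    list) and, by default, the hysteresis of every bidirectionally
    measured edge as a 2-cycle report — hysteresis is the most direct
    signature of a direction-dependent set-up problem, and including it
    makes the implication ranking sensitive to biases that cancel around
    longer cycles. Returns the threshold-flagged report with the ligand
    ranking.
    """
    if cycles is None:
        cycles = enumerate_cycles(network)
    reports = [cycle_closure(c, network, direction_policy, threshold)
               for c in cycles]
    if include_hysteresis:
        for h in edge_hysteresis(network, threshold):
            reports.append(CycleReport((h.source, h.target), h.h, h.flagged))
    return flag_cycles(reports, threshold)


def flag_cycles(reports: list[CycleReport],
                threshold: float = DEFAULT_THRESHOLD) -> FlagReport:
    """Re-flag cycle reports at a threshold (|mean closure| >= threshold;
    the closure uncertainty does not enter the comparison) and rank ligands
    by the number of flagged cycles containing them."""
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    reflagged = [
        CycleReport(r.cycle, r.closure, abs(r.closure.value) >= threshold,
                    r.protocol)
        for r in reports
    ]
    return FlagReport(threshold, reflagged)
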