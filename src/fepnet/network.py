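"""Perturbation-network domain model and free-energy assembly.

A perturbation network is a graph whose nodes are ligands of a congeneric
series and whose directed edges carry computed relative binding free
energies (ddG). The module assembles per-edge ddG values from complex/free
leg results, folds racemic ligands into a single effective edge via a
Boltzmann combination of the enantiomers, converts experimental inhibition
constants to binding free energies, and reconstructs absolute per-ligand
binding free energies relative to a reference ligand by weighted least
squares over all directed edge observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .constants import C_STANDARD, DEFAULT_TEMPERATURE, R_KCAL, kt_kcal
from .values import FreeEnergyValue, ValueKind, quadrature

__all__ = [
    "Ligand",
    "LegResult",
    "EdgeMeasurement",
    "EdgeEstimate",
    "PerturbationNetwork",
    "NetworkEstimator",
    "ddg_from_legs",
    "aggregate_repeats",
    "combine_racemate",
    "ki_to_dg",
    "dg_to_ki",
    "network_estimate",
]

#: Default floor applied to edge sigmas so WLS weights stay finite on
#: noiseless synthetic data (kcal/mol).
SIGMA_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Ligand:
    """One member of the congeneric series.

    Parameters
    ----------
    id : str
        Short label, unique within a network (e.g. ``"3"``, ``"44"``).
    batch : str
        Which experimental subset the ligand belongs to (``"batch1"`` /
        ``"batch2"``).
    charge : int
        Net charge in the modelled protonation state (0 or +1 here).
    ki : float or None
        Experimental inhibition constant in mol/L, when reported.
    is_racemate : bool
        True when the compound is assayed as a racemic mixture; its edges
        are then computed per enantiomer and combined.
    enantiomer_ids : tuple of str, optional
        The two enantiomer sub-ligand ids (required iff ``is_racemate``).
    """

    id: str
    batch: str = "batch1"
    charge: int = 0
    ki: float | None = None
    is_racemate: bool = False
    enantiomer_ids: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.ki is not None and not self.ki > 0:
            raise ValueError(f"ligand {self.id}: ki must be > 0, got {self.ki}")
        if self.is_racemate:
            if self.enantiomer_ids is None or len(self.enantiomer_ids) != 2:
                raise ValueError(
                    f"ligand {self.id}: a racemate needs exactly two enantiomer ids"
                )
        elif self.enantiomer_ids is not None:
            raise ValueError(
                f"ligand {self.id}: enantiomer_ids given but is_racemate is False"
            )


@dataclass(frozen=True)
class LegResult:
    """Free-energy change of one environment of one repeat of an edge."""

    edge_id: str
    repeat: int
    environment: str  # "free" | "complex"
    dg: FreeEnergyValue

    def __post_init__(self) -> None:
        if self.environment not in ("free", "complex"):
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.dg.kind is not ValueKind.LEG:
            raise ValueError("LegResult requires a kind=leg value")


@dataclass
class EdgeMeasurement:
    """All repeats of one directed perturbation, both environments.

    ``repeats`` maps repeat index -> {"free": LegResult, "complex": LegResult}.
    """

    source: str
    target: str
    repeats: dict[int, dict[str, LegResult]] = field(default_factory=dict)
    protocol: str = ""

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("edge source and target must differ")

    @property
    def edge_id(self) -> str:
        return f"{self.source}~{self.target}"

    def add_leg(self, leg: LegResult) -> None:
        self.repeats.setdefault(leg.repeat, {})[leg.environment] = leg

    def ddg_repeats(self) -> list[FreeEnergyValue]:
        """Per-repeat relative binding free energies (complex minus free)."""
        if not self.repeats:
            raise ValueError(f"edge {self.edge_id} has no repeats")
        out = []
        for idx in sorted(self.repeats):
            legs = self.repeats[idx]
            missing = {"free", "complex"} - set(legs)
            if missing:
                raise ValueError(
                    f"edge {self.edge_id} repeat {idx} is missing legs: {sorted(missing)}"
                )
            out.append(ddg_from_legs(legs["complex"].dg, legs["free"].dg,
                                     tag=f"{self.edge_id}#r{idx}"))
        return out

    def ddg_mean(self) -> FreeEnergyValue:
        return aggregate_repeats(self.ddg_repeats(), tag=self.edge_id)


@dataclass
class EdgeEstimate:
    """A directed edge with its aggregated ddG and retained repeat values."""

    source: str
    target: str
    ddg: FreeEnergyValue
    repeat_values: tuple[FreeEnergyValue, ...] = ()
    protocol: str = ""
    charge_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("edge source and target must differ")
        if self.ddg.kind is not ValueKind.EDGE_MEAN:
            raise ValueError("EdgeEstimate requires a kind=edge_mean value")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


class PerturbationNetwork:
    """Ligands plus directed aggregated edges, anchored at a reference.

    Forward and reverse measurements of the same pair are stored as two
    distinct directed edges. The reference ligand carries an absolute
    binding free energy (from its experimental Ki) that anchors the
    network-wide reconstruction.
    """

    def __init__(
        self,
        ligands: list[Ligand] | dict[str, Ligand],
        reference_id: str,
        reference_dg: float | None = None,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> None:
        if isinstance(ligands, dict):
            ligands = list(ligands.values())
        self.ligands: dict[str, Ligand] = {}
        for lig in ligands:
            if lig.id in self.ligands:
                raise ValueError(f"duplicate ligand id {lig.id!r}")
            self.ligands[lig.id] = lig
        if reference_id not in self.ligands:
            raise ValueError(f"reference ligand {reference_id!r} not in network")
        self.reference_id = reference_id
        self.temperature = temperature
        if reference_dg is None:
            ref = self.ligands[reference_id]
            if ref.ki is None:
                raise ValueError(
                    "reference_dg not given and reference ligand has no Ki"
                )
            reference_dg = ki_to_dg(ref.ki, temperature)
        self.reference_dg = float(reference_dg)
        self.edges: dict[tuple[str, str], EdgeEstimate] = {}

    def add_edge(self, edge: EdgeEstimate) -> None:
        for end in edge.key:
            if end not in self.ligands:
                raise ValueError(f"edge endpoint {end!r} is not a declared ligand")
        if edge.key in self.edges:
            raise ValueError(f"duplicate directed edge {edge.key}")
        self.edges[edge.key] = edge

    def edge(self, source: str, target: str) -> EdgeEstimate | None:
        return self.edges.get((source, target))

    def undirected_pairs(self) -> set[frozenset[str]]:
        return {frozenset(k) for k in self.edges}

    def ligand_ids(self) -> list[str]:
        return sorted(self.ligands)


# ---------------------------------------------------------------------------
# assembly operations
# ---------------------------------------------------------------------------

def ddg_from_legs(
    dg_complex: FreeEnergyValue,
    dg_free: FreeEnergyValue,
    tag: str = "",
) -> FreeEnergyValue:
    """Relative binding free energy of one repeat from its two legs.

    ddG(X->Y) = dG_complex(X->Y) - dG_free(X->Y); the uncertainty is the
    quadrature sum of the two leg uncertainties.
    """
    for leg in (dg_complex, dg_free):
        if leg.kind is not ValueKind.LEG:
            raise ValueError(f"expected kind=leg inputs, got {leg.kind}")
    ident = [t.rsplit(":", 1)[0] for t in (dg_complex.tag, dg_free.tag)]
    if all(ident) and ident[0] != ident[1]:
        raise ValueError(
            f"leg identity mismatch: {dg_complex.tag!r} vs {dg_free.tag!r}"
        )
    return FreeEnergyValue(
        dg_complex.value - dg_free.value,
        quadrature(dg_complex.sigma, dg_free.sigma),
        ValueKind.EDGE_REPEAT,
        tag or dg_complex.tag,
    )


def aggregate_repeats(
    repeats: list[FreeEnergyValue], tag: str = ""
) -> FreeEnergyValue:
    """Aggregate independent repeats of one directed edge.

    Mean, with the standard error of the mean (sample std / sqrt(n)) for
    n >= 2; a single repeat passes through with its own propagated sigma.
    """
    if not repeats:
        raise ValueError("aggregate_repeats needs at least one repeat")
    vals = np.array([r.value for r in repeats], dtype=float)
    if len(vals) == 1:
        return FreeEnergyValue(float(vals[0]), repeats[0].sigma,
                               ValueKind.EDGE_MEAN, tag or repeats[0].tag)
    sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
    return FreeEnergyValue(float(vals.mean()), sem, ValueKind.EDGE_MEAN,
                           tag or repeats[0].tag)


def combine_racemate(
    ddg_r: FreeEnergyValue,
    ddg_s: FreeEnergyValue,
    temperature: float = DEFAULT_TEMPERATURE,
) -> FreeEnergyValue:
    """Effective ddG of a 1:1 racemic mixture from its enantiomers.

    ddG_rac = -kT ln[ (exp(-ddG_R/kT) + exp(-ddG_S/kT)) / 2 ]

    computed in the log domain so inputs hundreds of kT apart do not
    overflow. The uncertainty propagates with Boltzmann weights
    w_i = exp(-ddG_i/kT)/sum: sigma^2 = sum_i w_i^2 sigma_i^2.
    """
    kt = kt_kcal(temperature)
    a = np.array([-ddg_r.value / kt, -ddg_s.value / kt])
    value = -kt * float(logsumexp(a, b=np.array([0.5, 0.5])))
    # Boltzmann weights, normalized in log domain.
    logw = a - logsumexp(a)
    w = np.exp(logw)
    sigma = float(np.sqrt(w[0] ** 2 * ddg_r.sigma ** 2 + w[1] ** 2 * ddg_s.sigma ** 2))
    return FreeEnergyValue(value, sigma, ddg_r.kind, ddg_r.tag or ddg_s.tag)


def ki_to_dg(ki: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy (kcal/mol) from an inhibition constant (mol/L).

    dG = RT ln(Ki / C0) with the standard state C0 = 1 mol/L.
    """
    if not ki > 0:
        raise ValueError(f"ki must be > 0, got {ki}")
    return R_KCAL * temperature * math.log(ki / C_STANDARD)


def dg_to_ki(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`ki_to_dg`: Ki (mol/L) from a binding free energy."""
    return C_STANDARD * math.exp(dg / (R_KCAL * temperature))


# ---------------------------------------------------------------------------
# network-wide reconstruction
# ---------------------------------------------------------------------------

class NetworkEstimator(BaseEstimator):
    """Absolute per-ligand binding free energies from directed edge ddGs.

    Weighted least squares over every directed observation: an edge
    (s -> t) with value d and error sigma contributes the residual
    (dG_t - dG_s - d)/sigma. The reference ligand is eliminated as a hard
    constraint at its experimental value, and per-ligand uncertainties come
    from the diagonal of the (pseudo-)inverse normal matrix.

    Parameters
    ----------
    sigma_floor : float
        Minimum edge sigma (kcal/mol) used when forming weights, so that
        noiseless synthetic edges do not produce infinite weights.
    scale_covariance : bool
        Rescale the covariance by the reduced chi-square of the fit
        (standard WLS practice). With few repeats per edge the stated edge
        sigmas are themselves noisy and tend to understate the true
        scatter; the residual-based scale recalibrates the per-ligand
        uncertainties. Networks with no redundancy (zero residual degrees
        of freedom) keep the unscaled covariance.

    Attributes
    ----------
    ligand_ids_ : list of str
        Ligands with a resolved absolute estimate (reference included).
    dg_ : dict mapping ligand id -> FreeEnergyValue (kind=ligand_dg)
    unresolvable_ : list of str
        Ligands with no path to the reference; reported, never dropped
        silently.
    """

    def __init__(self, sigma_floor: float = SIGMA_FLOOR,
                 scale_covariance: bool = True):
        self.sigma_floor = sigma_floor
        self.scale_covariance = scale_covariance

    def fit(self, network: PerturbationNetwork) -> "NetworkEstimator":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(network.ligands)
        for pair in network.undirected_pairs():
            g.add_edge(*sorted(pair))
        ref = network.reference_id
        reachable = nx.node_connected_component(g, ref)
        self.unresolvable_ = sorted(set(network.ligands) - reachable)
        if self.unresolvable_:
            warnings.warn(
                "ligands with no path to the reference are unresolvable: "
                f"{self.unresolvable_}", stacklevel=2,
            )
        nodes = sorted(reachable - {ref})
        index = {lig: i for i, lig in enumerate(nodes)}

        rows, rhs, wts = [], [], []
        for (s, t), edge in sorted(network.edges.items()):
            if s not in reachable or t not in reachable:
                continue
            # dG_t - dG_s = ddg, with the anchored reference moved to the RHS
            row = np.zeros(len(nodes))
            b = edge.ddg.value
            if t == ref:
                b -= network.reference_dg
            else:
                row[index[t]] += 1.0
            if s == ref:
                b += network.reference_dg
            else:
                row[index[s]] -= 1.0
            rows.append(row)
            rhs.append(b)
            wts.append(1.0 / max(edge.ddg.sigma, self.sigma_floor) ** 2)

        if nodes and not rows:
            raise ValueError("no edges connect the reachable ligands")

        dg: dict[str, FreeEnergyValue] = {
            ref: FreeEnergyValue(network.reference_dg, 0.0, ValueKind.LIGAND_DG, ref)
        }
        self.scale_ = 1.0
        if nodes:
            a = np.asarray(rows)
            b = np.asarray(rhs)
            w = np.asarray(wts)
            h = a.T @ (w[:, None] * a)
            rhs_vec = a.T @ (w * b)
            cov = np.linalg.pinv(h)
            x = cov @ rhs_vec
            dof = len(b) - len(nodes)
            if self.scale_covariance and dof > 0:
                resid = b - a @ x
                self.scale_ = float((w * resid**2).sum() / dof)
                cov = cov * self.scale_
            else:
                self.scale_ = 1.0
            sig = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            for lig, i in index.items():
                dg[lig] = FreeEnergyValue(float(x[i]), float(sig[i]),
                                          ValueKind.LIGAND_DG, lig)
        self.dg_ = dg
        self.ligand_ids_ = sorted(dg)
        return self

    def to_frame(self):
        """Fitted estimates as a DataFrame (ligand_id, dg, sigma)."""
        import pandas as pd

        rows = [
            {"ligand_id": lig, "dg_kcal_mol": v.value, "sigma_kcal_mol": v.sigma}
            for lig, v in sorted(self.dg_.items())
        ]
        for lig in self.unresolvable_:
            rows.append({"ligand_id": lig, "dg_kcal_mol": np.nan,
                         "sigma_kcal_mol": np.nan})
        return pd.DataFrame(rows)


def network_estimate(
    network: PerturbationNetwork, sigma_floor: float = SIGMA_FLOOR
) -> dict[str, FreeEnergyValue]:
    """Functional wrapper over :class:`NetworkEstimator`. Returns the
    per-ligand dG table (unresolvable ligands are absent from the mapping
    but warned about)."""
    est = NetworkEstimator(sigma_floor=sigma_floor).fit(network)
    return est.dg_
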