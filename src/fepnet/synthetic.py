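"""Ground-truthed synthetic datasets for the perturbation-network pipeline.

The generator emulates a two-batch congeneric kinase-inhibitor series: 15
ligands spanning inhibition constants from 10 uM down to 0.2 nM, a
perturbation map whose 3- and 4-membered cycles match the published cycle
structure of the real study, forward and reverse measurements with two
independent repeats each, one racemic ligand represented by two enantiomer
sub-ligands, and direction-dependent "misposed pose" / "missing
binding-site water" biases on complex legs that manufacture hysteresis and
non-zero cycle closures exactly the way bad input poses do in real
calculations.

Per-leg sampling uses 1-D Gaussian states: state k along the coupling
schedule has reduced potential u_k(x) = (x - mu_k)^2 / 2 + c_k, whose free
energy is known in closed form, so the exact end-to-end free energy of
every leg is available as ground truth. Setting ``samples_per_state = 0``
switches to an analytic mode in which legs carry their exact (noisy)
target values with no sampling — useful when the property under study is
downstream of the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt_kcal
from .estimators import ReducedPotentialMatrix
from .network import Ligand, dg_to_ki, ki_to_dg
from .values import FreeEnergyValue, ValueKind

__all__ = [
    "GroundTruth",
    "ScenarioConfig",
    "LegRecord",
    "ScenarioData",
    "generate_ground_truth",
    "simulate_leg",
    "generate_scenario",
    "protocol_config",
    "FIXTURE_EDGES",
    "FIXTURE_BATCH1",
    "FIXTURE_BATCH2",
]

# --- the 15-ligand two-batch fixture map -----------------------------------

FIXTURE_BATCH1 = ("2", "3", "4", "5", "6", "7")
FIXTURE_BATCH2 = ("8", "15", "16", "35", "36", "38", "39", "44", "45")

#: Undirected perturbation pairs. Batch-1 pairs realize the ten published
#: 3-/4-cycles over ligands 2..7; batch-2 pairs realize the 45-16-44 and
#: 38-39-35-36 cycles; 8 and 16 are joined to keep batch 2 connected,
#: 8~15 is the charge-mismatch pair (15 modelled neutral), and 7~15
#: bridges the two batches.
FIXTURE_EDGES: tuple[tuple[str, str], ...] = (
    # batch 1
    ("3", "2"), ("2", "5"), ("5", "6"), ("3", "6"), ("3", "5"), ("2", "6"),
    ("3", "4"), ("4", "7"), ("7", "6"), ("3", "7"), ("4", "6"),
    # batch 2
    ("45", "16"), ("16", "44"), ("44", "45"),
    ("38", "39"), ("39", "35"), ("35", "36"), ("36", "38"),
    ("8", "15"), ("8", "16"), ("35", "45"),
    # inter-batch bridge
    ("7", "15"),
)

RACEMATE_PARENT = "38"
RACEMATE_ENANTIOMERS = ("38R", "38S")
REFERENCE_ID = "3"
REFERENCE_KI = 1.0e-5  # mol/L
CHARGE_MISMATCH_PAIRS = (frozenset(("8", "15")),)

#: Default problem ligands: poses that docking got wrong, and ligands
#: whose edges suffer from the missing bridging water.
DEFAULT_MISPOSED = ("2", "4", "7", "16", "44")
DEFAULT_WATER_DEFECT = ("7",)

KI_RANGE = (2.0e-10, 1.0e-5)  # mol/L span of the series


@dataclass
class GroundTruth:
    """True binding free energies and problem-ligand sets of a scenario."""

    dg: dict[str, float]                  # per ligand, kcal/mol (racemate: effective)
    ki: dict[str, float]                  # back-computed, mol/L
    misposed: frozenset[str]
    water_defect: frozenset[str]
    racemates: dict[str, tuple[str, str]]  # parent -> enantiomer ids
    enantiomer_dg: dict[str, float]        # per enantiomer, kcal/mol
    temperature: float = DEFAULT_TEMPERATURE


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic study scenario ("protocol analogue").

    ``pose_bias`` / ``water_bias`` (kcal/mol) are added to the complex-leg
    target of every directed edge whose source ligand is in the misposed /
    water-defect set; ``repeat_noise`` is the per-repeat Gaussian sigma on
    the complex leg. ``samples_per_state = 0`` selects the analytic mode.
    """

    topology: str = "paper_fixture"       # or "random_connected"
    n_ligands: int = 15                   # used by random_connected
    repeats: int = 2
    n_states: int = 11
    samples_per_state: int = 500
    repeat_noise: float = 0.3
    pose_bias: float = 0.0
    water_bias: float = 0.0
    misposed: tuple[str, ...] = DEFAULT_MISPOSED
    water_defect: tuple[str, ...] = DEFAULT_WATER_DEFECT
    exp_sigma: float = 0.4
    temperature: float = DEFAULT_TEMPERATURE
    protocol: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("paper_fixture", "random_connected"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.samples_per_state < 0:
            raise ValueError("samples_per_state must be >= 0")
        if self.repeat_noise < 0 or self.pose_bias < 0 or self.water_bias < 0:
            raise ValueError("noise and bias magnitudes must be >= 0")


@dataclass(frozen=True)
class LegRecord:
    """One environment of one repeat of one directed (sub-)edge."""

    source: str          # may be an enantiomer id
    target: str
    repeat: int
    environment: str     # "free" | "complex"
    target_df: float     # exact leg free-energy target, kcal/mol (incl. noise+bias)
    matrix: ReducedPotentialMatrix | None = None

    @property
    def edge_id(self) -> str:
        return f"{self.source}~{self.target}"

    def exact_value(self) -> FreeEnergyValue:
        return FreeEnergyValue(self.target_df, 0.0, ValueKind.LEG,
                               f"{self.edge_id}#r{self.repeat}")


@dataclass
class ScenarioData:
    """Everything the analysis consumes, plus the truth behind it."""

    config: ScenarioConfig
    truth: GroundTruth
    ligands: list[Ligand]
    directed_edges: list[tuple[str, str]]   # network-level (parent ids)
    legs: list[LegRecord] = field(default_factory=list)
    experimental_dg: dict[str, float] = field(default_factory=dict)
    reference_id: str = REFERENCE_ID
    reference_dg: float = 0.0


# ---------------------------------------------------------------------------


def _fixture_ligands() -> list[Ligand]:
    out = []
    for lid in FIXTURE_BATCH1:
        out.append(Ligand(lid, batch="batch1", charge=0))
    for lid in FIXTURE_BATCH2:
        charge = 0 if lid == "15" else 1  # 15 modelled neutral
        if lid == RACEMATE_PARENT:
            out.append(Ligand(lid, batch="batch2", charge=charge,
                              is_racemate=True,
                              enantiomer_ids=RACEMATE_ENANTIOMERS))
        else:
            out.append(Ligand(lid, batch="batch2", charge=charge))
    return out


def _random_topology(n: int, rng: np.random.Generator):
    """Connected random map: a spanning path plus chords that close
    triangles, mimicking how perturbation maps are designed."""
    if n < 4:
        raise ValueError("random_connected needs at least 4 ligands")
    ids = [str(i + 1) for i in range(n)]
    edges = [(ids[i], ids[i + 1]) for i in range(n - 1)]
    for i in range(n - 2):  # close a triangle on every consecutive triple
        if rng.random() < 0.7:
            edges.append((ids[i], ids[i + 2]))
    ligands = [Ligand(l, batch="batch1", charge=0) for l in ids]
    return ligands, tuple(edges)


def generate_ground_truth(config: ScenarioConfig) -> GroundTruth:
    """Draw true binding free energies for the scenario's ligands.

    dG values are uniform over the span implied by the series' Ki range
    (10 uM down to 0.2 nM at the scenario temperature); the reference
    ligand is pinned to the dG of its 10 uM inhibition constant. The
    racemic parent's effective dG is the Boltzmann combination of its two
    enantiomers' values.
    """
    rng = np.random.default_rng(config.seed)
    t = config.temperature
    lo, hi = (ki_to_dg(KI_RANGE[0], t), ki_to_dg(KI_RANGE[1], t))
    if config.topology == "paper_fixture":
        ligand_ids = list(FIXTURE_BATCH1 + FIXTURE_BATCH2)
        racemates = {RACEMATE_PARENT: RACEMATE_ENANTIOMERS}
        misposed = frozenset(config.misposed)
        water = frozenset(config.water_defect)
    else:
        ligands, _ = _random_topology(config.n_ligands, rng)
        ligand_ids = [l.id for l in ligands]
        racemates = {}
        misposed = frozenset(m for m in config.misposed if m in ligand_ids)
        water = frozenset(w for w in config.water_defect if w in ligand_ids)

    dg = {lid: float(rng.uniform(lo, hi)) for lid in ligand_ids}
    ref = REFERENCE_ID if REFERENCE_ID in dg else ligand_ids[0]
    dg[ref] = ki_to_dg(REFERENCE_KI, t)

    enantiomer_dg: dict[str, float] = {}
    kt = kt_kcal(t)
    for parent, (e_r, e_s) in racemates.items():
        # The analysis collapses enantiomer edges with the mixture rule
        # ddG_rac->X = -kT ln[(exp(-ddG_R/kT) + exp(-ddG_S/kT))/2], whose
        # implied effective parent value is
        # dG_eff = +kT ln[(exp(g_R/kT) + exp(g_S/kT))/2]. Solve that
        # backwards so the parent's effective dG stays the drawn in-range
        # value while the enantiomers differ by a fixed gap.
        gap = float(rng.uniform(0.2, 1.0))
        g_s = dg[parent] - kt * math.log(0.5 * (1.0 + math.exp(-gap / kt)))
        g_r = g_s - gap
        enantiomer_dg[e_r] = g_r
        enantiomer_dg[e_s] = g_s

    ki = {lid: dg_to_ki(v, t) for lid, v in dg.items()}
    return GroundTruth(dg=dg, ki=ki, misposed=misposed, water_defect=water,
                       racemates=racemates, enantiomer_dg=enantiomer_dg,
                       temperature=t)


def simulate_leg(
    target_df: float,
    n_states: int = 11,
    samples_per_state: int = 500,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int | np.random.Generator = 0,
    leg_id: str = "",
) -> ReducedPotentialMatrix:
    """Gaussian-state leg whose exact free-energy change is ``target_df``
    (kcal/mol).

    State k has u_k(x) = (x - mu_k)^2/2 + c_k with mu_k spanning [0, 2]
    along the schedule (so adjacent states overlap strongly) and offsets
    c_k linear in lambda, chosen so the exact dimensionless end-to-end
    free-energy difference equals target_df / kT.
    """
    if n_states < 2:
        raise ValueError("need at least two states")
    if samples_per_state < 1:
        raise ValueError("samples_per_state must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    kt = kt_kcal(temperature)
    lam = np.linspace(0.0, 1.0, n_states)
    mu = 2.0 * lam
    c = lam * (target_df / kt)
    counts = np.full(n_states, samples_per_state)
    x = rng.normal(mu.repeat(samples_per_state), 1.0)
    u = 0.5 * (x[None, :] - mu[:, None]) ** 2 + c[:, None]
    return ReducedPotentialMatrix(u=u, counts=counts, lambda_schedule=lam,
                                  leg_id=leg_id)


def _bias_for(source_parent: str, truth: GroundTruth,
              config: ScenarioConfig) -> float:
    b = 0.0
    if source_parent in truth.misposed:
        b += config.pose_bias
    if source_parent in truth.water_defect:
        b += config.water_bias
    return b


def generate_scenario(config: ScenarioConfig) -> ScenarioData:
    """Emit the complete leg-level dataset for one scenario.

    For every directed edge and repeat the free and complex legs receive
    exact targets satisfying ddG = dG_complex - dG_free for the true
    relative binding free energy, the complex leg additionally carrying
    per-repeat Gaussian noise and (when the directed source is a problem
    ligand) the pose/water bias. Edges incident to the racemic parent are
    emitted once per enantiomer. The experimental table carries lognormal
    Ki noise equivalent to ``exp_sigma`` kcal/mol on dG.
    """
    rng = np.random.default_rng(config.seed)
    truth = generate_ground_truth(config)
    if config.topology == "paper_fixture":
        ligands = _fixture_ligands()
        pairs = FIXTURE_EDGES
    else:
        ligands, pairs = _random_topology(config.n_ligands,
                                          np.random.default_rng(config.seed))
    ligand_ids = {l.id for l in ligands}
    ref = REFERENCE_ID if REFERENCE_ID in ligand_ids else sorted(ligand_ids)[0]

    def true_dg(node: str) -> float:
        if node in truth.enantiomer_dg:
            return truth.enantiomer_dg[node]
        return truth.dg[node]

    def parent_of(node: str) -> str:
        for parent, enns in truth.racemates.items():
            if node in enns:
                return parent
        return node

    legs: list[LegRecord] = []
    directed_edges: list[tuple[str, str]] = []
    for a, b in pairs:
        directed_edges.extend([(a, b), (b, a)])
        base_free = float(rng.uniform(-1.0, 1.0))  # per-pair solvation leg
        for (s, t), free_target in (((a, b), base_free), ((b, a), -base_free)):
            # expand a racemate endpoint into its enantiomers
            sub_sources = (truth.racemates.get(s) or (s,))
            sub_targets = (truth.racemates.get(t) or (t,))
            for ss in sub_sources:
                for tt in sub_targets:
                    ddg_true = true_dg(tt) - true_dg(ss)
                    bias = _bias_for(parent_of(ss), truth, config)
                    for r in range(1, config.repeats + 1):
                        noise = float(rng.normal(0.0, config.repeat_noise)) \
                            if config.repeat_noise > 0 else 0.0
                        complex_target = free_target + ddg_true + bias + noise
                        for env, target in (("free", free_target),
                                            ("complex", complex_target)):
                            matrix = None
                            if config.samples_per_state > 0:
                                matrix = simulate_leg(
                                    target, config.n_states,
                                    config.samples_per_state,
                                    config.temperature, rng,
                                    leg_id=f"{ss}~{tt}#r{r}:{env}",
                                )
                            legs.append(LegRecord(ss, tt, r, env, target, matrix))

    # experimental table: lognormal Ki noise == Gaussian dG noise
    exp_dg = {}
    for lid in sorted(truth.dg):
        eps = float(rng.normal(0.0, config.exp_sigma)) if config.exp_sigma > 0 else 0.0
        exp_dg[lid] = truth.dg[lid] + eps
    exp_dg[ref] = ki_to_dg(REFERENCE_KI, config.temperature)

    return ScenarioData(
        config=config, truth=truth, ligands=ligands,
        directed_edges=directed_edges, legs=legs,
        experimental_dg=exp_dg, reference_id=ref,
        reference_dg=ki_to_dg(REFERENCE_KI, config.temperature),
    )


def protocol_config(label: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Scenario analogues of the five set-up protocols.

    A: automated poses, no binding-site water (pose and water biases on);
    B: poses fixed by hand (water bias only); C: water placed by hand
    (pose bias only); D: both fixed (no bias); E: protocol A with ten-fold
    sampling.
    """
    base = dict(pose_bias=2.0, water_bias=1.0, seed=seed, protocol=label)
    if label == "A":
        pass
    elif label == "B":
        base["pose_bias"] = 0.0
    elif label == "C":
        base["water_bias"] = 0.0
    elif label == "D":
        base["pose_bias"] = 0.0
        base["water_bias"] = 0.0
    elif label == "E":
        base["samples_per_state"] = 10 * ScenarioConfig().samples_per_state
    else:
        raise ValueError(f"unknown protocol label {label!r}")
    base.update(overrides)
    return ScenarioConfig(**base)
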