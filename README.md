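# fepnet

Perturbation-network analysis for alchemical relative binding free energy
(RBFE) calculations: MBAR estimation of per-leg free energies, assembly of
relative binding free energies (ΔΔG) over a ligand perturbation map,
network-wide reconstruction of absolute binding free energies against a
reference ligand, hysteresis and thermodynamic-cycle-closure diagnostics,
and benchmark metrics under assumed experimental uncertainty.

## The problem

Alchemical free-energy calculations morph one ligand X into a congeneric
ligand Y along a coupling parameter λ, in two environments ("legs"):
free in solvent and bound in the protein. The relative binding free energy
of one perturbation is

    ΔΔG(X→Y) = ΔG_complex(X→Y) − ΔG_free(X→Y),

and a hit-to-lead study runs a whole network of such perturbations —
forward and reverse, with independent repeats — over a congeneric series.
Absolute binding free energies are then reconstructed relative to a
reference ligand whose inhibition constant is known
(ΔG = RT ln(K_i/C⁰), C⁰ = 1 mol/L).

Because every computed edge should be the gradient of a single underlying
potential, two self-consistency diagnostics are available *without any
experimental data*: **hysteresis** (a forward and reverse perturbation
should cancel, ΔΔG(X→Y) + ΔΔG(Y→X) = 0) and **cycle closure** (oriented
ΔΔG values around any closed cycle of ligands should sum to zero).
Deviations at or above a threshold (0.8 kcal/mol here) flag perturbations
whose input poses or binding-site water content need attention. `fepnet`
implements this whole analysis layer for a 15-ligand, two-batch kinase
inhibitor map (one racemic ligand, one charge-mismatched edge), together
with a ground-truthed synthetic-data generator that emulates the map's
cycle structure and its characteristic failure modes.

## What is inside

| module | contents |
|---|---|
| `fepnet.estimators` | MBAR (self-consistent + Newton, log-domain, asymptotic covariance), two-state Bennett (BAR) and Zwanzig exponential averaging as oracles |
| `fepnet.network` | ligand/edge domain model, leg differencing, repeat aggregation, racemic-mixture combination, K_i↔ΔG conversion, WLS network reconstruction (`NetworkEstimator`) |
| `fepnet.diagnostics` | hysteresis, simple-cycle enumeration (length ≤ 4), closure with selectable direction policy, threshold flagging, ligand implication ranking |
| `fepnet.metrics` | R², MUE, slope with a Gaussian parametric bootstrap and the achievable-R² upper bound under assumed experimental noise |
| `fepnet.synthetic` | ground-truthed scenario generator (two-batch fixture map or random maps, Gaussian-state legs with closed-form free energies, pose/water biases, repeat noise) |
| `fepnet.io`, `fepnet.cli` | plain-text formats (TSV/CSV/JSON) and the `fepnet` command-line pipeline |

Estimator-shaped components follow scikit-learn conventions (`fit`,
fitted attributes with trailing underscores, `get_params`/`set_params`);
module-level functions are thin wrappers over them.

## Worked example

The packaged demo applies the |closure| ≥ 0.8 kcal/mol rule to the
published cycle-closure table of the five set-up protocols (A: automated
docked poses, no binding-site water; B: poses fixed by hand; C: water
placed by hand; D: both; E: A with ten-fold sampling):

```
$ fepnet demo-table3
protocol A: 6/12 cycles flagged: 2-6-5, 3-4-7-6, 4-6-7, 3-4-7, 3-4-6, 45-16-44
protocol B: 1/12 cycles flagged: 45-16-44
protocol C: 4/12 cycles flagged: 3-4-7-6, 3-7-6, 4-6-7, 45-16-44
protocol D: 1/12 cycles flagged: 45-16-44
protocol E: 1/10 cycles flagged: 3-2-5-6
```

Fixing the poses (A→B) removes five of the six flags; placing the water
(A→C) removes two; the 45-16-44 triangle stays flagged under every
protocol, implicating those three ligands independently of experiment.

The same analysis runs end-to-end on synthetic data with known truth:

```python
import fepnet as fn

cfg = fn.protocol_config("A", seed=7, samples_per_state=0)   # biased-pose analogue
sc  = fn.generate_scenario(cfg)
net = fn.build_network(sc)

flags = fn.diagnose_network(net)        # 2-cycles (hysteresis) + 3-/4-cycles
print(flags.n_flagged, flags.ranking[:3])
# 13 [('7', 4), ('16', 3), ('2', 3)]    — ligand 7 is truly misposed

est = fn.NetworkEstimator().fit(net)    # absolute dG per ligand, ref. ligand "3"
rep = fn.bootstrap_metrics({k: v.value for k, v in est.dg_.items()},
                           sc.experimental_dg, exp_sigma=0.4,
                           n_boot=1000, seed=7)
print(f"R2 = {rep.r2:.2f} ± {rep.r2_sigma:.2f}, MUE = {rep.mue:.2f} ± {rep.mue_sigma:.2f}")
# R2 = 0.32 ± 0.17, MUE = 1.72 ± 0.37   — a biased protocol scores poorly
```

The ranking's top ligand (7) is one of the ligands the generator actually
misposed, and the benchmark metrics degrade exactly the way a bad set-up
protocol does; the achievable R² given 0.4 kcal/mol experimental noise on
this series is ≈ 0.96, so the gap is attributable to the injected bias.

The file pipeline mirrors the library:
`fepnet simulate → estimate → network → diagnose → evaluate`
(see `fepnet --help`; every stage writes a manifest and a log).

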