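"""Benchmark metrics for predicted vs experimental binding free energies.

R^2 (squared Pearson correlation), mean unsigned error and the ordinary
least-squares slope of predicted regressed on experimental, with a
Gaussian parametric bootstrap over both the predicted uncertainties and an
assumed uniform experimental uncertainty (default 0.4 kcal/mol — a typical
figure when Ki values are reported without error bars). The achievable-R^2
upper bound is the same bootstrap applied to the experimental vector
against a noise-perturbed copy of itself: the score a perfect predictor
would obtain given experimental noise alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "bootstrap_metrics",
    "r2_upper_bound",
    "compare_scenarios",
    "DEFAULT_EXP_SIGMA",
]

#: Assumed experimental uncertainty on dG from Ki, kcal/mol.
DEFAULT_EXP_SIGMA = 0.4


@dataclass
class MetricsReport:
    """Bootstrap summary of one scenario's agreement with experiment."""

    r2: float
    r2_sigma: float
    mue: float
    mue_sigma: float
    slope: float
    slope_sigma: float
    n_ligands: int
    protocol: str = ""
    n_boot: int = 0
    seed: int | None = None
    exp_sigma: float = DEFAULT_EXP_SIGMA
    r2_upper: float | None = None
    r2_upper_sigma: float | None = None
    n_flagged: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _common(predicted: dict[str, float], experimental: dict[str, float]):
    ligands = sorted(set(predicted) & set(experimental))
    if len(ligands) < 3:
        raise ValueError(
            f"need at least 3 common ligands, got {len(ligands)}"
        )
    pred = np.array([predicted[l] for l in ligands], dtype=float)
    exp = np.array([experimental[l] for l in ligands], dtype=float)
    return ligands, pred, exp


def compute_metrics(
    predicted: dict[str, float], experimental: dict[str, float]
) -> tuple[float, float, float]:
    """(R^2, MUE, slope) over the ligands present in both tables.

    R^2 is the squared Pearson correlation; the slope is from OLS of
    predicted (ordinate) on experimental (abscissa); MUE is the mean
    absolute deviation in kcal/mol.
    """
    _, pred, exp = _common(predicted, experimental)
    if np.std(pred) == 0 or np.std(exp) == 0:
        raise ValueError("R^2 undefined: zero variance in predictions or experiment")
    r = stats.pearsonr(pred, exp).statistic
    slope = stats.linregress(exp, pred).slope
    mue = float(np.mean(np.abs(pred - exp)))
    return float(r * r), mue, float(slope)


def bootstrap_metrics(
    predicted: dict[str, float],
    experimental: dict[str, float],
    predicted_sigma: dict[str, float] | None = None,
    exp_sigma: float = DEFAULT_EXP_SIGMA,
    n_boot: int = 1000,
    seed: int | None = None,
    protocol: str = "",
) -> MetricsReport:
    """Parametric bootstrap of (R^2, MUE, slope).

    Each draw perturbs every predicted value by N(0, sigma_i^2) and every
    experimental value by N(0, exp_sigma^2) and recomputes the metrics;
    means and standard deviations over draws are reported.
    """
    if exp_sigma < 0:
        raise ValueError("exp_sigma must be >= 0")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ligands, pred, exp = _common(predicted, experimental)
    psig = np.array(
        [0.0 if predicted_sigma is None else predicted_sigma.get(l, 0.0)
         for l in ligands]
    )
    if exp_sigma == 0.0 and not psig.any():
        # degenerate: every draw is identical
        mean = np.array(compute_metrics(dict(zip(ligands, pred)),
                                        dict(zip(ligands, exp))))
        sd = np.zeros(3)
    else:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_boot, 3))
        for b in range(n_boot):
            p = pred + rng.normal(0.0, 1.0, len(pred)) * psig
            e = exp + rng.normal(0.0, exp_sigma, len(exp))
            draws[b] = compute_metrics(dict(zip(ligands, p)),
                                       dict(zip(ligands, e)))
        mean = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=0)
    return MetricsReport(
        r2=float(mean[0]), r2_sigma=float(sd[0]),
        mue=float(mean[1]), mue_sigma=float(sd[1]),
        slope=float(mean[2]), slope_sigma=float(sd[2]),
        n_ligands=len(ligands), protocol=protocol,
        n_boot=n_boot, seed=seed, exp_sigma=exp_sigma,
    )


def r2_upper_bound(
    experimental: dict[str, float],
    exp_sigma: float = DEFAULT_EXP_SIGMA,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Best achievable R^2 given experimental noise alone.

    Mean and std over draws of the R^2 between the experimental vector and
    a copy perturbed by N(0, exp_sigma^2) per ligand. exp_sigma = 0 gives
    exactly (1.0, 0.0).
    """
    exp = np.array([experimental[l] for l in sorted(experimental)], dtype=float)
    if len(exp) < 3:
        raise ValueError("need at least 3 ligands")
    if np.std(exp) == 0:
        raise ValueError("upper bound undefined: experimental vector has zero variance")
    if exp_sigma == 0:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_boot)
    for b in range(n_boot):
        noisy = exp + rng.normal(0.0, exp_sigma, len(exp))
        if np.std(noisy) == 0:  # pragma: no cover - measure-zero event
            r2s[b] = 0.0
            continue
        r = stats.pearsonr(exp, noisy).statistic
        r2s[b] = r * r
    return float(r2s.mean()), float(r2s.std(ddof=0))


def compare_scenarios(reports: list[MetricsReport]) -> pd.DataFrame:
    """Side-by-side table of scenario metrics, sorted by MUE ascending.

    Scenarios evaluated over different ligand counts trigger a warning
    listing the mismatch; rows are still produced.
    """
    if not reports:
        raise ValueError("no reports to compare")
    ns = {r.n_ligands for r in reports}
    if len(ns) > 1:
        import warnings

        warnings.warn(f"scenario ligand counts differ: {sorted(ns)}", stacklevel=2)
    rows = [
        {
            "protocol": r.protocol,
            "r2": r.r2, "r2_sigma": r.r2_sigma,
            "mue": r.mue, "mue_sigma": r.mue_sigma,
            "slope": r.slope, "slope_sigma": r.slope_sigma,
            "n_ligands": r.n_ligands,
            "n_flagged": r.n_flagged,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows).sort_values(["mue", "protocol"], kind="mergesort")
    return df.reset_index(drop=True)
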