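"""Free-energy estimators from per-state reduced-potential samples.

The principal estimator is MBAR (multistate Bennett acceptance ratio),
which solves the self-consistent equations

    f_k = -ln sum_n exp(-u_kn) / sum_l N_l exp(f_l - u_ln)

for the dimensionless free energies of K thermodynamic states given the
reduced potential u_kn of every sample n evaluated in every state k.
Bennett's two-state acceptance ratio (the K=2 special case, solved by 1-D
root finding) and unidirectional Zwanzig exponential averaging are provided
as independent cross-checks.

All arithmetic on reduced potentials happens in the log domain; raw
exponentials of u are never formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .constants import DEFAULT_TEMPERATURE, kt_kcal
from .values import FreeEnergyValue, ValueKind

__all__ = [
    "ReducedPotentialMatrix",
    "MBARResult",
    "MBAR",
    "mbar_free_energies",
    "mbar_covariance",
    "leg_free_energy",
    "bar_two_state",
    "exp_averaging",
    "NoOverlapError",
]


class NoOverlapError(RuntimeError):
    """Raised when two states share no measurable phase-space overlap."""


@dataclass
class ReducedPotentialMatrix:
    """Samples of reduced potentials for K alchemical states.

    Parameters
    ----------
    u : ndarray, shape (K, N)
        ``u[k, n]`` is state k's reduced potential evaluated on sample n.
        Samples are ordered by origin state: the first ``counts[0]`` columns
        were drawn from state 0, the next ``counts[1]`` from state 1, etc.
    counts : ndarray, shape (K,)
        Number of samples drawn from each state; zero marks a "virtual"
        state that is evaluated but never sampled.
    lambda_schedule : ndarray, shape (K,), optional
        Coupling-parameter value of each state, strictly increasing in
        [0, 1]. Defaults to K equidistant values.
    """

    u: np.ndarray
    counts: np.ndarray
    lambda_schedule: np.ndarray | None = None
    leg_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.u.ndim != 2:
            raise ValueError("u must be a K x N matrix")
        k, n = self.u.shape
        if k < 2:
            raise ValueError(f"need at least two states, got K={k}")
        if self.counts.shape != (k,):
            raise ValueError("counts must have one entry per state")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != n:
            raise ValueError(
                f"counts sum to {int(self.counts.sum())} but u has {n} samples"
            )
        if not np.isfinite(self.u).all():
            raise ValueError("u contains non-finite entries")
        if self.lambda_schedule is None:
            self.lambda_schedule = np.linspace(0.0, 1.0, k)
        else:
            self.lambda_schedule = np.asarray(self.lambda_schedule, dtype=float)
            if self.lambda_schedule.shape != (k,):
                raise ValueError("lambda_schedule must have one value per state")
            if not (np.diff(self.lambda_schedule) > 0).all():
                raise ValueError("lambda_schedule must be strictly increasing")

    @property
    def n_states(self) -> int:
        return self.u.shape[0]

    @property
    def n_samples(self) -> int:
        return self.u.shape[1]

    def origin_slices(self) -> list[slice]:
        """Column slice of the samples drawn from each state."""
        edges = np.concatenate([[0], np.cumsum(self.counts)])
        return [slice(int(edges[k]), int(edges[k + 1]))
                for k in range(self.n_states)]


@dataclass
class MBARResult:
    """Converged (or not) MBAR solution.

    ``f`` holds dimensionless free energies with the gauge f[0] = 0;
    ``covariance`` is the asymptotic covariance of f.
    """

    f: np.ndarray
    covariance: np.ndarray
    iterations: int
    converged: bool

    def delta_f(self, i: int = 0, j: int = -1) -> float:
        return float(self.f[j] - self.f[i])

    def delta_f_sigma(self, i: int = 0, j: int = -1) -> float:
        c = self.covariance
        var = c[i, i] + c[j, j] - 2.0 * c[i, j]
        return float(np.sqrt(max(var, 0.0)))


class MBAR(BaseEstimator):
    """MBAR solver: self-consistent iteration with Newton acceleration.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the max absolute change of f between
        iterations (dimensionless).
    max_iter : int
        Iteration budget; exceeding it yields ``converged_ = False`` and a
        warning, never a silent success.
    n_sc_start : int
        Self-consistent sweeps performed before Newton steps are attempted;
        Newton steps that fail to reduce the residual fall back to a
        self-consistent sweep.

    Attributes
    ----------
    f_ : ndarray, shape (K,)
        Dimensionless state free energies, f_[0] == 0.
    covariance_ : ndarray, shape (K, K)
        Asymptotic covariance of f_ from the weighted-sample estimator.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 10_000,
                 n_sc_start: int = 5):
        self.tol = tol
        self.max_iter = max_iter
        self.n_sc_start = n_sc_start

    # -- solver internals ---------------------------------------------------
    # hot path: hand-rolled logsumexp (max-shifted) — the scipy version
    # carries array-API dispatch overhead that dominates at this size

    @staticmethod
    def _lse(a: np.ndarray, axis: int) -> np.ndarray:
        amax = np.max(a, axis=axis, keepdims=True)
        out = np.log(np.sum(np.exp(a - amax), axis=axis))
        return out + np.squeeze(amax, axis=axis)

    @staticmethod
    def _log_denom(u: np.ndarray, f: np.ndarray, log_n: np.ndarray) -> np.ndarray:
        """log D_n = logsumexp_l (ln N_l + f_l - u_ln); shape (N,)."""
        return MBAR._lse(log_n[:, None] + f[:, None] - u, axis=0)

    @staticmethod
    def _sc_update(u: np.ndarray, f: np.ndarray, log_n: np.ndarray) -> np.ndarray:
        log_d = MBAR._log_denom(u, f, log_n)
        f_new = -MBAR._lse(-u - log_d[None, :], axis=1)
        return f_new - f_new[0]

    @staticmethod
    def _weights(u: np.ndarray, f: np.ndarray, log_n: np.ndarray) -> np.ndarray:
        """W_nk = exp(f_k - u_kn) / D_n, shape (N, K); sum_n W_nk = 1 at
        the fixed point for sampled states."""
        log_d = MBAR._log_denom(u, f, log_n)
        return np.exp((f[:, None] - u - log_d[None, :]).T)

    def fit(self, matrix: ReducedPotentialMatrix) -> "MBAR":
        u = matrix.u
        counts = matrix.counts.astype(float)
        sampled = counts > 0
        if sampled.sum() < 2:
            raise ValueError("MBAR needs at least two sampled states")
        with np.errstate(divide="ignore"):
            log_n = np.where(sampled, np.log(np.maximum(counts, 1e-300)), -np.inf)

        f = self._warm_start(matrix)
        converged = False
        it = 0
        while it < self.max_iter:
            it += 1
            f_sc = self._sc_update(u, f, log_n)
            resid = float(np.max(np.abs(f_sc - f)))
            if resid < self.tol:
                f = f_sc
                converged = True
                break
            if it <= self.n_sc_start:
                f = f_sc
                continue
            f_newton = self._newton_step(u, f, log_n, counts, sampled)
            if f_newton is not None:
                resid_newton = float(
                    np.max(np.abs(self._sc_update(u, f_newton, log_n) - f_newton))
                )
                if resid_newton < resid:
                    f = f_newton
                    continue
            f = f_sc
        if not converged:
            warnings.warn(
                f"MBAR did not converge in {it} iterations "
                f"(residual {resid:.2e} > tol {self.tol:.1e})", stacklevel=2,
            )
        self.f_ = f
        self.n_iter_ = it
        self.converged_ = converged
        self.covariance_ = self._asymptotic_covariance(u, f, log_n, counts)
        return self

    def _warm_start(self, matrix: ReducedPotentialMatrix) -> np.ndarray:
        """Forward exponential-averaging ladder over adjacent sampled states."""
        u = matrix.u
        k = matrix.n_states
        slices = matrix.origin_slices()
        sampled = [i for i in range(k) if matrix.counts[i] > 0]
        f = np.zeros(k)
        ladder = {sampled[0]: 0.0}
        for a, b in zip(sampled[:-1], sampled[1:]):
            w = u[b, slices[a]] - u[a, slices[a]]
            df = -(logsumexp(-w) - np.log(len(w)))
            ladder[b] = ladder[a] + float(df)
        # virtual states: interpolate linearly on the state index
        xs = np.array(sampled, dtype=float)
        ys = np.array([ladder[i] for i in sampled])
        f[:] = np.interp(np.arange(k, dtype=float), xs, ys)
        return f - f[0]

    @staticmethod
    def _newton_step(u, f, log_n, counts, sampled) -> np.ndarray | None:
        """One Newton step on f[1:] with f[0] fixed; None if the linear
        solve fails."""
        w = MBAR._weights(u, f, log_n)  # (N, K)
        col = w.sum(axis=0)
        grad = counts * (col - 1.0)
        grad = np.where(sampled, grad, 0.0)
        # H_kl = N_k (delta_kl sum_n W_nk - N_l sum_n W_nk W_nl)
        wtw = w.T @ w
        h = np.diag(counts * col) - (counts[:, None] * wtw * counts[None, :])
        try:
            step = np.linalg.solve(h[1:, 1:], -grad[1:])
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(step).all():
            return None
        # damp absurd steps so the SC fallback can take over
        if np.max(np.abs(step)) > 50.0:
            return None
        f_new = f.copy()
        f_new[1:] += step
        return f_new - f_new[0]

    @staticmethod
    def _asymptotic_covariance(u, f, log_n, counts) -> np.ndarray:
        """Asymptotic covariance of f via the weighted-sample estimator.

        Theta = V S (I - S V' N V S)^+ S V', where W = U S V' is the thin
        SVD of the (N, K) weight matrix; computed from the K x K Gram
        matrix W'W so the sample dimension is never decomposed.
        """
        w = MBAR._weights(u, f, log_n)
        gram = w.T @ w
        evals, v = np.linalg.eigh(gram)
        s = np.sqrt(np.clip(evals, 0.0, None))
        n_diag = np.diag(counts)
        inner = np.eye(len(f)) - np.diag(s) @ v.T @ n_diag @ v @ np.diag(s)
        inner_pinv = np.linalg.pinv(inner, rcond=1e-10, hermitian=True)
        theta = v @ np.diag(s) @ inner_pinv @ np.diag(s) @ v.T
        return (theta + theta.T) / 2.0

    def result(self) -> MBARResult:
        return MBARResult(self.f_, self.covariance_, self.n_iter_, self.converged_)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def mbar_free_energies(
    matrix: ReducedPotentialMatrix,
    tolerance: float = 1e-10,
    max_iterations: int = 10_000,
) -> MBARResult:
    """Solve the MBAR equations for a reduced-potential matrix."""
    return MBAR(tol=tolerance, max_iter=max_iterations).fit(matrix).result()


def mbar_covariance(result: MBARResult, matrix: ReducedPotentialMatrix) -> np.ndarray:
    """Asymptotic K x K covariance of the state free energies."""
    if not result.converged:
        warnings.warn("covariance requested for a non-converged MBAR result",
                      stacklevel=2)
    counts = matrix.counts.astype(float)
    with np.errstate(divide="ignore"):
        log_n = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), -np.inf)
    return MBAR._asymptotic_covariance(matrix.u, result.f, log_n, counts)


def leg_free_energy(
    matrix: ReducedPotentialMatrix,
    temperature: float = DEFAULT_TEMPERATURE,
    tolerance: float = 1e-10,
    max_iterations: int = 10_000,
) -> FreeEnergyValue:
    """End-to-end free-energy change of one leg, in kcal/mol.

    Runs MBAR and converts the dimensionless end-state difference
    f[K-1] - f[0] with kT at the given temperature.
    """
    res = mbar_free_energies(matrix, tolerance, max_iterations)
    kt = kt_kcal(temperature)
    return FreeEnergyValue(
        kt * res.delta_f(), kt * res.delta_f_sigma(),
        ValueKind.LEG, matrix.leg_id,
    )


def _work_values(matrix: ReducedPotentialMatrix) -> tuple[np.ndarray, np.ndarray]:
    if matrix.n_states != 2:
        raise ValueError("two-state estimators require K = 2")
    s0, s1 = matrix.origin_slices()
    w_f = matrix.u[1, s0] - matrix.u[0, s0]  # forward work, samples from 0
    w_r = matrix.u[0, s1] - matrix.u[1, s1]  # reverse work, samples from 1
    return w_f, w_r


def bar_two_state(matrix: ReducedPotentialMatrix) -> FreeEnergyValue:
    """Bennett acceptance-ratio estimate of Delta f (dimensionless) for a
    two-state matrix, by 1-D root finding on the acceptance equation.

    At K = 2 the MBAR fixed point satisfies the same equation, so the two
    estimators agree to solver precision. The returned value is in reduced
    units; no uncertainty is attached (oracle use).
    """
    w_f, w_r = _work_values(matrix)
    n0, n1 = len(w_f), len(w_r)
    if n0 == 0 or n1 == 0:
        raise ValueError("BAR needs samples from both states")
    du = np.concatenate([w_f, -w_r])  # u1 - u0 for every sample
    m = np.log(n0 / n1)

    def g(df: float) -> float:
        return float(expit(df - m - du).sum() - n1)

    span = float(np.max(np.abs(du))) + 50.0
    lo, hi = -span, span
    df = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    # the acceptance equation is monotone and always has a root; lack of
    # phase-space overlap shows up as a flat plateau (all Fermi terms
    # saturated at 0 or 1), i.e. a vanishing slope at the root
    s = expit(df - m - du)
    slope = float((s * (1.0 - s)).sum())
    if slope < 1e-8 * len(du):
        raise NoOverlapError(
            "BAR root is degenerate (no measurable overlap between states)"
        )
    return FreeEnergyValue(float(df), 0.0, ValueKind.LEG, matrix.leg_id)


def exp_averaging(
    matrix: ReducedPotentialMatrix, direction: str = "forward"
) -> FreeEnergyValue:
    """Zwanzig exponential-averaging estimate of Delta f (dimensionless).

    forward: Delta f = -ln < exp(-(u1 - u0)) > over state-0 samples;
    reverse uses state-1 samples. Biased at finite n — the forward and
    reverse estimates bracket the BAR answer in expectation.
    """
    w_f, w_r = _work_values(matrix)
    if direction == "forward":
        if len(w_f) == 0:
            raise ValueError("no samples from state 0")
        df = -(logsumexp(-w_f) - np.log(len(w_f)))
    elif direction == "reverse":
        if len(w_r) == 0:
            raise ValueError("no samples from state 1")
        df = logsumexp(-w_r) - np.log(len(w_r))
    else:
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    return FreeEnergyValue(float(df), 0.0, ValueKind.LEG, matrix.leg_id)
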