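"""Shared fixtures: small Gaussian two-state systems and toy networks."""

from __future__ import annotations

import numpy as np
import pytest

from fepnet import (
    EdgeEstimate,
    FreeEnergyValue,
    Ligand,
    PerturbationNetwork,
    ReducedPotentialMatrix,
    ValueKind,
)


def gaussian_sigma_system(n_per_state: int, seed: int) -> ReducedPotentialMatrix:
    """Two harmonic states of width 1 and 2: u0 = x^2/2, u1 = x^2/8.

    Exact dimensionless free-energy difference:
    f1 - f0 = -ln(sigma1/sigma0) = -ln 2.
    """
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 1, n_per_state),
                        rng.normal(0, 2, n_per_state)])
    u = np.vstack([x**2 / 2.0, x**2 / 8.0])
    return ReducedPotentialMatrix(u=u, counts=np.array([n_per_state, n_per_state]))


@pytest.fixture
def gaussian_system() -> ReducedPotentialMatrix:
    return gaussian_sigma_system(2000, seed=42)


def edge(source: str, target: str, value: float, sigma: float = 0.1) -> EdgeEstimate:
    return EdgeEstimate(
        source=source, target=target,
        ddg=FreeEnergyValue(value, sigma, ValueKind.EDGE_MEAN, f"{source}~{target}"),
    )


def make_network(edges: list[tuple], reference: str = "ref",
                 reference_dg: float = -6.86) -> PerturbationNetwork:
    """Network from (source, target, value[, sigma]) tuples."""
    ids = sorted({e[0] for e in edges} | {e[1] for e in edges} | {reference})
    net = PerturbationNetwork([Ligand(i) for i in ids], reference,
                              reference_dg=reference_dg)
    for e in edges:
        net.add_edge(edge(*e))
    return net
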