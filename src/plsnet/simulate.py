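"""Synthetic linear gene networks with multifactorial-style expression data.

The generator produces a sparse signed adjacency (regulator row -> target
column) and simulates each experimental condition as a small simultaneous
perturbation of every gene: per-gene basal perturbations ``b ~ N(0,
perturbation_sd^2)`` are propagated through the network to the linear
steady state ``x = A^T x + b``, i.e. ``x = (I - A^T)^{-1} b``, and
independent measurement noise ``N(0, noise_sd^2)`` is added.  The spectral
radius of ``|A|`` is kept below 1 so the steady-state solve is stable.

A linear steady-state model (rather than kinetic ODE dynamics) is the
desk-scale testbed matching the additive regression model the inference
method fits; weights are signed but the gold standard records only which
edges exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import GoldStandard

__all__ = [
    "SyntheticNetwork",
    "generate_network",
    "simulate_expression",
    "as_gold_standard",
]

# adjacency magnitudes are rescaled to keep spectral radius at or below this
SPECTRAL_CAP = 0.9


@dataclass(frozen=True)
class SyntheticNetwork:
    """Ground-truth linear network.

    ``adjacency[i, j]`` is the signed weight with which gene i drives
    gene j; no self-loops; ``spectral radius(|adjacency|) < 1``.
    """

    adjacency: np.ndarray
    gene_ids: tuple
    noise_sd: float
    perturbation_sd: float
    seed: int

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", A)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        p = len(self.gene_ids)
        if A.shape != (p, p):
            raise ValueError(f"adjacency shape {A.shape} does not match {p} genes")
        if np.any(np.diagonal(A) != 0):
            raise ValueError("self-loops are not allowed")
        if A.size and np.max(np.abs(np.linalg.eigvals(np.abs(A)))) >= 1.0:
            raise ValueError("spectral radius of |adjacency| must be < 1")

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    @property
    def regulator_set(self) -> tuple:
        """Genes with out-degree > 0."""
        out = np.any(self.adjacency != 0, axis=1)
        return tuple(g for g, has in zip(self.gene_ids, out) if has)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))


def generate_network(
    p,
    avg_out_degree=2.0,
    weight_range=(0.5, 1.5),
    seed=0,
    noise_sd=0.2,
    perturbation_sd=1.0,
) -> SyntheticNetwork:
    """Draw a random sparse signed network.

    Each ordered non-self pair carries an edge independently with
    probability ``avg_out_degree / (p - 1)``; weights are uniform in
    ``weight_range`` with random sign.  If the resulting ``|A|`` has
    spectral radius >= 0.9 all weights are rescaled to bring it to 0.9.

    Raises
    ------
    ValueError
        If ``p < 2``, ``avg_out_degree < 0`` or ``avg_out_degree > p - 1``.
    """
    if p < 2:
        raise ValueError("need at least 2 genes")
    if avg_out_degree < 0:
        raise ValueError("avg_out_degree must be >= 0")
    if avg_out_degree > p - 1:
        raise ValueError(
            f"avg_out_degree {avg_out_degree} infeasible for {p} genes (max {p - 1})"
        )
    rng = np.random.default_rng(seed)
    edge_prob = avg_out_degree / (p - 1)
    mask = rng.random((p, p)) < edge_prob
    np.fill_diagonal(mask, False)
    lo, hi = weight_range
    weights = rng.uniform(lo, hi, size=(p, p)) * rng.choice([-1.0, 1.0], size=(p, p))
    A = np.where(mask, weights, 0.0)
    if A.any():
        radius = np.max(np.abs(np.linalg.eigvals(np.abs(A))))
        if radius >= SPECTRAL_CAP:
            A *= SPECTRAL_CAP / radius
    return SyntheticNetwork(
        adjacency=A,
        gene_ids=tuple(f"G{i + 1}" for i in range(p)),
        noise_sd=float(noise_sd),
        perturbation_sd=float(perturbation_sd),
        seed=int(seed),
    )


def simulate_expression(network: SyntheticNetwork, n_conditions, seed=None) -> pd.DataFrame:
    """Simulate multifactorial-perturbation expression data.

    Each condition draws per-gene basal perturbations, solves the linear
    steady state and adds measurement noise.  ``seed=None`` derives the
    stream from the network's own seed, so the same network yields the
    same data.

    Returns a conditions x genes DataFrame.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    rng = np.random.default_rng(network.seed if seed is None else seed)
    p = network.p
    B = rng.normal(0.0, network.perturbation_sd, size=(n_conditions, p))
    # x = A^T x + b  per condition  =>  X = B (I - A)^{-1} row-wise
    X = np.linalg.solve((np.eye(p) - network.adjacency).T, B.T).T
    if network.noise_sd > 0:
        X = X + rng.normal(0.0, network.noise_sd, size=X.shape)
    return pd.DataFrame(X, columns=network.gene_ids)


def as_gold_standard(network: SyntheticNetwork) -> GoldStandard:
    """Gold standard with positives = existing edges and eligible universe
    = all non-self (regulator, gene) pairs over the regulator set."""
    idx = {i: g for i, g in enumerate(network.gene_ids)}
    rows, cols = np.nonzero(network.adjacency)
    positives = frozenset((idx[i], idx[j]) for i, j in zip(rows, cols))
    regulators = network.regulator_set
    eligible = frozenset(
        (r, g) for r in regulators for g in network.gene_ids if r != g
    )
    return GoldStandard(positives=positives, eligible_pairs=eligible)
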