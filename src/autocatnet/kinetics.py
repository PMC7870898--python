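"""Linear kinetic model of covalent catalyst accumulation.

Each species i obeys ``xdot_i = sum_j alpha_ij x_j + beta_ij`` with x(0) = 0:
covalent catalysts (concentration x_j) contribute first-order terms, the
noncovalent fragment complexes a constant production.  The model neglects
substrate depletion, so it applies to early reaction times (the experimental
incubation, 60 min by default).

The solution of ``xdot = A x + b`` is computed exactly through the exponential
of the augmented matrix ``[[A, b], [0, 0]]``, which is well defined even when
A is singular (it usually is: rows of species receiving no catalysis are 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy import stats

from .chemistry import ReactionNetwork, SpeciesId

logger = logging.getLogger(__name__)

#: Default incubation time, minutes (the experiment incubates 1 h at 48 C).
DEFAULT_INCUBATION_MIN = 60.0


class UndefinedCompositionError(ValueError):
    """No mass anywhere: fractions are undefined."""


@dataclass
class KineticState:
    t: float  # minutes
    x: np.ndarray  # uM, ordered as net.species


@dataclass
class Composition:
    """Normalized species fractions, optionally with the total yield in uM."""

    fractions: dict[SpeciesId, float]
    yield_uM: float | None = None

    def as_vector(self, species: tuple[SpeciesId, ...]) -> np.ndarray:
        return np.array([self.fractions.get(s, 0.0) for s in species])


def complex_formation_time(k_on_per_uM_min: float = 0.65, partner_uM: float = 1.6) -> float:
    """Characteristic time (min) for noncovalent complex formation, 1/(k_on * [Z]).

    At the experimental Z-fragment concentration this is ~1 min, far below the
    60-min incubation — the basis for treating complex formation as fast.
    """
    return 1.0 / (k_on_per_uM_min * partner_uM)


def solve_kinetics(net: ReactionNetwork, t: float) -> KineticState:
    """Exact solution of ``xdot = A x + b``, x(0) = 0, at time ``t`` (minutes)."""
    if t < 0:
        raise ValueError("time must be >= 0")
    n = net.size
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = net.A
    M[:n, n] = net.b
    phi = expm(M * t)
    x = phi[:n, n]
    # clip tiny negative round-off; the exact solution is nonnegative
    return KineticState(t=t, x=np.maximum(x, 0.0))


def predict_yield(net: ReactionNetwork, t: float = DEFAULT_INCUBATION_MIN) -> float:
    """Total covalent catalyst concentration (uM) accumulated by time t."""
    return float(solve_kinetics(net, t).x.sum())


def predict_fractions(net: ReactionNetwork, t: float = DEFAULT_INCUBATION_MIN) -> Composition:
    """Species fractions x_i(t) / sum_j x_j(t) under the kinetic model."""
    if t <= 0:
        raise ValueError("fractions require t > 0")
    state = solve_kinetics(net, t)
    total = state.x.sum()
    if total <= 0:
        raise UndefinedCompositionError("no production into any species (all beta = 0)")
    return Composition(
        fractions={s: float(v) for s, v in zip(net.species, state.x / total)},
        yield_uM=float(total),
    )


def indegree_fractions(net: ReactionNetwork, weights: str = "alpha") -> Composition:
    """Weighted in-degree centrality, normalized to fractions.

    ``weights="alpha"`` sums covalent rates into each species (the
    perturbation theory's working approximation); ``weights="beta"`` sums the
    noncovalent contributions, which is the exact composition in the
    noncovalent-only regime (all alpha = 0), where growth is linear: x = b t.
    """
    if weights == "alpha":
        c = net.A.sum(axis=1)
    elif weights == "beta":
        c = net.b.copy()
    else:
        raise ValueError("weights must be 'alpha' or 'beta'")
    total = c.sum()
    if total <= 0:
        raise UndefinedCompositionError(f"all {weights}-weighted in-degrees are zero")
    return Composition(fractions={s: float(v) for s, v in zip(net.species, c / total)})


@dataclass
class EigenvectorResult:
    composition: Composition
    converged: bool
    iterations: int


def eigenvector_fractions(
    net: ReactionNetwork, tol: float = 1e-12, max_iter: int = 100_000
) -> EigenvectorResult:
    """Leading-eigenvector centrality of A by power iteration from uniform.

    Predicts fractions in the covalent-only regime at long times, where
    x(t) aligns with the dominant eigenvector of A (Perron direction).
    Non-convergence (e.g. rotational degeneracy of a pure cycle whose
    dominant eigenvalues are complex) is flagged rather than raised.
    """
    A = net.A
    if not np.any(A > 0):
        raise UndefinedCompositionError("zero rate matrix: eigenvector centrality undefined")
    v = np.full(net.size, 1.0 / net.size)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = A @ v
        norm = w.sum()
        if norm <= 0:  # A nilpotent along this direction
            break
        w /= norm
        if np.abs(w - v).max() < tol:
            v = w
            converged = True
            break
        v = w
    if not converged:
        logger.warning("power iteration did not converge in %d iterations", it)
    comp = Composition(fractions={s: float(max(val, 0.0)) for s, val in zip(net.species, v)})
    return EigenvectorResult(composition=comp, converged=converged, iterations=it)


def has_self_loop(net: ReactionNetwork, sp: SpeciesId, table=None) -> bool:
    i = net.index(sp)
    return (sp, sp) in net.edges or net.A[i, i] > 0


@dataclass
class CentralityComparison:
    r: float
    n_pairs: int
    records: "object"  # pandas DataFrame: network, species, indegree, eigen, self_loop
    n_skipped: int


def compare_centralities(nets: list[ReactionNetwork]) -> CentralityComparison:
    """Pooled Pearson correlation between in-degree and eigenvector fractions.

    Pools every (network, species) fraction pair across the input networks.
    Species with a self-loop are flagged: their eigenvector fraction tends to
    exceed the in-degree one (self-amplification that in-degree ignores).
    Networks with degenerate compositions are skipped with a log entry.
    """
    import pandas as pd

    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    rows = []
    skipped = 0
    for net in nets:
        try:
            ind = indegree_fractions(net, weights="alpha")
            eig = eigenvector_fractions(net)
        except UndefinedCompositionError:
            logger.info("skipping network %s: degenerate composition", net.key)
            skipped += 1
            continue
        if not eig.converged:
            logger.info("skipping network %s: eigenvector iteration did not converge", net.key)
            skipped += 1
            continue
        for s in net.species:
            rows.append(
                {
                    "network": net.key,
                    "species": str(s),
                    "indegree": ind.fractions[s],
                    "eigen": eig.composition.fractions[s],
                    "self_loop": has_self_loop(net, s),
                }
            )
    df = pd.DataFrame(rows)
    if len(df) < 2:
        raise ValueError("not enough non-degenerate networks to correlate")
    if df["indegree"].nunique() == 1 or df["eigen"].nunique() == 1:
        r = 1.0 if np.allclose(df["indegree"], df["eigen"]) else float("nan")
    else:
        r = float(stats.pearsonr(df["indegree"], df["eigen"]).statistic)
    return CentralityComparison(r=r, n_pairs=len(df), records=df, n_skipped=skipped)
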