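"""Compositional perturbation between networks differing by one species.

For networks G and G' = G + {a}, with V the common species set, the
perturbation is the L1 distance between the two compositions renormalized
on V:

    p = sum_{v in V} |y'_v - y_v|,    0 <= p <= 2.

Under the in-degree approximation of compositions, p admits a closed-form
prediction from four topology parameters: the breadth n (species of G
targeted by a), the novelty m (species of G sharing a's IGS), the background
strength sigma_G (sum of all catalytic rates inside G) and the rate e of a's
reactions:

    p_hat = 2 n (1 - n m / s) / (s + n),   s = sigma_G / e.

The prediction assumes every target's renormalized fraction increases; when
it would be negative the record is flagged invalid rather than clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import RateTable, ReactionNetwork, SpeciesId, build_network, network_key
from .kinetics import Composition

logger = logging.getLogger(__name__)


class UndefinedPerturbationError(ValueError):
    """A composition carries no mass on the common species set."""


def perturbation(comp_G: Composition, comp_Gp: Composition, V: set[SpeciesId]) -> float:
    """L1 distance between two compositions renormalized on the common set V.

    Symmetric in its two arguments; the maximum, 2, is reached for a full
    compositional switch (all mass moving to disjoint species).
    """
    if not V:
        raise UndefinedPerturbationError("common species set V is empty")
    ordered = tuple(sorted(V))
    y = comp_G.as_vector(ordered)
    yp = comp_Gp.as_vector(ordered)
    ty, typ = y.sum(), yp.sum()
    if ty <= 0 or typ <= 0:
        raise UndefinedPerturbationError("zero mass on V in one of the compositions")
    return float(np.abs(yp / typ - y / ty).sum())


@dataclass
class PerturbationParams:
    """Topology parameters governing the predicted perturbation."""

    n: int  # perturbation breadth: targets of a inside G
    m: int  # catalytic novelty: species of G sharing a's IGS (0 = innovation)
    sigma_G: float  # background strength: sum of catalytic rates inside G, min^-1
    e: float  # rate of the reactions catalyzed by a, min^-1


def background_strength(G: ReactionNetwork) -> float:
    """sigma_G: total rate over all directed interactions present in G.

    Counts each ordered pair (j -> i) once, self-loops included; only rates at
    or above the edge threshold enter (they define "interactions present").
    """
    return float(sum(G.A[G.index(i), G.index(j)] for (j, i) in G.edges))


def perturbation_params(G: ReactionNetwork, a: SpeciesId, table: RateTable) -> PerturbationParams:
    """Extract (n, m, sigma_G, e) for adding species ``a`` to network ``G``."""
    if a in G.species:
        raise ValueError(f"species {a} already in network")
    n = sum(
        1 for v in G.species if table.pair_alpha(a.igs, v.tag) >= table.edge_threshold
    )
    m = sum(1 for u in G.species if u.igs == a.igs)
    return PerturbationParams(
        n=n, m=m, sigma_G=background_strength(G), e=table.strong_pair_alpha(a.igs)
    )


def predict_perturbation(params: PerturbationParams) -> tuple[float, bool]:
    """Analytical perturbation prediction from topology parameters.

    Returns ``(p_hat, valid)``: with s = sigma_G/e,
    ``p_hat = 2 n (1 - n m / s) / (s + n)``; for an innovation (m = 0) this
    reduces to ``2 / (1 + s/n)``.  ``valid`` is False when the formula's
    assumptions fail (p_hat outside [0, 2]); the raw value is returned as-is.
    """
    if params.e <= 0:
        raise ValueError("e must be > 0")
    if params.sigma_G <= 0:
        raise ZeroDivisionError("sigma_G must be > 0 for the prediction")
    s = params.sigma_G / params.e
    p_hat = 2.0 * params.n * (1.0 - params.n * params.m / s) / (s + params.n)
    return p_hat, 0.0 <= p_hat <= 2.0


@dataclass
class PerturbationRecord:
    G_key: str
    Gp_key: str
    added: SpeciesId
    params: PerturbationParams
    p: float
    p_hat: float
    valid: bool
    source: str = "indegree"  # composition source used for the measured p

    def as_row(self) -> dict:
        return {
            "G_id": self.G_key,
            "Gp_id": self.Gp_key,
            "added_species": str(self.added),
            "n": self.params.n,
            "m": self.params.m,
            "sigma_G": self.params.sigma_G,
            "e": self.params.e,
            "p": self.p,
            "p_hat": self.p_hat,
            "valid": self.valid,
            "source": self.source,
        }


def enumerate_perturbation_pairs(
    landscape: dict[str, Composition],
    table: RateTable,
    source: str = "landscape",
) -> list[PerturbationRecord]:
    """All ordered (G, G') pairs in a landscape differing by one added species.

    ``landscape`` maps canonical species-set keys (see
    :func:`autocatnet.chemistry.network_key`) to compositions.  For each pair
    with species(G') = species(G) + {a}, the measured p is computed from the
    stored compositions and p_hat from the topology of G.
    """
    from .chemistry import species_from_key

    keys = {k: frozenset(species_from_key(k)) for k in landscape}
    by_set = {v: k for k, v in keys.items()}
    records: list[PerturbationRecord] = []
    for G_key, G_set in sorted((k, v) for k, v in keys.items()):
        for Gp_set, Gp_key in by_set.items():
            if len(Gp_set) != len(G_set) + 1 or not G_set < Gp_set:
                continue
            (a,) = Gp_set - G_set
            G_net = build_network(G_set, table)
            params = perturbation_params(G_net, a, table)
            try:
                p = perturbation(landscape[G_key], landscape[Gp_key], set(G_set))
            except UndefinedPerturbationError:
                logger.info("skipping pair %s -> %s: zero mass on V", G_key, Gp_key)
                continue
            if params.sigma_G > 0:
                p_hat, valid = predict_perturbation(params)
            else:
                p_hat, valid = float("nan"), False
            records.append(
                PerturbationRecord(
                    G_key=G_key,
                    Gp_key=Gp_key,
                    added=a,
                    params=params,
                    p=p,
                    p_hat=p_hat,
                    valid=valid,
                    source=source,
                )
            )
    return records


def records_table(records: list[PerturbationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def mean_perturbation(records: list[PerturbationRecord]) -> pd.Series:
    """Mean measured perturbation over all G' for each base network G."""
    if not records:
        logger.info("no perturbation records to average")
        return pd.Series(dtype=float, name="mean_p")
    df = records_table(records)
    return df.groupby("G_id")["p"].mean().rename("mean_p")
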