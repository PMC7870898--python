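"""Independent oracle constructions shared by unit and acceptance tests.

These build networks satisfying the assumptions of the analytical
perturbation prediction — every target of the added catalyst receives prior
catalysis only from the m same-IGS catalysts at rate e — plus arbitrary
background strength from self-looping bystander species.  The direct
in-degree perturbation on such networks must equal the closed-form
prediction.
"""

from __future__ import annotations

import numpy as np

from autocatnet.chemistry import RateTable, ReactionNetwork, SpeciesId, build_network


def make_eq1_instance(
    rng: np.random.Generator,
    n: int | None = None,
    m: int | None = None,
    n_background: int | None = None,
    e: float = 1.0,
):
    """Random network satisfying the derivation's assumptions.

    Returns ``(G, a, table)``: ``a``'s IGS pairs tag "T" with rate ``e``; the
    n targets carry tag "T" and inert IGS letters; the m same-IGS catalysts
    carry inert tags; background species self-loop at random rates.
    """
    n = int(rng.integers(1, 5)) if n is None else n
    m = int(rng.integers(0, 3)) if m is None else m
    n_background = int(rng.integers(1, 6)) if n_background is None else n_background

    igs_letters = ["a"] + [f"i{k}" for k in range(n + m + n_background)]
    tag_letters = ["T"] + [f"t{k}" for k in range(n + m + n_background)]
    alpha: dict[tuple[str, str], float] = {("a", "T"): e}

    species = []
    for k in range(n):  # targets: tag T, inert IGS
        species.append(SpeciesId(f"i{k}", "T"))
    for k in range(m):  # same-IGS catalysts, inert tags
        species.append(SpeciesId("a", f"t{k}"))
    bg_rates = rng.uniform(0.5, 3.0, size=n_background)
    for k in range(n_background):  # self-looping bystanders
        igs, tag = f"i{n + k}", f"t{m + k}"
        alpha[(igs, tag)] = float(bg_rates[k])
        species.append(SpeciesId(igs, tag))

    table = RateTable(
        alpha=alpha,
        beta={},
        edge_threshold=1e-9,
        igs_alphabet=tuple(igs_letters),
        tag_alphabet=tuple(tag_letters),
    )
    a = SpeciesId("a", f"t{m}")  # inert tag, not itself a target
    G = build_network(species, table)
    return G, a, table


def direct_indegree_perturbation(G: ReactionNetwork, a: SpeciesId, table: RateTable) -> float:
    """Measured perturbation from in-degree compositions before/after adding a."""
    from autocatnet.kinetics import indegree_fractions
    from autocatnet.perturbation import perturbation

    Gp = build_network(set(G.species) | {a}, table)
    before = indegree_fractions(G, weights="alpha")
    after = indegree_fractions(Gp, weights="alpha")
    return perturbation(before, after, set(G.species))


def generalized_prediction(G: ReactionNetwork, a: SpeciesId, table: RateTable) -> float | None:
    """Closed-form in-degree perturbation 2en(sigma - D_T)/(sigma (sigma + ne)).

    D_T is the total prior in-degree of a's targets.  Returns None when the
    positivity assumption (every target's renormalized fraction increases)
    fails, or when a's target edges are not all at one rate e.
    """
    from autocatnet.perturbation import background_strength

    targets = [v for v in G.species if table.pair_alpha(a.igs, v.tag) >= table.edge_threshold]
    if not targets:
        return None
    rates = {table.pair_alpha(a.igs, v.tag) for v in targets}
    if len(rates) != 1:
        return None
    e = rates.pop()
    n = len(targets)
    sigma = background_strength(G)
    if sigma <= 0:
        return None
    indeg = {v: sum(G.A[G.index(v), :]) for v in G.species}
    D_T = sum(indeg[v] for v in targets)
    if any(indeg[v] >= sigma / n for v in targets):  # a target's fraction would drop
        return None
    return 2 * e * n * (sigma - D_T) / (sigma * (sigma + n * e))
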