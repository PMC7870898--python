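"""Species, IGS/tag pairing rules, rate tables and reaction-network construction.

The chemistry is a set of self-assembling ribozyme species, each identified by
two nucleotides: the variable position M of its internal guide sequence (IGS,
``gMg``) and the variable position N of its 3' tag (``cNu``).  A species whose
IGS base-pairs with another species' tag catalyzes the covalent ligation of
that species, so a rate table over (IGS letter, tag letter) pairs induces a
directed, weighted reaction network on any species set.

Rates come in two flavours, matching the titration model ``v0 = alpha*x + beta``:
``alpha`` (min^-1, per uM of covalent catalyst) quantifies catalysis by covalent
ribozymes and ``beta`` (uM min^-1) the constant contribution of noncovalent
fragment complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "U")

#: Watson-Crick complement on the RNA alphabet.
WC_COMPLEMENT: dict[str, str] = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: IGS/tag letter pairs drawn as strong interactions in the concrete chemistry.
STRONG_PAIRS: frozenset[tuple[str, str]] = frozenset({("G", "C"), ("C", "G")})


class AlphabetError(ValueError):
    """A letter does not belong to the declared IGS or tag alphabet."""


class EmptyNetworkError(ValueError):
    """Network construction was asked for an empty species set."""


class DegenerateDesignError(ValueError):
    """Titration data cannot identify a slope (fewer than 2 distinct x)."""


@dataclass(frozen=True, order=True)
class SpeciesId:
    """A catalytic species, identified by its IGS letter and tag letter."""

    igs: str
    tag: str

    def __str__(self) -> str:  # e.g. "GC" = IGS gGg, tag cCu
        return f"{self.igs}{self.tag}"

    @classmethod
    def from_string(cls, s: str) -> "SpeciesId":
        s = s.strip()
        if len(s) != 2:
            raise ValueError(f"species id must be two letters, got {s!r}")
        return cls(s[0], s[1])


def all_species(
    igs_alphabet: Sequence[str] = NUCLEOTIDES, tag_alphabet: Sequence[str] = NUCLEOTIDES
) -> list[SpeciesId]:
    """All species of the chemistry, in canonical (igs, tag) order.

    The concrete chemistry has 4 x 4 = 16 species.
    """
    return [SpeciesId(m, n) for m in sorted(igs_alphabet) for n in sorted(tag_alphabet)]


def num_networks_of_size(k: int, n_species: int = 16) -> int:
    """Number of distinct networks with exactly ``k`` of ``n_species`` species."""
    from math import comb

    return comb(n_species, k)


@dataclass
class RateTable:
    """Catalytic rates per (catalyst IGS letter, product tag letter).

    Missing entries read as 0.  ``edge_threshold`` (min^-1) is the alpha rate
    below which a pair is not drawn as a graph edge; the default excludes all
    non-Watson-Crick pairs, whose default rates are 0.
    """

    alpha: dict[tuple[str, str], float]
    beta: dict[tuple[str, str], float]
    edge_threshold: float = 1e-6
    igs_alphabet: tuple[str, ...] = NUCLEOTIDES
    tag_alphabet: tuple[str, ...] = NUCLEOTIDES

    def __post_init__(self) -> None:
        for name, table in (("alpha", self.alpha), ("beta", self.beta)):
            for (m, n), rate in table.items():
                if rate < 0:
                    raise ValueError(f"negative {name} rate for pair ({m}, {n})")

    def _check(self, igs: str, tag: str) -> None:
        if igs not in self.igs_alphabet:
            raise AlphabetError(f"unknown IGS letter {igs!r}")
        if tag not in self.tag_alphabet:
            raise AlphabetError(f"unknown tag letter {tag!r}")

    def pair_alpha(self, igs: str, tag: str) -> float:
        self._check(igs, tag)
        return self.alpha.get((igs, tag), 0.0)

    def pair_beta(self, igs: str, tag: str) -> float:
        self._check(igs, tag)
        return self.beta.get((igs, tag), 0.0)

    def strong_pair_alpha(self, igs: str) -> float:
        """Rate of the IGS's strongest pairing (its Watson-Crick tag, when defined).

        For non-nucleotide alphabets this is the maximal alpha over tags.
        """
        if igs in WC_COMPLEMENT and WC_COMPLEMENT[igs] in self.tag_alphabet:
            return self.pair_alpha(igs, WC_COMPLEMENT[igs])
        return max(self.pair_alpha(igs, n) for n in self.tag_alphabet)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"igs": m, "tag": n, "alpha": self.pair_alpha(m, n), "beta": self.pair_beta(m, n)}
            for m in self.igs_alphabet
            for n in self.tag_alphabet
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, edge_threshold: float = 1e-6) -> "RateTable":
        df = pd.read_csv(path, dtype={"igs": str, "tag": str})
        required = {"igs", "tag", "alpha", "beta"}
        if not required.issubset(df.columns):
            raise ValueError(f"rate CSV must have columns {sorted(required)}")
        alpha = {(r.igs, r.tag): float(r.alpha) for r in df.itertuples()}
        beta = {(r.igs, r.tag): float(r.beta) for r in df.itertuples()}
        igs_letters = tuple(sorted(set(df.igs) | set(NUCLEOTIDES)))
        tag_letters = tuple(sorted(set(df.tag) | set(NUCLEOTIDES)))
        return cls(alpha, beta, edge_threshold, igs_letters, tag_letters)


def default_rate_table(
    alpha_strong: float = 0.012,
    alpha_weak: float = 0.0036,
    beta_scale: float = 0.05,
    edge_threshold: float = 1e-6,
) -> RateTable:
    """Placeholder default table for the concrete 16-species chemistry.

    Ordering follows the measured hierarchy: G:C = C:G maximal, A:U = U:A
    weaker, wobble (G:U, U:G) and mismatches negligible (0).  Magnitudes are
    chosen so that 60-min incubations of typical droplet-fusion networks
    yield totals in the 0.05-1 uM range, spanning roughly an order of
    magnitude across topologies; measured values can be supplied via
    :meth:`RateTable.from_csv`.
    ``beta = beta_scale * alpha`` in uM min^-1.
    """
    alpha: dict[tuple[str, str], float] = {}
    for m in NUCLEOTIDES:
        n = WC_COMPLEMENT[m]
        alpha[(m, n)] = alpha_strong if (m, n) in STRONG_PAIRS else alpha_weak
    beta = {pair: beta_scale * a for pair, a in alpha.items()}
    return RateTable(alpha=alpha, beta=beta, edge_threshold=edge_threshold)


def pair_rate(igs: str, tag: str, table: RateTable) -> tuple[float, float]:
    """(alpha, beta) for one IGS/tag letter pair; absent entries read as 0."""
    return table.pair_alpha(igs, tag), table.pair_beta(igs, tag)


@dataclass
class ReactionNetwork:
    """A species set with its induced linear kinetics ``xdot = A x + b``.

    ``A[i, j] = alpha(igs_j, tag_i)`` (min^-1): catalysis of species i's
    formation by covalent catalysts of species j.  ``b[i]`` sums the
    noncovalent contributions ``beta(igs_j, tag_i)`` over present species j
    (uM min^-1).  Edges are directed pairs j -> i with alpha at or above the
    table's edge threshold.
    """

    species: tuple[SpeciesId, ...]
    A: np.ndarray
    b: np.ndarray
    edges: tuple[tuple[SpeciesId, SpeciesId], ...]

    @property
    def size(self) -> int:
        return len(self.species)

    def index(self, sp: SpeciesId) -> int:
        return self.species.index(sp)

    @property
    def key(self) -> str:
        """Canonical species-set key, e.g. ``"AU+GC+UA"``."""
        return network_key(self.species)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": str(j),
                    "target": str(i),
                    "rate": self.A[self.index(i), self.index(j)],
                }
                for (j, i) in self.edges
            ]
        )

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"species": str(s), "igs": s.igs, "tag": s.tag, "b": self.b[k]} for k, s in enumerate(self.species)]
        )


def network_key(species: Iterable[SpeciesId]) -> str:
    return "+".join(str(s) for s in sorted(set(species)))


def species_from_key(key: str) -> tuple[SpeciesId, ...]:
    return tuple(sorted(SpeciesId.from_string(tok) for tok in key.split("+") if tok))


def build_network(species: Iterable[SpeciesId], table: RateTable) -> ReactionNetwork:
    """Construct the reaction network induced by ``table`` on a species set.

    Deterministic: species are canonically ordered lexicographically by
    (igs, tag), so the result is independent of input order.
    """
    ordered = tuple(sorted(set(species)))
    if not ordered:
        raise EmptyNetworkError("cannot build a network from an empty species set")
    n = len(ordered)
    A = np.zeros((n, n))
    b = np.zeros(n)
    edges: list[tuple[SpeciesId, SpeciesId]] = []
    for i, target in enumerate(ordered):
        for j, source in enumerate(ordered):
            a = table.pair_alpha(source.igs, target.tag)
            A[i, j] = a
            b[i] += table.pair_beta(source.igs, target.tag)
            if a >= table.edge_threshold:
                edges.append((source, target))
    return ReactionNetwork(species=ordered, A=A, b=b, edges=tuple(edges))


@dataclass
class TitrationData:
    """Doped covalent-catalyst titration: initial rates v0 vs doped concentration x."""

    doped_concentrations: np.ndarray  # uM
    initial_rates: np.ndarray  # uM min^-1

    def __post_init__(self) -> None:
        self.doped_concentrations = np.asarray(self.doped_concentrations, dtype=float)
        self.initial_rates = np.asarray(self.initial_rates, dtype=float)
        if self.doped_concentrations.shape != self.initial_rates.shape:
            raise ValueError("x and v0 must have equal lengths")
        if np.any(self.doped_concentrations < 0):
            raise ValueError("doped concentrations must be >= 0")


@dataclass
class TitrationFit:
    alpha: float  # slope, min^-1
    beta: float  # intercept, uM min^-1
    alpha_se: float
    beta_se: float
    residual_variance: float
    r_value: float


def fit_titration(data: TitrationData) -> TitrationFit:
    """Ordinary least-squares fit of ``v0 = alpha*x + beta``.

    alpha is the covalent (first-order) rate, beta the noncovalent (constant)
    rate.  Requires at least two distinct doping concentrations.
    """
    x, v0 = data.doped_concentrations, data.initial_rates
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateDesignError("need >= 2 distinct doped concentrations")
    res = stats.linregress(x, v0)
    resid = v0 - (res.slope * x + res.intercept)
    dof = max(x.size - 2, 1)
    return TitrationFit(
        alpha=res.slope,
        beta=res.intercept,
        alpha_se=res.stderr,
        beta_se=res.intercept_stderr,
        residual_variance=float(resid @ resid) / dof,
        r_value=res.rvalue,
    )
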