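"""Network growth by single-species accretion and its perturbation dynamics.

A trajectory starts from a random species set and adds one random species at
a time; each addition perturbs the composition of the pre-existing network.
The cumulative perturbation series shows inflexions (curvature sign changes)
whose sharpness — the absolute discrete third derivative — marks sudden
compositional shifts.  Strong inflexions (top quartile of sharpness) tend to
coincide with catalytic innovations: additions that introduce an interaction
type absent from the network so far.

Besides the concrete 16-species nucleotide chemistry, an abstract chemistry
over an L-letter alphabet supports the density study: a pool of at most 24
specific IGS/tag letter pairs, thinned at random to vary the catalytic
density (probability that one species catalyzes another's formation).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import RateTable, SpeciesId, STRONG_PAIRS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chemistry:
    """Abstract L x L species grid with a set of specific interaction types.

    Each specific (IGS letter, tag letter) pair carries the uniform rate
    ``e``; all other pairs are inert.  ``density`` is the probability that a
    random species catalyzes another random species, |interactions| / L^2.
    """

    L: int
    interactions: frozenset[tuple[str, str]]
    e: float = 1.0

    def __post_init__(self) -> None:
        letters = set(self.alphabet)
        if not all(m in letters and n in letters for m, n in self.interactions):
            raise ValueError("interactions must use letters from the alphabet")
        if not self.interactions:
            raise ValueError("chemistry needs at least one specific interaction")

    @property
    def alphabet(self) -> tuple[str, ...]:
        if self.L > 26:
            raise ValueError("alphabet supports at most 26 letters")
        return tuple(string.ascii_uppercase[: self.L])

    @property
    def density(self) -> float:
        return len(self.interactions) / self.L**2

    def species_pool(self) -> list[SpeciesId]:
        return [SpeciesId(m, n) for m in self.alphabet for n in self.alphabet]

    def rate_table(self, beta_scale: float = 0.1) -> RateTable:
        alpha = {pair: self.e for pair in self.interactions}
        beta = {pair: self.e * beta_scale for pair in self.interactions}
        return RateTable(
            alpha=alpha,
            beta=beta,
            edge_threshold=self.e / 2,
            igs_alphabet=self.alphabet,
            tag_alphabet=self.alphabet,
        )

    @classmethod
    def full_pool(cls, L: int = 24, n_pairs: int = 24) -> list[tuple[str, str]]:
        """The pool of specific interaction types: letter i's IGS pairs letter i's tag."""
        letters = string.ascii_uppercase[:L]
        return [(letters[i], letters[i]) for i in range(min(n_pairs, L))]

    @classmethod
    def random(
        cls,
        L: int = 24,
        n_pairs: int = 24,
        density: float = 1.0,
        rng: np.random.Generator | None = None,
        e: float = 1.0,
    ) -> "Chemistry":
        """Chemistry with a random ``density``-fraction of the specific-pair pool kept."""
        if not 0 < density <= 1:
            raise ValueError("density must be in (0, 1]")
        pool = cls.full_pool(L, n_pairs)
        k = max(1, round(density * len(pool)))
        if rng is None or k == len(pool):
            kept = pool[:k]
        else:
            idx = rng.choice(len(pool), size=k, replace=False)
            kept = [pool[i] for i in sorted(idx)]
        return cls(L=L, interactions=frozenset(kept), e=e)


@dataclass
class InflexionPoint:
    step: int  # index into the cumulative series (0-based addition index)
    sharpness: float
    strong: bool = False
    innovation: bool = False


@dataclass
class Trajectory:
    """One accretion run: ordered additions with per-step perturbations."""

    start_species: tuple[SpeciesId, ...]
    additions: tuple[SpeciesId, ...]
    p: np.ndarray  # per-step perturbation
    P: np.ndarray  # cumulative perturbation, nondecreasing
    n_targets: np.ndarray  # targeting breadth of each added species
    innovations: np.ndarray  # bool per step
    inflexions: list[InflexionPoint] = field(default_factory=list)
    n_degenerate: int = 0  # steps with zero composition mass (p set to 0)

    def to_table(self, trajectory_id: str | int = 0) -> pd.DataFrame:
        sharp = {ip.step: ip for ip in self.inflexions}
        return pd.DataFrame(
            [
                {
                    "trajectory_id": trajectory_id,
                    "step": k + 1,
                    "added_species": str(self.additions[k]),
                    "p": self.p[k],
                    "P": self.P[k],
                    "n_targets": int(self.n_targets[k]),
                    "sharpness": sharp[k].sharpness if k in sharp else np.nan,
                    "inflexion": k in sharp,
                    "strong": sharp[k].strong if k in sharp else False,
                    "innovation": bool(self.innovations[k]),
                }
                for k in range(len(self.additions))
            ]
        )


def _alpha_matrix(table: RateTable) -> tuple[dict[str, int], dict[str, int], np.ndarray]:
    igs_idx = {m: i for i, m in enumerate(table.igs_alphabet)}
    tag_idx = {n: i for i, n in enumerate(table.tag_alphabet)}
    M = np.zeros((len(igs_idx), len(tag_idx)))
    for (m, n), a in table.alpha.items():
        M[igs_idx[m], tag_idx[n]] = a
    M[M < table.edge_threshold] = 0.0  # only interactions count for topology
    return igs_idx, tag_idx, M


def grow_trajectory(
    pool: list[SpeciesId],
    table: RateTable,
    start_size: int,
    end_size: int,
    rng: np.random.Generator,
    strong_pairs: frozenset[tuple[str, str]] | None = None,
    composition: str = "indegree",
    t: float = 60.0,
) -> Trajectory:
    """Grow a network from ``start_size`` to ``end_size`` by random accretion.

    The start set and addition order are drawn uniformly without replacement.
    Per-step perturbations compare in-degree compositions (default) before and
    after each addition, renormalized on the pre-existing species; steps with
    zero composition mass contribute p = 0 with a logged warning.  Set
    ``composition="kinetic"`` to use full kinetic-model fractions instead.

    ``strong_pairs`` designates the interaction types whose first appearance
    counts as a catalytic innovation; defaults to the strong Watson-Crick
    pairs for the nucleotide alphabet, and to every interacting pair for
    abstract chemistries.
    """
    if start_size < 1:
        raise ValueError("start_size must be >= 1")
    if end_size > len(pool):
        raise ValueError("species pool exhausted: end_size exceeds pool size")
    if end_size < start_size:
        raise ValueError("end_size must be >= start_size")
    if strong_pairs is None:
        if set(table.igs_alphabet) == {"A", "C", "G", "U"}:
            strong_pairs = STRONG_PAIRS
        else:
            strong_pairs = frozenset(p for p, a in table.alpha.items() if a >= table.edge_threshold)

    igs_idx, tag_idx, M = _alpha_matrix(table)
    order = rng.permutation(len(pool))
    chosen = [pool[i] for i in order[:end_size]]
    start = tuple(sorted(chosen[:start_size]))
    additions = tuple(chosen[start_size:])

    cur_igs = np.array([igs_idx[s.igs] for s in start], dtype=int)
    cur_tag = np.array([tag_idx[s.tag] for s in start], dtype=int)
    # weighted in-degrees of current species (from current species only)
    c = M[cur_igs][:, cur_tag].sum(axis=0)
    seen_types = {
        (s.igs, v.tag) for s in start for v in start if M[igs_idx[s.igs], tag_idx[v.tag]] > 0
    }

    if composition == "kinetic":
        from .chemistry import build_network
        from .kinetics import predict_fractions, UndefinedCompositionError

    p_vals, n_vals, innov = [], [], []
    n_degenerate = 0
    cur_species = list(start)
    for a in additions:
        ai, at = igs_idx[a.igs], tag_idx[a.tag]
        delta = M[ai, cur_tag]  # a's catalysis of each existing species
        n_vals.append(int(np.count_nonzero(delta)))

        if composition == "kinetic":
            try:
                before = predict_fractions(build_network(cur_species, table), t)
                after = predict_fractions(build_network(cur_species + [a], table), t)
                from .perturbation import perturbation as _pert

                p_k = _pert(before, after, set(cur_species))
            except Exception:
                logger.warning("degenerate kinetic composition at step; p set to 0")
                p_k = 0.0
                n_degenerate += 1
        else:
            tot_before, tot_after = c.sum(), c.sum() + delta.sum()
            if tot_before <= 0 or tot_after <= 0:
                logger.debug("zero in-degree mass at step; p set to 0")
                p_k = 0.0
                n_degenerate += 1
            else:
                p_k = float(np.abs((c + delta) / tot_after - c / tot_before).sum())
        p_vals.append(p_k)

        new_types = {(a.igs, v.tag) for v in cur_species if M[ai, tag_idx[v.tag]] > 0}
        new_types |= {(u.igs, a.tag) for u in cur_species if M[igs_idx[u.igs], at] > 0}
        if M[ai, at] > 0:
            new_types.add((a.igs, a.tag))
        innov.append(bool((new_types & strong_pairs) - seen_types))
        seen_types |= new_types

        # incorporate a into the running in-degree vector
        c = np.append(c + delta, M[cur_igs, at].sum() + M[ai, at])
        cur_igs = np.append(cur_igs, ai)
        cur_tag = np.append(cur_tag, at)
        cur_species.append(a)

    p_arr = np.array(p_vals)
    return Trajectory(
        start_species=start,
        additions=additions,
        p=p_arr,
        P=np.cumsum(p_arr),
        n_targets=np.array(n_vals, dtype=int),
        innovations=np.array(innov, dtype=bool),
        n_degenerate=n_degenerate,
    )


def find_inflexions(P: np.ndarray) -> list[InflexionPoint]:
    """Curvature sign changes of a cumulative series, with their sharpness.

    The discrete second difference ``d2[k] = P[k+1] - 2 P[k] + P[k-1]`` is
    scanned for sign changes (zeros between opposite signs are crossed); an
    inflexion is recorded at the last index of the old sign, with sharpness
    ``|P[k+2] - 3 P[k+1] + 3 P[k] - P[k-1]|`` — the third-difference stencil,
    equal to |d2[k+1] - d2[k]|.
    """
    P = np.asarray(P, dtype=float)
    if P.size < 4:
        raise ValueError("cumulative series too short (need >= 4 points)")
    d2 = P[2:] - 2 * P[1:-1] + P[:-2]  # d2[j] is curvature at index j+1
    # curvature below the rounding noise of the series counts as exactly flat
    tiny = 1e-12 * max(1.0, float(np.abs(P).max()))
    d2 = np.where(np.abs(d2) <= tiny, 0.0, d2)
    out: list[InflexionPoint] = []
    for j in range(d2.size - 1):  # curvature index k = j + 1
        if d2[j] == 0:
            continue
        nxt = d2[j + 1 :]
        nonzero = nxt[nxt != 0]
        if nonzero.size and np.sign(nonzero[0]) != np.sign(d2[j]):
            k = j + 1
            if k + 2 <= P.size - 1:
                sharp = abs(P[k + 2] - 3 * P[k + 1] + 3 * P[k] - P[k - 1])
                out.append(InflexionPoint(step=k, sharpness=sharp))
    return out


def classify_strong(sharpness: np.ndarray, percentile: float = 75.0) -> np.ndarray:
    """Boolean flags: sharpness at or above the ensemble percentile (top quartile).

    Uses the linear-interpolation percentile convention; with all values
    equal, every inflexion is strong.
    """
    sharpness = np.asarray(sharpness, dtype=float)
    if sharpness.size == 0:
        return np.zeros(0, dtype=bool)
    cut = np.percentile(sharpness, percentile)
    return sharpness >= cut


def label_innovations(traj: Trajectory) -> np.ndarray:
    """Per-step innovation flags (computed during growth; exposed for tables)."""
    return traj.innovations.copy()


def annotate_trajectories(
    trajs: list[Trajectory], percentile: float = 75.0, pooled: bool = True
) -> None:
    """Attach inflexions with strong/innovation flags to each trajectory.

    ``pooled=True`` computes the sharpness percentile over the whole ensemble
    (default); otherwise per trajectory.
    """
    all_inflexions: list[list[InflexionPoint]] = []
    for traj in trajs:
        infl = find_inflexions(traj.P) if traj.P.size >= 4 else []
        for ip in infl:
            ip.innovation = bool(traj.innovations[ip.step])
        all_inflexions.append(infl)
    if pooled:
        sharp = np.array([ip.sharpness for infl in all_inflexions for ip in infl])
        flags = classify_strong(sharp, percentile)
        i = 0
        for infl in all_inflexions:
            for ip in infl:
                ip.strong = bool(flags[i])
                i += 1
    else:
        for infl in all_inflexions:
            flags = classify_strong(np.array([ip.sharpness for ip in infl]), percentile)
            for ip, f in zip(infl, flags):
                ip.strong = bool(f)
    for traj, infl in zip(trajs, all_inflexions):
        traj.inflexions = infl


@dataclass
class DensitySummary:
    """Ensemble statistics of the growth study at one catalytic density."""

    density: float  # |interactions| / L^2
    pool_fraction: float  # fraction of the specific-pair pool retained
    n_trajectories: int
    breadth_by_rank: pd.DataFrame  # rank, mean n of strong-inflexion catalysts
    waiting_by_rank: pd.DataFrame  # rank, mean additions since previous strong inflexion
    strong_counts: pd.Series  # strong inflexions per trajectory -> n trajectories
    mean_strong_per_traj: float
    mean_strong_sharpness: float


def _ensemble_summary(trajs: list[Trajectory], density: float, pool_fraction: float) -> DensitySummary:
    annotate_trajectories(trajs)
    breadth_rows, waiting_rows, counts = [], [], []
    strong_sharp = []
    for traj in trajs:
        strong = [ip for ip in traj.inflexions if ip.strong]
        counts.append(len(strong))
        prev = None
        for rank, ip in enumerate(sorted(strong, key=lambda ip: ip.step), start=1):
            breadth_rows.append({"rank": rank, "n": int(traj.n_targets[ip.step])})
            if prev is not None:  # waiting is defined between two strong inflexions
                waiting_rows.append({"rank": rank, "waiting": ip.step - prev})
            prev = ip.step
            strong_sharp.append(ip.sharpness)
    breadth = (
        pd.DataFrame(breadth_rows, columns=["rank", "n"]).groupby("rank")["n"].agg(["mean", "count"]).reset_index()
        if breadth_rows
        else pd.DataFrame(columns=["rank", "mean", "count"])
    )
    waiting = (
        pd.DataFrame(waiting_rows, columns=["rank", "waiting"]).groupby("rank")["waiting"].agg(["mean", "count"]).reset_index()
        if waiting_rows
        else pd.DataFrame(columns=["rank", "mean", "count"])
    )
    return DensitySummary(
        density=density,
        pool_fraction=pool_fraction,
        n_trajectories=len(trajs),
        breadth_by_rank=breadth,
        waiting_by_rank=waiting,
        strong_counts=pd.Series(counts).value_counts().sort_index(),
        mean_strong_per_traj=float(np.mean(counts)) if counts else 0.0,
        mean_strong_sharpness=float(np.mean(strong_sharp)) if strong_sharp else float("nan"),
    )


def simulate_trajectory_study(
    densities: list[float],
    n_traj: int = 1000,
    start_size: int = 2,
    end_size: int = 100,
    L: int = 24,
    n_pairs: int = 24,
    seed: int = 0,
    e: float = 1.0,
) -> dict[float, DensitySummary]:
    """Growth-trajectory ensembles across chemistries of varying catalytic density.

    For each pool fraction in ``densities`` a chemistry is drawn by random
    removal from the specific-pair pool, and ``n_traj`` trajectories are grown
    from ``start_size`` to ``end_size`` species.  Summaries per density:
    targeting breadth of strong-perturbation catalysts vs inflexion rank,
    waiting time between strong inflexions vs rank, and the distribution of
    strong-inflexion counts per trajectory.  Fully determined by ``seed``.
    """
    root = np.random.SeedSequence(seed)
    out: dict[float, DensitySummary] = {}
    for frac, ss in zip(densities, root.spawn(len(densities))):
        child = ss.spawn(n_traj + 1)
        chem = Chemistry.random(L=L, n_pairs=n_pairs, density=frac, rng=np.random.default_rng(child[0]), e=e)
        pool = chem.species_pool()
        if end_size > len(pool):
            raise ValueError("species pool too small for requested end size")
        table = chem.rate_table()
        trajs = [
            grow_trajectory(pool, table, start_size, end_size, np.random.default_rng(child[i + 1]))
            for i in range(n_traj)
        ]
        out[frac] = _ensemble_summary(trajs, density=chem.density, pool_fraction=frac)
    return out
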