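"""Aggregation of droplet-level measurements into a network landscape.

A landscape groups droplet compositions by identical species set ("network"),
averages replicates, and supports the statistics reported over it: ranking
conservation of catalyst pairs, yield ranking, the growth-variation trade-off
contingency test, the background-strength/yield correlation, and the pooled
model-measurement correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

from .chemistry import RateTable, SpeciesId, build_network, network_key
from .kinetics import Composition
from .perturbation import background_strength

logger = logging.getLogger(__name__)


@dataclass
class NetworkRecord:
    network_id: str
    species: tuple[SpeciesId, ...]
    n_replicates: int
    mean_fractions: Composition
    sd_fractions: dict[SpeciesId, float]
    mean_yield_uM: float
    sem_yield: float


def droplets_from_measurements(measurements) -> list[tuple[frozenset[SpeciesId], Composition]]:
    """Adapt droplet-pipeline measurements to aggregation input pairs."""
    return [(frozenset(m.species), m.fractions) for m in measurements]


def aggregate_networks(droplets: list[tuple[frozenset[SpeciesId], Composition]]) -> list[NetworkRecord]:
    """Group droplet compositions by species set; mean, s.d. and SEM per network.

    ``droplets`` are (species set, composition) pairs, the composition carrying
    per-droplet fractions and yield.  Output is deterministically ordered by
    network key.
    """
    groups: dict[frozenset[SpeciesId], list[Composition]] = {}
    for sset, comp in droplets:
        groups.setdefault(frozenset(sset), []).append(comp)
    records = []
    for sset in sorted(groups, key=lambda s: network_key(s)):
        comps = groups[sset]
        species = tuple(sorted(sset))
        mat = np.array([c.as_vector(species) for c in comps])
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1) if len(comps) > 1 else np.zeros(len(species))
        yields = np.array([c.yield_uM if c.yield_uM is not None else np.nan for c in comps])
        mean_yield = float(np.nanmean(yields)) if not np.all(np.isnan(yields)) else float("nan")
        n_y = int(np.sum(~np.isnan(yields)))
        sem = float(np.nanstd(yields, ddof=1) / np.sqrt(n_y)) if n_y > 1 else float("nan")
        records.append(
            NetworkRecord(
                network_id=network_key(sset),
                species=species,
                n_replicates=len(comps),
                mean_fractions=Composition(
                    fractions=dict(zip(species, mean / mean.sum())), yield_uM=mean_yield
                ),
                sd_fractions=dict(zip(species, sd)),
                mean_yield_uM=mean_yield,
                sem_yield=sem,
            )
        )
    return records


def landscape_table(records: list[NetworkRecord]) -> pd.DataFrame:
    """One row per network x species: the landscape CSV schema."""
    rows = []
    for rec in records:
        for s in rec.species:
            rows.append(
                {
                    "network_id": rec.network_id,
                    "size": len(rec.species),
                    "species": str(s),
                    "mean_fraction": rec.mean_fractions.fractions[s],
                    "sd": rec.sd_fractions[s],
                    "n_replicates": rec.n_replicates,
                    "mean_yield_uM": rec.mean_yield_uM,
                    "sem_yield": rec.sem_yield,
                }
            )
    return pd.DataFrame(rows)


def rank_conservation(records: list[NetworkRecord], flip_threshold: float = 0.10) -> float:
    """Fraction of catalyst pairs whose within-network ranking is not conserved.

    For each unordered species pair, over all networks containing both, the
    minority orientation's share of networks is compared to
    ``flip_threshold``; at or above it the pair counts as non-conserved.
    Exact fraction ties count as conserved.  Pairs co-occurring in fewer than
    2 networks are excluded from the denominator.
    """
    pair_counts: dict[tuple[SpeciesId, SpeciesId], list[int]] = {}
    for rec in records:
        fr = rec.mean_fractions.fractions
        for u, v in combinations(rec.species, 2):
            key = (u, v)
            counts = pair_counts.setdefault(key, [0, 0, 0])  # u>v, v>u, tie
            if fr[u] > fr[v]:
                counts[0] += 1
            elif fr[v] > fr[u]:
                counts[1] += 1
            else:
                counts[2] += 1
    n_pairs = 0
    n_flipped = 0
    for counts in pair_counts.values():
        total = sum(counts)
        if total < 2:
            continue
        n_pairs += 1
        minority = min(counts[0], counts[1])
        if minority / total >= flip_threshold:
            n_flipped += 1
    if n_pairs == 0:
        raise ValueError("no species pair co-occurs in >= 2 networks")
    return n_flipped / n_pairs


def yield_ranking(
    records: list[NetworkRecord], size: int, min_replicates: int = 10
) -> pd.DataFrame:
    """Networks of a given size ranked from lowest to highest mean yield.

    Only networks with at least ``min_replicates`` replicates enter; ties are
    broken by network id.  The table carries mean yield, SEM and rank, plus a
    ``fold_range`` attribute (max/min mean yield).
    """
    rows = [
        {
            "network_id": r.network_id,
            "mean_yield_uM": r.mean_yield_uM,
            "sem_yield": r.sem_yield,
            "n_replicates": r.n_replicates,
        }
        for r in records
        if len(r.species) == size and r.n_replicates >= min_replicates
    ]
    df = pd.DataFrame(rows, columns=["network_id", "mean_yield_uM", "sem_yield", "n_replicates"])
    df = df.sort_values(["mean_yield_uM", "network_id"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if len(df) and df["mean_yield_uM"].iloc[0] > 0:
        df.attrs["fold_range"] = df["mean_yield_uM"].iloc[-1] / df["mean_yield_uM"].iloc[0]
    else:
        df.attrs["fold_range"] = float("nan")
    return df


@dataclass
class TradeoffResult:
    table: np.ndarray  # [[strong & high, strong & low], [weak & high, weak & low]]
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    degenerate: bool


def tradeoff_test(
    df: pd.DataFrame,
    p_threshold: float = 0.8,
    yield_threshold_uM: float = 0.08,
    p_col: str = "p",
    yield_col: str = "yield_uM",
) -> TradeoffResult:
    """Growth-variation trade-off: are strongly perturbable, high-yield networks rare?

    Builds the 2x2 contingency of (p > p_threshold) x (yield > yield_threshold)
    and runs a one-sided Fisher exact test with the alternative that strong &
    high-yield co-occurrence is *below* independence.  The odds ratio is the
    conditional maximum-likelihood estimate with an exact 95% CI.
    """
    strong = df[p_col] > p_threshold
    high = df[yield_col] > yield_threshold_uM
    table = np.array(
        [
            [int((strong & high).sum()), int((strong & ~high).sum())],
            [int((~strong & high).sum()), int((~strong & ~high).sum())],
        ]
    )
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        logger.warning("degenerate contingency table (empty margin): p = 1")
        return TradeoffResult(table, 1.0, float("nan"), float("nan"), float("nan"), True)
    _, p_value = stats.fisher_exact(table, alternative="less")
    orr = odds_ratio(table, kind="conditional")
    ci = orr.confidence_interval(0.95)
    return TradeoffResult(
        table=table,
        p_value=float(p_value),
        odds_ratio=float(orr.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        degenerate=False,
    )


def _binned_summary(x: np.ndarray, y: np.ndarray, n_bins: int = 10, min_count: int = 10) -> pd.DataFrame:
    """Equal-width bin means along x; bins with < min_count points discarded."""
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() < min_count:
            continue
        rows.append(
            {
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "n": int(mask.sum()),
                "mean_x": float(x[mask].mean()),
                "mean_y": float(y[mask].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["bin_center", "n", "mean_x", "mean_y"])


def sigma_yield_correlation(
    records: list[NetworkRecord], table: RateTable, n_bins: int = 10
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between background strength sigma_G and mean yield."""
    if len(records) < 3:
        raise ValueError("need >= 3 networks")
    sigmas = np.array(
        [background_strength(build_network(r.species, table)) for r in records]
    )
    yields = np.array([r.mean_yield_uM for r in records])
    if np.unique(sigmas).size == 1 or np.unique(yields).size == 1:
        raise ValueError("constant input: correlation undefined")
    r = float(stats.pearsonr(sigmas, yields).statistic)
    return r, _binned_summary(sigmas, yields, n_bins=n_bins)


def model_measurement_correlation(
    predicted: dict[str, Composition], measured: dict[str, Composition], n_bins: int = 10
) -> tuple[float, pd.DataFrame]:
    """Pooled Pearson r between predicted and measured species fractions.

    Both inputs are keyed by canonical network id; fraction pairs are pooled
    over all (network, species) present in both.  Also returns a decile-binned
    summary of measured vs predicted (bins with < 10 points discarded).
    """
    xs, ys = [], []
    for key in predicted.keys() & measured.keys():
        pf, mf = predicted[key].fractions, measured[key].fractions
        for s in pf.keys() & mf.keys():
            xs.append(pf[s])
            ys.append(mf[s])
    if not xs:
        raise ValueError("no overlapping (network, species) keys")
    x, y = np.array(xs), np.array(ys)
    r = float(stats.pearsonr(x, y).statistic)
    return r, _binned_summary(x, y, n_bins=n_bins)
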