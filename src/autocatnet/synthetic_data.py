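"""Synthetic inputs with the statistical structure of the droplet experiment.

The experiment encapsulates 24 fragment-mixture combinations (50 fragment
slots in total) in small droplets, fuses random sets of 1-5 of them with a
reaction droplet, incubates, and reads each fused droplet out by barcoded
sequencing: hairpin reporters encode which mixtures were received, ribozyme
UMI counts sample the final composition.  This module reproduces that
pipeline in silico — combination design by entropy maximization, droplet
fusion, kinetics-derived ground truth, and multinomial UMI sampling with
per-UMI read counts and spurious error UMIs — so the processing and analysis
modules are testable end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import (
    RateTable,
    SpeciesId,
    TitrationData,
    all_species,
    build_network,
    network_key,
)
from .kinetics import Composition, UndefinedCompositionError, predict_fractions

logger = logging.getLogger(__name__)


def barcode_diversity(n_rounds: int = 3, n_indices: int = 96) -> int:
    """Droplet-barcode diversity of split-and-pool ligation (96^3 = 884,736)."""
    return n_indices**n_rounds


# ---------------------------------------------------------------------------
# Combination design


@dataclass
class CombinationDesign:
    """24 fragment-mixture combinations distributing 50 fragment slots."""

    combinations: tuple[tuple[SpeciesId, ...], ...]
    entropy_score: float = float("nan")
    n_distinct_networks: int = 0

    def __post_init__(self) -> None:
        if any(len(c) == 0 for c in self.combinations):
            raise ValueError("every combination must be nonempty")

    @property
    def total_slots(self) -> int:
        return sum(len(c) for c in self.combinations)

    def reporter_map(self) -> dict[str, frozenset[SpeciesId]]:
        return {
            f"HP{i:02d}": frozenset(combo) for i, combo in enumerate(self.combinations)
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "combinations": [[str(s) for s in combo] for combo in self.combinations],
            "entropy_score": self.entropy_score,
            "n_distinct_networks": self.n_distinct_networks,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CombinationDesign":
        payload = json.loads(Path(path).read_text())
        return cls(
            combinations=tuple(
                tuple(SpeciesId.from_string(s) for s in combo)
                for combo in payload["combinations"]
            ),
            entropy_score=payload.get("entropy_score", float("nan")),
            n_distinct_networks=payload.get("n_distinct_networks", 0),
        )


def _random_assignment(
    rng: np.random.Generator,
    n_combinations: int,
    total_slots: int,
    species: list[SpeciesId],
) -> tuple[tuple[SpeciesId, ...], ...]:
    """Distribute slots over nonempty tubes; each tube holds distinct species."""
    max_size = len(species)
    sizes = np.ones(n_combinations, dtype=int)
    for _ in range(total_slots - n_combinations):
        open_tubes = np.flatnonzero(sizes < max_size)
        sizes[rng.choice(open_tubes)] += 1
    combos = []
    for size in sizes:
        idx = rng.choice(len(species), size=size, replace=False)
        combos.append(tuple(sorted(species[i] for i in idx)))
    return tuple(combos)


def _histogram_entropy(values: np.ndarray, n_bins: int = 20) -> float:
    """Shannon entropy (nats) of a fixed-width histogram over the observed range."""
    if values.size == 0:
        return 0.0
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _network_eigs(
    sset: frozenset[SpeciesId], table: RateTable, cache: dict
) -> tuple[float, float]:
    """(lambda_1, lambda_1 - lambda_2) of the alpha matrix, by real part."""
    if sset not in cache:
        net = build_network(sset, table)
        eigs = np.linalg.eigvals(net.A)
        if np.any(np.abs(eigs.imag) > 1e-9):
            logger.warning("complex eigenvalues for network %s; using real parts", network_key(sset))
        real = np.sort(eigs.real)[::-1]
        lam1 = float(real[0])
        gap = float(real[0] - real[1]) if real.size > 1 else 0.0
        cache[sset] = (lam1, gap)
    return cache[sset]


def _simulate_fusions(
    design: tuple[tuple[SpeciesId, ...], ...],
    n_fusions: int,
    rng: np.random.Generator,
    fusion_probs: np.ndarray,
) -> list[frozenset[SpeciesId]]:
    ks = rng.choice(np.arange(1, len(fusion_probs) + 1), size=n_fusions, p=fusion_probs)
    out = []
    for k in ks:
        picked = rng.choice(len(design), size=k, replace=True)
        sset: set[SpeciesId] = set()
        for i in picked:
            sset.update(design[i])
        out.append(frozenset(sset))
    return out


def design_score(
    design: tuple[tuple[SpeciesId, ...], ...],
    table: RateTable,
    n_fusion_sims: int,
    rng: np.random.Generator,
    fusion_probs: np.ndarray,
    n_bins: int = 20,
    cache: dict | None = None,
) -> tuple[float, int]:
    """(summed histogram entropy of lambda_1 and lambda_1-lambda_2, distinct networks)."""
    cache = cache if cache is not None else {}
    fusions = _simulate_fusions(design, n_fusion_sims, rng, fusion_probs)
    eigs = np.array([_network_eigs(s, table, cache) for s in fusions])
    score = _histogram_entropy(eigs[:, 0], n_bins) + _histogram_entropy(eigs[:, 1], n_bins)
    return score, len(set(fusions))


def choose_total_slots(
    candidates: list[int],
    table: RateTable,
    n_fusion_sims: int,
    rng: np.random.Generator,
    n_combinations: int = 24,
    fusion_probs: np.ndarray | None = None,
) -> int:
    """Slot total maximizing distinct networks over simulated random fusions."""
    fusion_probs = _default_fusion_probs() if fusion_probs is None else fusion_probs
    species = all_species()
    best, best_count = candidates[0], -1
    for total in candidates:
        design = _random_assignment(rng, n_combinations, total, species)
        fusions = _simulate_fusions(design, n_fusion_sims, rng, fusion_probs)
        count = len(set(fusions))
        if count > best_count:
            best, best_count = total, count
    return best


def design_combinations(
    n_candidates: int = 1000,
    n_fusion_sims: int = 1000,
    rng: np.random.Generator | int | None = None,
    table: RateTable | None = None,
    n_combinations: int = 24,
    total_slots: int = 50,
    n_bins: int = 20,
    fusion_probs: np.ndarray | None = None,
) -> CombinationDesign:
    """Entropy-maximizing fragment-combination design.

    Among ``n_candidates`` random assignments of ``total_slots`` fragment
    slots to ``n_combinations`` nonempty mixtures, returns the one maximizing
    the summed histogram entropies of the growth rate (lambda_1 of the rate
    matrix) and the transient gap (lambda_1 - lambda_2) over networks from
    ``n_fusion_sims`` simulated random droplet fusions.  The experimental
    campaign used 100,000 candidates and 10,000 fusions; the defaults here
    are scaled to 1,000 / 1,000.
    """
    from .chemistry import default_rate_table

    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    if total_slots < n_combinations or total_slots > n_combinations * 16:
        raise ValueError("infeasible slot count for nonempty distinct-species tubes")
    rng = np.random.default_rng(rng)
    table = table or default_rate_table()
    fusion_probs = _default_fusion_probs() if fusion_probs is None else fusion_probs
    species = all_species(table.igs_alphabet, table.tag_alphabet)
    cache: dict = {}
    best_design, best_score, best_distinct = None, -np.inf, 0
    for _ in range(n_candidates):
        design = _random_assignment(rng, n_combinations, total_slots, species)
        score, distinct = design_score(
            design, table, n_fusion_sims, rng, fusion_probs, n_bins, cache
        )
        if score > best_score:
            best_design, best_score, best_distinct = design, score, distinct
    assert best_design is not None
    return CombinationDesign(
        combinations=best_design,
        entropy_score=best_score,
        n_distinct_networks=best_distinct,
    )


def reachable_networks(
    design: tuple[tuple[SpeciesId, ...], ...], max_fusions: int = 5
) -> set[frozenset[SpeciesId]]:
    """All species-set unions reachable by fusing up to ``max_fusions`` mixtures.

    Exhaustive; intended for small designs (oracle for fusion simulation).
    """
    out: set[frozenset[SpeciesId]] = set()
    for k in range(1, max_fusions + 1):
        for picked in combinations_with_replacement(range(len(design)), k):
            sset: set[SpeciesId] = set()
            for i in picked:
                sset.update(design[i])
            out.add(frozenset(sset))
    return out


# ---------------------------------------------------------------------------
# Droplet experiment simulation


def _default_fusion_probs() -> np.ndarray:
    return np.full(5, 0.2)  # uniform over 1..5 fused droplets


@dataclass
class SimulationConfig:
    """Generative model of droplet fusion and sequencing depth.

    UMI capture is proportional to concentration: a molecule population at
    concentration c yields Poisson(``umis_per_uM`` * c) UMIs, which makes the
    pipeline's reporter-based yield conversion consistent by construction.
    ``ribozyme_depth``, when set, fixes the ribozyme UMI count per droplet
    instead (useful for sampling-depth studies); ``max_ribozyme_umis`` caps
    the count either way, reflecting the finite sequencing depth available to
    each droplet barcode.  Reads per UMI are
    1 + Poisson(``mean_reads_per_umi`` - 1); ``error_umi_rate`` is the Poisson
    mean of spurious single-read UMIs per droplet, which the read filter
    should remove.
    """

    fusion_count_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    umis_per_uM: float = 4000.0
    ribozyme_depth: int | None = None
    max_ribozyme_umis: int = 4000
    mean_reads_per_umi: float = 5.0
    error_umi_rate: float = 3.0
    incubation_min: float = 60.0
    reporter_concentration_uM: float = 0.03
    dilution_factor: float = 0.1

    def __post_init__(self) -> None:
        probs = np.asarray(self.fusion_count_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("fusion-count probabilities must be nonnegative and sum to 1")
        if self.umis_per_uM <= 0 or self.mean_reads_per_umi < 1:
            raise ValueError("depth parameters must be positive")


@dataclass
class SimulatedExperiment:
    umi_records: pd.DataFrame  # droplet_barcode, molecule_id, umi, read_count
    ground_truth: pd.DataFrame  # droplet_barcode, network_id, species, fraction, yield_uM
    design: CombinationDesign


def simulate_experiment(
    design: CombinationDesign,
    table: RateTable,
    config: SimulationConfig | None = None,
    n_droplets: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> SimulatedExperiment:
    """Simulate fused droplets through incubation and barcoded sequencing.

    Each droplet draws a fusion count k, k mixtures with replacement, forms
    the union network, computes its true composition and yield with the
    kinetic model (the same code path the analysis uses), then emits hairpin
    UMIs per encoded reporter and multinomial ribozyme UMIs, with per-UMI
    read counts and spurious error UMIs to exercise the filters.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(rng)
    probs = np.asarray(config.fusion_count_probs)
    eff_reporter_uM = config.reporter_concentration_uM * config.dilution_factor
    species16 = all_species(table.igs_alphabet, table.tag_alphabet)

    comp_cache: dict[frozenset[SpeciesId], Composition] = {}
    bc_col, mol_col, umi_col, reads_col = [], [], [], []
    truth_rows = []
    for d in range(n_droplets):
        barcode = f"BC{d:06d}"
        k = int(rng.choice(np.arange(1, probs.size + 1), p=probs))
        picked = rng.choice(len(design.combinations), size=k, replace=True)
        reporters = sorted({f"HP{i:02d}" for i in picked})
        sset = frozenset(s for i in set(picked) for s in design.combinations[i])
        if sset not in comp_cache:
            try:
                comp_cache[sset] = predict_fractions(
                    build_network(sset, table), config.incubation_min
                )
            except UndefinedCompositionError:
                # no catalytic interaction in this union: nothing is produced
                comp_cache[sset] = None
        comp = comp_cache[sset]
        ordered = tuple(sorted(sset))
        if comp is None:
            fracs = np.full(len(ordered), np.nan)
            yield_uM = 0.0
        else:
            fracs = comp.as_vector(ordered)
            yield_uM = comp.yield_uM or 0.0

        umi_serial = 0
        # hairpin reporter UMIs
        for rep in reporters:
            n_hp = rng.poisson(config.umis_per_uM * eff_reporter_uM)
            if n_hp == 0:
                continue
            bc_col.append(np.repeat(barcode, n_hp))
            mol_col.append(np.repeat(rep, n_hp))
            umi_col.append(np.char.add("U", (np.arange(umi_serial, umi_serial + n_hp)).astype(str)))
            reads_col.append(1 + rng.poisson(config.mean_reads_per_umi - 1, size=n_hp))
            umi_serial += n_hp
        # ribozyme UMIs, multinomial over the true composition
        if comp is None:
            n_rz = 0
        elif config.ribozyme_depth is not None:
            n_rz = int(config.ribozyme_depth)
        else:
            n_rz = int(rng.poisson(config.umis_per_uM * yield_uM))
        n_rz = min(n_rz, config.max_ribozyme_umis)
        if n_rz > 0:
            counts = rng.multinomial(n_rz, fracs)
            for sp, cnt in zip(ordered, counts):
                if cnt == 0:
                    continue
                bc_col.append(np.repeat(barcode, cnt))
                mol_col.append(np.repeat(str(sp), cnt))
                umi_col.append(np.char.add("U", (np.arange(umi_serial, umi_serial + cnt)).astype(str)))
                reads_col.append(1 + rng.poisson(config.mean_reads_per_umi - 1, size=cnt))
                umi_serial += cnt
        # spurious error UMIs: singleton reads on random species
        n_err = rng.poisson(config.error_umi_rate)
        if n_err > 0:
            err_species = rng.choice(len(species16), size=n_err)
            bc_col.append(np.repeat(barcode, n_err))
            mol_col.append(np.array([str(species16[i]) for i in err_species]))
            umi_col.append(np.char.add("E", (np.arange(n_err) + umi_serial).astype(str)))
            reads_col.append(np.ones(n_err, dtype=int))

        for sp, f in zip(ordered, fracs):
            truth_rows.append(
                {
                    "droplet_barcode": barcode,
                    "network_id": network_key(sset),
                    "species": str(sp),
                    "fraction": float(f),
                    "yield_uM": yield_uM,
                }
            )

    umi_records = pd.DataFrame(
        {
            "droplet_barcode": np.concatenate(bc_col) if bc_col else np.array([], dtype=str),
            "molecule_id": np.concatenate(mol_col) if mol_col else np.array([], dtype=str),
            "umi": np.concatenate(umi_col) if umi_col else np.array([], dtype=str),
            "read_count": np.concatenate(reads_col) if reads_col else np.array([], dtype=int),
        }
    )
    return SimulatedExperiment(
        umi_records=umi_records,
        ground_truth=pd.DataFrame(truth_rows),
        design=design,
    )


# ---------------------------------------------------------------------------
# Titration


def simulate_titration(
    alpha: float,
    beta: float,
    x: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> TitrationData:
    """Initial rates ``v0 = alpha*x + beta`` with additive Gaussian noise."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("doped concentrations must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(rng)
    v0 = alpha * x + beta
    if noise_sd > 0:
        v0 = v0 + rng.normal(0.0, noise_sd, size=x.shape)
    return TitrationData(doped_concentrations=x, initial_rates=v0)
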