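"""Droplet barcoded-sequencing count processing.

Input records are pre-parsed UMI observations: (droplet barcode, molecule
identity, UMI, read count), where the molecule is either a ribozyme species
(two-letter MN id) or a hairpin reporter encoding one of the initial fragment
mixtures.  The pipeline deduplicates UMIs, removes low-read UMIs (sequencing
noise), decodes each droplet's fragment content from its retained reporters,
discards ribozyme counts inconsistent with that content, applies minimum-UMI
droplet filters, and converts counts to species fractions and a yield in uM
via the reporters of known concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import SpeciesId, network_key
from .kinetics import Composition

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("droplet_barcode", "molecule_id", "umi", "read_count")

#: Prefix distinguishing hairpin-reporter molecule ids from ribozyme ids.
REPORTER_PREFIX = "HP"


@dataclass
class PipelineConfig:
    """Thresholds and conversion parameters of the count-processing pipeline.

    Reporter UMIs identify the fragment mixtures a droplet received; a
    reporter is believed only when it carries at least ``reporter_min_share``
    of the droplet's hairpin UMIs.  Droplets need ``min_hairpin_umis``
    reporter UMIs and ``min_ribozyme_umis`` ribozyme UMIs (after removing
    species without a valid reporter).  Yield conversion assumes each
    retained reporter is present at ``reporter_concentration_uM`` diluted by
    ``dilution_factor`` into the fused droplet volume.
    """

    min_reads_per_umi_ribozyme: int = 2
    min_reads_per_umi_hairpin: int = 2
    reporter_min_share: float = 0.075
    min_hairpin_umis: int = 10
    min_ribozyme_umis: int = 20
    reporter_concentration_uM: float = 0.03
    dilution_factor: float = 0.1

    @property
    def effective_reporter_uM(self) -> float:
        return self.reporter_concentration_uM * self.dilution_factor


@dataclass
class DropletMeasurement:
    droplet_barcode: str
    reporters: tuple[str, ...]
    species: tuple[SpeciesId, ...]
    umi_counts: dict[SpeciesId, int]
    fractions: Composition
    yield_uM: float

    @property
    def network_id(self) -> str:
        return network_key(self.species)


@dataclass
class Rejection:
    droplet_barcode: str
    reason: str  # no_reporter | low_hairpin | low_ribozyme


def is_reporter(molecule_id: str) -> bool:
    return str(molecule_id).startswith(REPORTER_PREFIX)


def dedup_umis(records: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicate (droplet, molecule, UMI) keys, summing read counts.

    Malformed rows (missing fields, nonpositive read counts) are skipped with
    a log entry; total reads over well-formed rows are conserved.
    """
    df = records.loc[:, list(REQUIRED_COLUMNS)].copy()
    bad = df[list(REQUIRED_COLUMNS)].isna().any(axis=1) | (
        pd.to_numeric(df["read_count"], errors="coerce").fillna(0) < 1
    )
    if bad.any():
        logger.warning("skipping %d malformed UMI records", int(bad.sum()))
        df = df[~bad]
    df["read_count"] = df["read_count"].astype(int)
    return (
        df.groupby(["droplet_barcode", "molecule_id", "umi"], as_index=False, sort=True)[
            "read_count"
        ].sum()
    )


def filter_umis(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Drop UMIs below the per-class minimum read count (ribozyme vs hairpin)."""
    reporter = records["molecule_id"].map(is_reporter)
    threshold = np.where(
        reporter, config.min_reads_per_umi_hairpin, config.min_reads_per_umi_ribozyme
    )
    return records[records["read_count"] >= threshold].reset_index(drop=True)


def call_droplet(
    records: pd.DataFrame,
    reporter_map: dict[str, frozenset[SpeciesId]],
    config: PipelineConfig,
) -> DropletMeasurement | Rejection:
    """Resolve one droplet barcode's records into a composition, or reject it.

    Steps: (1) retain reporters holding >= ``reporter_min_share`` of hairpin
    UMIs; (2) the inferred species set is the union of fragment sets the
    retained reporters encode; (3) ribozyme UMIs of species outside that set
    are discarded; (4) the droplet is rejected unless it retains at least
    ``min_hairpin_umis`` hairpin and ``min_ribozyme_umis`` ribozyme UMIs;
    (5) fractions are per-species ribozyme UMI shares.
    """
    barcode = str(records["droplet_barcode"].iloc[0])
    reporter_mask = records["molecule_id"].map(is_reporter)
    hp = records[reporter_mask]
    rz = records[~reporter_mask]

    hp_counts = hp.groupby("molecule_id")["umi"].nunique()
    total_hp = int(hp_counts.sum())
    if total_hp == 0:
        return Rejection(barcode, "no_reporter")
    retained = hp_counts[hp_counts / total_hp >= config.reporter_min_share]
    if retained.empty:
        return Rejection(barcode, "no_reporter")
    retained_hp_umis = int(retained.sum())

    species: set[SpeciesId] = set()
    for rep in retained.index:
        if rep not in reporter_map:
            logger.warning("unknown reporter %s in droplet %s", rep, barcode)
            continue
        species |= reporter_map[rep]
    if not species:
        return Rejection(barcode, "no_reporter")
    allowed = {str(s) for s in species}

    rz_counts = rz[rz["molecule_id"].isin(allowed)].groupby("molecule_id")["umi"].nunique()
    total_rz = int(rz_counts.sum())

    if retained_hp_umis < config.min_hairpin_umis:
        return Rejection(barcode, "low_hairpin")
    if total_rz < config.min_ribozyme_umis:
        return Rejection(barcode, "low_ribozyme")

    umi_counts = {SpeciesId.from_string(m): int(c) for m, c in rz_counts.items()}
    fractions = {sp: umi_counts.get(sp, 0) / total_rz for sp in sorted(species)}
    meas = DropletMeasurement(
        droplet_barcode=barcode,
        reporters=tuple(sorted(retained.index)),
        species=tuple(sorted(species)),
        umi_counts=umi_counts,
        fractions=Composition(fractions=fractions),
        yield_uM=0.0,
    )
    meas.yield_uM = compute_yield(meas, retained_hp_umis, config)
    meas.fractions.yield_uM = meas.yield_uM
    return meas


def compute_yield(droplet: DropletMeasurement, hairpin_umis: int, config: PipelineConfig) -> float:
    """Convert ribozyme UMI counts to a concentration via the reporters.

    Each retained reporter contributes a known effective concentration, so
    ``conversion = n_reporters * effective_uM / hairpin_umis`` (uM per UMI)
    and ``yield = ribozyme_umis * conversion``.
    """
    if hairpin_umis <= 0:
        raise ValueError("yield undefined without hairpin UMIs")
    conversion = len(droplet.reporters) * config.effective_reporter_uM / hairpin_umis
    return sum(droplet.umi_counts.values()) * conversion


@dataclass
class PipelineResult:
    droplets: list[DropletMeasurement]
    rejections: list[Rejection]

    def fractions_table(self) -> pd.DataFrame:
        rows = []
        for d in self.droplets:
            for sp, f in d.fractions.fractions.items():
                rows.append(
                    {
                        "droplet_barcode": d.droplet_barcode,
                        "network_id": d.network_id,
                        "species": str(sp),
                        "fraction": f,
                        "yield_uM": d.yield_uM,
                    }
                )
        return pd.DataFrame(rows)

    def rejection_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"droplet_barcode": r.droplet_barcode, "reason": r.reason} for r in self.rejections]
        )


def process_umi_table(
    records: pd.DataFrame,
    reporter_map: dict[str, frozenset[SpeciesId]],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Full pipeline: dedup, read filter, then per-droplet calling."""
    config = config or PipelineConfig()
    deduped = filter_umis(dedup_umis(records), config)
    droplets: list[DropletMeasurement] = []
    rejections: list[Rejection] = []
    for _, group in deduped.groupby("droplet_barcode", sort=True):
        result = call_droplet(group, reporter_map, config)
        if isinstance(result, Rejection):
            rejections.append(result)
        else:
            droplets.append(result)
    return PipelineResult(droplets=droplets, rejections=rejections)


def read_umi_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"droplet_barcode": str, "molecule_id": str, "umi": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"UMI table missing columns: {sorted(missing)}")
    return df
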