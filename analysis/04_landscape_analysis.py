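#!/usr/bin/env python
"""Landscape-level statistics over the processed droplet compositions.

Aggregates droplets into networks and computes: ranking conservation of
catalyst pairs, the yield ranking of 4-species networks, the pooled
model-vs-measurement fraction correlation, the background-strength/yield
correlation, and the growth-variation trade-off test.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from autocatnet.chemistry import SpeciesId, build_network, default_rate_table, species_from_key
from autocatnet.kinetics import Composition, predict_fractions
from autocatnet.landscape import (
    aggregate_networks,
    landscape_table,
    model_measurement_correlation,
    rank_conservation,
    sigma_yield_correlation,
    tradeoff_test,
    yield_ranking,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def load_droplets(path: Path):
    df = pd.read_csv(path)
    droplets = []
    for (_, net_id), grp in df.groupby(["droplet_barcode", "network_id"]):
        fr = {SpeciesId.from_string(s): f for s, f in zip(grp["species"], grp["fraction"])}
        droplets.append(
            (
                frozenset(species_from_key(net_id)),
                Composition(fractions=fr, yield_uM=float(grp["yield_uM"].iloc[0])),
            )
        )
    return droplets


def main() -> None:
    comp_path = RESULTS / "droplet_compositions.csv"
    if not comp_path.exists():
        sys.exit("run analysis/03_process_droplets.py first")
    table = default_rate_table()
    records = aggregate_networks(load_droplets(comp_path))
    landscape_table(records).to_csv(RESULTS / "landscape.csv", index=False)
    print(f"landscape: {len(records)} unique networks, "
          f"mean replicates {sum(r.n_replicates for r in records) / len(records):.1f}")

    frac_flipped = rank_conservation(records, flip_threshold=0.10)
    print(f"ranking non-conservation: {100 * frac_flipped:.1f}% of catalyst pairs flip "
          f"in >= 10% of the networks containing them")

    ranking = yield_ranking(records, size=4, min_replicates=10)
    ranking.to_csv(RESULTS / "yield_ranking_4species.csv", index=False)
    if len(ranking) >= 2:
        print(f"4-species yield ranking: {len(ranking)} networks, "
              f"fold range {ranking.attrs['fold_range']:.1f}x")

    measured = {r.network_id: r.mean_fractions for r in records}
    predicted = {}
    for r in records:
        try:
            predicted[r.network_id] = predict_fractions(build_network(r.species, table), 60)
        except Exception:
            continue
    r_mm, _ = model_measurement_correlation(predicted, measured)
    print(f"kinetic model vs measured fractions: pooled Pearson r = {r_mm:.3f}")

    r_sy, _ = sigma_yield_correlation(records, table)
    print(f"background strength vs yield: Pearson r = {r_sy:.3f}")

    # growth-variation trade-off over (perturbation, yield) pairs
    pert_path = RESULTS / "perturbation_records.csv"
    stats = {
        "n_networks": len(records),
        "rank_nonconservation": frac_flipped,
        "model_measurement_r": r_mm,
        "sigma_yield_r": r_sy,
    }
    if pert_path.exists():
        pert = pd.read_csv(pert_path)
        yields = {r.network_id: r.mean_yield_uM for r in records}
        pert["yield_uM"] = pert["G_id"].map(yields)
        res = tradeoff_test(pert.dropna(subset=["yield_uM"]))
        print(f"trade-off test: table {res.table.tolist()}, one-sided Fisher p = {res.p_value:.3g}, "
              f"odds ratio {res.odds_ratio:.3g}")
        stats["tradeoff_p"] = res.p_value
        stats["tradeoff_odds_ratio"] = res.odds_ratio
    else:
        print("perturbation records not found; run analysis/05 then re-run for the trade-off test")
    (RESULTS / "landscape_stats.json").write_text(json.dumps(stats, indent=2))
    print(f"wrote {RESULTS / 'landscape.csv'} and {RESULTS / 'landscape_stats.json'}")


if __name__ == "__main__":
    main()
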