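"""Simulate the study inputs: a standard-mix run, genotype cohorts of
meibum chromatograms (wild type n=5, heterozygous n=7, null n=5), and
replicate melting curves for both thermotropic phenotypes.

Outputs under results/sim/: scan CSVs with ground-truth sidecars and
melting-curve CSVs.  Everything is seeded and reproducible.
"""

import dataclasses
import json
from pathlib import Path

from meiboquant.chromatogram_io import write_curve, write_scans
from meiboquant.lipid_registry import build_default_registry
from meiboquant.melting import SOAT1_NULL_PARAMS, WILD_TYPE_PARAMS
from meiboquant.synthetic_data import (
    MeltSimSpec,
    SimConfig,
    make_preset,
    simulate_chromatogram,
    simulate_melting_curve,
)

BASE_SEED = 20210204
COHORTS = {"wild_type": 5, "het": 7, "soat1_null": 5}
MELT_PARAMS = {"wild_type": WILD_TYPE_PARAMS, "soat1_null": SOAT1_NULL_PARAMS}
N_MELT_REPLICATES = 3  # animals per genotype in the melting experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    registry = build_default_registry()
    seed = BASE_SEED

    std = simulate_chromatogram(make_preset("standard_mix"),
                                SimConfig(seed=seed), registry)
    write_scans(std, OUT / "standard_mix.csv")
    print(f"standard mix: {len(std)} scans -> {OUT / 'standard_mix.csv'}")

    for genotype, n in COHORTS.items():
        comp = make_preset(genotype)
        for i in range(n):
            seed += 1
            scans = simulate_chromatogram(comp, SimConfig(seed=seed), registry)
            stem = OUT / f"{genotype}_{i + 1}"
            write_scans(scans, stem.with_suffix(".csv"))
            truth = {sid: dataclasses.asdict(s) for sid, s in comp.species.items()}
            stem.with_suffix(".truth.json").write_text(json.dumps(
                {"preset": genotype, "species": truth}, indent=1))
        print(f"{genotype}: {n} replicate chromatograms")

    for genotype, params in MELT_PARAMS.items():
        for i in range(N_MELT_REPLICATES):
            seed += 1
            curve = simulate_melting_curve(
                MeltSimSpec(params, noise_sd=0.01, seed=seed))
            path = OUT / f"melt_{genotype}_{i + 1}.csv"
            write_curve(curve.temperature_k, curve.birefringence, path)
        print(f"{genotype}: {N_MELT_REPLICATES} melting curves "
              f"(T1={params.T1} K, T2={params.T2} K, k={params.k}, m={params.m})")


if __name__ == "__main__":
    main()
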