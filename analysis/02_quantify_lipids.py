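"""Quantify the simulated cohorts: response-factor calibration from the
standard mix, then per-sample sterol ratios, CE chain profiles and
class balances, summarized by genotype with pairwise Welch t-tests.

Reads results/sim/ (run 01_simulate_cohort.py first); writes tidy
tables under results/tables/.
"""

from pathlib import Path

import pandas as pd

from meiboquant.chromatogram_io import read_scans
from meiboquant.eic_quant import calibrate_response, compare_groups, quantify_sample
from meiboquant.lipid_registry import build_default_registry

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results" / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    registry = build_default_registry()

    std = read_scans(SIM / "standard_mix.csv")
    factors = calibrate_response(std, registry)
    pd.Series(factors.factors, name="relative_response").rename_axis(
        "species").to_csv(OUT / "response_factors.csv")
    print("response factors (Chl = 1.00):")
    for sid, v in factors.factors.items():
        print(f"  {sid:10s} {v:.3f}")

    rows, profiles = [], []
    for path in sorted(SIM.glob("*_*.csv")):
        if path.name.startswith(("melt_", "standard_mix")):
            continue
        genotype, _, replicate = path.stem.rpartition("_")
        report = quantify_sample(read_scans(path), registry, factors,
                                 sample_id=path.stem, genotype=genotype)
        rows.append({"sample_id": path.stem, "genotype": genotype,
                     "chl_ce_ratio_percent": report.chl_ce_ratio_percent,
                     **{f"class_{k}": v
                        for k, v in report.class_balance_percent.items()}})
        for label, pct in report.chain_profile_fragment.items():
            profiles.append({"sample_id": path.stem, "genotype": genotype,
                             "mode": "fragment", "label": label, "percent": pct})
        for label, pct in report.chain_profile_adduct.items():
            profiles.append({"sample_id": path.stem, "genotype": genotype,
                             "mode": "adduct", "label": label, "percent": pct})

    samples = pd.DataFrame(rows)
    samples.to_csv(OUT / "samples.csv", index=False)
    pd.DataFrame(profiles).to_csv(OUT / "chain_profiles.csv", index=False)

    groups = {g: sub["chl_ce_ratio_percent"].to_numpy()
              for g, sub in samples.groupby("genotype")}
    summary, pairs = compare_groups(groups)
    summary.to_csv(OUT / "ratio_by_genotype.csv")
    pairs.to_csv(OUT / "pairwise_tests.csv", index=False)

    print("\nChl/(Chl+CE) percent by genotype (mean +/- SD):")
    for g, row in summary.iterrows():
        print(f"  {g:12s} {row['mean']:6.2f} +/- {row['sd']:.2f}  (n={int(row['n'])})")
    print("\npairwise Welch t-tests:")
    for _, row in pairs.iterrows():
        print(f"  {row.group_a} vs {row.group_b}: p = {row.p_value:.2e}")
    print("\nclass balance means (%):")
    print(samples.groupby("genotype")[
        [c for c in samples.columns if c.startswith("class_")]].mean().round(2))


if __name__ == "__main__":
    main()
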