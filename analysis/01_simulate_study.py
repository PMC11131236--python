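#!/usr/bin/env python
"""Generate the synthetic metabolome-wide MR study inputs.

Emulates the structure of the real study at desk scale: 50 metabolite
exposure GWAS (5 with a true causal effect of 0.25 years per SD on the
outcome), one reproductive-timing outcome GWAS, an adult-BMI GWAS for
the multivariable models, a block-AR(1) LD reference panel, a
metabolite-class annotation table, and an observational validation
cohort.  Writes everything as TSV plus a study config YAML and a
ground-truth JSON under the output directory.
"""

import argparse
import json
from pathlib import Path

from metabomr import StudyConfig, simulate_study
from metabomr.enrichment import MetaboliteSetDB
from metabomr.summary_io import write_summary_stats


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    data_dir = args.outdir / "data"
    (data_dir / "exposures").mkdir(parents=True, exist_ok=True)

    data = simulate_study(n_metabolites=50, n_causal=5, theta=0.25,
                          with_bmi=True, theta_bmi=-0.3, seed=args.seed)

    data.panel.to_tsv(data_dir / "panel_meta.tsv", data_dir / "panel_r.tsv")
    exposure_paths = {}
    for name, stats in data.exposures.items():
        path = data_dir / "exposures" / f"{name}.tsv"
        write_summary_stats(stats, path)
        exposure_paths[name] = str(path)
    write_summary_stats(data.outcome, data_dir / "outcome.tsv")
    write_summary_stats(data.bmi, data_dir / "bmi.tsv")
    data.cohort.to_csv(data_dir / "cohort.tsv", sep="\t", index=False)
    MetaboliteSetDB(data.set_db).to_tsv(data_dir / "metabolite_sets.tsv")

    config = StudyConfig(
        seed=args.seed,
        exposure_paths=exposure_paths,
        outcome_path=str(data_dir / "outcome.tsv"),
        panel_meta_path=str(data_dir / "panel_meta.tsv"),
        panel_r_path=str(data_dir / "panel_r.tsv"),
        bmi_path=str(data_dir / "bmi.tsv"),
        cohort_path=str(data_dir / "cohort.tsv"),
        set_db_path=str(data_dir / "metabolite_sets.tsv"),
        outdir=str(args.outdir),
    )
    config.to_yaml(args.outdir / "config.yaml")
    with open(args.outdir / "truth.json", "w") as fh:
        json.dump({"causal": list(data.causal), "theta": 0.25,
                   "theta_bmi": -0.3, "seed": args.seed}, fh, indent=2)

    print(f"simulated {len(data.exposures)} metabolite GWAS "
          f"({len(data.causal)} causal at theta = 0.25 y/SD), "
          f"{len(data.panel)} panel SNPs, outcome n = 201,323 records kept: "
          f"{len(data.outcome)}")
    print(f"inputs and config written under {args.outdir}")


if __name__ == "__main__":
    main()
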