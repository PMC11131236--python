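#!/usr/bin/env python
"""Metabolite-set enrichment and observational cohort validation.

Hypergeometric over-representation of the colocalized metabolites
against the annotation sets, and OLS validation of the metabolite /
age-at-event association in the cohort (+/- BMI adjustment, +/- the
early-menopause exclusion at 45 years).
"""

import argparse
from pathlib import Path

from metabomr import StudyConfig
from metabomr.pipeline import (load_study_data, stage_coloc, stage_instruments,
                               stage_mr, stage_ora, stage_validation)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    config = StudyConfig.from_yaml(args.study / "config.yaml")
    data = load_study_data(config)
    strong, _, _ = stage_instruments(data, config)
    _, hsets, prioritized = stage_mr(data, config, strong)
    _, _, colocalized = stage_coloc(data, config, hsets, prioritized)

    ora = stage_ora(data, colocalized)
    ora.to_csv(args.study / "ora.tsv", sep="\t", index=False)
    if ora.empty:
        print("enrichment skipped (no colocalized metabolites or no annotation)")
    else:
        hit = ora[ora["fdr_q"] < 0.05]
        print(f"enrichment over {len(ora)} sets; {len(hit)} at FDR < 0.05")
        print(ora.head(3)[["set_id", "k", "K", "n", "N", "p", "fdr_q"]]
              .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    val = stage_validation(data, config)
    val.to_csv(args.study / "validation.tsv", sep="\t", index=False)
    print("\ncohort validation (slope in years per unit metabolite):")
    print(val[["adjusted_bmi", "exclude_early", "beta", "se", "p", "n"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(f"wrote {args.study / 'ora.tsv'} and {args.study / 'validation.tsv'}")


if __name__ == "__main__":
    main()
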