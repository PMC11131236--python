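#!/usr/bin/env python
"""Pleiotropy, heterogeneity and directionality diagnostics.

For every FDR-prioritized metabolite with enough instruments: Cochran's
Q around the IVW fit, the MR-Egger intercept test, the MR-PRESSO
global/outlier test, and per-SNP Steiger directionality.
"""

import argparse
from pathlib import Path

from metabomr import StudyConfig
from metabomr.pipeline import (load_study_data, stage_instruments, stage_mr,
                               stage_sensitivity)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    config = StudyConfig.from_yaml(args.study / "config.yaml")
    data = load_study_data(config)
    strong, _, _ = stage_instruments(data, config)
    _, hsets, prioritized = stage_mr(data, config, strong)
    table = stage_sensitivity(config, hsets, prioritized, seed=config.seed + 1)

    table.to_csv(args.study / "sensitivity.tsv", sep="\t", index=False)
    if table.empty:
        print("no prioritized metabolites: sensitivity stage skipped")
        return
    multi = table[table["nsnp"] >= 3]
    print(f"diagnostics for {len(table)} prioritized metabolites "
          f"({len(multi)} with >= 3 instruments)")
    flagged_q = (table["q_p"] < 0.05).sum()
    flagged_e = (multi["egger_intercept_p"] < 0.05).sum()
    flagged_p = (table["presso_global_p"] < 0.05).sum()
    print(f"heterogeneity (Q p < 0.05): {flagged_q}; "
          f"directional pleiotropy (Egger intercept p < 0.05): {flagged_e}; "
          f"PRESSO global p < 0.05: {flagged_p}")
    print(f"Steiger supports metabolite -> outcome for "
          f"{int(table['steiger_verdict'].sum())}/{len(table)}")
    print(f"wrote {args.study / 'sensitivity.tsv'}")


if __name__ == "__main__":
    main()
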