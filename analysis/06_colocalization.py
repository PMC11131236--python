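#!/usr/bin/env python
"""Colocalization of prioritized metabolites with the outcome.

For each instrument region (+/-500 kb, MAF > 0.01, priors p1 = p2 =
1e-4, p12 = 1e-5), computes the five-hypothesis posteriors; a
metabolite is called colocalized when PP(H4) > 0.8 in at least one of
its regions.
"""

import argparse
import json
from pathlib import Path

from metabomr import StudyConfig
from metabomr.pipeline import load_study_data, stage_coloc, stage_instruments, stage_mr


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    config = StudyConfig.from_yaml(args.study / "config.yaml")
    data = load_study_data(config)
    strong, _, _ = stage_instruments(data, config)
    _, hsets, prioritized = stage_mr(data, config, strong)
    table, verdicts, colocalized = stage_coloc(data, config, hsets, prioritized)

    table.to_csv(args.study / "coloc.tsv", sep="\t", index=False)
    with open(args.study / "coloc_verdicts.json", "w") as fh:
        json.dump({m: {k: (v if not hasattr(v, "item") else v.item())
                       for k, v in verdict.items()}
                   for m, verdict in verdicts.items()}, fh, indent=2, default=str)

    print(f"colocalization over {len(table)} instrument regions of "
          f"{len(verdicts)} prioritized metabolites")
    print(f"colocalized (max PP4 > {config.h4:g}): {len(colocalized)} -> {colocalized}")
    if not table.empty:
        best = table.sort_values("pp4", ascending=False).head(5)
        print(best[["metabolite", "lead_snp", "nsnps", "pp3", "pp4"]]
              .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"wrote {args.study / 'coloc.tsv'}")


if __name__ == "__main__":
    main()
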