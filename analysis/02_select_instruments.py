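#!/usr/bin/env python
"""Select genetic instruments for every metabolite.

Genome-wide significance filter (P <= 5e-8), greedy LD clumping
(r^2 < 0.001 within +/-500 kb) against the reference panel, and the
global-F weak-instrument filter (F >= 10).  Writes the instrument
table and prints the first funnel counts.
"""

import argparse
from pathlib import Path

from metabomr import StudyConfig
from metabomr.pipeline import load_study_data, stage_instruments


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    config = StudyConfig.from_yaml(args.study / "config.yaml")
    data = load_study_data(config)
    strong, table, counts = stage_instruments(data, config)

    table.to_csv(args.study / "instruments.tsv", sep="\t", index=False)
    print(f"{counts['exposures_in']} exposures -> "
          f"{counts['with_instruments']} with genome-wide instruments -> "
          f"{counts['strong_instruments']} passing F >= {config.f_min:g}")
    ks = table.groupby("metabolite")["snp"].size()
    print(f"instruments per metabolite: min {ks.min()}, median {ks.median():.0f}, "
          f"max {ks.max()}; median F = {table['F'].median():.0f}")
    print(f"wrote {args.study / 'instruments.tsv'}")


if __name__ == "__main__":
    main()
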