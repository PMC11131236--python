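"""Genetic-instrument selection: significance filter, LD clumping, strength.

The relevance assumption of MR is enforced in three steps: keep SNPs
genome-wide significantly associated with the metabolite (P <= 5e-8),
prune them to near-independence by greedy LD clumping (r^2 < 0.001
within +/-500 kb of the index SNP), and discard metabolites whose
instruments are jointly weak (global F below 10).  The variance a SNP
explains in a standardized exposure is approximated by
r^2 = 2 beta^2 f (1 - f), and the global F-statistic is
F = (R^2 / k) / ((1 - R^2) / (n - k - 1)) with R^2 the sum of per-SNP
r^2 over the (near-independent) instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError
from .summary_io import SummaryStats
from .synthetic import LDPanel

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.001
CLUMP_WINDOW_KB = 500.0
F_MIN = 10.0


@dataclass(eq=False)
class InstrumentSet:
    """Selected instruments for one metabolite with strength summaries."""

    metabolite: str
    table: pd.DataFrame       # sumstat columns + per-SNP r2
    r2_total: float
    f_stat: float
    k: int
    n: float

    def snps(self) -> List[str]:
        return list(self.table["snp"])


def select_significant(stats: SummaryStats, p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Records with exposure p at or below the threshold, ascending p."""
    if not 0 < p_threshold < 1:
        raise InputError("p_threshold must lie in (0, 1)")
    hits = stats.df[stats.df["p"] <= p_threshold]
    return hits.sort_values(["p", "snp"], kind="mergesort").reset_index(drop=True)


def clump(snps: pd.DataFrame, panel: LDPanel, r2_threshold: float = CLUMP_R2,
          window_kb: float = CLUMP_WINDOW_KB) -> pd.DataFrame:
    """Greedy LD clumping of a p-sorted SNP table.

    Keeps the most significant SNP, removes every SNP within
    ``window_kb`` of it whose panel r^2 is at or above the threshold,
    and recurses on the remainder; the result is pairwise independent
    by construction.  SNPs absent from the panel are dropped with a
    warning (assuming independence would be anti-conservative).
    """
    present = snps["snp"].isin(panel.index.keys())
    if (~present).any():
        logger.warning("clump: dropping %d SNPs absent from the LD panel", int((~present).sum()))
    work = snps.loc[present].sort_values(["p", "snp"], kind="mergesort").reset_index(drop=True)
    kept_rows = []
    window_bp = window_kb * 1000.0
    alive = work.copy()
    while len(alive):
        best = alive.iloc[0]
        kept_rows.append(best)
        bi = panel.index[best["snp"]]
        bpos, bchr = best["pos"], best["chr"]
        drop = []
        for j in range(1, len(alive)):
            row = alive.iloc[j]
            if row["chr"] != bchr or abs(row["pos"] - bpos) > window_bp:
                continue
            if panel.r[bi, panel.index[row["snp"]]] ** 2 >= r2_threshold:
                drop.append(j)
        alive = alive.drop(alive.index[[0] + drop]).reset_index(drop=True)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def variance_explained(beta: float, eaf: float) -> float:
    """Per-SNP exposure variance explained: r^2 = 2 beta^2 f (1 - f)."""
    eaf = np.asarray(eaf, float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise InputError("eaf must lie in (0, 1)")
    return 2.0 * np.asarray(beta, float) ** 2 * eaf * (1.0 - eaf)


def f_statistic(r2_total: float, n: float, k: int) -> float:
    """Global instrument-strength F from total R^2, sample size and IV count."""
    if not 0 <= r2_total < 1:
        raise InputError("r2_total must lie in [0, 1)")
    if n <= k + 1:
        raise DegenerateInputError(f"need n > k+1 (n={n}, k={k})")
    return (r2_total / k) / ((1.0 - r2_total) / (n - k - 1.0))


def build_instruments(stats: SummaryStats, panel: LDPanel,
                      p_threshold: float = GENOME_WIDE_P,
                      r2_threshold: float = CLUMP_R2,
                      window_kb: float = CLUMP_WINDOW_KB) -> Optional[InstrumentSet]:
    """Significance filter + clump + strength summary for one metabolite.

    Returns None when no SNP passes the significance threshold (the
    metabolite is then skipped downstream).
    """
    hits = select_significant(stats, p_threshold)
    if hits.empty:
        return None
    kept = clump(hits, panel, r2_threshold, window_kb)
    if kept.empty:
        return None
    kept = kept.copy()
    kept["r2"] = variance_explained(kept["beta"].to_numpy(), kept["eaf"].to_numpy())
    r2_total = float(np.minimum(kept["r2"].sum(), 1 - 1e-12))
    n = float(np.nanmedian(kept["n"])) if kept["n"].notna().any() else np.nan
    k = len(kept)
    f = f_statistic(r2_total, n, k) if np.isfinite(n) else np.nan
    return InstrumentSet(stats.trait, kept, r2_total, f, k, n)


def filter_weak(sets: List[InstrumentSet], f_min: float = F_MIN) -> List[InstrumentSet]:
    """Retain instrument sets with F at or above ``f_min`` (weak sets logged)."""
    kept = []
    for s in sets:
        if np.isfinite(s.f_stat) and s.f_stat >= f_min:
            kept.append(s)
        else:
            logger.info("filter_weak: excluding %s (F=%.2f)", s.metabolite, s.f_stat)
    return kept
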