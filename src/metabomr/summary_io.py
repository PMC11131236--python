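"""GWAS summary-statistics containers, file I/O and allele harmonization.

Two-sample MR joins per-SNP effect estimates from an exposure GWAS
(metabolite level, SD units per effect allele) with estimates from an
outcome GWAS (age at menarche / menopause, years per effect allele).
Before any estimator runs, the two studies must be expressed for the
same effect allele at every SNP: this module aligns allele swaps and
strand flips, resolves palindromic (A/T, C/G) ambiguity by allele
frequency, and substitutes LD proxies for instruments missing from the
outcome study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import EmptyHarmonizationError, FormatError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import LDPanel

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
SUMSTAT_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = frozenset("ACGT")


def complement(allele: str) -> str:
    """DNA complement of a single-base allele."""
    return _COMPLEMENT[allele]


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T or C/G SNPs, whose strand cannot be resolved by alleles."""
    return _COMPLEMENT.get(ea) == oa


@dataclass
class SummaryStats:
    """Per-SNP association records of one GWAS for a single trait.

    ``df`` carries the columns in :data:`SUMSTAT_COLUMNS`; ``eaf``, ``p``
    and ``n`` may contain NaN where the source did not report them.
    """

    trait: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"summary table for {self.trait!r} lacks columns {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, snps) -> "SummaryStats":
        """Records restricted to ``snps`` (order of the table preserved)."""
        keep = self.df["snp"].isin(set(snps))
        return SummaryStats(self.trait, self.df.loc[keep].copy())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    One row per instrument with exposure and outcome beta/se expressed
    for the same effect allele; ``proxy`` flags records where the outcome
    effect was carried over from an LD proxy (``proxy_source``).
    """

    metabolite: str
    outcome: str
    df: pd.DataFrame
    required = ["snp", "ea", "oa", "eaf", "beta_exp", "se_exp", "beta_out", "se_out"]

    def __post_init__(self) -> None:
        missing = [c for c in self.required if c not in self.df.columns]
        if missing:
            raise FormatError(f"harmonized set lacks columns {missing}")
        if "proxy" not in self.df.columns:
            self.df = self.df.assign(proxy=False, proxy_source=None)
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def bx(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(float)

    @property
    def bx_se(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(float)

    @property
    def by(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(float)

    @property
    def by_se(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(float)


DEFAULT_DIALECT = {c: c for c in SUMSTAT_COLUMNS}
_REQUIRED_KEYS = ("snp", "ea", "oa", "beta", "se")


def _zscore_from_p(p: np.ndarray) -> np.ndarray:
    # |z| implied by a two-sided normal p-value
    return -special.ndtri(np.clip(p, 1e-320, 1.0) / 2.0)


def read_summary_stats(path, dialect: Optional[dict] = None, trait: Optional[str] = None,
                       p_consistency_tol: float = 0.10) -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    ``dialect`` maps canonical keys (snp, chr, pos, ea, oa, eaf, beta,
    se, p, n) to the file's column names; canonical names are assumed
    for keys not mapped.  Rows violating the record invariants (non-ACGT
    or multi-base alleles, se <= 0, eaf outside (0,1), p outside (0,1],
    p inconsistent with |beta/se| by more than ``p_consistency_tol``
    relative) are dropped with a logged count.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    for key in _REQUIRED_KEYS:
        if key not in dialect:
            raise FormatError(f"dialect does not map required column {key!r}")
    raw = pd.read_csv(path, sep="\t", dtype={dialect["snp"]: str})
    if raw.empty:
        raise FormatError(f"{path} contains no records")
    missing = [dialect[k] for k in _REQUIRED_KEYS if dialect[k] not in raw.columns]
    if missing:
        raise FormatError(f"{path} lacks required columns {missing}")

    df = pd.DataFrame(index=raw.index)
    for key in SUMSTAT_COLUMNS:
        col = dialect.get(key)
        df[key] = raw[col] if col in raw.columns else np.nan
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()

    n0 = len(df)
    ok = df["ea"].isin(_BASES) & df["oa"].isin(_BASES) & (df["ea"] != df["oa"])
    ok &= pd.to_numeric(df["se"], errors="coerce") > 0
    ok &= pd.to_numeric(df["beta"], errors="coerce").notna()
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    ok &= eaf.isna() | ((eaf > 0) & (eaf < 1))
    p = pd.to_numeric(df["p"], errors="coerce")
    ok &= p.isna() | ((p > 0) & (p <= 1))
    # p must agree with |beta/se| under the normal approximation
    with np.errstate(divide="ignore", invalid="ignore"):
        z_obs = np.abs(df["beta"].to_numpy(float) / df["se"].to_numpy(float))
        z_imp = _zscore_from_p(p.to_numpy(float))
    # below ~1e-290 the p-value is at the subnormal floor and ndtri
    # saturates, so agreement with |beta/se| cannot be judged
    both = (p.notna().to_numpy() & (p.to_numpy(float) < 1.0)
            & (p.to_numpy(float) > 1e-290) & np.isfinite(z_obs) & (z_obs > 0))
    rel = np.where(both & (z_imp > 0), np.abs(z_obs - z_imp) / np.maximum(z_imp, 1e-12), 0.0)
    ok &= ~(both & (rel > p_consistency_tol))

    dropped = int(n0 - ok.sum())
    if dropped:
        logger.info("read_summary_stats(%s): dropped %d/%d invalid rows", path, dropped, n0)
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise FormatError(f"{path}: no valid records after filtering")
    return SummaryStats(trait or str(path), df)


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write the canonical tab-separated dialect read by read_summary_stats."""
    stats.to_tsv(path)


def _orient_row(exp_ea, exp_oa, out_ea, out_oa):
    """How the outcome alleles relate to the exposure alleles.

    Returns 'same', 'swap', or None (incompatible allele pair).  Strand
    flips are resolved by complementing the outcome alleles first.
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "same"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "swap"
    c_ea, c_oa = _COMPLEMENT[out_ea], _COMPLEMENT[out_oa]
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return "same"
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return "swap"
    return None


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindrome_maf_limit: float = 0.42) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Swapped alleles flip the outcome beta sign and complement its eaf;
    strand-flipped records are complemented then matched.  Palindromic
    SNPs are oriented by allele frequency and kept only when the minor
    allele frequency is below ``palindrome_maf_limit`` in both studies;
    otherwise they are dropped as ambiguous.  SNPs absent from either
    study, or with incompatible alleles, are excluded.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise EmptyHarmonizationError("empty input summary statistics")
    merged = exposure.df.merge(outcome.df, on="snp", suffixes=("_exp", "_out"), how="inner")

    rows = []
    for rec in merged.itertuples(index=False):
        exp_ea, exp_oa = rec.ea_exp, rec.oa_exp
        out_ea, out_oa = rec.ea_out, rec.oa_out
        beta_out, eaf_out = rec.beta_out, rec.eaf_out
        if is_palindromic(exp_ea, exp_oa):
            if not is_palindromic(out_ea, out_oa) or {out_ea, out_oa} != {exp_ea, exp_oa}:
                continue
            eaf_exp = rec.eaf_exp
            if pd.isna(eaf_exp) or pd.isna(eaf_out):
                continue
            maf_exp = min(eaf_exp, 1 - eaf_exp)
            maf_out = min(eaf_out, 1 - eaf_out)
            if maf_exp >= palindrome_maf_limit or maf_out >= palindrome_maf_limit:
                continue  # too close to 0.5 to trust frequency orientation
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                beta_out = -beta_out
                eaf_out = 1 - eaf_out
        else:
            how = _orient_row(exp_ea, exp_oa, out_ea, out_oa)
            if how is None:
                continue
            if how == "swap":
                beta_out = -beta_out
                eaf_out = 1 - eaf_out if pd.notna(eaf_out) else eaf_out
        rows.append({
            "snp": rec.snp, "chr": rec.chr_exp, "pos": rec.pos_exp,
            "ea": exp_ea, "oa": exp_oa,
            "eaf": rec.eaf_exp if pd.notna(rec.eaf_exp) else eaf_out,
            "beta_exp": rec.beta_exp, "se_exp": rec.se_exp,
            "p_exp": rec.p_exp, "n_exp": rec.n_exp,
            "beta_out": beta_out, "se_out": rec.se_out,
            "p_out": rec.p_out, "n_out": rec.n_out,
            "proxy": False, "proxy_source": None,
        })
    if not rows:
        raise EmptyHarmonizationError(
            f"no SNPs shared by {exposure.trait!r} and {outcome.trait!r} after harmonization")
    return HarmonizedSet(exposure.trait, outcome.trait, pd.DataFrame(rows))


@dataclass
class ProxyRecord:
    """An outcome record substituted for a missing instrument."""

    query: str
    proxy: str
    r: float
    r2: float
    distance: int
    outcome_row: pd.Series = field(repr=False)


def find_proxy(snp: str, outcome: SummaryStats, panel: "LDPanel",
               r2_min: float = 0.8) -> Optional[ProxyRecord]:
    """Best LD proxy for ``snp`` among SNPs present in the outcome study.

    Returns the outcome-present panel SNP with maximal r-squared at or
    above ``r2_min``; ties are broken by base-pair distance, then by
    lexicographic id.  ``None`` when no candidate qualifies.  The signed
    r orients the proxy's effect allele relative to the query's.
    """
    if snp not in panel.index:
        raise InputError(f"{snp} not present in LD panel")
    qi = panel.index[snp]
    meta = panel.snps
    qpos = int(meta.at[qi, "pos"])
    qchr = meta.at[qi, "chr"]
    present = outcome.df["snp"]
    candidates = meta[(meta["snp"] != snp) & (meta["chr"] == qchr) & meta["snp"].isin(set(present))]
    best = None
    for ci, cand in candidates.iterrows():
        r = float(panel.r[qi, ci])
        r2 = r * r
        if r2 < r2_min:
            continue
        dist = abs(int(cand["pos"]) - qpos)
        key = (-r2, dist, cand["snp"])
        if best is None or key < best[0]:
            row = outcome.df[outcome.df["snp"] == cand["snp"]].iloc[0]
            best = (key, ProxyRecord(snp, cand["snp"], r, r2, dist, row))
    return best[1] if best else None


def harmonize_with_proxies(exposure: SummaryStats, outcome: SummaryStats, panel: "LDPanel",
                           r2_min: float = 0.8,
                           palindrome_maf_limit: float = 0.42) -> HarmonizedSet:
    """Harmonize, substituting LD proxies for instruments missing from the outcome.

    The exposure effect of a proxied instrument is carried over
    unchanged; the proxy's outcome effect enters with the sign of the
    panel correlation between the two SNPs' panel effect alleles, after
    the proxy record itself is oriented to the panel.
    """
    present = set(outcome.df["snp"])
    missing = [s for s in exposure.df["snp"] if s not in present and s in panel.index]
    extra_rows = []
    for snp in missing:
        rec = find_proxy(snp, outcome, panel, r2_min=r2_min)
        if rec is None:
            continue
        prow = rec.outcome_row
        pi = panel.index[rec.proxy]
        panel_ea = panel.snps.at[pi, "ea"]
        panel_oa = panel.snps.at[pi, "oa"]
        how = _orient_row(panel_ea, panel_oa, prow["ea"], prow["oa"])
        if how is None:
            continue
        beta = -prow["beta"] if how == "swap" else prow["beta"]
        if rec.r < 0:
            beta = -beta
        qi = panel.index[snp]
        extra_rows.append({
            "snp": snp, "chr": panel.snps.at[qi, "chr"], "pos": panel.snps.at[qi, "pos"],
            "ea": panel.snps.at[qi, "ea"], "oa": panel.snps.at[qi, "oa"],
            # reference-panel frequency stands in for the unreported outcome eaf
            "eaf": float(panel.snps.at[qi, "maf"]),
            "beta": beta, "se": prow["se"], "p": prow["p"], "n": prow["n"],
            "_proxy_source": rec.proxy,
        })
    out_df = outcome.df
    if extra_rows:
        out_df = pd.concat([out_df, pd.DataFrame(extra_rows).drop(columns="_proxy_source")],
                           ignore_index=True)
    hset = harmonize(exposure, SummaryStats(outcome.trait, out_df), palindrome_maf_limit)
    if extra_rows:
        src = {r["snp"]: r["_proxy_source"] for r in extra_rows}
        hset.df["proxy"] = hset.df["snp"].isin(src)
        hset.df["proxy_source"] = hset.df["snp"].map(src)
    return hset


def normal_p(beta, se):
    """Two-sided normal p-value for beta/se, clipped into (0, 1]."""
    z = np.asarray(beta, float) / np.asarray(se, float)
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
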