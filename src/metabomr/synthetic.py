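"""Seeded generators for LD panels, GWAS summary statistics and cohorts.

The study this package reproduces consumes only summary-level GWAS
data, so genetic effects are simulated directly on the effect scale
rather than through individual-level genotypes.  For a biallelic SNP
with effect-allele frequency f genotyped in n individuals, the sampling
standard error of a per-allele effect on a standardized trait is
approximately 1/sqrt(2 f (1-f) n); marginal effects and estimation
noise at SNPs in linkage disequilibrium are correlated through the
panel correlation matrix.  LD within a block follows an AR(1) profile
(r between SNPs i and j equals rho^|i-j|), which gives exact
closed-form r-squared values for clumping and proxy-lookup tests;
distinct blocks are independent and placed more than 500 kb apart.

Ground truth is carried by :class:`SimTruth`: theta is the causal
effect of the metabolite on the outcome (years per SD), ``snp_effects``
the per-SNP effects on the metabolite (SD per allele), and
``pleiotropy`` per-SNP direct effects on the outcome (years per allele)
that bypass the metabolite, violating the exclusion restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError
from .summary_io import SummaryStats, normal_p

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class LDPanel:
    """Pairwise LD reference: SNP metadata plus a signed correlation matrix.

    ``snps`` has columns snp, chr, pos, ea, oa, maf; ``r`` is the
    symmetric correlation matrix between panel effect-allele dosages.
    """

    snps: pd.DataFrame
    r: np.ndarray
    _chol: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.snps)
        if self.r.shape != (n, n):
            raise InputError("r matrix does not match SNP metadata")
        if not np.allclose(self.r, self.r.T):
            raise InputError("r matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise InputError("r matrix must have unit diagonal")
        maf = self.snps["maf"].to_numpy(float)
        if np.any((maf <= 0) | (maf > 0.5)):
            raise InputError("maf must lie in (0, 0.5]")
        for _, grp in self.snps.groupby("chr"):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise InputError("positions must be strictly increasing within a chromosome")
        self.index = {s: i for i, s in enumerate(self.snps["snp"])}

    def __len__(self) -> int:
        return len(self.snps)

    def r2(self, snp_a: str, snp_b: str) -> float:
        return float(self.r[self.index[snp_a], self.index[snp_b]] ** 2)

    def cholesky(self) -> np.ndarray:
        """Cached Cholesky factor of r (jittered) for correlated noise draws."""
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.r + 1e-9 * np.eye(len(self)))
        return self._chol

    def to_tsv(self, meta_path, r_path) -> None:
        self.snps.to_csv(meta_path, sep="\t", index=False)
        iu = np.triu_indices(len(self), k=1)
        nz = self.r[iu] != 0.0          # block-diagonal panels stay compact
        pd.DataFrame({
            "snp_a": self.snps["snp"].to_numpy()[iu[0][nz]],
            "snp_b": self.snps["snp"].to_numpy()[iu[1][nz]],
            "r": self.r[iu][nz],
        }).to_csv(r_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, meta_path, r_path) -> "LDPanel":
        snps = pd.read_csv(meta_path, sep="\t", dtype={"snp": str})
        pairs = pd.read_csv(r_path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        idx = {s: i for i, s in enumerate(snps["snp"])}
        r = np.eye(len(snps))
        ia = pairs["snp_a"].map(idx).to_numpy()
        ib = pairs["snp_b"].map(idx).to_numpy()
        r[ia, ib] = pairs["r"].to_numpy()
        r[ib, ia] = pairs["r"].to_numpy()
        return cls(snps, r)


@dataclass
class SimTruth:
    """Ground truth of one simulated exposure/outcome GWAS pair."""

    theta: float
    snp_effects: np.ndarray
    pleiotropy: np.ndarray
    n_exp: int
    n_out: int
    seed: int

    def __post_init__(self) -> None:
        self.snp_effects = np.asarray(self.snp_effects, float)
        self.pleiotropy = np.asarray(self.pleiotropy, float)
        if self.n_exp <= 0 or self.n_out <= 0:
            raise InputError("sample sizes must be positive")
        if self.snp_effects.shape != self.pleiotropy.shape:
            raise InputError("snp_effects and pleiotropy must have equal length")


def simulate_ld_panel(n_blocks: int, block_size: int, rho: float,
                      maf_range: Tuple[float, float] = (0.05, 0.5),
                      seed: int = 0, chrom: int = 1, spacing_bp: int = 10_000,
                      block_gap_bp: int = 1_000_000,
                      palindromic_fraction: float = 0.05) -> LDPanel:
    """Block-diagonal AR(1) LD panel.

    r between SNPs i, j of a block is rho^|i-j| and exactly 0 across
    blocks; block starts are ``block_gap_bp`` apart (> 500 kb) so
    distinct blocks never share a clumping window.
    """
    if n_blocks <= 0 or block_size <= 0:
        raise InputError("n_blocks and block_size must be positive")
    if not 0 <= rho < 1:
        raise InputError("rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise InputError("maf_range must be a sub-interval of (0, 0.5]")

    rng = np.random.default_rng(seed)
    m = n_blocks * block_size
    block = rho ** np.abs(np.subtract.outer(np.arange(block_size), np.arange(block_size)))
    r = np.zeros((m, m))
    for b in range(n_blocks):
        s = b * block_size
        r[s:s + block_size, s:s + block_size] = block

    pos = np.concatenate([
        b * block_gap_bp + 1 + spacing_bp * np.arange(block_size) for b in range(n_blocks)
    ])
    maf = rng.uniform(lo, hi, m)
    pal = rng.random(m) < palindromic_fraction
    pairs = [
        _PALINDROMIC[rng.integers(len(_PALINDROMIC))] if p
        else _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        for p in pal
    ]
    snps = pd.DataFrame({
        "snp": [f"rs{chrom}{i:05d}" for i in range(m)],
        "chr": chrom,
        "pos": pos.astype(int),
        "ea": [a for a, _ in pairs],
        "oa": [b for _, b in pairs],
        "maf": maf,
    })
    return LDPanel(snps, r)


def _corrupt_alleles(df: pd.DataFrame, rng: np.random.Generator,
                     swap_fraction: float, flip_fraction: float) -> pd.DataFrame:
    """Re-express a fraction of records for the other allele or strand.

    Swapped records report the other allele as effect allele (beta sign
    and eaf complemented); strand-flipped records report complemented
    alleles with unchanged orientation.  Harmonization must undo both.
    """
    from .summary_io import complement

    df = df.copy()
    u = rng.random(len(df))
    swap = u < swap_fraction
    flip = (u >= swap_fraction) & (u < swap_fraction + flip_fraction)
    ea, oa = df["ea"].copy(), df["oa"].copy()
    df.loc[swap, "ea"] = oa[swap]
    df.loc[swap, "oa"] = ea[swap]
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
    df.loc[flip, "ea"] = df.loc[flip, "ea"].map(complement)
    df.loc[flip, "oa"] = df.loc[flip, "oa"].map(complement)
    return df


def simulate_gwas_pair(panel: LDPanel, truth: SimTruth,
                       swap_fraction: float = 0.1, flip_fraction: float = 0.05,
                       exposure_label: str = "metabolite",
                       outcome_label: str = "outcome") -> Tuple[SummaryStats, SummaryStats]:
    """Exposure and outcome summary statistics with known ground truth.

    Marginal true effects are the LD-smeared causal effects R @ b; the
    outcome's marginal mean is theta * (R @ b) + R @ alpha.  Estimation
    noise is drawn with correlation R and per-SNP scale
    1/sqrt(2 f (1-f) n).  A seeded fraction of records is emitted with
    swapped or strand-flipped alleles to exercise harmonization.
    """
    m = len(panel)
    if len(truth.snp_effects) != m:
        raise InputError("truth dimensions do not match panel")
    rng = np.random.default_rng(truth.seed)
    f = panel.snps["maf"].to_numpy(float)
    het = 2.0 * f * (1.0 - f)
    se_exp = 1.0 / np.sqrt(het * truth.n_exp)
    se_out = 1.0 / np.sqrt(het * truth.n_out)

    b_marg = panel.r @ truth.snp_effects
    a_marg = panel.r @ truth.pleiotropy
    L = panel.cholesky()
    beta_exp = b_marg + se_exp * (L @ rng.standard_normal(m))
    beta_out = truth.theta * b_marg + a_marg + se_out * (L @ rng.standard_normal(m))

    def _table(beta, se):
        return pd.DataFrame({
            "snp": panel.snps["snp"], "chr": panel.snps["chr"], "pos": panel.snps["pos"],
            "ea": panel.snps["ea"], "oa": panel.snps["oa"], "eaf": f,
            "beta": beta, "se": se, "p": normal_p(beta, se),
        })

    exp_df = _table(beta_exp, se_exp).assign(n=truth.n_exp)
    out_df = _table(beta_out, se_out).assign(n=truth.n_out)
    exp_df = _corrupt_alleles(exp_df, rng, 0.0, 0.0)  # exposure kept panel-oriented
    out_df = _corrupt_alleles(out_df, rng, swap_fraction, flip_fraction)
    return (SummaryStats(exposure_label, exp_df), SummaryStats(outcome_label, out_df))


def simulate_cohort(n: int, intercept: float = 50.0, beta_metab: float = 1.0,
                    beta_bmi: float = -0.5, noise_sd: float = 2.0,
                    early_fraction: float = 0.0, seed: int = 0,
                    early_cutoff: float = 45.0,
                    bmi_missing_fraction: float = 0.2) -> pd.DataFrame:
    """Individual-level cohort with age-at-event linear in metabolite and BMI.

    age = intercept + beta_metab * metab + beta_bmi * BMI + eps.  A
    fraction ``early_fraction`` of subjects is drawn with age below
    ``early_cutoff`` (exercising the early-menopause exclusion); the
    remaining subjects are rejection-sampled onto age >= cutoff, so the
    cutoff exactly separates the two groups by construction.  Childhood
    BMI z-scores at ages 7/8/9/11 are emitted with seeded missingness
    to exercise adjacent-age imputation.
    """
    if n <= 0:
        raise InputError("n must be positive")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    if not 0 <= early_fraction <= 1:
        raise InputError("early_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_early = int(round(early_fraction * n))

    metab = rng.standard_normal(n)
    bmi = rng.standard_normal(n)
    age = intercept + beta_metab * metab + beta_bmi * bmi + noise_sd * rng.standard_normal(n)
    early = np.zeros(n, bool)
    early[rng.choice(n, size=n_early, replace=False)] = True
    age[early] = rng.uniform(early_cutoff - 10.0, early_cutoff - 1e-6, n_early)
    # resample late subjects that landed below the cutoff
    for _ in range(1000):
        bad = (~early) & (age < early_cutoff)
        if not bad.any():
            break
        k = int(bad.sum())
        metab[bad] = rng.standard_normal(k)
        bmi[bad] = rng.standard_normal(k)
        age[bad] = (intercept + beta_metab * metab[bad] + beta_bmi * bmi[bad]
                    + noise_sd * rng.standard_normal(k))
    else:  # pragma: no cover
        raise InputError("cannot place non-early subjects at or above the cutoff; "
                         "intercept too close to early_cutoff")

    base = 0.6 * bmi
    cols = {}
    for a in (7, 8, 9, 11):
        z = base + 0.3 * rng.standard_normal(n)
        miss = rng.random(n) < (bmi_missing_fraction if a == 8 else bmi_missing_fraction / 2)
        cols[f"bmi_z_age{a}"] = np.where(miss, np.nan, z)
    return pd.DataFrame({
        "metabolite": metab, "bmi": bmi, "age_at_event": age,
        "event": True, "early": early, **cols,
    })


# ---------------------------------------------------------------------------
# full synthetic study


@dataclass
class StudyData:
    """In-memory inputs of one synthetic MR study."""

    panel: LDPanel
    exposures: dict            # metabolite -> SummaryStats
    outcome: SummaryStats
    truths: dict               # metabolite -> SimTruth
    bmi: Optional[SummaryStats] = None
    cohort: Optional[pd.DataFrame] = None
    set_db: Optional[dict] = None        # set id -> list of metabolite labels
    causal: Sequence[str] = ()


def simulate_study(n_metabolites: int = 50, n_causal: int = 5, theta: float = 0.25,
                   n_exp: int = 24_925, n_out: int = 201_323,
                   instruments_range: Tuple[int, int] = (1, 5),
                   effect_range: Tuple[float, float] = (0.15, 0.40),
                   block_size: int = 5, rho: float = 0.9,
                   outcome_missing_fraction: float = 0.03,
                   pleiotropy_sd: float = 0.0,
                   with_bmi: bool = False, theta_bmi: float = 0.0,
                   n_outcome_loci: int = 20, outcome_locus_effect: float = 0.5,
                   seed: int = 0) -> StudyData:
    """A metabolome-wide study: many metabolites, one outcome, shared panel.

    Each metabolite owns 1-5 LD blocks (one causal SNP per block, the
    per-metabolite count drawn uniformly from ``instruments_range``);
    the first ``n_causal`` metabolites affect the outcome with effect
    ``theta`` years per SD, the rest are null.  Sample sizes default to
    the discovery scale of the emulated study (exposure n = 24,925;
    outcome n = 201,323).  A fraction of outcome records is withheld to
    exercise proxy substitution; annotation sets group causal
    metabolites into one class so enrichment has signal.
    """
    rng = np.random.default_rng(seed)
    k_inst = rng.integers(instruments_range[0], instruments_range[1] + 1, n_metabolites)
    n_blocks = int(k_inst.sum()) + (3 if with_bmi else 0) + n_outcome_loci
    panel = simulate_ld_panel(n_blocks, block_size, rho,
                              seed=int(rng.integers(2**31)))
    m = len(panel)

    labels = [f"metab_{i:03d}" for i in range(n_metabolites)]
    causal = labels[:n_causal]
    block_cursor = 0
    exposures, truths = {}, {}
    total_out_mean = np.zeros(m)
    f = panel.snps["maf"].to_numpy(float)
    het = 2.0 * f * (1.0 - f)

    per_metab_b = {}
    for i, lab in enumerate(labels):
        b = np.zeros(m)
        for _ in range(int(k_inst[i])):
            lead = block_cursor * block_size + block_size // 2
            sign = 1.0 if rng.random() < 0.5 else -1.0
            b[lead] = sign * rng.uniform(*effect_range)
            block_cursor += 1
        per_metab_b[lab] = b
        th = theta if lab in causal else 0.0
        alpha = (rng.normal(0.0, pleiotropy_sd, m) if pleiotropy_sd > 0 else np.zeros(m))
        truths[lab] = SimTruth(th, b, alpha, n_exp, n_out, seed=int(rng.integers(2**31)))
        total_out_mean += th * (panel.r @ b) + panel.r @ alpha

    bmi_stats = None
    if with_bmi:
        b_bmi = np.zeros(m)
        for j in range(3):
            lead = block_cursor * block_size + block_size // 2
            b_bmi[lead] = rng.uniform(*effect_range)
            block_cursor += 1
        total_out_mean += theta_bmi * (panel.r @ b_bmi)
        se_bmi = 1.0 / np.sqrt(het * 700_000)
        beta_bmi = panel.r @ b_bmi + se_bmi * (panel.cholesky() @ rng.standard_normal(m))
        bmi_stats = SummaryStats("bmi", pd.DataFrame({
            "snp": panel.snps["snp"], "chr": panel.snps["chr"], "pos": panel.snps["pos"],
            "ea": panel.snps["ea"], "oa": panel.snps["oa"], "eaf": f,
            "beta": beta_bmi, "se": se_bmi, "p": normal_p(beta_bmi, se_bmi), "n": 700_000,
        }))

    # the outcome's own genetic architecture: loci with direct effects on
    # the outcome and none on any metabolite, so reverse-MR instruments
    # are not confined to shared loci
    for _ in range(n_outcome_loci):
        lead = block_cursor * block_size + block_size // 2
        sign = 1.0 if rng.random() < 0.5 else -1.0
        own = np.zeros(m)
        own[lead] = sign * outcome_locus_effect
        total_out_mean += panel.r @ own
        block_cursor += 1

    L = panel.cholesky()
    for lab in labels:
        se_exp = 1.0 / np.sqrt(het * n_exp)
        beta_exp = panel.r @ per_metab_b[lab] + se_exp * (L @ rng.standard_normal(m))
        exposures[lab] = SummaryStats(lab, pd.DataFrame({
            "snp": panel.snps["snp"], "chr": panel.snps["chr"], "pos": panel.snps["pos"],
            "ea": panel.snps["ea"], "oa": panel.snps["oa"], "eaf": f,
            "beta": beta_exp, "se": se_exp, "p": normal_p(beta_exp, se_exp), "n": n_exp,
        }))

    se_out = 1.0 / np.sqrt(het * n_out)
    beta_out = total_out_mean + se_out * (L @ rng.standard_normal(m))
    out_df = pd.DataFrame({
        "snp": panel.snps["snp"], "chr": panel.snps["chr"], "pos": panel.snps["pos"],
        "ea": panel.snps["ea"], "oa": panel.snps["oa"], "eaf": f,
        "beta": beta_out, "se": se_out, "p": normal_p(beta_out, se_out), "n": n_out,
    })
    out_df = _corrupt_alleles(out_df, rng, 0.1, 0.05)
    keep = rng.random(m) >= outcome_missing_fraction
    outcome = SummaryStats("outcome", out_df.loc[keep])

    # annotation: causal metabolites share one class, nulls spread over others
    set_db = {"class_causal": list(causal)}
    for j, lab in enumerate(labels[n_causal:]):
        set_db.setdefault(f"class_{j % 5}", []).append(lab)

    cohort = simulate_cohort(n=2000, intercept=51.0, beta_metab=theta * 4, beta_bmi=-0.5,
                             noise_sd=4.0, early_fraction=0.15,
                             seed=int(rng.integers(2**31)))
    return StudyData(panel=panel, exposures=exposures, outcome=outcome, truths=truths,
                     bmi=bmi_stats, cohort=cohort, set_db=set_db, causal=causal)
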