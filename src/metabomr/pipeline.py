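"""Study orchestration: the full funnel from summary statistics to tables.

Stages mirror the study design: per-metabolite instrument selection ->
harmonization with proxy substitution -> MR estimation -> FDR
prioritization -> sensitivity diagnostics (FDR-passing metabolites with
multiple instruments) -> multivariable BMI adjustment (>= 3
instruments) -> colocalization of FDR-passing metabolites' instrument
regions -> per-metabolite colocalization verdict -> reverse MR for
colocalized metabolites -> over-representation analysis -> cohort
validation.  Each stage is an importable function consuming the
previous stage's products; :func:`run_pipeline` composes them and
conserves the funnel bookkeeping in the run manifest (tested =
prioritized + non-prioritized; prioritized = colocalized +
non-colocalized + coloc-skipped).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from .enrichment import MetaboliteSetDB, hypergeom_ora, linear_validation
from .errors import EmptyHarmonizationError, InputError
from .estimators import MRResult, egger, fdr_adjust, ivw, mvmr_ivw
from .instruments import InstrumentSet, build_instruments, filter_weak
from .sensitivity import cochran_q, presso, reverse_mr, steiger_filter
from .summary_io import HarmonizedSet, harmonize_with_proxies, read_summary_stats
from .synthetic import LDPanel, StudyData, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Every numeric choice of the study in one place (defaults as published)."""

    p_iv: float = 5e-8
    clump_r2: float = 0.001
    window_kb: float = 500.0
    proxy_r2: float = 0.8
    f_min: float = 10.0
    fdr: float = 0.05
    h4: float = 0.8
    maf_min: float = 0.01
    early_cutoff: float = 45.0
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_half_width: int = 500_000
    presso_n_sim: int = 1000
    n_boot: int = 200
    seed: int = 0
    sensitivity_all: bool = False     # run sensitivity on every metabolite, not just FDR-passing
    exposure_paths: Dict[str, str] = field(default_factory=dict)
    exposure_dialect: Dict[str, str] = field(default_factory=dict)
    outcome_path: Optional[str] = None
    panel_meta_path: Optional[str] = None
    panel_r_path: Optional[str] = None
    bmi_path: Optional[str] = None
    cohort_path: Optional[str] = None
    set_db_path: Optional[str] = None
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.p_iv < 1 and 0 <= self.clump_r2 <= 1 and 0 < self.fdr < 1
                and 0 < self.h4 < 1 and 0 <= self.maf_min < 0.5):
            raise InputError("threshold outside its documented range")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All output tables of one run plus the manifest."""

    instruments: pd.DataFrame
    mr: pd.DataFrame
    sensitivity: pd.DataFrame
    mvmr: pd.DataFrame
    coloc: pd.DataFrame
    reverse: pd.DataFrame
    ora: pd.DataFrame
    validation: pd.DataFrame
    manifest: Dict[str, object]

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "instruments": self.instruments, "mr": self.mr,
            "sensitivity": self.sensitivity, "mvmr": self.mvmr,
            "coloc": self.coloc, "reverse_mr": self.reverse,
            "ora": self.ora, "validation": self.validation,
        }


def _result_row(res: MRResult) -> dict:
    return {
        "metabolite": res.exposure, "outcome": res.outcome, "method": res.method,
        "estimate": res.estimate, "se": res.se, "ci_low": res.ci_low,
        "ci_high": res.ci_high, "p": res.p, "nsnp": res.nsnp,
        "egger_intercept": res.intercept, "egger_intercept_p": res.intercept_p,
        "q": res.q, "q_p": res.q_p, "fdr_q": res.fdr_q,
        "status": res.status, "note": res.note,
    }


def load_study_data(config: StudyConfig) -> StudyData:
    """Read the study inputs named by the config from disk."""
    panel = LDPanel.from_tsv(config.panel_meta_path, config.panel_r_path)
    exposures = {
        name: read_summary_stats(path, dialect=config.exposure_dialect or None, trait=name)
        for name, path in sorted(config.exposure_paths.items())
    }
    outcome = read_summary_stats(config.outcome_path, trait="outcome")
    bmi = read_summary_stats(config.bmi_path, trait="bmi") if config.bmi_path else None
    cohort = pd.read_csv(config.cohort_path, sep="\t") if config.cohort_path else None
    set_db = (MetaboliteSetDB.from_tsv(config.set_db_path).sets
              if config.set_db_path else None)
    return StudyData(panel=panel, exposures=exposures, outcome=outcome, truths={},
                     bmi=bmi, cohort=cohort, set_db=set_db)


# ---------------------------------------------------------------------------
# stages


def stage_instruments(data: StudyData, config: StudyConfig
                      ) -> Tuple[List[InstrumentSet], pd.DataFrame, Dict[str, int]]:
    """Select, clump and strength-filter instruments for every exposure."""
    inst_sets = []
    for name in sorted(data.exposures):
        s = build_instruments(data.exposures[name], data.panel,
                              config.p_iv, config.clump_r2, config.window_kb)
        if s is not None:
            inst_sets.append(s)
    strong = filter_weak(inst_sets, config.f_min)
    counts = {"exposures_in": len(data.exposures),
              "with_instruments": len(inst_sets),
              "strong_instruments": len(strong)}
    rows = []
    for s in strong:
        for rec in s.table.itertuples(index=False):
            rows.append({"metabolite": s.metabolite, "snp": rec.snp, "ea": rec.ea,
                         "oa": rec.oa, "eaf": rec.eaf, "beta": rec.beta, "se": rec.se,
                         "p": rec.p, "r2": rec.r2, "F": s.f_stat, "k": s.k, "n": s.n})
    return strong, pd.DataFrame(rows), counts


def stage_mr(data: StudyData, config: StudyConfig, strong: List[InstrumentSet]
             ) -> Tuple[pd.DataFrame, Dict[str, HarmonizedSet], List[str]]:
    """Harmonize (with proxies), estimate per metabolite, FDR-prioritize."""
    mr_rows, hsets = [], {}
    for s in strong:
        exp_sub = data.exposures[s.metabolite].subset(s.snps())
        try:
            hset = harmonize_with_proxies(exp_sub, data.outcome, data.panel,
                                          r2_min=config.proxy_r2)
        except EmptyHarmonizationError:
            logger.info("pipeline: %s has no harmonizable instruments", s.metabolite)
            continue
        hsets[s.metabolite] = hset
        mr_rows.append(_result_row(ivw(hset)))
    mr_table = pd.DataFrame(mr_rows)
    prioritized: List[str] = []
    if not mr_table.empty:
        ok = mr_table["status"] == "ok"
        mr_table.loc[ok, "fdr_q"] = fdr_adjust(mr_table.loc[ok, "p"])
        prioritized = list(mr_table.loc[ok & (mr_table["fdr_q"] <= config.fdr),
                                        "metabolite"])
    return mr_table, hsets, prioritized


def stage_sensitivity(config: StudyConfig, hsets: Dict[str, HarmonizedSet],
                      targets: List[str], seed: int) -> pd.DataFrame:
    """Cochran Q, Egger intercept, PRESSO and Steiger for the target metabolites."""
    rng = np.random.default_rng(seed)
    rows = []
    for name in targets:
        hset = hsets[name]
        k = len(hset)
        row = {"metabolite": name, "nsnp": k, "q": np.nan, "q_p": np.nan,
               "egger_intercept": np.nan, "egger_intercept_p": np.nan,
               "presso_global_p": np.nan, "presso_outliers": "",
               "steiger_verdict": None}
        if k >= 2:
            fit = ivw(hset)
            row["q"], _, row["q_p"] = cochran_q(hset, fit)
        if k >= 3:
            eg = egger(hset)
            if eg.status == "ok":
                row["egger_intercept"] = eg.intercept
                row["egger_intercept_p"] = eg.intercept_p
        if k >= 4:
            pr = presso(hset, n_sim=config.presso_n_sim, seed=int(rng.integers(2**31)))
            if pr.status == "ok":
                row["presso_global_p"] = pr.global_p
                row["presso_outliers"] = ",".join(hset.df["snp"].iloc[pr.outlier_indices])
        st = steiger_filter(hset)
        row["steiger_verdict"] = bool(st["direction"].all())
        rows.append(row)
    return pd.DataFrame(rows)


def stage_mvmr(data: StudyData, hsets: Dict[str, HarmonizedSet],
               prioritized: List[str]) -> pd.DataFrame:
    """Conditional metabolite + BMI effects for metabolites with >= 3 IVs."""
    rows = []
    if data.bmi is None:
        return pd.DataFrame(rows)
    for name in prioritized:
        hset = hsets[name]
        if len(hset) < 3:
            continue
        bmi_sub = data.bmi.subset(list(hset.df["snp"]))
        merged = hset.df.merge(bmi_sub.df[["snp", "ea", "beta"]], on="snp",
                               suffixes=("", "_bmi"))
        if merged.empty:
            continue
        flip = merged["ea_bmi"] != merged["ea"]
        bmi_beta = np.where(flip, -merged["beta"], merged["beta"])
        res = mvmr_ivw(np.column_stack([merged["beta_exp"], bmi_beta]),
                       merged["beta_out"].to_numpy(float),
                       merged["se_out"].to_numpy(float),
                       [name, "bmi"], data.outcome.trait)
        for r in res.as_results():
            rows.append(_result_row(r))
    return pd.DataFrame(rows)


def stage_coloc(data: StudyData, config: StudyConfig,
                hsets: Dict[str, HarmonizedSet], prioritized: List[str]
                ) -> Tuple[pd.DataFrame, Dict[str, dict], List[str]]:
    """Per-instrument-region colocalization and the per-metabolite verdict."""
    rows, verdicts = [], {}
    for name in prioritized:
        results = []
        for lead in hsets[name].df["snp"]:
            pair = coloc_mod.extract_region(data.exposures[name], data.outcome, lead,
                                            half_width=config.coloc_half_width,
                                            maf_min=config.maf_min)
            if pair is None:
                logger.info("coloc: region around %s (%s) skipped", lead, name)
                continue
            res = coloc_mod.coloc_abf(pair[0], pair[1], config.coloc_p1,
                                      config.coloc_p2, config.coloc_p12)
            results.append(res)
            rows.append({"metabolite": name, "lead_snp": res.region,
                         "nsnps": res.nsnps,
                         **{f"pp{i}": res.pp[i] for i in range(5)}})
        verdicts[name] = coloc_mod.verdict(results, config.h4)
    table = pd.DataFrame(rows)
    if not table.empty:
        table["colocalized"] = table["metabolite"].map(
            lambda m: verdicts[m]["colocalized"])
    colocalized = [m for m, v in verdicts.items() if v["colocalized"]]
    return table, verdicts, colocalized


def stage_reverse(data: StudyData, config: StudyConfig, colocalized: List[str],
                  seed: int) -> pd.DataFrame:
    """Bidirectional MR: outcome as exposure against each colocalized metabolite."""
    rng = np.random.default_rng(seed)
    rows = []
    for name in colocalized:
        res = reverse_mr(data.outcome, data.exposures[name], data.panel,
                         p_threshold=config.p_iv, n_boot=config.n_boot,
                         seed=int(rng.integers(2**31)))
        for method, r in res.items():
            row = _result_row(r)
            row["metabolite"] = name    # table keyed by the metabolite being explained
            rows.append(row)
    return pd.DataFrame(rows)


def stage_ora(data: StudyData, colocalized: List[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of colocalized metabolites."""
    if not data.set_db or not colocalized:
        return pd.DataFrame()
    db = MetaboliteSetDB(data.set_db)
    universe = db.universe(list(data.exposures))
    return hypergeom_ora(colocalized, db, universe)


def stage_validation(data: StudyData, config: StudyConfig) -> pd.DataFrame:
    """Observational cohort models: +/- BMI adjustment, +/- early exclusion."""
    rows = []
    if data.cohort is None:
        return pd.DataFrame(rows)
    for adjusted in (False, True):
        for excl in (False, True):
            covs = ["bmi"] if adjusted else []
            try:
                r = linear_validation(data.cohort, covariates=covs,
                                      exclude_early=excl,
                                      early_cutoff=config.early_cutoff)
            except Exception as exc:  # degenerate cohorts logged, not fatal
                logger.info("validation model skipped: %s", exc)
                continue
            rows.append({"metabolite": "metabolite", "model": "ols",
                         "adjusted_bmi": adjusted, "exclude_early": excl, **r})
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig, data: Optional[StudyData] = None) -> ResultBundle:
    """Run the full study funnel and return every table plus the manifest."""
    if data is None:
        data = load_study_data(config)

    strong, inst_table, counts = stage_instruments(data, config)
    mr_table, hsets, prioritized = stage_mr(data, config, strong)
    counts["mr_tested"] = len(mr_table)
    counts["prioritized"] = len(prioritized)
    counts["non_prioritized"] = counts["mr_tested"] - len(prioritized)

    sens_targets = (sorted(hsets) if config.sensitivity_all else prioritized)
    sens_table = stage_sensitivity(config, hsets, sens_targets, seed=config.seed + 1)
    counts["sensitivity_run"] = len(sens_table)

    mvmr_table = stage_mvmr(data, hsets, prioritized)
    coloc_table, verdicts, colocalized = stage_coloc(data, config, hsets, prioritized)
    counts["coloc_tested"] = len(verdicts)
    counts["colocalized"] = len(colocalized)
    counts["non_colocalized"] = sum(
        1 for v in verdicts.values() if not v["colocalized"] and v["n_regions"] > 0)
    counts["coloc_skipped"] = sum(1 for v in verdicts.values() if v["n_regions"] == 0)

    rev_table = stage_reverse(data, config, colocalized, seed=config.seed + 2)
    ora_table = stage_ora(data, colocalized)
    counts["ora_sets"] = len(ora_table)
    val_table = stage_validation(data, config)

    manifest = {
        "config_digest": config.digest(), "seed": config.seed, "counts": counts,
        "prioritized": prioritized, "colocalized": colocalized,
    }
    return ResultBundle(inst_table, mr_table, sens_table, mvmr_table, coloc_table,
                        rev_table, ora_table, val_table, manifest)


def write_results(bundle: ResultBundle, outdir) -> Dict[str, str]:
    """One TSV per table plus a JSON manifest; round-trips bit-exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_files = {}
    for name, table in bundle.tables().items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest_files[name] = str(path)
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump({**bundle.manifest, "files": manifest_files}, fh, indent=2, default=str)
    manifest_files["manifest"] = str(mpath)
    return manifest_files


def simulate_and_run(seed: int = 0, config: Optional[StudyConfig] = None,
                     **study_kwargs) -> ResultBundle:
    """Convenience driver: synthetic study + full pipeline at one seed."""
    config = config or StudyConfig(seed=seed)
    data = simulate_study(seed=seed, **study_kwargs)
    return run_pipeline(config, data)
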