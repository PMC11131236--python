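"""Metabolite-set over-representation analysis and cohort validation models.

The follow-up stage of the study asks two questions about the
MR-prioritized, colocalized metabolites: do they cluster in annotated
metabolite classes more than chance would allow (one-tailed
hypergeometric test per set, BH-FDR across sets), and do directly
measured levels of the same metabolites associate with age at
menarche/menopause in an independent cohort (ordinary least squares
with optional childhood/adult BMI covariates, z-scored predictors,
adjacent-age BMI imputation, and exclusion of early menopause before
age 45)?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, FormatError, InputError
from .estimators import fdr_adjust


@dataclass
class MetaboliteSetDB:
    """Local annotation table: set id -> member metabolite identifiers."""

    sets: Dict[str, List[str]]
    names: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {sid: sorted(set(members)) for sid, members in self.sets.items()}

    def universe(self, extra: Sequence[str] = ()) -> List[str]:
        u = set(extra)
        for members in self.sets.values():
            u.update(members)
        return sorted(u)

    @classmethod
    def from_tsv(cls, members_path, names_path=None) -> "MetaboliteSetDB":
        df = pd.read_csv(members_path, sep="\t", dtype=str)
        if not {"set_id", "metabolite_id"} <= set(df.columns):
            raise FormatError("set table needs columns set_id, metabolite_id")
        sets: Dict[str, List[str]] = {}
        for sid, grp in df.groupby("set_id"):
            sets[sid] = list(grp["metabolite_id"])
        names = {}
        if names_path is not None:
            nd = pd.read_csv(names_path, sep="\t", dtype=str)
            names = dict(zip(nd["set_id"], nd["name"]))
        return cls(sets, names)

    def to_tsv(self, members_path, names_path=None) -> None:
        rows = [(sid, m) for sid, members in self.sets.items() for m in members]
        pd.DataFrame(rows, columns=["set_id", "metabolite_id"]).to_csv(
            members_path, sep="\t", index=False)
        if names_path is not None:
            pd.DataFrame(sorted(self.names.items()), columns=["set_id", "name"]).to_csv(
                names_path, sep="\t", index=False)


def hypergeom_ora(selected: Sequence[str], db: MetaboliteSetDB,
                  universe: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation per annotated set.

    With N metabolites in the universe, K in the set, n selected and k
    in the overlap, p = P(X >= k) for X ~ Hypergeometric(N, K, n); BH
    FDR is applied across sets.  Empty selection yields an empty table.
    """
    selected = sorted(set(selected))
    if not selected:
        return pd.DataFrame(columns=["set_id", "name", "k", "K", "n", "N", "p", "fdr_q"])
    universe = sorted(set(universe)) if universe is not None else db.universe(selected)
    if not set(selected) <= set(universe):
        raise InputError("selected metabolites must be contained in the universe")
    N, n = len(universe), len(selected)
    uset = set(universe)
    rows = []
    for sid, members in sorted(db.sets.items()):
        K = len(set(members) & uset)
        k = len(set(members) & set(selected))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_id": sid, "name": db.names.get(sid, sid),
                     "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr_q"] = fdr_adjust(out["p"])
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def zscore(values, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, SD 1 over non-missing entries (sample SD).

    Missing values are propagated; a constant vector (zero SD) raises.
    """
    x = np.asarray(values, float)
    obs = x[np.isfinite(x)]
    if obs.size < 2:
        raise DegenerateInputError("zscore needs >= 2 non-missing values")
    sd = np.std(obs, ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("zscore undefined for a constant vector")
    return (x - obs.mean()) / sd


def impute_adjacent(frame: pd.DataFrame, target: str = "bmi_z_age8",
                    fallbacks: Sequence[str] = ("bmi_z_age7", "bmi_z_age9")) -> pd.Series:
    """Fill missing age-8 BMI z-scores from age 7 (first) or age 9.

    Subjects missing all three remain missing (and are dropped from
    BMI-adjusted models by the complete-case regression).
    """
    for col in (target, *fallbacks):
        if col not in frame.columns:
            raise InputError(f"column {col!r} absent from cohort")
    out = frame[target].copy()
    for col in fallbacks:
        out = out.fillna(frame[col])
    return out


def linear_validation(cohort: pd.DataFrame, metabolite: str = "metabolite",
                      outcome: str = "age_at_event",
                      covariates: Sequence[str] = (),
                      exclude_early: bool = False,
                      early_cutoff: float = 45.0) -> Dict[str, float]:
    """OLS of the outcome age on a metabolite with optional covariates.

    Complete-case analysis; with ``exclude_early`` subjects whose
    outcome is below ``early_cutoff`` years are removed first (the
    early-menopause exclusion).  Returns the metabolite slope in years
    per unit, its SE, p, and the analysis n.
    """
    cols = [outcome, metabolite, *covariates]
    data = cohort[cols].dropna()
    if exclude_early:
        data = data[data[outcome] >= early_cutoff]
    if len(data) < len(covariates) + 3:
        raise DegenerateInputError("too few complete cases for the model")
    X = sm.add_constant(data[[metabolite, *covariates]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DegenerateInputError("rank-deficient design matrix")
    fit = sm.OLS(data[outcome], X).fit()
    return {
        "beta": float(fit.params[metabolite]), "se": float(fit.bse[metabolite]),
        "p": float(fit.pvalues[metabolite]), "n": int(fit.nobs),
    }
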