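"""Phenotype and covariate preparation for the family analysis.

Covers the derived variables and filters applied before model fitting:

* the urinary iodine / creatinine ratio (UICR, ug iodine per g creatinine),
  computed as ``ui / ucr * 100`` and entered into models log-transformed;
* the exclusion cascade (overt thyroid dysfunction, prior treatment,
  pregnancy, TPOAb positivity at >= 34.0 IU/mL, missing measurements, and
  families reduced below two phenotyped members), with a stricter
  *euthyroid* mode restricted to subjects free of any thyroid-disease
  history whose TSH and fT4 fall inside the population reference intervals;
* rank-based inverse normal transformation of the traits (Blom offset,
  average ranks for ties);
* forward/backward stepwise screening of fixed-effect covariates inside the
  polygenic model, using likelihood-ratio p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree
from .univariate_vc import VCModelSpec, chi2_pvalue, fit_vc

__all__ = [
    "TSH_REFERENCE",
    "FT4_REFERENCE",
    "TPOAB_POSITIVE",
    "CovariateModel",
    "compute_uicr",
    "apply_exclusions",
    "inverse_normal_transform",
    "screen_covariates",
    "BASIC_CANDIDATES",
    "EXTENDED_CANDIDATES",
]

TSH_REFERENCE = (0.62, 6.86)  # mIU/L, population reference interval
FT4_REFERENCE = (0.89, 1.76)  # ng/dL
TPOAB_POSITIVE = 34.0  # IU/mL; at or above counts as antibody-positive

#: Candidate fixed-effect sets for the stepwise screen. ``age2`` is the
#: squared (centred) age; ``log_uicr`` the log iodine/creatinine ratio.
BASIC_CANDIDATES = ("age", "age2", "sex")
EXTENDED_CANDIDATES = ("age", "sex", "bmi", "smoking", "log_uicr", "menopause")


def compute_uicr(ui, ucr):
    """Urinary iodine (ug/L) over creatinine (mg/dL) times 100.

    Gives iodine in ug per g creatinine. Non-positive or missing creatinine
    yields a missing value (NaN), never zero.
    """
    ui = np.asarray(ui, dtype=float)
    ucr = np.asarray(ucr, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ucr > 0, ui / ucr * 100.0, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def inverse_normal_transform(values, c: float = 0.375):
    """Rank-based inverse normal transformation (Blom offset by default).

    Non-missing entries are replaced by ``Phi^-1((r - c) / (n - 2c + 1))``
    where ``r`` is the average rank among non-missing values. Missing
    entries stay missing. The transform is monotone: it preserves the rank
    order of the input, mapping ties to equal values.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("inverse normal transform of an all-missing vector")
    if n < 2:
        raise ValueError("need at least two non-missing values")
    ranks = stats.rankdata(values[ok], method="average")
    out = np.full(values.shape, np.nan)
    out[ok] = stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))
    return out


_MAIN_RULES = (
    "overt_dysfunction",
    "prior_treatment",
    "pregnant",
    "tpoab_positive",
    "missing_measurement",
    "family_lt_2",
)
_EUTHYROID_RULES = (
    "thyroid_history",
    "tsh_out_of_range",
    "ft4_out_of_range",
    "missing_covariate",
    "family_lt_2_euthyroid",
)

_EUTHYROID_COVARIATES = ("age", "bmi", "ui", "ucr")


def _flag(table: pd.DataFrame, col: str) -> pd.Series:
    if col in table.columns:
        return table[col].fillna(False).astype(bool)
    return pd.Series(False, index=table.index)


def apply_exclusions(
    table: pd.DataFrame, mode: str = "main"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the subject-selection cascade; returns (filtered, tally).

    ``main`` removes subjects with overt thyroid dysfunction, prior
    treatment for thyroid disease, pregnancy, TPOAb >= 34.0 IU/mL, or a
    missing TSH/fT4/urinary-iodine measurement, then drops families left
    with fewer than two members. ``euthyroid`` additionally removes any
    prior or family history of thyroid disease, TSH outside [0.62, 6.86]
    mIU/L or fT4 outside [0.89, 1.76] ng/dL (closed intervals: boundary
    values are retained), and rows with missing model covariates.

    The tally maps each rule, in application order, to the number of rows
    it removed; applying the same mode twice removes nothing further.
    """
    if mode not in ("main", "euthyroid"):
        raise ValueError(f"unknown exclusion mode {mode!r}")
    df = table.copy()
    tally: dict[str, int] = {}

    def drop(rule: str, mask: pd.Series):
        nonlocal df
        mask = mask.reindex(df.index).fillna(False).astype(bool)
        tally[rule] = int(mask.sum())
        df = df.loc[~mask]

    drop("overt_dysfunction", _flag(df, "overt_dysfunction"))
    drop("prior_treatment", _flag(df, "prior_treatment"))
    drop("pregnant", _flag(df, "pregnant"))
    if "tpoab" in df.columns:
        drop("tpoab_positive", df["tpoab"] >= TPOAB_POSITIVE)
    else:
        tally["tpoab_positive"] = 0
    missing = df[["tsh", "ft4", "ui"]].isna().any(axis=1)
    drop("missing_measurement", missing)
    drop("family_lt_2", _small_families(df))

    if mode == "euthyroid":
        hist = _flag(df, "thyroid_history") | _flag(df, "family_history")
        drop("thyroid_history", hist)
        lo, hi = TSH_REFERENCE
        drop("tsh_out_of_range", (df["tsh"] < lo) | (df["tsh"] > hi))
        lo, hi = FT4_REFERENCE
        drop("ft4_out_of_range", (df["ft4"] < lo) | (df["ft4"] > hi))
        covs = [c for c in _EUTHYROID_COVARIATES if c in df.columns]
        drop("missing_covariate", df[covs].isna().any(axis=1) if covs else pd.Series(False, index=df.index))
        drop("family_lt_2_euthyroid", _small_families(df))
    return df, tally


def _small_families(df: pd.DataFrame) -> pd.Series:
    sizes = df.groupby("family_id")["family_id"].transform("size")
    return sizes < 2


@dataclass
class CovariateModel:
    """Outcome of the stepwise fixed-effect screen."""

    selected: list[str]
    coefficients: dict[str, float]
    screening_log: list[dict] = field(default_factory=list)

    def design(self, table: pd.DataFrame) -> np.ndarray:
        """Intercept plus the selected covariate columns of ``table``."""
        cols = [np.ones(len(table))]
        cols += [table[name].to_numpy(dtype=float) for name in self.selected]
        return np.column_stack(cols)


def screen_covariates(
    y: np.ndarray,
    candidates: pd.DataFrame,
    ped: Pedigree,
    p_enter: float = 0.10,
    p_remove: float = 0.10,
    components: tuple[str, ...] = ("A", "E"),
    max_iter: int = 20,
) -> CovariateModel:
    """Forward/backward stepwise covariate selection inside the polygenic
    model.

    At each forward step the candidate whose addition gives the smallest
    likelihood-ratio p-value is entered if that p-value is below
    ``p_enter``; at each backward step any entered covariate whose removal
    p-value exceeds ``p_remove`` is dropped (worst first). Iterates to a
    fixpoint. Complete-case: rows missing the trait or any candidate are
    excluded throughout, so all inner fits use the same rows.

    Candidates whose inner fit fails to converge are skipped for that step
    and recorded in the log.
    """
    import warnings

    y = np.asarray(y, dtype=float)
    cand_names = list(candidates.columns)
    cmat = candidates.to_numpy(dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(cmat), axis=1)
    y_work = np.where(keep, y, np.nan)  # fit_vc drops NaN rows

    spec = VCModelSpec(components=components)

    def fit_with(names: list[str], starts: int = 1):
        X = np.column_stack(
            [np.ones(y.size)] + [cmat[:, cand_names.index(n)] for n in names]
        )
        X = np.where(keep[:, None], X, np.nan)
        return fit_vc(spec, y_work, X, ped, n_starts=starts)

    selected: list[str] = []
    log: list[dict] = []
    current = fit_with(selected)
    for _ in range(max_iter):
        changed = False
        # forward
        best_name, best_fit, best_p = None, None, np.inf
        for name in cand_names:
            if name in selected:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trial = fit_with(selected + [name])
            if not trial.converged:
                log.append({"step": "forward", "candidate": name, "skipped": True})
                continue
            p = chi2_pvalue(max(0.0, 2 * (trial.loglik - current.loglik)), 1)
            log.append({"step": "forward", "candidate": name, "p": p})
            if p < best_p:
                best_name, best_fit, best_p = name, trial, p
        if best_name is not None and best_p < p_enter:
            selected.append(best_name)
            current = best_fit
            log.append({"step": "enter", "candidate": best_name, "p": best_p})
            changed = True
        # backward
        while selected:
            worst_name, worst_p = None, -np.inf
            for name in selected:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    trial = fit_with([n for n in selected if n != name])
                p = chi2_pvalue(max(0.0, 2 * (current.loglik - trial.loglik)), 1)
                if p > worst_p:
                    worst_name, worst_p = name, p
            if worst_p > p_remove:
                selected.remove(worst_name)
                current = fit_with(selected)
                log.append({"step": "remove", "candidate": worst_name, "p": worst_p})
                changed = True
            else:
                break
        if not changed:
            break
    final = fit_with(selected, starts=3)
    names = ["intercept"] + selected
    coefs = dict(zip(names, final.beta)) if final.beta is not None else {}
    return CovariateModel(selected=selected, coefficients=coefs, screening_log=log)
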