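"""Proteome-wide covariate-adjusted association scan.

For each aptamer on the panel, fits ordinary least squares of MWF on the
log2-transformed protein abundance, adjusting for age at protein
measurement, age^2, sex, and eGFR, and records the protein coefficient,
its standard error, t statistic and two-sided p-value — the volcano-plot
table.  Hit lists are the genes whose aptamers reach unadjusted p below
the significance level, split by the sign of the coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import (
    EmptyJoinError,
    InputError,
    InsufficientDataError,
    ParameterError,
    SingularDesignError,
)

logger = logging.getLogger(__name__)

# relative tolerance below which the residual variance is treated as an
# exact fit (zero-noise data): SE -> 0, p -> 0 for nonzero coefficients
_EXACT_FIT_RTOL = 1e-20


@dataclass
class OLSFit:
    """Coefficients, standard errors and t-test p-values of one OLS fit."""

    params: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_values: np.ndarray
    df_resid: int
    rss: float
    n: int


def fit_ols(y, X, column_names: Optional[Sequence[str]] = None) -> OLSFit:
    """Ordinary least squares with classical t-based inference.

    Parameters
    ----------
    y : 1-D response vector.
    X : 2-D design matrix including the intercept column.
    column_names : optional names used in error messages.

    SEs use the unbiased residual variance (df = n - k); p-values are
    two-sided from the t distribution.  A rank-deficient design raises
    :class:`SingularDesignError` naming the offending columns; n <= k
    raises :class:`InsufficientDataError`.  When the residual variance is
    numerically zero (an exact fit), SEs are 0 and p is 0 for nonzero
    coefficients, 1 otherwise.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("design matrix must be 2-D")
    n, k = X.shape
    if n != len(y):
        raise InputError(f"len(y)={len(y)} does not match rows(X)={n}")
    names = list(column_names) if column_names is not None else [f"x{j}" for j in range(k)]
    if len(names) != k:
        raise InputError("column_names length does not match design width")
    if n <= k:
        raise InsufficientDataError(f"n={n} observations for k={k} parameters")

    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    rdiag = np.abs(np.diag(R))
    tol = rdiag.max() * max(n, k) * np.finfo(float).eps if rdiag.max() > 0 else 0.0
    rank = int((rdiag > tol).sum())
    if rank < k:
        offending = [names[piv[j]] for j in range(rank, k)]
        raise SingularDesignError(offending)

    beta_piv = linalg.solve_triangular(R, Q.T @ y)
    beta = np.empty(k)
    beta[piv] = beta_piv
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    s2 = rss / df

    Rinv = linalg.solve_triangular(R, np.eye(k))
    cov_unscaled_piv = Rinv @ Rinv.T  # (X'X)^-1 in pivoted order
    diag_unscaled = np.empty(k)
    diag_unscaled[piv] = np.diag(cov_unscaled_piv)

    scale = float(np.mean(y * y)) if n else 1.0
    if s2 <= _EXACT_FIT_RTOL * max(1.0, scale):
        se = np.zeros(k)
        nonzero = np.abs(beta) > np.sqrt(tol if tol > 0 else np.finfo(float).eps)
        t_stat = np.zeros(k)
        t_stat[nonzero] = np.sign(beta[nonzero]) * np.inf
        p = np.where(nonzero, 0.0, 1.0)
    else:
        se = np.sqrt(s2 * diag_unscaled)
        t_stat = beta / se
        p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    return OLSFit(params=beta, se=se, t_stat=t_stat, p_values=p, df_resid=df, rss=rss, n=n)


def _mwf_column(cohort: pd.DataFrame, mwf_field: str) -> str:
    if mwf_field == "global":
        return "mwf_global"
    if mwf_field.startswith("region:"):
        col = f"mwf_region_{mwf_field.split(':', 1)[1]}"
        if col not in cohort.columns:
            raise InputError(f"cohort has no column {col}")
        return col
    raise ParameterError(f"mwf_field must be 'global' or 'region:<id>', got {mwf_field!r}")


_DESIGN_NAMES = ["intercept", "log2_abundance", "age", "age_sq", "sex", "egfr"]


def run_scan(
    cohort: pd.DataFrame,
    proteins: pd.DataFrame,
    mwf_field: str = "global",
    alpha: float = 0.05,
    swap_direction: bool = False,
) -> pd.DataFrame:
    """Fit the adjusted association model for every aptamer.

    Model: MWF ~ intercept + log2(abundance) + age + age^2 + sex + eGFR,
    with age taken at protein measurement.  ``swap_direction=True``
    instead fits log2(abundance) as the response with MWF as the
    predictor; t and p of the shared term are identical, only the beta
    scale changes.  Subjects with missing values are dropped per protein
    (complete-case); a per-protein singular or under-determined design
    yields a null record rather than aborting the scan.

    Returns a DataFrame with columns aptamer_id, gene_symbol, beta, se,
    t_stat, p_value, q_bh, n_used, direction.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if len(proteins) == 0:
        raise InputError("protein matrix is empty")
    meta_cols = {"aptamer_id", "gene_symbol"}
    subject_cols = [c for c in proteins.columns if c not in meta_cols]
    shared = [s for s in cohort["subject_id"] if s in set(subject_cols)]
    if not shared:
        raise EmptyJoinError("no overlapping subjects between cohort and protein matrix")

    coh = cohort.set_index("subject_id").loc[shared]
    mwf = coh[_mwf_column(coh.reset_index(), mwf_field)].to_numpy(dtype=float)
    age = coh["age_protein"].to_numpy(dtype=float)
    sex = coh["sex"].to_numpy(dtype=float)
    egfr = coh["egfr"].to_numpy(dtype=float)
    covars = np.column_stack([age, age**2, sex, egfr])
    cov_ok = np.isfinite(covars).all(axis=1) & np.isfinite(mwf)

    abund = proteins[shared].to_numpy(dtype=float)
    records = []
    for i in range(len(proteins)):
        x = abund[i]
        ok = cov_ok & np.isfinite(x) & (x > 0)
        n_used = int(ok.sum())
        rec = {
            "aptamer_id": proteins["aptamer_id"].iat[i],
            "gene_symbol": proteins["gene_symbol"].iat[i],
            "beta": np.nan,
            "se": np.nan,
            "t_stat": np.nan,
            "p_value": np.nan,
            "n_used": n_used,
        }
        if n_used > len(_DESIGN_NAMES):
            log2x = np.log2(x[ok])
            if swap_direction:
                y = log2x
                pred = mwf[ok]
            else:
                y = mwf[ok]
                pred = log2x
            X = np.column_stack([np.ones(n_used), pred, covars[ok]])
            try:
                fit = fit_ols(y, X, column_names=_DESIGN_NAMES)
            except SingularDesignError as err:
                logger.debug("aptamer %s: %s", rec["aptamer_id"], err)
            else:
                rec.update(
                    beta=fit.params[1],
                    se=fit.se[1],
                    t_stat=fit.t_stat[1],
                    p_value=fit.p_values[1],
                )
        records.append(rec)
    table = pd.DataFrame(records)

    table["q_bh"] = np.nan
    valid = table["p_value"].notna()
    if valid.any():
        table.loc[valid, "q_bh"] = stats.false_discovery_control(
            table.loc[valid, "p_value"].to_numpy(), method="bh"
        )
    sig = valid & (table["p_value"] < alpha)
    table["direction"] = "null"
    table.loc[sig & (table["beta"] > 0), "direction"] = "positive"
    table.loc[sig & (table["beta"] < 0), "direction"] = "negative"
    return table


def split_significant(
    records: pd.DataFrame, alpha: float = 0.05
) -> Tuple[List[str], List[str]]:
    """Collapse significant aptamer records to gene-level hit lists.

    A gene enters a list if any of its aptamers reaches p < alpha; a gene
    with both positive- and negative-significant aptamers is assigned by
    its most significant one, keeping the lists disjoint.  Lists are
    ordered by ascending p.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if len(records) == 0:
        raise InputError("records table is empty")
    sig = records[(records["p_value"].notna()) & (records["p_value"] < alpha)]
    positive: List[Tuple[float, str]] = []
    negative: List[Tuple[float, str]] = []
    for gene, grp in sig.groupby("gene_symbol", sort=False):
        best = grp.loc[grp["p_value"].idxmin()]
        if best["beta"] > 0:
            positive.append((best["p_value"], gene))
        elif best["beta"] < 0:
            negative.append((best["p_value"], gene))
    positive.sort()
    negative.sort()
    return [g for _, g in positive], [g for _, g in negative]
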