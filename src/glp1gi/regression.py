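"""Adjusted logistic regression: the fourth signal-detection method.

For a given event and target drug, each retained report contributes one
observation; the outcome is whether the report mentions the event, the
exposure is target drug versus the pooled comparator drugs, and age
(continuous, mean-centered) and sex (female reference) enter as
confounder adjustments.  Without covariates the drug coefficient equals
the log reporting odds ratio of the corresponding 2x2 table exactly, which
is the bridge between this model and the disproportionality statistics.

Fitting is maximum likelihood by Newton-Raphson (statsmodels ``Logit``).
Complete separation is detected and reported (``converged=False``,
``reason="separation"``) rather than silently penalized; an optional Firth
(Jeffreys-prior) penalized fit is available for separated or sparse data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .reports import RETAINED_DRUGS

_SUPPORTED_COVARIATES = ("age_years", "sex")


@dataclass(frozen=True)
class RegressionSpec:
    """One drug x event logistic model specification."""

    event: str
    target_drug: str
    covariates: tuple[str, ...] = ("age_years", "sex")
    comparator: tuple[str, ...] | None = None
    max_iter: int = 50
    tol: float = 1e-8
    firth: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.covariates) - set(_SUPPORTED_COVARIATES)
        if unknown:
            raise ValueError(f"unsupported covariates {sorted(unknown)}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class CoefficientTable:
    """Per-term estimates of one fitted model.

    ``terms`` has one row per coefficient: name, beta (natural-log-odds
    scale), se, wald_z = beta/se, p = 2*(1 - Phi(|wald_z|)).
    """

    terms: pd.DataFrame
    converged: bool
    n_obs: int
    n_dropped_missing: int = 0
    reason: str = ""

    def beta(self, name: str = "drug") -> float:
        return float(self.terms.set_index("name").loc[name, "beta"])

    def p(self, name: str = "drug") -> float:
        return float(self.terms.set_index("name").loc[name, "p"])

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_dropped_missing": self.n_dropped_missing,
            "reason": self.reason,
            "terms": self.terms.to_dict(orient="records"),
        }


def _design(
    df: pd.DataFrame, spec: RegressionSpec
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    comparator = spec.comparator or tuple(
        d for d in RETAINED_DRUGS if d != spec.target_drug
    )
    sub = df[df["drug"].isin({spec.target_drug, *comparator})]
    # collapse to one observation per report
    rep = sub.groupby("report_id").agg(
        drug=("drug", "first"),
        sex=("sex", "first"),
        age_years=("age_years", "first"),
    )
    has_event = sub[sub["event_pt"] == spec.event]["report_id"].unique()
    y = rep.index.isin(has_event).astype(float)

    cols = [np.ones(len(rep)), (rep["drug"] == spec.target_drug).to_numpy(float)]
    names = ["intercept", "drug"]
    keep = np.ones(len(rep), dtype=bool)
    if "age_years" in spec.covariates:
        age = rep["age_years"].to_numpy(float)
        keep &= ~np.isnan(age)
        cols.append(age)
        names.append("age_centered")
    if "sex" in spec.covariates:
        keep &= rep["sex"].isin(["female", "male"]).to_numpy()
        cols.append((rep["sex"] == "male").to_numpy(float))
        names.append("sex_male")

    x = np.column_stack(cols)[keep]
    y = y[keep]
    if "age_centered" in names:
        j = names.index("age_centered")
        x[:, j] = x[:, j] - x[:, j].mean()
    return x, y, names, int((~keep).sum())


def _wald_table(names: Sequence[str], beta: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    z = beta / se
    return pd.DataFrame(
        {
            "name": list(names),
            "beta": beta,
            "se": se,
            "wald_z": z,
            "p": 2.0 * (1.0 - norm.cdf(np.abs(z))),
        }
    )


def _check_separation(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation along the drug indicator: within one exposure
    group all outcomes identical while differing from the other group, or a
    monotone direction in the fitted linear predictor (left to the solver
    diagnostics)."""
    drug = x[:, 1].astype(bool)
    for mask in (drug, ~drug):
        if mask.any() and len(np.unique(y[mask])) == 1:
            other = ~mask
            if other.any() and len(np.unique(y[other])) == 1 and (
                y[mask][0] != y[other][0]
            ):
                return True
            if other.any() and y[mask][0] not in y[other]:
                return True
    return False


def _firth_fit(
    x: np.ndarray, y: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Firth-penalized logistic fit: score + 0.5 * trace adjustment via the
    hat-matrix diagonal (Jeffreys prior); finite estimates under separation."""
    beta = np.zeros(x.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        xtw = x.T * w
        info = xtw @ x
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", x, info_inv, x) * w
        score = x.T @ (y - mu + h * (0.5 - mu))
        beta = beta + info_inv @ score
        ll = np.sum(y * eta - np.log1p(np.exp(eta))) + 0.5 * np.linalg.slogdet(info)[1]
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    else:
        return beta, np.sqrt(np.diag(info_inv)), False
    return beta, np.sqrt(np.diag(info_inv)), True


def fit_logistic(df: pd.DataFrame, spec: RegressionSpec) -> CoefficientTable:
    """Fit one drug x event logistic model on a normalized report table.

    Reports with missing covariates are dropped listwise (counted in
    ``n_dropped_missing``).  Raises :class:`ValueError` for a singular
    design naming the collinear terms; returns ``converged=False`` with
    ``reason`` for separation or degenerate outcomes.
    """
    x, y, names, n_dropped = _design(df, spec)
    empty = _wald_table(names, np.full(len(names), np.nan), np.full(len(names), np.nan))
    if len(y) == 0 or y.sum() == 0 or y.sum() == len(y):
        return CoefficientTable(empty, False, len(y), n_dropped, "no_outcome_variation")

    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a dependent column by rank drop on removal
        collinear = [
            names[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"singular design matrix; collinear terms: {collinear}")

    if spec.firth:
        beta, se, ok = _firth_fit(x, y, spec.max_iter, spec.tol)
        return CoefficientTable(
            _wald_table(names, beta, se), ok, len(y), n_dropped,
            "" if ok else "max_iter",
        )

    if _check_separation(x, y):
        return CoefficientTable(empty, False, len(y), n_dropped, "separation")

    model = sm.Logit(y, x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(
                method="newton", maxiter=spec.max_iter, tol=spec.tol, disp=False
            )
        except (np.linalg.LinAlgError, Exception) as exc:  # PerfectSeparation etc.
            kind = type(exc).__name__
            reason = "separation" if "Separation" in kind else f"fit_error:{kind}"
            return CoefficientTable(empty, False, len(y), n_dropped, reason)
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 15:
        reason = "separation" if np.abs(res.params).max() > 15 else "max_iter"
        return CoefficientTable(
            _wald_table(names, res.params, res.bse), False, len(y), n_dropped, reason
        )
    return CoefficientTable(_wald_table(names, res.params, res.bse), True,
                            len(y), n_dropped)


def batch_fit(
    df: pd.DataFrame,
    events: Iterable[str],
    drugs: Iterable[str] | None = None,
    covariates: tuple[str, ...] = ("age_years", "sex"),
    firth: bool = False,
) -> dict[tuple[str, str], CoefficientTable]:
    """Independent fits for every (drug, event) pair.

    Per-pair failures (separation, degenerate outcomes) are recorded in the
    returned :class:`CoefficientTable` without aborting the batch.
    """
    drugs = tuple(drugs) if drugs is not None else RETAINED_DRUGS
    out: dict[tuple[str, str], CoefficientTable] = {}
    for event in events:
        for drug in drugs:
            spec = RegressionSpec(
                event=event, target_drug=drug, covariates=covariates, firth=firth
            )
            try:
                out[(drug, event)] = fit_logistic(df, spec)
            except ValueError as exc:
                empty = _wald_table(["intercept", "drug"], np.array([np.nan, np.nan]),
                                    np.array([np.nan, np.nan]))
                out[(drug, event)] = CoefficientTable(
                    empty, False, 0, 0, f"error:{exc}"
                )
    return out
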