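"""Disproportionality statistics and signal-criteria evaluation.

Four detection methods are computed per 2x2 table:

* **ROR** — reporting odds ratio ``(a*d)/(b*c)`` with the delta-method
  CI ``exp(ln ROR +- z*sqrt(1/a + 1/b + 1/c + 1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with
  variance ``1/a - 1/(a+b) + 1/c - 1/(c+d)`` on the log scale, plus the
  Pearson chi-square (Yates-corrected by default) used in the classical
  PRR signal rule.
* **BCPNN information component**, in two standard parameterizations:
  the closed-form shrinkage IC (``ic_noren``) and the two-layer
  Beta-prior IC with exact posterior moments (``ic_bate``).
* **Adjusted logistic regression** (fit elsewhere, in
  :mod:`glp1gi.regression`); its coefficient feeds the combined
  signal evaluation here.

The critical value defaults to ``z = 1.96`` — the convention of the
pharmacovigilance formula literature (rather than ``Phi^-1(0.975)``);
at 3 printed decimals the choice is visible on sparse tables.

Zero cells: ROR and PRR apply the Haldane-Anscombe +0.5 correction to all
four cells and flag the result ``corrected``; corrected estimates are kept
out of exact-reproduction comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import polygamma, psi

from .contingency import ContingencyTable

Z95 = 1.96
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class EstimateWithCI:
    """A ratio-scale estimate with its two-sided confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    corrected: bool = False  # Haldane-Anscombe +0.5 applied
    estimable: bool = True

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


@dataclass(frozen=True)
class ICResult:
    """BCPNN information component (base-2 log observed/expected)."""

    method: str
    ic: float
    ic025: float
    expected_count: float
    prior_params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BatePriors:
    """Priors of the two-layer Beta model: margins ~ Beta(alpha1, alpha-alpha1)
    etc.; the joint-cell prior Beta(gamma11, gamma-gamma11) has gamma scaled
    so the prior information component is centred on zero."""

    alpha1: float = 1.0
    alpha: float = 2.0
    beta1: float = 1.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.alpha1, self.alpha, self.beta1, self.beta, self.gamma11)
        if any(v <= 0 for v in vals):
            raise ValueError("prior parameters must be positive")
        if self.alpha <= self.alpha1 or self.beta <= self.beta1:
            raise ValueError("margin priors need alpha > alpha1, beta > beta1")


def _maybe_correct(table: ContingencyTable) -> tuple[ContingencyTable, bool]:
    if table.has_zero_cell:
        return table.continuity_corrected(), True
    return table, False


def _estimable(table: ContingencyTable) -> bool:
    # Degenerate margins (an empty row or column) cannot be rescued by the
    # continuity correction in any meaningful way.
    return (table.a + table.b) > 0 and (table.c + table.d) > 0 and (
        table.a + table.c
    ) > 0 and (table.b + table.d) > 0


def ror(table: ContingencyTable, z: float = Z95, level: float = 0.95) -> EstimateWithCI:
    """Reporting odds ratio with delta-method CI on the log scale."""
    ok = _estimable(table)
    t, corrected = _maybe_correct(table)
    if not ok:
        return EstimateWithCI(np.nan, np.nan, np.nan, level, corrected, False)
    est = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return EstimateWithCI(
        est, est * math.exp(-z * se), est * math.exp(z * se), level, corrected
    )


def prr(table: ContingencyTable, z: float = Z95, level: float = 0.95) -> EstimateWithCI:
    """Proportional reporting ratio with delta-method CI on the log scale."""
    ok = _estimable(table)
    t, corrected = _maybe_correct(table)
    if not ok:
        return EstimateWithCI(np.nan, np.nan, np.nan, level, corrected, False)
    est = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    var = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
    se = math.sqrt(max(var, 0.0))
    return EstimateWithCI(
        est, est * math.exp(-z * se), est * math.exp(z * se), level, corrected
    )


def chi_square(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2 table (Yates-corrected by default).

    Returns ``nan`` when any expected cell count is zero.
    """
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if np.any(expected == 0):
        return float("nan")
    stat, _, _, _ = sps.chi2_contingency(obs, correction=yates)
    return float(stat)


def ic_noren(table: ContingencyTable) -> ICResult:
    """Closed-form shrinkage information component.

    ``IC = log2((a + 1/2) / (E + 1/2))`` with expectation
    ``E = (a+b)(a+c)/N``; the lower 95% credibility bound uses the
    published percentile approximation
    ``IC025 = IC - 3.3*(a+1/2)^(-1/2) - 2*(a+1/2)^(-3/2)``.
    """
    e = (table.a + table.b) * (table.a + table.c) / table.n
    ic = math.log2((table.a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (table.a + 0.5) ** -0.5 - 2.0 * (table.a + 0.5) ** -1.5
    return ICResult("noren_shrinkage", ic, ic025, e)


def _bate_posteriors(
    table: ContingencyTable, priors: BatePriors
) -> dict[str, tuple[float, float]]:
    """Beta posterior parameters of the joint cell and the two margins."""
    n = table.n
    cx = table.a + table.b  # drug margin
    cy = table.a + table.c  # event margin
    gamma = (
        priors.gamma11
        * (n + priors.alpha)
        * (n + priors.beta)
        / ((cx + priors.alpha1) * (cy + priors.beta1))
    )
    return {
        "joint": (table.a + priors.gamma11, n - table.a + gamma - priors.gamma11),
        "drug": (cx + priors.alpha1, n - cx + priors.alpha - priors.alpha1),
        "event": (cy + priors.beta1, n - cy + priors.beta - priors.beta1),
        "_gamma": (gamma, np.nan),
    }


def ic_bate(
    table: ContingencyTable,
    priors: BatePriors | None = None,
    z: float = Z95,
) -> ICResult:
    """Two-layer Beta-prior information component with exact moments.

    The joint reporting probability and the two margins get independent
    Beta posteriors; the posterior mean and variance of
    ``IC = log2(p_xy / (p_x p_y))`` follow exactly from digamma/trigamma
    moments of ``log p`` under a Beta law.  The joint-cell prior weight
    ``gamma`` is scaled so that the prior IC is centred on zero.
    """
    priors = priors or BatePriors()
    post = _bate_posteriors(table, priors)
    mean = 0.0
    var = 0.0
    for name, sign in (("joint", 1.0), ("drug", -1.0), ("event", -1.0)):
        u, v = post[name]
        mean += sign * (psi(u) - psi(u + v)) / _LN2
        var += (polygamma(1, u) - polygamma(1, u + v)) / _LN2**2
    e = (table.a + table.b) * (table.a + table.c) / table.n
    return ICResult(
        "bate_prior",
        float(mean),
        float(mean - z * math.sqrt(var)),
        e,
        prior_params={
            "alpha1": priors.alpha1,
            "alpha": priors.alpha,
            "beta1": priors.beta1,
            "beta": priors.beta,
            "gamma11": priors.gamma11,
            "gamma": float(post["_gamma"][0]),
        },
    )


# ---------------------------------------------------------------------------
# Combined signal evaluation


@dataclass(frozen=True)
class SignalCriteria:
    """Classical thresholds of the four signal rules.

    ROR: CI lower bound > 1 with at least ``min_cases`` cases.
    PRR: PRR >= 2 with chi-square >= 4 and at least 3 cases.
    BCPNN: IC025 > 0.  MLR: beta > 0 with p < 0.05.
    """

    min_cases: int = 3
    ror_ci_low_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    beta_gt: float = 0.0
    beta_p_lt: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_cases, self.prr_min, self.chi2_min, self.beta_p_lt) <= 0:
            raise ValueError("signal thresholds must be strictly positive")


@dataclass
class SignalResult:
    """All statistics and per-method signal flags for one drug x event pair."""

    drug: str
    event: str
    table: ContingencyTable
    ror: EstimateWithCI
    prr: EstimateWithCI
    chi2: float
    ic: ICResult
    ic_alt: ICResult | None = None
    beta: float | None = None
    beta_p: float | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def n_methods_positive(self) -> int:
        return sum(bool(v) for v in self.flags.values())

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "event": self.event,
            "cases": self.table.a,
            "ror": self.ror.estimate,
            "ror_ci_low": self.ror.ci_low,
            "ror_ci_high": self.ror.ci_high,
            "prr": self.prr.estimate,
            "prr_ci_low": self.prr.ci_low,
            "prr_ci_high": self.prr.ci_high,
            "chi2": self.chi2,
            "ic": self.ic.ic,
            "ic025": self.ic.ic025,
            "beta": self.beta,
            "beta_p": self.beta_p,
            "flag_ror": self.flags.get("ror", False),
            "flag_prr": self.flags.get("prr", False),
            "flag_ic": self.flags.get("ic", False),
            "flag_mlr": self.flags.get("mlr", False),
            "n_methods_positive": self.n_methods_positive,
        }


def evaluate_signal(
    table: ContingencyTable,
    criteria: SignalCriteria | None = None,
    beta: float | None = None,
    beta_p: float | None = None,
    ic_method: str = "noren",
    z: float = Z95,
) -> SignalResult:
    """Compute all four statistics for one 2x2 table and apply the rules.

    Non-estimable statistics yield ``flag=False`` with a reason code in
    ``result.reasons`` rather than an error; a value is deemed highlighted
    (bold, in tabular display) exactly when its method flag is true.
    """
    criteria = criteria or SignalCriteria()
    r = ror(table, z=z)
    p = prr(table, z=z)
    chi2 = chi_square(table)
    icn = ic_noren(table)
    icb = ic_bate(table, z=z)
    headline = icn if ic_method == "noren" else icb

    flags: dict[str, bool] = {}
    reasons: dict[str, str] = {}

    if not r.estimable:
        flags["ror"] = False
        reasons["ror"] = "non_estimable"
    elif table.a < criteria.min_cases:
        flags["ror"] = False
        reasons["ror"] = "min_cases"
    else:
        flags["ror"] = bool(r.ci_low > criteria.ror_ci_low_gt)

    if not p.estimable:
        flags["prr"] = False
        reasons["prr"] = "non_estimable"
    elif table.a < 3:
        flags["prr"] = False
        reasons["prr"] = "min_cases"
    elif math.isnan(chi2):
        flags["prr"] = False
        reasons["prr"] = "non_estimable"
    else:
        flags["prr"] = bool(
            p.estimate >= criteria.prr_min and chi2 >= criteria.chi2_min
        )

    flags["ic"] = bool(headline.ic025 > criteria.ic025_gt)

    if beta is None or beta_p is None:
        flags["mlr"] = False
        reasons["mlr"] = "not_fitted"
    else:
        flags["mlr"] = bool(beta > criteria.beta_gt and beta_p < criteria.beta_p_lt)

    return SignalResult(
        drug=table.drug,
        event=table.event,
        table=table,
        ror=r,
        prr=p,
        chi2=chi2,
        ic=headline,
        ic_alt=icb if ic_method == "noren" else icn,
        beta=beta,
        beta_p=beta_p,
        flags=flags,
        reasons=reasons,
    )


def signal_table(results) -> "pd.DataFrame":
    """Tidy one-row-per-pair export of :class:`SignalResult` objects."""
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in results])
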