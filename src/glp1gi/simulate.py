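"""Synthetic spontaneous-report generator.

Generates report-level datasets with the statistical structure the
disproportionality analysis assumes, so the whole pipeline is testable
without any database download and so that parameter recovery can be
measured against known effect sizes.

The generative model, per report: sex ~ Bernoulli(female_share); age from a
band mixture with uniform age inside each band; the drug from the
multinomial report shares (optionally tilted by age, to create confounded
exposure); reporting year uniform over the drug's marketing era; reporter
and indication from their marginals; then each tracked event independently
with

    logit p(event | drug, x) = logit(baseline) + ln(theta[drug, event])
                               + confounding terms(x)

and finally the serious-outcome flags.  The multiplier ``theta`` acts on
the reporting *odds*, so the reporting odds ratio against the pooled
comparator estimates exactly ``theta`` — the generator controls relative
reporting, not incidence, which is all a spontaneous-report system can
identify.  Reports drawing no tracked event are retained with the
placeholder term :data:`NO_EVENT_PT` (they populate the b/d cells).

Default parameter values follow the published cohort's marginals: report
shares 26.6/24.9/24.6/23.9% over the four drugs, 62% female, age-band
shares 10/19.8/32/38.2%, 65% consumer reports, and event baselines equal
to the pooled event proportions of the packaged count fixture.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .fixture import CountFixture, load_fixture
from .reports import GI_SOC, OUTCOMES, REPORT_COLUMNS, RETAINED_DRUGS, _coerce_frame

#: Placeholder preferred term for reports with no tracked event.
NO_EVENT_PT = "no_tracked_gi_event"
#: Placeholder preferred term used when expanding fixture counts.
OTHER_EVENT_PT = "other_gi_event"

_AGE_CENTER = 55.0  # decade-scale covariates are centered here

DEFAULT_AGE_BANDS = (
    (18.0, 45.0, 0.10),
    (45.0, 55.0, 0.198),
    (55.0, 65.0, 0.32),
    (65.0, 90.0, 0.382),
)
DEFAULT_OUTCOME_PROBS = {
    "hospitalization": 0.203,
    "life_threatening": 0.012,
    "death": 0.012,
    "disability": 0.008,
}
DEFAULT_INDICATION_PROBS = {
    "diabetes_mellitus": 0.89,
    "obesity": 0.03,
    "weight_loss": 0.08,
}


def _default_baselines() -> dict[str, float]:
    fx = load_fixture()
    out = {}
    for ev in fx.event_names:
        if fx.is_complete(ev) and not fx.row_flags(ev):
            total = sum(fx.cases(ev, d) for d in fx.drugs)
            out[ev] = total / fx.total_reports
    return out


@dataclass
class SyntheticConfig:
    """Generative model of a simulated report set.

    ``rate_multiplier`` maps ``(drug, event)`` to the odds-scale relative
    reporting rate theta (default 1 everywhere).  ``confounding`` maps an
    event to log-odds slopes ``{"age_per_decade": ..., "female": ...}``;
    ``drug_age_tilt`` maps a drug to a log-odds-per-decade tilt of drug
    assignment, which induces confounded exposure when combined with an
    age slope on the event.
    """

    n_reports: int = 10_000
    drug_shares: dict[str, float] = field(
        default_factory=lambda: {
            "exenatide": 0.266,
            "liraglutide": 0.249,
            "dulaglutide": 0.246,
            "semaglutide": 0.239,
        }
    )
    event_baseline: dict[str, float] | None = None
    rate_multiplier: dict[tuple[str, str], float] = field(default_factory=dict)
    female_share: float = 0.62
    age_bands: tuple = DEFAULT_AGE_BANDS
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS)
    )
    outcome_probs_by_drug: dict[str, dict[str, float]] = field(default_factory=dict)
    consumer_share: float = 0.65
    indication_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDICATION_PROBS)
    )
    year_range: tuple[int, int] = (2007, 2023)
    approval_years: dict[str, int] | None = None
    confounding: dict[str, dict[str, float]] = field(default_factory=dict)
    drug_age_tilt: dict[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_baseline is None:
            self.event_baseline = _default_baselines()
        if self.approval_years is None:
            self.approval_years = dict(load_fixture().approval_years)
        for name, probs in (
            ("drug_shares", self.drug_shares.values()),
            ("age_bands", [b[2] for b in self.age_bands]),
        ):
            probs = list(probs)
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"{name} entries must lie in [0, 1] and sum to 1")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1")
        if any(t <= 0 for t in self.rate_multiplier.values()):
            raise ValueError("rate multipliers must be positive")
        for p in (*self.event_baseline.values(), self.female_share,
                  self.consumer_share, *self.outcome_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["rate_multiplier"] = {
            f"{dg}:{ev}": v for (dg, ev), v in self.rate_multiplier.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        kw = dict(d)
        if "rate_multiplier" in kw:
            kw["rate_multiplier"] = {
                tuple(k.split(":", 1)): float(v)
                for k, v in kw["rate_multiplier"].items()
            }
        if "age_bands" in kw:
            kw["age_bands"] = tuple(tuple(b) for b in kw["age_bands"])
        if "year_range" in kw:
            kw["year_range"] = tuple(kw["year_range"])
        return cls(**kw)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- model pieces ------------------------------------------------------
    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.drug_shares)

    @property
    def events(self) -> tuple[str, ...]:
        return tuple(self.event_baseline)

    def theta(self, drug: str, event: str) -> float:
        return self.rate_multiplier.get((drug, event), 1.0)

    def event_logit(self, drug: str, event: str, age, female):
        """Log-odds of reporting `event` given drug and covariates."""
        q = self.event_baseline[event]
        logit = np.log(q / (1.0 - q)) + np.log(self.theta(drug, event))
        conf = self.confounding.get(event)
        if conf:
            logit = (
                logit
                + conf.get("age_per_decade", 0.0) * (np.asarray(age) - _AGE_CENTER) / 10.0
                + conf.get("female", 0.0) * np.asarray(female)
            )
        return logit

    def drug_weights(self, age) -> np.ndarray:
        """Per-report drug-assignment weights (n, n_drugs), normalized."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        w = np.empty((len(age), len(self.drugs)))
        for j, d in enumerate(self.drugs):
            tilt = self.drug_age_tilt.get(d, 0.0)
            w[:, j] = self.drug_shares[d] * np.exp(tilt * (age - _AGE_CENTER) / 10.0)
        return w / w.sum(axis=1, keepdims=True)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))


def generate(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic report set as a normalized report table.

    Reproducible given the seed (``seed`` overrides ``config.seed``).
    The returned frame's ``attrs`` carry the seed and config hash.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    drugs = config.drugs
    events = config.events

    female = rng.random(n) < config.female_share
    band_idx = rng.choice(
        len(config.age_bands), size=n, p=[b[2] for b in config.age_bands]
    )
    lo = np.array([b[0] for b in config.age_bands])[band_idx]
    hi = np.array([b[1] for b in config.age_bands])[band_idx]
    age = lo + rng.random(n) * (hi - lo)

    if config.drug_age_tilt:
        w = config.drug_weights(age)
        cum = np.cumsum(w, axis=1)
        drug_idx = (rng.random((n, 1)) > cum[:, :-1]).sum(axis=1)
    else:
        drug_idx = rng.choice(
            len(drugs), size=n, p=[config.drug_shares[d] for d in drugs]
        )
    drug = np.array(drugs, dtype=object)[drug_idx]

    year_lo = np.array(
        [
            max(config.year_range[0], config.approval_years.get(d, config.year_range[0]))
            for d in drugs
        ]
    )[drug_idx]
    year = year_lo + (
        rng.random(n) * (config.year_range[1] + 1 - year_lo)
    ).astype(int)

    reporter = np.where(
        rng.random(n) < config.consumer_share, "consumer", "healthcare_professional"
    )
    ind_names = list(config.indication_probs)
    ind_p = np.array([config.indication_probs[k] for k in ind_names], dtype=float)
    ind_p = ind_p / ind_p.sum()
    indication = np.array(ind_names, dtype=object)[
        rng.choice(len(ind_names), size=n, p=ind_p)
    ]

    # event incidence matrix (n, n_events)
    hits = np.zeros((n, len(events)), dtype=bool)
    for k, ev in enumerate(events):
        p = np.full(n, np.nan)
        for j, d in enumerate(drugs):
            mask = drug_idx == j
            p[mask] = _sigmoid(config.event_logit(d, ev, age[mask], female[mask]))
        hits[:, k] = rng.random(n) < p

    # serious outcomes
    out_flags = np.empty(n, dtype=object)
    out_flags[:] = ""
    outc_matrix = np.zeros((n, len(OUTCOMES)), dtype=bool)
    for k, oc in enumerate(OUTCOMES):
        p = np.full(n, config.outcome_probs.get(oc, 0.0))
        for d, probs in config.outcome_probs_by_drug.items():
            if oc in probs:
                p[drug == d] = probs[oc]
        outc_matrix[:, k] = rng.random(n) < p
    for k, oc in enumerate(OUTCOMES):
        sel = outc_matrix[:, k]
        out_flags[sel] = np.where(
            out_flags[sel] == "", oc, out_flags[sel] + "|" + oc
        )

    report_id = np.array([f"R{i:08d}" for i in range(n)], dtype=object)
    ev_arr = np.array(events, dtype=object)
    ii, kk = np.nonzero(hits)
    zero_idx = np.flatnonzero(hits.sum(axis=1) == 0)
    row_report = np.concatenate([ii, zero_idx])
    event_col = np.concatenate(
        [ev_arr[kk], np.full(zero_idx.size, NO_EVENT_PT, dtype=object)]
    )
    order = np.argsort(row_report, kind="stable")
    row_report = row_report[order]
    event_col = event_col[order]

    df = pd.DataFrame(
        {
            "report_id": report_id[row_report],
            "case_id": report_id[row_report],
            "case_version": 1,
            "drug": drug[row_report],
            "role_code": "primary_suspect",
            "event_pt": event_col,
            "event_soc": GI_SOC,
            "sex": np.where(female, "female", "male")[row_report],
            "age_years": np.round(age, 1)[row_report],
            "reporting_year": year[row_report],
            "reporter": reporter[row_report],
            "country": "US",
            "indication": indication[row_report],
            "outcomes": out_flags[row_report],
        },
        columns=REPORT_COLUMNS,
    )

    if config.duplicate_rate > 0:
        dup_reports = rng.random(n) < config.duplicate_rate
        dup = df[df["report_id"].isin(report_id[dup_reports])]
        df = pd.concat([df, dup], ignore_index=True)

    df = _coerce_frame(df)
    df.attrs["seed"] = int(config.seed if seed is None else seed)
    df.attrs["config_hash"] = config.config_hash()
    return df


# ---------------------------------------------------------------------------
# Closed-form expectations


@dataclass
class ExpectedTables:
    """Expected 2x2 cell means (event-level counting) under a config."""

    cells: dict[tuple[str, str], tuple[float, float, float, float]]
    rows_per_drug: dict[str, float]

    def table(self, drug: str, event: str):
        return self.cells[(drug, event)]


def _covariate_grid(config: SyntheticConfig, n_nodes: int = 16):
    """Gauss-Legendre nodes over the age bands crossed with sex."""
    xs, ws = np.polynomial.legendre.leggauss(n_nodes)
    ages, weights = [], []
    for lo, hi, share in config.age_bands:
        ages.append(0.5 * (hi - lo) * xs + 0.5 * (hi + lo))
        weights.append(0.5 * ws * share)  # uniform density within the band
    age = np.concatenate(ages)
    w_age = np.concatenate(weights)
    age = np.concatenate([age, age])
    female = np.concatenate([np.ones(w_age.size), np.zeros(w_age.size)])
    w = np.concatenate(
        [w_age * config.female_share, w_age * (1 - config.female_share)]
    )
    return age, female, w


def expected_tables(config: SyntheticConfig) -> ExpectedTables:
    """Exact expected cell means under the generative model.

    Integrates the event probabilities over the covariate distribution
    (Gauss-Legendre within each age band, exact over sex), honouring any
    confounding slopes and age-tilted drug assignment.  Doubling
    ``n_reports`` doubles every expected cell.
    """
    age, female, w = _covariate_grid(config)
    drugs, events = config.drugs, config.events
    w_drug = config.drug_weights(age)  # covariate-conditional assignment

    # P(drug, x) weights on the grid
    p_dx = w[:, None] * w_drug  # (grid, n_drugs)
    a = {}
    rows = {}
    p_event = np.empty((age.size, len(drugs), len(events)))
    for j, d in enumerate(drugs):
        for k, ev in enumerate(events):
            p_event[:, j, k] = _sigmoid(config.event_logit(d, ev, age, female))
    n = config.n_reports
    for j, d in enumerate(drugs):
        p_no_event = np.prod(1.0 - p_event[:, j, :], axis=1)
        rows[d] = float(
            n * np.sum(p_dx[:, j] * (p_event[:, j, :].sum(axis=1) + p_no_event))
        )
        for k, ev in enumerate(events):
            a[(d, ev)] = float(n * np.sum(p_dx[:, j] * p_event[:, j, k]))

    cells = {}
    for d in drugs:
        for ev in events:
            a_de = a[(d, ev)]
            b_de = rows[d] - a_de
            c_de = sum(a[(d2, ev)] for d2 in drugs if d2 != d)
            d_de = sum(rows[d2] for d2 in drugs if d2 != d) - c_de
            cells[(d, ev)] = (a_de, b_de, c_de, d_de)
    return ExpectedTables(cells=cells, rows_per_drug=rows)


# ---------------------------------------------------------------------------
# Fixture expansion (inverse of counting)


def expand_fixture_to_reports(fixture: CountFixture, event: str) -> pd.DataFrame:
    """Expand one packaged count row into a synthetic report table.

    For each drug, emits exactly ``a`` rows carrying the event and
    ``total - a`` rows carrying :data:`OTHER_EVENT_PT`, so that re-counting
    reproduces the fixture's 2x2 tables bit-for-bit; the total row count
    equals the analyzed-cohort size.  Demographics are unspecified.
    Per-event expansion is the only faithful inverse: per-drug event counts
    sum to more than the drug report totals (reports carry several events),
    so no single report set can reproduce every row at once.
    """
    missing = [d for d in fixture.drugs if fixture.cases(event, d) is None]
    if missing:
        raise ValueError(f"fixture row {event!r} lacks counts for {missing}")
    frames = []
    for d in fixture.drugs:
        a = fixture.cases(event, d)
        total = fixture.drug_totals[d]
        ids = [f"F-{d}-{i:05d}" for i in range(total)]
        frames.append(
            pd.DataFrame(
                {
                    "report_id": ids,
                    "case_id": ids,
                    "case_version": 1,
                    "drug": d,
                    "role_code": "primary_suspect",
                    "event_pt": [event] * a + [OTHER_EVENT_PT] * (total - a),
                    "event_soc": GI_SOC,
                    "sex": "unspecified",
                    "age_years": np.nan,
                    "reporting_year": pd.NA,
                    "reporter": "unspecified",
                    "country": "US",
                    "indication": "missing",
                    "outcomes": "",
                },
                columns=REPORT_COLUMNS,
            )
        )
    return _coerce_frame(pd.concat(frames, ignore_index=True))
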