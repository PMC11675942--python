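"""Minimal reader for FAERS-style quarterly ASCII files.

The FDA Adverse Event Reporting System distributes quarterly "$"-delimited
ASCII tables.  This reader handles the small stable column subset the
pipeline needs, across the five files DEMO/DRUG/REAC/OUTC/INDI, and emits
the normalized report table of :mod:`glp1gi.reports` — one row per
(report, drug row, reaction PT).  Unknown columns are ignored; the schema
drift of real quarters is out of scope.

Columns used:
  DEMO: primaryid, caseid, caseversion, age, age_cod, sex, occp_cod,
        reporter_country, fda_dt
  DRUG: primaryid, role_cod, drugname
  REAC: primaryid, pt
  OUTC: primaryid, outc_cod
  INDI: primaryid, indi_pt
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .reports import (
    GI_SOC,
    OUTCOMES,
    REPORT_COLUMNS,
    _coerce_frame,
    normalize_drug_name,
)

FAERS_FILES = ("DEMO", "DRUG", "REAC", "OUTC", "INDI")

_ROLE_CODES = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interacting",
}
_SEX = {"F": "female", "M": "male"}
# FAERS occupation codes: MD/PH/OT/HP are health professionals, CN consumer.
_REPORTER = {
    "CN": "consumer",
    "MD": "healthcare_professional",
    "PH": "healthcare_professional",
    "HP": "healthcare_professional",
    "OT": "healthcare_professional",
}
_OUTCOME = {"DS": "disability", "LT": "life_threatening", "HO": "hospitalization",
            "DE": "death"}
# Age-unit codes, conversion factor to years.
_AGE_FACTOR = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "DY": 1 / 365.25}

_INDICATION_PRIORITY = ("diabetes_mellitus", "obesity", "weight_loss", "other")


def _map_indication(pt: str) -> str:
    s = str(pt).strip().lower()
    if "diabetes" in s:
        return "diabetes_mellitus"
    if "obesity" in s:
        return "obesity"
    if "weight" in s:
        return "weight_loss"
    return "other"


def _read_table(directory: str, name: str) -> pd.DataFrame:
    path = None
    for candidate in (f"{name}.txt", f"{name}.TXT", name):
        p = os.path.join(directory, candidate)
        if os.path.exists(p):
            path = p
            break
    if path is None:
        raise FileNotFoundError(f"FAERS file {name} not found in {directory}")
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_faers_ascii(
    directory: str,
    soc_map: Mapping[str, str] | None = None,
    default_soc: str = GI_SOC,
) -> pd.DataFrame:
    """Join the five FAERS ASCII files into the normalized report table.

    One output row is emitted per (DEMO report, DRUG row, REAC preferred
    term).  Outcomes and indications are aggregated per report; orphan
    REAC/OUTC/INDI rows with no DEMO match are dropped and counted in
    ``df.attrs["orphans"]``.  ``soc_map`` assigns a system organ class per
    preferred term (anything unmapped gets ``default_soc``).  Output order
    is deterministic: sorted by (case_id, case_version, report_id, drug,
    event_pt).  Versioned duplicates are *not* resolved here — that is
    :func:`glp1gi.reports.deduplicate`'s job.
    """
    demo = _read_table(directory, "DEMO")
    drug = _read_table(directory, "DRUG")
    reac = _read_table(directory, "REAC")
    outc = _read_table(directory, "OUTC")
    indi = _read_table(directory, "INDI")

    known_ids = set(demo["primaryid"])
    orphans = {
        name: int((~tbl["primaryid"].isin(known_ids)).sum())
        for name, tbl in (("DRUG", drug), ("REAC", reac), ("OUTC", outc), ("INDI", indi))
    }

    outc = outc[outc["primaryid"].isin(known_ids)]
    outc_agg = (
        outc.assign(flag=outc["outc_cod"].str.strip().str.upper().map(_OUTCOME))
        .dropna(subset=["flag"])
        .groupby("primaryid")["flag"]
        .apply(lambda s: "|".join(sorted(set(s))))
    )

    indi = indi[indi["primaryid"].isin(known_ids)]
    if len(indi):
        indi_agg = (
            indi.assign(ind=indi["indi_pt"].map(_map_indication))
            .groupby("primaryid")["ind"]
            .apply(
                lambda s: min(set(s), key=_INDICATION_PRIORITY.index)
            )
        )
    else:
        indi_agg = pd.Series(dtype=str)

    demo = demo.set_index("primaryid", drop=False)
    age_num = pd.to_numeric(demo.get("age", ""), errors="coerce")
    age_factor = (
        demo.get("age_cod", "").str.strip().str.upper().map(_AGE_FACTOR)
    )
    demo_age = age_num * age_factor

    base = pd.DataFrame(
        {
            "report_id": demo["primaryid"],
            "case_id": demo["caseid"],
            "case_version": pd.to_numeric(demo["caseversion"], errors="coerce"),
            "sex": demo.get("sex", "").str.strip().str.upper().map(_SEX).fillna(
                "unspecified"
            ),
            "age_years": demo_age,
            "reporting_year": pd.to_numeric(
                demo.get("fda_dt", "").str.slice(0, 4), errors="coerce"
            ),
            "reporter": demo.get("occp_cod", "")
            .str.strip()
            .str.upper()
            .map(_REPORTER)
            .fillna("unspecified"),
            "country": demo.get("reporter_country", "").str.strip().str.upper(),
            "outcomes": demo["primaryid"].map(outc_agg).fillna(""),
            "indication": demo["primaryid"].map(indi_agg).fillna("missing"),
        }
    )

    drug = drug[drug["primaryid"].isin(known_ids)].copy()
    drug["drug"] = drug["drugname"].map(normalize_drug_name)
    drug["role_code"] = (
        drug["role_cod"].str.strip().str.upper().map(_ROLE_CODES).fillna("concomitant")
    )

    reac = reac[reac["primaryid"].isin(known_ids)].copy()
    reac["event_pt"] = reac["pt"].str.strip().str.lower().str.replace(" ", "_")
    soc_map = soc_map or {}
    reac["event_soc"] = reac["event_pt"].map(soc_map).fillna(default_soc)

    rows = drug[["primaryid", "drug", "role_code"]].merge(
        reac[["primaryid", "event_pt", "event_soc"]], on="primaryid"
    )
    out = rows.merge(base, left_on="primaryid", right_on="report_id").drop(
        columns="primaryid"
    )
    out = _coerce_frame(out[REPORT_COLUMNS])
    out = out.sort_values(
        ["case_id", "case_version", "report_id", "drug", "event_pt"]
    ).reset_index(drop=True)
    out.attrs["orphans"] = orphans
    return out
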