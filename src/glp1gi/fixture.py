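"""Packaged published counts for exact reproduction.

``printed_counts.json`` carries the per-drug gastrointestinal report totals,
the per-event per-drug case counts, and the printed disproportionality
statistics of a published US FAERS analysis of the four retained GLP-1
receptor agonists, together with provenance notes and discrepancy flags
(rows and cells whose printed statistics are arithmetically inconsistent
with their own printed counts — see ``known_discrepant_note`` in the
resource).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping


@dataclass(frozen=True)
class CountFixture:
    """The published count tables, indexed for 2x2 construction."""

    drug_totals: Mapping[str, int]
    total_reports: int
    events: Mapping[str, Mapping]
    z_critical: float
    approval_years: Mapping[str, int]
    drug_shares_printed: Mapping[str, float]
    excluded_statistics: Mapping[str, str]
    known_discrepant_cells: frozenset[tuple[str, str, str]]
    raw: Mapping

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.drug_totals)

    @property
    def event_names(self) -> tuple[str, ...]:
        return tuple(self.events)

    def cases(self, event: str, drug: str) -> int | None:
        """Printed case count for (event, drug); None where not printed."""
        return self.events[event]["cases"][drug]

    def is_complete(self, event: str) -> bool:
        """True when the event row has a printed count for all four drugs."""
        return all(self.events[event]["cases"][d] is not None for d in self.drugs)

    def row_flags(self, event: str) -> tuple[str, ...]:
        return tuple(self.events[event].get("flags", ()))

    def is_discrepant(self, drug: str, event: str, statistic: str) -> bool:
        """True when the printed cell failed the arithmetic audit, or its
        whole row is flagged (erratum / transposition / incomplete)."""
        if self.row_flags(event):
            return True
        return (drug, event, statistic) in self.known_discrepant_cells

    def printed(self, event: str, drug: str, statistic: str):
        """Printed value of a statistic: 'ror'/'prr' give (est, lo, hi);
        'ic025' and 'beta' give scalars; None where the table prints none."""
        row = self.events[event]
        if statistic in ("ror", "prr"):
            val = row[f"printed_{statistic}"][drug]
            return tuple(val) if val is not None else None
        if statistic in ("ic025", "beta"):
            return row[f"printed_{statistic}"][drug]
        raise KeyError(statistic)


def load_fixture() -> CountFixture:
    """Load the packaged published-count fixture."""
    with resources.files("glp1gi.data").joinpath("printed_counts.json").open() as fh:
        raw = json.load(fh)
    return CountFixture(
        drug_totals=raw["drug_totals"],
        total_reports=raw["total_reports"],
        events=raw["events"],
        z_critical=raw["z_critical"],
        approval_years=raw["approval_years"],
        drug_shares_printed=raw["drug_shares_printed"],
        excluded_statistics=raw["excluded_statistics"],
        known_discrepant_cells=frozenset(
            tuple(c) for c in raw["known_discrepant_cells"]
        ),
        raw=raw,
    )
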