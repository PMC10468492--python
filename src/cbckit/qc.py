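"""Data-quality funnel for survey entries.

Exclusions are applied in a fixed, documented order — ineligible entries,
duplicate origins (first occurrence kept), speeders, straight-liners,
incompletes — and each removed respondent is counted once, under the first
rule that catches them.  Totals are invariant to the rule order; the
per-rule breakdown is not, which is why the order is part of the contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attributes import ConfigurationError
from .dataset import ChoiceDataset


@dataclass(frozen=True)
class FunnelRules:
    """Which quality rules to apply (eligibility is always applied first)."""

    duplicates: bool = True
    speeders: bool = True
    straightliners: bool = True
    incompletes: bool = True


@dataclass
class FunnelReport:
    """Auditable accounting of survey exclusions."""

    opened: int
    eligible: int
    excluded_by_rule: dict[str, int]
    analytic: int

    @property
    def quality_excluded(self) -> int:
        return sum(self.excluded_by_rule.values())

    @property
    def eligibility_rate(self) -> float:
        """Percent of opened entries meeting inclusion criteria (1 decimal)."""
        return round(100.0 * self.eligible / self.opened, 1) if self.opened else 0.0

    @property
    def quality_exclusion_rate(self) -> float:
        """Percent of eligible entries failing quality rules (1 decimal)."""
        return (
            round(100.0 * self.quality_excluded / self.eligible, 1)
            if self.eligible
            else 0.0
        )

    def to_dict(self) -> dict:
        return {
            "opened": self.opened,
            "eligible": self.eligible,
            "eligibility_rate_pct": self.eligibility_rate,
            "excluded_by_rule": dict(self.excluded_by_rule),
            "quality_excluded": self.quality_excluded,
            "quality_exclusion_rate_pct": self.quality_exclusion_rate,
            "analytic": self.analytic,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __str__(self) -> str:
        lines = [
            f"opened survey          {self.opened}",
            f"met inclusion criteria {self.eligible} ({self.eligibility_rate}%)",
        ]
        for rule, n in self.excluded_by_rule.items():
            lines.append(f"  excluded: {rule:<14} {n}")
        lines += [
            f"quality-excluded       {self.quality_excluded} "
            f"({self.quality_exclusion_rate}%)",
            f"analytic sample        {self.analytic}",
        ]
        return "\n".join(lines)


def _require_column(df: pd.DataFrame, col: str, rule: str) -> None:
    if col not in df.columns:
        raise ConfigurationError(
            f"funnel rule {rule!r} requires metadata column {col!r}, which is missing"
        )


def apply_funnel(
    dataset: ChoiceDataset,
    min_minutes: float = 10.0,
    rules: FunnelRules = FunnelRules(),
) -> tuple[ChoiceDataset, FunnelReport]:
    """Apply the exclusion funnel and return the analytic dataset plus report."""
    resp = dataset.respondents
    opened = len(resp)
    excluded: dict[str, int] = {}
    removed = pd.Series(False, index=resp.index)
    if opened == 0:  # vacuous funnel: nothing to check, nothing to remove
        return dataset.copy(), FunnelReport(0, 0, {}, 0)

    if "eligible" in resp.columns:
        ineligible = ~resp["eligible"].astype(bool)
    else:
        ineligible = pd.Series(False, index=resp.index)
    eligible_n = int((~ineligible).sum())
    removed |= ineligible

    def mark(rule: str, mask: pd.Series) -> None:
        nonlocal removed
        new = mask & ~removed
        excluded[rule] = int(new.sum())
        removed |= new

    if rules.duplicates:
        _require_column(resp, "origin_id", "duplicates")
        dup = resp["origin_id"].duplicated(keep="first") & ~removed
        mark("duplicate_origin", dup)
    if rules.speeders:
        _require_column(resp, "completion_minutes", "speeders")
        mark("speeder", resp["completion_minutes"] < min_minutes)
    if rules.straightliners or rules.incompletes:
        tasks = dataset.tasks
        stats = tasks.groupby("respondent_id")["chosen"].agg(["count", "size", "nunique"])
        stats = stats.reindex(resp["respondent_id"]).fillna(0)
        answered_all = (stats["count"] == stats["size"]) & (stats["size"] > 0)
        if rules.straightliners:
            straight = (answered_all & (stats["nunique"] == 1)).to_numpy()
            mark("straightliner", pd.Series(straight, index=resp.index))
        if rules.incompletes:
            incomplete = (~answered_all).to_numpy()
            mark("incomplete", pd.Series(incomplete, index=resp.index))

    keep_ids = set(resp.loc[~removed, "respondent_id"])
    out = dataset.copy()
    out.respondents = resp.loc[~removed].reset_index(drop=True)
    out.tasks = dataset.tasks[dataset.tasks["respondent_id"].isin(keep_ids)].reset_index(
        drop=True
    )
    report = FunnelReport(
        opened=opened,
        eligible=eligible_n,
        excluded_by_rule=excluded,
        analytic=len(out.respondents),
    )
    return out, report
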