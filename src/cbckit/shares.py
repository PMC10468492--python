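"""Share-of-preference simulation for hypothetical program scenarios.

Each scenario (one level per attribute) is evaluated one-at-a-time against
the opt-out: the share is the percentage of respondents predicted to
choose the program over None.  Three simulators are provided:

* ``first_choice`` — a respondent counts toward the program iff its
  raw-scale utility strictly exceeds their opt-out utility (exact ties
  split 50/50);
* ``logit`` — expected share exp(u) / (exp(u) + exp(u_none));
* ``rfc`` (randomized first choice) — per draw, each part-worth is
  perturbed by independent normal "attribute" error and each alternative's
  total utility by extreme-value "product" error before taking the first
  choice; shares are averaged over draws and respondents.

Simulation always operates on raw logit-scale utilities; zero-centered
values are display-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .attributes import (
    BURDEN,
    CLINICIAN,
    COST,
    COST_HIGH,
    COST_LOW,
    COURIER,
    DAILY_ORAL,
    DISPENSING,
    DOSING,
    IN_PERSON,
    INJECTABLE,
    ON_DEMAND,
    ONE_WEEK,
    ONLINE,
    PICKUP,
    SAME_DAY,
    AttributeSpace,
    Concept,
    ConfigurationError,
    Prohibition,
    default_prohibitions,
)
from .partworths import UtilityEstimate


@dataclass(frozen=True)
class Scenario:
    """A named hypothetical program: one level label per attribute."""

    name: str
    levels: dict[str, str]

    def concept(self, space: AttributeSpace) -> Concept:
        idx = []
        for attr in space:
            if attr.name not in self.levels:
                raise ConfigurationError(
                    f"scenario {self.name!r} missing attribute {attr.name!r}"
                )
            idx.append(attr.level_index(self.levels[attr.name]))
        return Concept(tuple(idx))

    def validate(
        self, space: AttributeSpace, prohibitions: Sequence[Prohibition] = ()
    ) -> None:
        concept = self.concept(space)
        if concept.violates(space, prohibitions):
            raise ConfigurationError(
                f"scenario {self.name!r} violates a prohibition"
            )


@dataclass(frozen=True)
class SimConfig:
    """Share-simulator settings.

    ``attribute_error_scale`` multiplies the per-coordinate population
    standard deviation of the utilities to obtain the normal attribute
    error; ``product_error_scale`` scales the extreme-value alternative
    error.  Both apply to the ``rfc`` model only.
    """

    model: str = "rfc"
    n_draws: int = 1000
    attribute_error_scale: float = 0.5
    product_error_scale: float = 1.0
    seed: int = 0
    use_posterior_draws: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("first_choice", "logit", "rfc"):
            raise ConfigurationError(f"unknown share model {self.model!r}")
        if self.model == "rfc" and self.n_draws < 1:
            raise ConfigurationError("rfc requires n_draws >= 1")
        if self.attribute_error_scale < 0 or self.product_error_scale < 0:
            raise ConfigurationError("error scales must be nonnegative")


@dataclass
class ShareReport:
    """Scenario x group share-of-preference matrix (percent choosing the program)."""

    shares: pd.DataFrame  # rows scenarios, columns Total + groups
    config: SimConfig

    def none_shares(self) -> pd.DataFrame:
        return 100.0 - self.shares


# ---- scenarios ----------------------------------------------------------------

_DEFAULT_SCENARIOS = [
    ("Injectable PrEP best case", INJECTABLE, COST_LOW, IN_PERSON, PICKUP, ONE_WEEK),
    ("Injectable PrEP worst case", INJECTABLE, COST_HIGH, IN_PERSON, PICKUP, ONE_WEEK),
    ("Oral daily PrEP best case", DAILY_ORAL, COST_LOW, ONLINE, COURIER, SAME_DAY),
    ("Oral daily PrEP worst case", DAILY_ORAL, COST_HIGH, IN_PERSON, PICKUP, ONE_WEEK),
    ("On-demand PrEP best case", ON_DEMAND, COST_LOW, ONLINE, COURIER, SAME_DAY),
    ("On-demand PrEP worst case", ON_DEMAND, COST_HIGH, IN_PERSON, PICKUP, ONE_WEEK),
]


def build_scenarios(
    space: AttributeSpace,
    prohibitions: Sequence[Prohibition] | None = None,
    source: str | Path | None = None,
) -> list[Scenario]:
    """The six default best/worst-case programs, or scenarios from a YAML/JSON file.

    Every scenario is validated against the attribute space and prohibition
    set (default: injectable cannot be mailed).
    """
    if prohibitions is None:
        prohibitions = default_prohibitions()
    if source is None:
        scenarios = [
            Scenario(
                name,
                {DOSING: d, COST: c, CLINICIAN: ci, DISPENSING: v, BURDEN: b},
            )
            for name, d, c, ci, v, b in _DEFAULT_SCENARIOS
        ]
    else:
        payload = yaml.safe_load(Path(source).read_text())
        scenarios = [Scenario(item["name"], dict(item["levels"])) for item in payload]
    for s in scenarios:
        s.validate(space, prohibitions)
    return scenarios


def scenarios_to_yaml(scenarios: Sequence[Scenario], path: str | Path) -> None:
    payload = [{"name": s.name, "levels": dict(s.levels)} for s in scenarios]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---- simulation ---------------------------------------------------------------


def _program_utilities(
    estimate: UtilityEstimate, scenario: Scenario
) -> tuple[np.ndarray, np.ndarray]:
    """Raw-scale program and opt-out utilities per respondent."""
    space = estimate.coding.space
    x = estimate.coding.encode_concept(scenario.concept(space).levels)
    u = estimate.raw @ x
    none = estimate.raw[:, estimate.coding.none_col]
    return u, none


def _respondent_shares(
    estimate: UtilityEstimate, scenario: Scenario, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-respondent probability (in [0,1]) of choosing the program over None."""
    u, none = _program_utilities(estimate, scenario)
    if config.model == "first_choice":
        return np.where(u > none, 1.0, np.where(u == none, 0.5, 0.0))
    if config.model == "logit":
        m = np.maximum(u, none)
        eu, en = np.exp(u - m), np.exp(none - m)
        return eu / (eu + en)
    # rfc
    n, p = estimate.raw.shape
    coord_sd = estimate.raw.std(axis=0, ddof=1) if n > 1 else np.ones(p)
    attr_sd = config.attribute_error_scale * coord_sd
    x = estimate.coding.encode_concept(scenario.concept(estimate.coding.space).levels)
    none_col = estimate.coding.none_col
    wins = np.zeros(n)
    for _ in range(config.n_draws):
        noise = rng.normal(0.0, 1.0, size=(n, p)) * attr_sd[None, :]
        beta = estimate.raw + noise
        u_d = beta @ x
        none_d = beta[:, none_col]
        if config.product_error_scale > 0:
            gum = rng.gumbel(0.0, config.product_error_scale, size=(n, 2))
            u_d = u_d + gum[:, 0]
            none_d = none_d + gum[:, 1]
        wins += np.where(u_d > none_d, 1.0, np.where(u_d == none_d, 0.5, 0.0))
    return wins / config.n_draws


def simulate_shares(
    estimate: UtilityEstimate,
    scenarios: Sequence[Scenario],
    groups: np.ndarray | None = None,
    config: SimConfig = SimConfig(),
    group_names: dict | None = None,
) -> ShareReport:
    """Predict share of preference for each scenario versus the opt-out.

    Each scenario is simulated independently against None; per-group and
    overall percentages are reported.  Program share plus None share is
    exactly 100 per cell.  Deterministic given :attr:`SimConfig.seed`.
    """
    if not scenarios:
        raise ConfigurationError("no scenarios supplied")
    rng = np.random.default_rng(config.seed)
    rows = {}
    for s in scenarios:
        probs = _respondent_shares(estimate, s, config, rng)
        row = {"Total": 100.0 * probs.mean()}
        if groups is not None:
            garr = np.asarray(groups)
            for g in np.unique(garr):
                name = (group_names or {}).get(g, f"Group {g + 1}")
                row[name] = 100.0 * probs[garr == g].mean()
        rows[s.name] = row
    return ShareReport(shares=pd.DataFrame(rows).T, config=config)


def sensitivity_table(
    estimate: UtilityEstimate,
    base: Scenario,
    attribute: str,
    config: SimConfig = SimConfig(),
    prohibitions: Sequence[Prohibition] | None = None,
) -> pd.DataFrame:
    """Share sweep: swap each level of ``attribute`` into the base scenario.

    Levels whose substitution would violate a prohibition are reported with
    a NaN share and flagged.  All other base levels are held fixed.
    """
    space = estimate.coding.space
    if prohibitions is None:
        prohibitions = default_prohibitions()
    base.validate(space, prohibitions)
    attr = space.attributes[space.attr_index(attribute)]
    rows = []
    for lev in attr.levels:
        levels = dict(base.levels)
        levels[attribute] = lev
        variant = Scenario(f"{base.name} [{attribute}={lev}]", levels)
        try:
            variant.validate(space, prohibitions)
        except ConfigurationError:
            rows.append({"level": lev, "share": np.nan, "prohibited": True})
            continue
        report = simulate_shares(estimate, [variant], config=config)
        rows.append(
            {
                "level": lev,
                "share": float(report.shares.iloc[0]["Total"]),
                "prohibited": False,
            }
        )
    return pd.DataFrame(rows)
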