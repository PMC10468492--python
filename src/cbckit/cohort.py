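"""Synthetic respondent cohorts with a known preference-segment structure.

The default cohort emulates the kind of five-segment MSM population seen in
PrEP delivery preference research: 718 respondents split 125/188/115/86/204
across segments whose mean part-worth profiles range from strongly
injectable-preferring to cost-dominated to PrEP-averse.  Segment means are
specified on the zero-centered display scale and divided by ``logit_scale``
(default 50) to obtain raw logit-scale coefficients; respondent-level
heterogeneity is normal noise on the coded coefficients.

Because the generating coefficients are retained, downstream estimators can
be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import (
    BURDEN,
    CLINICIAN,
    COST,
    DISPENSING,
    DOSING,
    AttributeSpace,
    ConfigurationError,
    default_attributes,
)
from .coding import CodingMap
from .dataset import NONE_CHOICE, ChoiceDataset, concept_column
from .design import SurveyVersion


@dataclass(frozen=True)
class SegmentDefinition:
    """One preference segment: size, mean level utilities, opt-out constant.

    ``level_utilities`` maps attribute name to a sequence of per-level mean
    utilities on the zero-centered display scale; they must sum to (near)
    zero within each attribute and are re-centered exactly on construction.
    ``spread`` is the within-segment standard deviation per coded
    coefficient on the raw logit scale.
    """

    label: str
    size: int
    level_utilities: Mapping[str, tuple[float, ...]]
    none_utility: float
    spread: float = 0.5

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigurationError(f"segment {self.label!r} must have size >= 1")
        if self.spread < 0:
            raise ConfigurationError("spread must be nonnegative")
        centered = {}
        for attr, vals in self.level_utilities.items():
            vals = tuple(float(v) for v in vals)
            if abs(sum(vals)) > 0.5:
                raise ConfigurationError(
                    f"segment {self.label!r}, attribute {attr!r}: level utilities "
                    f"must sum to ~0, got {sum(vals):.2f}"
                )
            m = sum(vals) / len(vals)
            centered[attr] = tuple(v - m for v in vals)
        object.__setattr__(self, "level_utilities", centered)

    def mean_beta(self, coding: CodingMap, logit_scale: float) -> np.ndarray:
        """Coded raw-scale mean coefficient vector for this segment."""
        levels = []
        for attr in coding.space:
            if attr.name not in self.level_utilities:
                raise ConfigurationError(
                    f"segment {self.label!r} missing attribute {attr.name!r}"
                )
            vals = self.level_utilities[attr.name]
            if len(vals) != attr.n_levels:
                raise ConfigurationError(
                    f"segment {self.label!r}, attribute {attr.name!r}: "
                    f"{len(vals)} utilities for {attr.n_levels} levels"
                )
            levels.extend(vals)
        lev = np.asarray(levels) / logit_scale
        return coding.contract(lev, self.none_utility / logit_scale)


@dataclass
class TrueUtilityMatrix:
    """Generating truth: one raw coded coefficient vector per respondent."""

    beta: np.ndarray  # (n_resp, n_params) raw logit scale
    segment_labels: np.ndarray  # (n_resp,) segment index
    coding: CodingMap
    segment_names: list[str]

    @property
    def n_respondents(self) -> int:
        return self.beta.shape[0]

    def population_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)


@dataclass(frozen=True)
class ArtifactConfig:
    """Fractions of respondents receiving each data-quality artifact.

    The four artifact sets are drawn disjointly (a respondent carries at
    most one artifact), so injected counts equal the funnel's per-rule
    removals exactly.
    """

    speeder_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    straightliner_fraction: float = 0.0
    incomplete_fraction: float = 0.0
    speeder_threshold_minutes: float = 10.0

    def __post_init__(self) -> None:
        fracs = (
            self.speeder_fraction,
            self.duplicate_fraction,
            self.straightliner_fraction,
            self.incomplete_fraction,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigurationError("artifact fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ConfigurationError("artifact fractions must sum to <= 1")


# ---- default five-segment population ----------------------------------------

_SEGMENT_TABLE = [
    # label, size, dosing (inj, on-demand, daily), cost (high, low),
    # clinician (in-person, online, text), dispensing (courier, mail, pickup),
    # burden (same-day, one-week), none
    ("High risk, LAI PrEP", 125,
     (140.0, 49.0, -189.0), (-42.3, 42.3), (-1.4, 13.2, -11.8),
     (17.1, -11.9, -5.2), (15.5, -15.5), -321.3),
    ("At risk, affordable PrEP", 188,
     (31.5, 1.4, -32.9), (-171.0, 171.0), (1.0, 14.4, -15.5),
     (9.2, 2.0, -11.2), (19.4, -19.4), -388.6),
    ("High risk, no on-demand PrEP", 115,
     (128.0, -131.8, 3.8), (-64.6, 64.6), (2.9, 18.7, -21.5),
     (-3.3, 6.2, -2.9), (29.1, -29.1), -493.7),
    ("Low risk, no PrEP", 86,
     (-58.4, 80.1, -21.7), (-110.5, 110.5), (-4.1, 9.4, -5.3),
     (16.0, 8.1, -24.1), (41.0, -41.0), 282.4),
    ("High risk, on-demand PrEP", 204,
     (-110.1, 78.4, 31.7), (-64.5, 64.5), (-16.5, 23.4, -6.9),
     (33.3, 5.5, -38.8), (30.3, -30.3), -653.9),
]


def default_segments(spread: float = 0.5) -> list[SegmentDefinition]:
    """The five default preference segments (sizes 125/188/115/86/204, N=718)."""
    out = []
    for label, size, dosing, cost, clinician, dispensing, burden, none in _SEGMENT_TABLE:
        out.append(
            SegmentDefinition(
                label=label,
                size=size,
                level_utilities={
                    DOSING: dosing,
                    COST: cost,
                    CLINICIAN: clinician,
                    DISPENSING: dispensing,
                    BURDEN: burden,
                },
                none_utility=none,
                spread=spread,
            )
        )
    return out


# ---- operations ---------------------------------------------------------------


def make_population(
    segments: Sequence[SegmentDefinition],
    logit_scale: float = 50.0,
    seed: int = 0,
    space: AttributeSpace | None = None,
) -> TrueUtilityMatrix:
    """Draw respondent-level raw coefficients around segment means.

    Respondent i in segment k receives ``beta = mean_k / logit_scale +
    Normal(0, spread_k^2)`` independently per coded coefficient (including
    the opt-out constant).  Deterministic given ``seed``.
    """
    if logit_scale <= 0:
        raise ConfigurationError("logit_scale must be positive")
    if not segments:
        raise ConfigurationError("at least one segment required")
    space = space or default_attributes()
    coding = CodingMap(space, include_none=True)
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k, seg in enumerate(segments):
        mean = seg.mean_beta(coding, logit_scale)
        noise = rng.normal(0.0, seg.spread, size=(seg.size, coding.n_params))
        blocks.append(mean[None, :] + noise)
        labels.extend([k] * seg.size)
    return TrueUtilityMatrix(
        beta=np.vstack(blocks),
        segment_labels=np.asarray(labels),
        coding=coding,
        segment_names=[s.label for s in segments],
    )


def simulate_choices(
    population: TrueUtilityMatrix,
    design: Sequence[SurveyVersion],
    seed: int = 0,
) -> ChoiceDataset:
    """Simulate multinomial-logit choices for every respondent and task.

    Respondent i answers version ``i mod n_versions`` (deterministic
    cycling).  For each task the chosen alternative is drawn with
    probability proportional to ``exp(utility)``, where a concept's utility
    is the coded inner product with the respondent's coefficients and the
    opt-out's utility is the respondent's None constant.  Baseline
    completion times are drawn uniformly on [12, 25] minutes (clear of the
    default 10-minute speeder threshold) and origin identifiers are unique,
    so that data-quality artifacts are introduced only by
    :func:`inject_artifacts`.
    """
    coding = population.coding
    space = coding.space
    rng = np.random.default_rng(seed)
    n_resp = population.n_respondents
    n_versions = len(design)
    if n_versions == 0:
        raise ConfigurationError("design is empty")
    n_tasks = len(design[0].tasks)
    n_concepts = len(design[0].tasks[0].concepts)
    include_none = design[0].tasks[0].include_none

    # encode each version once: (n_tasks, n_alts, p) plus raw level indices
    n_alt = n_concepts + (1 if include_none else 0)
    enc = np.zeros((n_versions, n_tasks, n_alt, coding.n_params))
    lev = np.zeros((n_versions, n_tasks, n_concepts, len(space)), dtype=int)
    for v, version in enumerate(design):
        for t, task in enumerate(version.tasks):
            for c, concept in enumerate(task.concepts):
                enc[v, t, c] = coding.encode_concept(concept.levels)
                lev[v, t, c] = concept.levels
            if include_none:
                enc[v, t, -1] = coding.encode_none()

    version_of = np.arange(n_resp) % n_versions
    U = np.einsum("rtap,rp->rta", enc[version_of], population.beta)
    U -= U.max(axis=2, keepdims=True)
    P = np.exp(U)
    P /= P.sum(axis=2, keepdims=True)
    cum = P.cumsum(axis=2)
    draw = rng.random((n_resp, n_tasks, 1))
    chosen = (draw > cum).sum(axis=2)  # (n_resp, n_tasks) alternative index
    if include_none:
        chosen = np.where(chosen == n_alt - 1, NONE_CHOICE, chosen)

    rows = {
        "respondent_id": np.repeat(np.arange(n_resp), n_tasks),
        "task_index": np.tile(np.arange(n_tasks), n_resp),
        "chosen": chosen.reshape(-1).astype(float),
    }
    shown = lev[version_of]  # (n_resp, n_tasks, C, A)
    for c in range(n_concepts):
        for ai, name in enumerate(space.names):
            rows[concept_column(c, name)] = shown[:, :, c, ai].reshape(-1)
    tasks = pd.DataFrame(rows)

    respondents = pd.DataFrame(
        {
            "respondent_id": np.arange(n_resp),
            "version_id": version_of,
            "segment_truth": population.segment_labels,
            "completion_minutes": rng.uniform(12.0, 25.0, size=n_resp),
            "origin_id": [f"origin-{i:05d}" for i in range(n_resp)],
            "eligible": True,
        }
    )
    return ChoiceDataset(tasks, respondents, list(space.names), n_concepts, include_none)


def inject_artifacts(
    dataset: ChoiceDataset,
    config: ArtifactConfig,
    seed: int = 0,
    counts: Mapping[str, int] | None = None,
    candidates: Sequence | None = None,
) -> tuple[ChoiceDataset, dict[str, int]]:
    """Mark disjoint respondent subsets with data-quality artifacts.

    Returns a modified copy plus the count of respondents per artifact:
    speeders get completion times below the threshold; duplicates get the
    origin identifier of an untouched respondent; straight-liners answer
    the same alternative in every task; incompletes lose their trailing
    half of tasks.

    ``counts`` overrides the fraction-derived per-artifact counts (keys
    among speeder/duplicate/straightliner/incomplete), and ``candidates``
    restricts injection to the given respondent ids — together they allow
    constructing a funnel with exact, known removals.
    """
    out = dataset.copy()
    n = out.n_respondents
    rng = np.random.default_rng(seed)
    if counts is None:
        counts = {
            "speeder": int(round(config.speeder_fraction * n)),
            "duplicate": int(round(config.duplicate_fraction * n)),
            "straightliner": int(round(config.straightliner_fraction * n)),
            "incomplete": int(round(config.incomplete_fraction * n)),
        }
    else:
        counts = {
            k: int(counts.get(k, 0))
            for k in ("speeder", "duplicate", "straightliner", "incomplete")
        }
    if candidates is None:
        pool = np.arange(n)
    else:
        wanted = set(candidates)
        pool = np.flatnonzero(
            out.respondents["respondent_id"].isin(wanted).to_numpy()
        )
    total = sum(counts.values())
    if total > len(pool):
        raise ConfigurationError("artifact counts exceed the candidate pool size")
    perm = pool[rng.permutation(len(pool))]
    pos = 0
    sets = {}
    for name in ("speeder", "duplicate", "straightliner", "incomplete"):
        sets[name] = perm[pos : pos + counts[name]]
        pos += counts[name]
    touched = set(np.concatenate(list(sets.values())).tolist())
    clean = np.asarray([i for i in pool if i not in touched])

    resp = out.respondents
    rid = resp["respondent_id"].to_numpy()
    if counts["speeder"]:
        resp.loc[resp.index[sets["speeder"]], "completion_minutes"] = rng.uniform(
            2.0, config.speeder_threshold_minutes - 0.1, size=counts["speeder"]
        )
    if counts["duplicate"]:
        if len(clean) == 0:
            raise ConfigurationError("no untouched respondent left to duplicate")
        donors = rng.choice(clean, size=counts["duplicate"], replace=True)
        resp.loc[resp.index[sets["duplicate"]], "origin_id"] = (
            resp["origin_id"].to_numpy()[donors]
        )
    if counts["straightliner"]:
        ids = set(rid[sets["straightliner"]])
        mask = out.tasks["respondent_id"].isin(ids)
        out.tasks.loc[mask, "chosen"] = 0.0
    if counts["incomplete"]:
        ids = set(rid[sets["incomplete"]])
        n_tasks = int(out.tasks["task_index"].max()) + 1
        mask = out.tasks["respondent_id"].isin(ids) & (
            out.tasks["task_index"] >= n_tasks // 2
        )
        out.tasks.loc[mask, "chosen"] = np.nan
    return out, counts


def add_screenouts(dataset: ChoiceDataset, n: int, seed: int = 0) -> ChoiceDataset:
    """Append ``n`` ineligible respondents (metadata only, no task rows).

    Emulates survey entries that opened the survey but failed inclusion
    screening, so the funnel's opened/eligible accounting is exercisable.
    """
    out = dataset.copy()
    start = (
        int(pd.to_numeric(out.respondents["respondent_id"]).max()) + 1
        if len(out.respondents)
        else 0
    )
    rng = np.random.default_rng(seed)
    extra = pd.DataFrame(
        {
            "respondent_id": np.arange(start, start + n),
            "version_id": -1,
            "segment_truth": -1,
            "completion_minutes": rng.uniform(1.0, 5.0, size=n),
            "origin_id": [f"screenout-{i:05d}" for i in range(n)],
            "eligible": False,
        }
    )
    out.respondents = pd.concat([out.respondents, extra], ignore_index=True)
    return out
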