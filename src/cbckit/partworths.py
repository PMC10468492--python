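"""Zero-centered part-worth utilities and relative importance scores.

Raw coded coefficients live on the logit scale and are not comparable
across respondents (each respondent's scale depends on their choice
consistency).  The zero-centered-diffs transform expands coefficients to
all level utilities (which sum to zero within each attribute by effects
coding) and rescales each respondent so their mean within-attribute range
equals 100 — i.e. total range = 100 x number of attributes.  The same
multiplier is applied to the opt-out constant.

Relative importance (RIS) of an attribute is its utility range as a share
of the respondent's summed ranges, times 100; respondent-level RIS sums to
exactly 100, and group RIS tables are means of respondent RIS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import CodingMap
from .hb import PosteriorDraws


@dataclass
class UtilityEstimate:
    """Per-respondent raw and zero-centered part-worths plus importances."""

    raw: np.ndarray  # (n_resp, n_params) coded coefficients, logit scale
    levels_zc: np.ndarray  # (n_resp, total_levels) zero-centered utilities
    none_zc: np.ndarray  # (n_resp,)
    importance: np.ndarray  # (n_resp, n_attrs), rows sum to 100
    multiplier: np.ndarray  # (n_resp,)
    coding: CodingMap
    respondent_ids: np.ndarray

    @property
    def n_respondents(self) -> int:
        return self.raw.shape[0]

    def raw_levels(self) -> tuple[np.ndarray, np.ndarray]:
        """Raw-scale expanded level utilities and opt-out constants."""
        return self.coding.expand(self.raw)

    def utilities_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.levels_zc, columns=self.coding.level_labels()
        )
        df["none"] = self.none_zc
        df.insert(0, "respondent_id", self.respondent_ids)
        return df

    def importance_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.importance, columns=self.coding.space.names)
        df.insert(0, "respondent_id", self.respondent_ids)
        return df


def _attribute_ranges(levels: np.ndarray, coding: CodingMap) -> np.ndarray:
    """Within-attribute utility range per respondent: (n_resp, n_attrs)."""
    ranges = []
    pos = 0
    for attr in coding.space:
        block = levels[:, pos : pos + attr.n_levels]
        ranges.append(block.max(axis=1) - block.min(axis=1))
        pos += attr.n_levels
    return np.stack(ranges, axis=1)


def zero_center(
    source: PosteriorDraws | np.ndarray,
    coding: CodingMap,
    respondent_ids: np.ndarray | None = None,
) -> UtilityEstimate:
    """Compute zero-centered-diffs utilities and RIS from coefficients.

    ``source`` is either :class:`PosteriorDraws` (posterior-mean respondent
    coefficients are used) or a raw coefficient matrix of shape
    ``(n_resp, n_params)``.  All-flat respondents (zero total range) keep
    multiplier 1 and receive equal importances, with a warning.
    """
    if isinstance(source, PosteriorDraws):
        raw = source.beta_mean
        respondent_ids = source.respondent_ids
    else:
        raw = np.atleast_2d(np.asarray(source, dtype=float))
        if respondent_ids is None:
            respondent_ids = np.arange(raw.shape[0])
    levels, none = coding.expand(raw)
    ranges = _attribute_ranges(levels, coding)
    total_range = ranges.sum(axis=1)
    n_attrs = len(coding.space)

    flat = total_range == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} respondent(s) have all-flat utilities; "
            "multiplier set to 1 and importances split equally",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        multiplier = np.where(flat, 1.0, 100.0 * n_attrs / np.where(flat, 1.0, total_range))
    levels_zc = levels * multiplier[:, None]
    none_zc = none * multiplier
    importance = np.where(
        flat[:, None],
        100.0 / n_attrs,
        100.0 * ranges / np.where(flat, 1.0, total_range)[:, None],
    )
    return UtilityEstimate(
        raw=raw,
        levels_zc=levels_zc,
        none_zc=none_zc,
        importance=importance,
        multiplier=multiplier,
        coding=coding,
        respondent_ids=np.asarray(respondent_ids),
    )


def _group_means(
    values: np.ndarray,
    groups: np.ndarray | None,
    index: list[str],
    group_names: dict | None = None,
) -> pd.DataFrame:
    """Table with a Total column plus one column per group, means over rows."""
    cols = {"Total": values.mean(axis=0)}
    if groups is not None:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            name = (group_names or {}).get(g, f"Group {g + 1}" if np.issubdtype(type(g), np.integer) else str(g))
            cols[name] = values[groups == g].mean(axis=0)
    return pd.DataFrame(cols, index=index)


def importance_table(
    estimate: UtilityEstimate,
    groups: np.ndarray | None = None,
    group_names: dict | None = None,
) -> pd.DataFrame:
    """Mean relative importance (%) per attribute: Total plus per-group columns.

    Every column sums to 100 up to floating tolerance (before display
    rounding), since each respondent's RIS sums to 100 exactly.
    """
    return _group_means(
        estimate.importance, groups, estimate.coding.space.names, group_names
    )


def utilities_table(
    estimate: UtilityEstimate,
    groups: np.ndarray | None = None,
    group_names: dict | None = None,
) -> pd.DataFrame:
    """Mean zero-centered part-worths per level (plus a final None row)."""
    values = np.concatenate([estimate.levels_zc, estimate.none_zc[:, None]], axis=1)
    index = estimate.coding.level_labels() + ["None"]
    return _group_means(values, groups, index, group_names)
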