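"""Effects coding of concepts into multinomial-logit model matrices.

Each attribute with L levels occupies L-1 sum-to-zero columns: level j < L-1
maps to the j-th unit vector, and the last (reference) level maps to a row of
-1s, so that the implied level utilities sum to zero within every attribute.
The opt-out ("None") alternative is modeled as an alternative-specific
constant occupying one extra column; its level columns are all zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .attributes import AttributeSpace, ConfigurationError


@dataclass(frozen=True)
class CodingMap:
    """Mapping from (attribute, level) pairs to effects-coded columns.

    For the default 5-attribute space (level counts 3/2/3/3/2) this yields
    8 free level columns plus one None-constant column: 9 parameters.
    """

    space: AttributeSpace
    include_none: bool = True

    @property
    def n_level_params(self) -> int:
        return sum(n - 1 for n in self.space.level_counts)

    @property
    def n_params(self) -> int:
        return self.n_level_params + (1 if self.include_none else 0)

    @property
    def none_col(self) -> int:
        if not self.include_none:
            raise ConfigurationError("coding has no None column")
        return self.n_params - 1

    def attr_slices(self) -> list[slice]:
        """Column slice per attribute, in attribute order."""
        out, start = [], 0
        for n in self.space.level_counts:
            out.append(slice(start, start + n - 1))
            start += n - 1
        return out

    def column_labels(self) -> list[str]:
        labels = []
        for a in self.space:
            for lev in a.levels[:-1]:
                labels.append(f"{a.name}:{lev}")
        if self.include_none:
            labels.append("none")
        return labels

    def level_labels(self) -> list[str]:
        return [f"{a}:{lev}" for a, lev in self.space.level_labels()]

    def encode_concept(self, levels: Sequence[int]) -> np.ndarray:
        """Effects-coded row for one concept (one level index per attribute)."""
        if len(levels) != len(self.space):
            raise ConfigurationError(
                f"concept has {len(levels)} levels, expected {len(self.space)}"
            )
        row = np.zeros(self.n_params)
        for (attr, sl, lev) in zip(self.space, self.attr_slices(), levels):
            lev = int(lev)
            if not 0 <= lev < attr.n_levels:
                raise ConfigurationError(
                    f"level index {lev} out of range for attribute {attr.name!r}"
                )
            if lev < attr.n_levels - 1:
                row[sl.start + lev] = 1.0
            else:
                row[sl] = -1.0
        return row

    def encode_none(self) -> np.ndarray:
        row = np.zeros(self.n_params)
        row[self.none_col] = 1.0
        return row

    def decode_row(self, row: np.ndarray) -> tuple[int, ...]:
        """Invert :meth:`encode_concept` (exact for rows it produced)."""
        levels = []
        for attr, sl in zip(self.space, self.attr_slices()):
            block = row[sl]
            if np.all(block == -1.0):
                levels.append(attr.n_levels - 1)
            else:
                (idx,) = np.nonzero(block)
                levels.append(int(idx[0]))
        return tuple(levels)

    def expand(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Expand coded coefficients into all level utilities plus None.

        Parameters
        ----------
        beta
            Array of shape ``(..., n_params)`` of coded coefficients.

        Returns
        -------
        levels, none
            ``levels`` has shape ``(..., total_levels)`` holding one utility
            per attribute level (reference level = negative sum of its
            attribute's free coefficients, so utilities sum to zero within
            each attribute); ``none`` has shape ``(...,)``.
        """
        beta = np.asarray(beta, dtype=float)
        out = np.zeros(beta.shape[:-1] + (self.space.total_levels,))
        pos = 0
        for attr, sl in zip(self.space, self.attr_slices()):
            block = beta[..., sl]
            out[..., pos : pos + attr.n_levels - 1] = block
            out[..., pos + attr.n_levels - 1] = -block.sum(axis=-1)
            pos += attr.n_levels
        none = (
            beta[..., self.none_col]
            if self.include_none
            else np.zeros(beta.shape[:-1])
        )
        return out, none

    def contract(self, level_utilities: np.ndarray, none: np.ndarray | float = 0.0) -> np.ndarray:
        """Inverse of :meth:`expand` for within-attribute-centered utilities."""
        level_utilities = np.asarray(level_utilities, dtype=float)
        beta = np.zeros(level_utilities.shape[:-1] + (self.n_params,))
        pos = 0
        for attr, sl in zip(self.space, self.attr_slices()):
            beta[..., sl] = level_utilities[..., pos : pos + attr.n_levels - 1]
            pos += attr.n_levels
        if self.include_none:
            beta[..., self.none_col] = none
        return beta
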