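"""Long-format container for CBC choice data.

A :class:`ChoiceDataset` pairs a per-task table (one row per respondent x
choice task, with the shown concepts encoded as level-index columns and the
chosen alternative) with a per-respondent metadata table (survey version,
completion time, origin identifier, eligibility, and optionally the true
generating segment for synthetic cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .attributes import AttributeSpace, ConfigurationError

#: chosen-column sentinel for the opt-out alternative
NONE_CHOICE = -1

RESPONDENT_COLUMNS = [
    "respondent_id",
    "version_id",
    "segment_truth",
    "completion_minutes",
    "origin_id",
    "eligible",
]


def concept_column(concept_index: int, attr_name: str) -> str:
    return f"c{concept_index}_{attr_name}"


@dataclass
class ChoiceDataset:
    """Respondents x tasks x shown concepts x chosen alternative.

    Attributes
    ----------
    tasks
        One row per (respondent, task): ``respondent_id``, ``task_index``,
        ``chosen`` (concept index, ``-1`` for None, NaN for unanswered), and
        one ``c{j}_{attribute}`` level-index column per shown concept and
        attribute.
    respondents
        One row per respondent with survey metadata.
    attr_names
        Attribute order used by the concept columns.
    n_concepts
        Number of concepts shown per task (excluding None).
    include_none
        Whether tasks offered an opt-out alternative.
    """

    tasks: pd.DataFrame
    respondents: pd.DataFrame
    attr_names: list[str]
    n_concepts: int
    include_none: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in ("respondent_id", "task_index", "chosen") if c not in self.tasks]
        if missing:
            raise ConfigurationError(f"task table missing columns: {missing}")
        if "respondent_id" not in self.respondents:
            raise ConfigurationError("respondent table missing 'respondent_id'")

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    @property
    def n_alternatives(self) -> int:
        return self.n_concepts + (1 if self.include_none else 0)

    def concept_columns(self) -> list[str]:
        return [
            concept_column(j, a)
            for j in range(self.n_concepts)
            for a in self.attr_names
        ]

    def concept_levels(self) -> np.ndarray:
        """Shown levels as an int array of shape (n_tasks, n_concepts, n_attrs)."""
        arr = self.tasks[self.concept_columns()].to_numpy(dtype=int)
        return arr.reshape(len(self.tasks), self.n_concepts, len(self.attr_names))

    def copy(self) -> "ChoiceDataset":
        return ChoiceDataset(
            self.tasks.copy(),
            self.respondents.copy(),
            list(self.attr_names),
            self.n_concepts,
            self.include_none,
        )

    # ---- CSV round trip ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write a single long CSV with respondent metadata merged onto tasks.

        Respondents without any task rows (e.g. screened-out entries) are
        kept as metadata-only rows with a blank task_index.
        """
        merged = self.respondents.merge(self.tasks, on="respondent_id", how="left")
        merged.attrs = {}
        header = pd.DataFrame(
            {
                "attr_names": [",".join(self.attr_names)],
                "n_concepts": [self.n_concepts],
                "include_none": [int(self.include_none)],
            }
        )
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("#cbckit " + header.to_json(orient="records") + "\n")
            merged.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChoiceDataset":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#cbckit "):
                raise ConfigurationError(f"{path} is not a cbckit choice CSV")
            meta = pd.read_json(
                __import__("io").StringIO(first[len("#cbckit "):]), orient="records"
            ).iloc[0]
            merged = pd.read_csv(fh)
        attr_names = str(meta["attr_names"]).split(",")
        n_concepts = int(meta["n_concepts"])
        include_none = bool(meta["include_none"])
        resp_cols = [c for c in RESPONDENT_COLUMNS if c in merged.columns]
        respondents = merged[resp_cols].drop_duplicates("respondent_id").reset_index(drop=True)
        task_cols = ["respondent_id", "task_index", "chosen"] + [
            concept_column(j, a) for j in range(n_concepts) for a in attr_names
        ]
        tasks = merged.loc[merged["task_index"].notna(), task_cols].reset_index(drop=True)
        tasks["task_index"] = tasks["task_index"].astype(int)
        for j in range(n_concepts):
            for a in attr_names:
                tasks[concept_column(j, a)] = tasks[concept_column(j, a)].astype(int)
        return cls(tasks, respondents, attr_names, n_concepts, include_none)
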