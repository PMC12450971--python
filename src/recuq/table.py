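"""Feature-table container and CSV round-trip.

A cohort is a samples x features matrix whose column names carry a group
tag: one of four radiomic image series (``ct_pre``, ``ct_post``, ``pet_pre``,
``pet_post``) or the clinical group (``clin``), encoded as
``<group>__<feature>``. The binary label is 1 for local recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import TableFormatError

RADIOMIC_GROUPS: tuple[str, ...] = ("ct_pre", "ct_post", "pet_pre", "pet_post")
CLINICAL_GROUP = "clin"
ALL_GROUPS: tuple[str, ...] = RADIOMIC_GROUPS + (CLINICAL_GROUP,)

GROUP_SEP = "__"


def group_of(column: str) -> str:
    """Group tag of a ``<group>__<feature>`` column name."""
    head, sep, tail = column.partition(GROUP_SEP)
    if not sep or not tail:
        raise TableFormatError(f"column {column!r} lacks a '<group>__<feature>' tag")
    if head not in ALL_GROUPS:
        raise TableFormatError(f"column {column!r} has unknown group {head!r}")
    return head


@dataclass
class FeatureTable:
    """Immutable-by-convention cohort: values indexed by sample id, plus labels.

    ``values`` columns are ``<group>__<feature>`` names; ``labels`` shares the
    index and holds 0/1 integers (1 = local recurrence).
    """

    values: pd.DataFrame
    labels: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise TableFormatError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise TableFormatError("duplicate feature names")
        if not self.values.index.equals(self.labels.index):
            raise TableFormatError("values and labels index mismatch")
        if self.values.isna().any().any():
            raise TableFormatError("missing values in feature matrix")
        lab = self.labels.to_numpy()
        if not np.isin(lab, (0, 1)).all():
            bad = sorted(set(lab) - {0, 1})
            raise TableFormatError(f"labels must be 0/1, found {bad}")
        for col in self.values.columns:
            group_of(col)  # raises on malformed / unknown tags

    # -- views --------------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return pd.Series({c: group_of(c) for c in self.values.columns})

    @property
    def radiomic_columns(self) -> list[str]:
        return [c for c in self.values.columns if group_of(c) != CLINICAL_GROUP]

    @property
    def clinical_columns(self) -> list[str]:
        return [c for c in self.values.columns if group_of(c) == CLINICAL_GROUP]

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[sample_ids], self.labels.loc[sample_ids], dict(self.meta))

    # -- IO -----------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write sample_id, label, then feature columns."""
        out = self.values.copy()
        out.insert(0, "label", self.labels.astype(int))
        out.index.name = "sample_id"
        out.to_csv(path)

    def __eq__(self, other) -> bool:  # value equality, meta ignored
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.values.equals(other.values) and self.labels.equals(other.labels)


def read_feature_table(path) -> FeatureTable:
    """Read a cohort CSV (sample_id, label, ``<group>__<feature>`` columns).

    Raises :class:`TableFormatError` with a specific message on duplicate
    ids, non-binary labels, or malformed column tags.
    """
    frame = pd.read_csv(path)
    if frame.columns[0] != "sample_id" or frame.columns[1] != "label":
        raise TableFormatError(
            f"{path}: first two columns must be sample_id, label "
            f"(found {list(frame.columns[:2])})"
        )
    frame = frame.set_index("sample_id")
    labels = frame.pop("label")
    if not np.isin(labels.to_numpy(), (0, 1)).all():
        bad = sorted(set(labels) - {0, 1})
        raise TableFormatError(f"{path}: non-binary label values {bad}")
    return FeatureTable(frame, labels.astype(int))
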