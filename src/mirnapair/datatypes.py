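"""Core data containers shared across the package.

Expression values throughout are assumed to be normalized, log-scale
intensities; the package never normalizes raw arrays itself.  Missing
values are explicit (NaN in memory, ``NA`` on disk), never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_KINDS",
    "DISCRETE_VALUES",
    "ExpressionMatrix",
    "GroupDesign",
    "TargetPair",
    "DiscretizedProfile",
]

FEATURE_KINDS = ("miRNA", "mRNA")

#: Admissible discretized fold-change codes: -1 under-, 0 not, +1 overexpressed
#: in a condition relative to the reference.
DISCRETE_VALUES = (-1, 0, 1)


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log-scale expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique feature ids, columns by unique sample ids.
        Values are floats; NaN marks a missing measurement.
    feature_kind : {"miRNA", "mRNA"}
        What the rows measure.
    """

    data: pd.DataFrame
    feature_kind: str

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(
                f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite or missing (NA)")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GroupDesign:
    """Maps each sample to a biological condition and names the reference.

    ``reference`` may be None only for two-channel designs where every
    array is already a case-vs-reference contrast and no reference group
    exists among the samples.
    """

    sample_to_condition: dict[str, str]
    reference: str | None

    def __post_init__(self) -> None:
        if not self.sample_to_condition:
            raise ValueError("design maps no samples")
        labels = set(self.sample_to_condition.values())
        if self.reference is not None:
            if self.reference not in labels:
                raise ValueError(
                    f"reference condition {self.reference!r} has no samples in the design"
                )
            if labels == {self.reference}:
                raise ValueError("design needs at least one non-reference condition")

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance (reference included)."""
        seen: list[str] = []
        for cond in self.sample_to_condition.values():
            if cond not in seen:
                seen.append(cond)
        return seen

    @property
    def non_reference_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != self.reference]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.sample_to_condition.items() if c == condition]


@dataclass(frozen=True, order=True)
class TargetPair:
    """One putative miRNA -> mRNA targeting relationship (consumed, never predicted)."""

    mirna_id: str
    mrna_id: str

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.mrna_id:
            raise ValueError("both miRNA and mRNA ids must be non-empty")


@dataclass
class DiscretizedProfile:
    """Per-feature vectors of discretized fold-change calls across conditions.

    ``values`` is a Z x C integer matrix over {-1, 0, +1}: +1 means the
    feature is differentially expressed and overexpressed in that condition
    relative to the reference, -1 underexpressed, 0 not differentially
    expressed.
    """

    feature_ids: list[str]
    conditions: list[str]
    values: np.ndarray

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.feature_ids),
            len(self.conditions),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.conditions)} conditions"
            )
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in discretized profile")
        bad = set(np.unique(self.values)) - set(DISCRETE_VALUES)
        if bad:
            raise ValueError(f"discretized values must be in {DISCRETE_VALUES}; found {sorted(bad)}")
        self.values = self.values.astype(np.int8)
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    def vector(self, feature_id: str) -> np.ndarray:
        """The length-C discretized vector of one feature."""
        try:
            row = self._index[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in discretized profile") from None
        return self.values[row]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.conditions)
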