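"""Text I/O for expression matrices, designs, target-pair lists and results.

All formats are tab-separated text with ``.`` as the decimal separator and
``NA`` for missing values, matching common GEO matrix exports.  Feature
matching across studies is by exact id string; alias resolution is out of
scope.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .datatypes import DiscretizedProfile, ExpressionMatrix, GroupDesign, TargetPair

if TYPE_CHECKING:  # pragma: no cover
    from .selection import PairResult

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_design",
    "write_design",
    "read_target_pairs",
    "write_target_pairs",
    "read_discretized",
    "write_discretized",
    "build_master",
    "write_pair_results",
    "read_pair_results",
]

logger = logging.getLogger(__name__)

_MISSING = {"NA", "NaN", "nan", ""}


def _parse_cell(token: str, row_no: int, col_name: str, path: Path) -> float:
    if token in _MISSING:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric value {token!r} at row {row_no}, column {col_name!r}"
        ) from None


def read_expression_table(path: str | Path, feature_kind: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature id, header = sample ids).

    Missing cells (``NA`` or empty) are recorded as NaN, never as zero.
    Raises on duplicate feature ids (naming the id) and on non-numeric or
    ragged rows (naming row and column).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = header[1:]
        if not sample_ids:
            raise ValueError(f"{path}: header names no samples")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for row_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}: row {row_no} has {len(row) - 1} values, "
                    f"expected {len(sample_ids)}"
                )
            fid = row[0]
            if fid in seen:
                raise ValueError(f"{path}: duplicate feature id {fid!r}")
            seen.add(fid)
            feature_ids.append(fid)
            rows.append(
                [_parse_cell(tok, row_no, sample_ids[j], path) for j, tok in enumerate(row[1:])]
            )
    data = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(data=data, feature_kind=feature_kind)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


def read_design(path: str | Path, reference: str | None) -> GroupDesign:
    """Read a two-column (sample_id, condition) TSV design table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"sample_id", "condition"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: design table needs columns {sorted(expected)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids in design: {dupes}")
    mapping = dict(zip(df["sample_id"], df["condition"]))
    return GroupDesign(sample_to_condition=mapping, reference=reference)


def write_design(design: GroupDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": list(design.sample_to_condition),
            "condition": list(design.sample_to_condition.values()),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_target_pairs(path: str | Path) -> list[TargetPair]:
    """Read a two-column (miRNA id, gene id) pair list, TargetScan-style export.

    An optional header row (``mirna_id<TAB>mrna_id``, any case, or a line
    starting with ``#``) is skipped.  Pairs are deduplicated preserving the
    order of first occurrence.
    """
    path = Path(path)
    pairs: list[TargetPair] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(
                    f"{path}: row {row_no} has {len(cols)} columns, expected 2"
                )
            if row_no == 1 and [c.lower() for c in cols] in (
                ["mirna_id", "mrna_id"],
                ["mirna", "mrna"],
                ["mirna", "gene"],
            ):
                continue
            key = (cols[0], cols[1])
            if key not in seen:
                seen.add(key)
                pairs.append(TargetPair(mirna_id=cols[0], mrna_id=cols[1]))
    if not pairs:
        logger.warning("target-pair file %s contains no pairs", path)
    return pairs


def write_target_pairs(pairs: Iterable[TargetPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tmrna_id\n")
        for p in pairs:
            fh.write(f"{p.mirna_id}\t{p.mrna_id}\n")


def read_discretized(path: str | Path) -> DiscretizedProfile:
    """Read a discretized profile stored in the expression-matrix TSV layout."""
    matrix = read_expression_table(path, feature_kind="mRNA")
    values = matrix.values
    if np.isnan(values).any():
        raise ValueError(f"{path}: discretized profile may not contain missing values")
    ivals = values.astype(int)
    if not np.array_equal(ivals, values):
        raise ValueError(f"{path}: discretized profile must contain only -1, 0, +1")
    return DiscretizedProfile(
        feature_ids=matrix.feature_ids, conditions=matrix.sample_ids, values=ivals
    )


def write_discretized(profile: DiscretizedProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def build_master(
    disc_a: DiscretizedProfile, disc_b: DiscretizedProfile
) -> DiscretizedProfile:
    """Merge two studies' discretized profiles into one "Master" profile.

    Features are matched by exact id and retained only if present in both
    studies and dysregulated (nonzero) in at least one condition of the
    union; conditions are the concatenation of both studies' condition
    lists, which must be disjoint.
    """
    overlap = set(disc_a.conditions) & set(disc_b.conditions)
    if overlap:
        raise ValueError(
            f"condition labels overlap between studies: {sorted(overlap)}; "
            "relabel before merging"
        )
    shared = [f for f in disc_a.feature_ids if f in disc_b]
    conditions = list(disc_a.conditions) + list(disc_b.conditions)
    if not shared:
        return DiscretizedProfile(
            feature_ids=[], conditions=conditions, values=np.zeros((0, len(conditions)), int)
        )
    merged = np.hstack(
        [
            np.vstack([disc_a.vector(f) for f in shared]),
            np.vstack([disc_b.vector(f) for f in shared]),
        ]
    )
    keep = np.any(merged != 0, axis=1)
    return DiscretizedProfile(
        feature_ids=[f for f, k in zip(shared, keep) if k],
        conditions=conditions,
        values=merged[keep],
    )


def pair_results_frame(results: "Iterable[PairResult]") -> pd.DataFrame:
    """Tabulate pair results, sorted by adjusted p then pair ids (NA last)."""
    rows = []
    for r in results:
        rows.append(
            {
                "mirna_id": r.pair.mirna_id,
                "mrna_id": r.pair.mrna_id,
                "measure": r.measure,
                "statistic": r.statistic,
                "p": r.p_raw,
                "adj_p": r.p_adj,
                "significant": r.significant,
                "status": r.status,
                "direction_conditions": ",".join(r.direction_conditions),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "mrna_id",
            "measure",
            "statistic",
            "p",
            "adj_p",
            "significant",
            "status",
            "direction_conditions",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["adj_p", "mirna_id", "mrna_id"], kind="stable", na_position="last"
        ).reset_index(drop=True)
    return df


def write_pair_results(results: "Iterable[PairResult]", path: str | Path) -> None:
    pair_results_frame(results).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pair_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    df["direction_conditions"] = df["direction_conditions"].fillna("")
    return df
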