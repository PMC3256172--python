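"""Per-condition differential expression versus a reference, and discretization.

A feature is called differentially expressed (DE) in a condition when the
absolute difference in average log expression against the reference group
(the FC-value) exceeds ``fc_threshold`` *and* the Benjamini-Hochberg
adjusted p-value of a Welch two-sample t-test is below ``alpha``.  DE
calls are then discretized to {-1, 0, +1}: +1 = DE and overexpressed in
the condition relative to the reference, -1 = DE and underexpressed,
0 = not DE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DiscretizedProfile, ExpressionMatrix, GroupDesign

__all__ = ["DEResult", "de_test", "discretize", "de_feature_set", "de_results_frame"]


@dataclass
class DEResult:
    """One feature's DE call in one non-reference condition."""

    feature_id: str
    condition: str
    fc_value: float  # mean(condition) - mean(reference), log units
    p_raw: float
    p_adj: float
    is_de: bool


def de_test(
    expr: ExpressionMatrix,
    design: GroupDesign,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> list[DEResult]:
    """Welch-t DE test of every feature in every non-reference condition.

    Missing values are dropped per feature before computing group means; a
    feature with fewer than 2 observed values in either group gets
    ``p_raw = 1`` and is never called DE.  BH adjustment is applied across
    features within each condition.
    """
    if design.reference is None:
        raise ValueError("de_test requires a design with a named reference condition")
    ref_samples = [s for s in design.samples_of(design.reference) if s in expr.data.columns]
    if len(ref_samples) < 2:
        raise ValueError(
            f"reference condition {design.reference!r} has {len(ref_samples)} samples; need >= 2"
        )
    ref_vals = expr.data[ref_samples].to_numpy()

    results: list[DEResult] = []
    for condition in design.non_reference_conditions:
        cond_samples = [s for s in design.samples_of(condition) if s in expr.data.columns]
        if len(cond_samples) < 2:
            raise ValueError(
                f"condition {condition!r} has {len(cond_samples)} samples; need >= 2"
            )
        cond_vals = expr.data[cond_samples].to_numpy()

        n_ref = np.sum(~np.isnan(ref_vals), axis=1)
        n_cond = np.sum(~np.isnan(cond_vals), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fc = np.nanmean(cond_vals, axis=1) - np.nanmean(ref_vals, axis=1)
            res = stats.ttest_ind(
                cond_vals, ref_vals, axis=1, equal_var=False, nan_policy="omit"
            )
        p_raw = np.asarray(res.pvalue, dtype=float)
        # Underpowered or degenerate features (too few observations, zero
        # variance in both groups) cannot be called: p = 1.
        invalid = (n_ref < 2) | (n_cond < 2) | np.isnan(p_raw)
        p_raw[invalid] = 1.0
        fc = np.where((n_ref < 1) | (n_cond < 1), np.nan, fc)

        p_adj = multipletests(p_raw, method="fdr_bh")[1]
        is_de = (
            ~np.isnan(fc)
            & (np.abs(fc) > fc_threshold)
            & (p_adj < alpha)
            & ~invalid
        )
        for i, fid in enumerate(expr.feature_ids):
            results.append(
                DEResult(
                    feature_id=fid,
                    condition=condition,
                    fc_value=float(fc[i]) if not np.isnan(fc[i]) else float("nan"),
                    p_raw=float(p_raw[i]),
                    p_adj=float(min(p_adj[i], 1.0)),
                    is_de=bool(is_de[i]),
                )
            )
    return results


def discretize(de: list[DEResult]) -> DiscretizedProfile:
    """Map DE calls to the {-1, 0, +1} code, feature x condition.

    +1 iff DE with positive FC-value, -1 iff DE with negative FC-value,
    0 otherwise.  A DE call with FC exactly 0 is contradictory input.
    """
    features: list[str] = []
    conditions: list[str] = []
    for r in de:
        if r.feature_id not in features:
            features.append(r.feature_id)
        if r.condition not in conditions:
            conditions.append(r.condition)
    values = np.zeros((len(features), len(conditions)), dtype=np.int8)
    filled = np.zeros_like(values, dtype=bool)
    f_idx = {f: i for i, f in enumerate(features)}
    c_idx = {c: j for j, c in enumerate(conditions)}
    for r in de:
        i, j = f_idx[r.feature_id], c_idx[r.condition]
        if r.is_de:
            if r.fc_value == 0 or np.isnan(r.fc_value):
                raise ValueError(
                    f"feature {r.feature_id!r} in condition {r.condition!r} is flagged DE "
                    f"with FC-value {r.fc_value}; contradictory input"
                )
            values[i, j] = 1 if r.fc_value > 0 else -1
        filled[i, j] = True
    if not filled.all():
        missing = [
            (features[i], conditions[j]) for i, j in zip(*np.nonzero(~filled))
        ]
        raise ValueError(f"DE results do not cover all cells; missing {missing[:5]}")
    return DiscretizedProfile(feature_ids=features, conditions=conditions, values=values)


def de_feature_set(de: list[DEResult]) -> set[str]:
    """Features DE in at least one condition."""
    return {r.feature_id for r in de if r.is_de}


def de_results_frame(de: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "condition": r.condition,
                "fc_value": r.fc_value,
                "p": r.p_raw,
                "adj_p": r.p_adj,
                "is_de": r.is_de,
            }
            for r in de
        ],
        columns=["feature_id", "condition", "fc_value", "p", "adj_p", "is_de"],
    )
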