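"""Candidate-pair construction, direction filters, FDR correction, calls.

MicroRNAs repress their targets, so a genuine pair must change in
opposite directions: the unmatched-data filter requires at least one
condition where the discretized values are nonzero with opposite signs;
the matched-data filter requires the average CE-values of miRNA and mRNA
to have opposite signs.  Pairs failing a filter are reported with status
``filtered`` and are never tested, which keeps the multiplicity family
well defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datatypes import DiscretizedProfile, TargetPair

if TYPE_CHECKING:  # pragma: no cover
    from .md import CEProfile

__all__ = [
    "PairResult",
    "candidate_pairs",
    "ud_direction_filter",
    "md_direction_filter",
    "bh_adjust",
    "call_significant",
    "concordance",
]

logger = logging.getLogger(__name__)

STATUS_TESTED = "tested"
STATUS_FILTERED = "filtered"
STATUS_NOT_TESTABLE = "not_testable"


@dataclass
class PairResult:
    """Outcome of one association test for one miRNA:mRNA pair.

    ``statistic`` is measure-specific: the observed-table null probability
    for the unmatched measure, the observed slope for the matched measure,
    or the Pearson correlation for the comparator.
    """

    pair: TargetPair
    measure: str  # "UD", "MD" or "CORR"
    statistic: float
    p_raw: float
    p_adj: float = math.nan
    significant: bool = False
    direction_conditions: tuple[str, ...] = ()
    status: str = STATUS_TESTED
    detail: object | None = field(default=None, repr=False, compare=False)


def candidate_pairs(
    predictions: Iterable[TargetPair],
    de_mirnas: set[str],
    de_mrnas: set[str],
) -> list[TargetPair]:
    """Restrict predicted pairs to those whose both members are DE, order-stable."""
    out: list[TargetPair] = []
    seen: set[TargetPair] = set()
    for p in predictions:
        if p in seen:
            continue
        seen.add(p)
        if p.mirna_id in de_mirnas and p.mrna_id in de_mrnas:
            out.append(p)
    return out


def ud_direction_filter(
    pairs: Iterable[TargetPair],
    mirna_disc: DiscretizedProfile,
    mrna_disc: DiscretizedProfile,
) -> list[TargetPair]:
    """Keep pairs with >= 1 condition of nonzero, opposite-signed change."""
    kept = []
    for p in pairs:
        prod = mirna_disc.vector(p.mirna_id).astype(int) * mrna_disc.vector(p.mrna_id)
        if np.any(prod == -1):
            kept.append(p)
    return kept


def opposite_conditions(
    pair: TargetPair,
    mirna_disc: DiscretizedProfile,
    mrna_disc: DiscretizedProfile,
) -> tuple[str, ...]:
    """Condition labels where the pair's discretized values are opposite-signed."""
    prod = mirna_disc.vector(pair.mirna_id).astype(int) * mrna_disc.vector(pair.mrna_id)
    return tuple(c for c, v in zip(mirna_disc.conditions, prod) if v == -1)


def md_direction_filter(
    pairs: Iterable[TargetPair],
    mirna_ce: "CEProfile",
    mrna_ce: "CEProfile",
) -> list[TargetPair]:
    """Keep pairs whose average CE-values have strictly opposite signs.

    A feature with average CE exactly zero carries no direction and its
    pairs are dropped with a warning.
    """
    kept = []
    for p in pairs:
        m_mean = float(np.nanmean(mirna_ce.vector(p.mirna_id)))
        g_mean = float(np.nanmean(mrna_ce.vector(p.mrna_id)))
        if m_mean == 0 or g_mean == 0 or np.isnan(m_mean) or np.isnan(g_mean):
            logger.warning(
                "pair %s:%s dropped by direction filter: zero/undefined mean CE",
                p.mirna_id,
                p.mrna_id,
            )
            continue
        if np.sign(m_mean) * np.sign(g_mean) == -1:
            kept.append(p)
    return kept


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(results: list[PairResult], alpha: float = 0.05) -> list[PairResult]:
    """Set significance flags by the per-measure rule (strict ``adj p < alpha``).

    The matched-data measure additionally requires a negative observed
    slope.  Filtered / not-testable results are never significant.
    """
    n_sig = 0
    for r in results:
        if r.status != STATUS_TESTED or math.isnan(r.p_adj):
            r.significant = False
            continue
        ok = r.p_adj < alpha
        if r.measure == "MD":
            ok = ok and r.statistic < 0
        r.significant = ok
        n_sig += ok
    sig = [r for r in results if r.significant]
    logger.info(
        "significant pairs: %d (%d unique miRNAs, %d unique mRNAs) of %d results",
        n_sig,
        len({r.pair.mirna_id for r in sig}),
        len({r.pair.mrna_id for r in sig}),
        len(results),
    )
    return results


def concordance(
    results_a: Iterable[PairResult], results_b: Iterable[PairResult]
) -> dict[str, object]:
    """Overlap of the significant pair sets of two analyses."""
    set_a = {(r.pair.mirna_id, r.pair.mrna_id) for r in results_a if r.significant}
    set_b = {(r.pair.mirna_id, r.pair.mrna_id) for r in results_b if r.significant}
    shared = set_a & set_b
    return {
        "n_significant_a": len(set_a),
        "n_significant_b": len(set_b),
        "n_shared": len(shared),
        "only_a": sorted(set_a - set_b),
        "only_b": sorted(set_b - set_a),
        "shared": sorted(shared),
    }
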