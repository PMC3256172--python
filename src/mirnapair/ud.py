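"""Unmatched-data association measure.

For a miRNA:mRNA pair the C discretized fold-change values (one per
non-reference condition) populate a 3x3 contingency table whose cell
(r, c) counts the conditions where the miRNA takes value r and the mRNA
takes value c, r, c in {-1, 0, +1}.  The null hypothesis — a change in
mRNA expression is independent of a change in miRNA expression — is given
cell probabilities by resampling pseudo-mRNAs from the pooled discretized
mRNA matrix, and the observed table is scored with an exact multinomial
goodness-of-fit test (Pearson chi-square when C is large).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import comb, gammaln
from scipy.stats import chi2

from .datatypes import DISCRETE_VALUES, DiscretizedProfile, TargetPair
from .resampling import PermutationConfig, pseudo_profiles
from .selection import (
    STATUS_NOT_TESTABLE,
    STATUS_TESTED,
    PairResult,
    opposite_conditions,
)

__all__ = [
    "ContingencyTable3x3",
    "NullCellProbs",
    "build_contingency",
    "null_cell_probs",
    "exact_multinomial_pvalue",
    "chisq_pvalue",
    "ud_test_pair",
]

logger = logging.getLogger(__name__)

#: Largest number of 9-cell compositions enumerated exactly; beyond this the
#: exact test falls back to a Monte-Carlo multinomial p-value.
MAX_ENUMERATION = 5_000_000

#: Above this many conditions the Pearson chi-square approximation is used.
CHISQ_THRESHOLD = 15


@dataclass
class ContingencyTable3x3:
    """3x3 table of condition counts, rows = miRNA value, columns = mRNA value.

    Row/column order is (-1, 0, +1); ``counts[0, 0]`` is the number of
    conditions where both members are underexpressed.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3):
            raise ValueError(f"contingency table must be 3x3, got {self.counts.shape}")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.array_equal(self.counts, np.round(self.counts)) or np.any(
                self.counts < 0
            ):
                raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def total(self) -> int:
        """C, the number of conditions tallied."""
        return int(self.counts.sum())


@dataclass
class NullCellProbs:
    """Null probabilities for the nine table cells (same layout as the table)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape == (9,):
            self.probs = self.probs.reshape(3, 3)
        if self.probs.shape != (3, 3):
            raise ValueError("cell probabilities must have 9 entries")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("cell probabilities must lie in [0, 1]")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities sum to {self.probs.sum()}, not 1")


def build_contingency(mirna_vec, mrna_vec) -> ContingencyTable3x3:
    """Tally the 3x3 table from two length-C discretized vectors."""
    a = np.asarray(mirna_vec, dtype=int)
    b = np.asarray(mrna_vec, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vectors must be 1-d and equal length; got {a.shape}, {b.shape}")
    for name, v in (("miRNA", a), ("mRNA", b)):
        bad = set(np.unique(v)) - set(DISCRETE_VALUES)
        if bad:
            raise ValueError(f"{name} vector has values outside {DISCRETE_VALUES}: {sorted(bad)}")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (a + 1, b + 1), 1)
    return ContingencyTable3x3(counts=counts)


def null_cell_probs(
    mirna_vec,
    mrna_profile: DiscretizedProfile,
    cfg: PermutationConfig,
    rng: np.random.Generator | None = None,
) -> NullCellProbs:
    """Estimate the nine cell probabilities under independence.

    Pseudo-mRNAs are drawn from the pooled Z x C discretized mRNA matrix
    (see :func:`mirnapair.resampling.pseudo_profiles`), ``cfg.n_rep``
    tables are tallied against the fixed miRNA vector, and the pooled
    counts are normalized to a unit-sum probability vector (division by
    ``n_rep * C``, so the nine values form a distribution).
    """
    a = np.asarray(mirna_vec, dtype=int)
    if rng is None:
        rng = cfg.rng()
    pseudo = pseudo_profiles(mrna_profile.values, cfg.n_rep, rng)  # n_rep x C
    counts = np.zeros((3, 3), dtype=np.int64)
    for r in DISCRETE_VALUES:
        cols = a == r
        if not cols.any():
            continue
        sub = pseudo[:, cols]
        for c in DISCRETE_VALUES:
            counts[r + 1, c + 1] = int(np.count_nonzero(sub == c))
    probs = counts / counts.sum()
    return NullCellProbs(probs=probs / probs.sum())


@lru_cache(maxsize=8)
def _compositions(total: int, cells: int = 9) -> np.ndarray:
    """All weak compositions of ``total`` into ``cells`` parts (stars and bars)."""
    if cells == 1:
        return np.array([[total]], dtype=np.int64)
    bars = np.array(
        list(itertools.combinations(range(total + cells - 1), cells - 1)),
        dtype=np.int64,
    )
    first = bars[:, :1]
    mids = bars[:, 1:] - bars[:, :-1] - 1
    last = total + cells - 2 - bars[:, -1:]
    return np.hstack([first, mids, last])


def _log_multinomial_pmf(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Row-wise log multinomial pmf; cells with zero probability force -inf
    unless their count is zero."""
    counts = np.atleast_2d(counts)
    logp = np.full(probs.shape, -np.inf)
    pos = probs > 0
    logp[pos] = np.log(probs[pos])
    with np.errstate(invalid="ignore"):
        term = np.where(counts == 0, 0.0, counts * logp[None, :])
    return (
        gammaln(counts.sum(axis=1) + 1)
        - gammaln(counts + 1).sum(axis=1)
        + term.sum(axis=1)
    )


def exact_multinomial_pvalue(
    table: ContingencyTable3x3,
    probs: NullCellProbs,
    rng: np.random.Generator | None = None,
    max_enumeration: int = MAX_ENUMERATION,
    n_mc: int = 100_000,
) -> float:
    """Exact multinomial goodness-of-fit p-value for the observed table.

    p is the total probability of every 9-cell outcome with the same total
    whose multinomial probability is <= that of the observed table (ties
    included, with a small relative tolerance for float equality).  If the
    number of compositions exceeds ``max_enumeration`` a Monte-Carlo
    estimate with an add-one correction is returned instead.
    """
    flat_obs = table.counts.ravel()
    p = probs.probs.ravel()
    C = table.total
    if np.any((p == 0) & (flat_obs > 0)):
        logger.warning(
            "observed count in a zero-probability cell: impossible under the null, p = 0"
        )
        return 0.0
    if C == 0:
        return 1.0
    log_obs = _log_multinomial_pmf(flat_obs, p)[0]
    tol = 1e-9 + 1e-12 * abs(log_obs)
    n_comp = comb(C + 8, 8, exact=True)
    if n_comp <= max_enumeration:
        comps = _compositions(C, 9)
        lp = _log_multinomial_pmf(comps, p)
        mass = np.exp(lp[lp <= log_obs + tol]).sum()
        return float(min(mass, 1.0))
    if rng is None:
        rng = np.random.default_rng()
    draws = rng.multinomial(C, p, size=n_mc)
    lp = _log_multinomial_pmf(draws, p)
    hits = int(np.count_nonzero(lp <= log_obs + tol))
    p_mc = (1 + hits) / (1 + n_mc)
    se = math.sqrt(p_mc * (1 - p_mc) / n_mc)
    logger.warning(
        "composition count %d exceeds %d; Monte-Carlo p = %.4g (SE %.2g)",
        n_comp,
        max_enumeration,
        p_mc,
        se,
    )
    return float(p_mc)


def chisq_pvalue(table: ContingencyTable3x3, probs: NullCellProbs) -> float:
    """Pearson goodness-of-fit p-value over cells with positive null probability."""
    obs = table.counts.ravel().astype(float)
    p = probs.probs.ravel()
    C = table.total
    if C == 0:
        raise ValueError("empty table")
    if np.any((p == 0) & (obs > 0)):
        logger.warning(
            "observed count in a zero-probability cell: impossible under the null, p = 0"
        )
        return 0.0
    pos = p > 0
    expected = C * p[pos]
    stat = float(((obs[pos] - expected) ** 2 / expected).sum())
    df = int(pos.sum()) - 1
    if df <= 0:
        return 1.0
    return float(chi2.sf(stat, df))


def ud_test_pair(
    pair: TargetPair,
    mirna_profile: DiscretizedProfile,
    mrna_profile: DiscretizedProfile,
    cfg: PermutationConfig,
    rng: np.random.Generator | None = None,
    null_probs: NullCellProbs | None = None,
    chisq_threshold: int = CHISQ_THRESHOLD,
) -> PairResult:
    """Score one pair with the unmatched-data measure.

    Composes :func:`build_contingency`, :func:`null_cell_probs` (unless a
    precomputed per-miRNA ``null_probs`` is supplied) and the exact
    multinomial test, switching to the chi-square approximation when the
    number of conditions exceeds ``chisq_threshold``.  A pair whose two
    vectors are all zero is degenerate and flagged not-testable with p = 1.
    """
    if pair.mirna_id not in mirna_profile:
        raise KeyError(f"miRNA {pair.mirna_id!r} not in discretized profile")
    if pair.mrna_id not in mrna_profile:
        raise KeyError(f"mRNA {pair.mrna_id!r} not in discretized profile")
    a = mirna_profile.vector(pair.mirna_id)
    b = mrna_profile.vector(pair.mrna_id)
    direction = opposite_conditions(pair, mirna_profile, mrna_profile)
    if not np.any(a) and not np.any(b):
        return PairResult(
            pair=pair,
            measure="UD",
            statistic=float("nan"),
            p_raw=1.0,
            status=STATUS_NOT_TESTABLE,
            direction_conditions=direction,
        )
    if rng is None:
        rng = cfg.rng()
    table = build_contingency(a, b)
    if null_probs is None:
        null_probs = null_cell_probs(a, mrna_profile, cfg, rng=rng)
    if table.total > chisq_threshold:
        p = chisq_pvalue(table, null_probs)
    else:
        p = exact_multinomial_pvalue(table, null_probs, rng=rng)
    flat_obs = table.counts.ravel()
    pmf_obs = float(np.exp(_log_multinomial_pmf(flat_obs, null_probs.probs.ravel())[0]))
    return PairResult(
        pair=pair,
        measure="UD",
        statistic=pmf_obs,
        p_raw=float(p),
        status=STATUS_TESTED,
        direction_conditions=direction,
        detail=table,
    )
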