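"""Matched-data association measure.

For matched case/reference cohorts the change in expression (CE-value) of
sample i is its log expression minus the per-feature median over the
reference samples: x_i - v for a miRNA, y_i - u for an mRNA.  Medians are
used because, with very few reference samples, they are robust to
outliers.  The association of a pair is the slope of the no-intercept
least-squares fit of mRNA CE on miRNA CE,

    lambda = sum(x~_i * y~_i) / sum(x~_i^2),

i.e. the change in mRNA expression per unit change in miRNA expression.
Its null distribution comes from slopes against pseudo-mRNAs resampled
from the pooled mRNA CE matrix, and the p-value is the left-tail
Pr(lambda <= lambda_obs): a genuine target must be repressed, so only
strongly negative slopes count as evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GroupDesign, TargetPair
from .resampling import PermutationConfig, pseudo_profiles
from .selection import STATUS_NOT_TESTABLE, STATUS_TESTED, PairResult

__all__ = [
    "CEProfile",
    "LambdaResult",
    "compute_ce",
    "estimate_lambda",
    "md_null_lambdas",
    "md_pvalue",
    "md_test_pair",
    "correlation_comparator",
]

logger = logging.getLogger(__name__)


@dataclass
class CEProfile:
    """Per-sample changes in expression relative to the reference median.

    ``data`` is features x case samples.  ``ref_medians`` holds the
    per-feature reference median subtracted out (all zero for two-channel
    input, where each array already is a case-vs-reference contrast and
    ``n_ref`` is 0).
    """

    data: pd.DataFrame
    ref_medians: pd.Series
    n_ref: int
    n_biol: int
    condition: str | None = None

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_biol < 2:
            raise ValueError("need at least 2 case samples")
        if self.data.shape[1] != self.n_biol:
            raise ValueError("data column count does not match n_biol")
        self._index = {f: i for i, f in enumerate(self.data.index)}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    def vector(self, feature_id: str) -> np.ndarray:
        try:
            row = self._index[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in CE profile") from None
        return self.data.to_numpy()[row]


@dataclass
class LambdaResult:
    """Observed slope, its permutation null, and the resulting p-values."""

    lambda_obs: float
    null_lambdas: np.ndarray
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False


def compute_ce(
    expr: ExpressionMatrix,
    design: GroupDesign,
    condition: str,
    channel_mode: str = "single",
) -> CEProfile:
    """CE-values of one case condition.

    ``single``: subtract the per-feature median over the reference samples
    from every case sample.  ``two``: the matrix already holds CE-values
    (each array is a case-vs-reference contrast) and is passed through; a
    named reference group in the design is then contradictory.
    """
    if channel_mode not in ("single", "two"):
        raise ValueError("channel_mode must be 'single' or 'two'")
    case_samples = [s for s in design.samples_of(condition) if s in expr.data.columns]
    if len(case_samples) < 2:
        raise ValueError(f"condition {condition!r} has {len(case_samples)} samples; need >= 2")
    if channel_mode == "two":
        if design.reference is not None:
            raise ValueError(
                "two-channel data already encode the reference contrast; "
                "a named reference group is contradictory"
            )
        return CEProfile(
            data=expr.data[case_samples].copy(),
            ref_medians=pd.Series(0.0, index=expr.data.index),
            n_ref=0,
            n_biol=len(case_samples),
            condition=condition,
        )
    if design.reference is None:
        raise ValueError("single-channel data need a named reference condition")
    ref_samples = [s for s in design.samples_of(design.reference) if s in expr.data.columns]
    if len(ref_samples) < 1:
        raise ValueError("reference condition has no samples in the matrix")
    # mid-median convention: mean of the two central values for even counts
    medians = expr.data[ref_samples].median(axis=1)
    ce = expr.data[case_samples].sub(medians, axis=0)
    return CEProfile(
        data=ce,
        ref_medians=medians,
        n_ref=len(ref_samples),
        n_biol=len(case_samples),
        condition=condition,
    )


def estimate_lambda(mirna_ce, mrna_ce) -> float:
    """Least-squares slope through the origin of mRNA CE on miRNA CE."""
    x = np.asarray(mirna_ce, dtype=float)
    y = np.asarray(mrna_ce, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("CE vectors must be 1-d and equal length")
    if x.size < 2:
        raise ValueError("need at least 2 matched samples")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("miRNA CE vector is identically zero; slope undefined")
    return float(x @ y / sxx)


def md_null_lambdas(
    mirna_ce,
    mrna_ce_matrix: np.ndarray,
    cfg: PermutationConfig,
    rng: np.random.Generator | None = None,
    pseudo: np.ndarray | None = None,
) -> np.ndarray:
    """Null slopes of the miRNA against ``cfg.n_rep`` pseudo-mRNAs.

    The pseudo-mRNAs are resampled from the pooled Z x N_biol mRNA CE
    matrix exactly as in the unmatched measure.  A precomputed ``pseudo``
    matrix may be supplied so that several statistics (slope and
    correlation) are evaluated on identical nulls.
    """
    x = np.asarray(mirna_ce, dtype=float)
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("miRNA CE vector is identically zero; slope undefined")
    if pseudo is None:
        if rng is None:
            rng = cfg.rng()
        pseudo = pseudo_profiles(np.asarray(mrna_ce_matrix, dtype=float), cfg.n_rep, rng)
    return pseudo @ x / sxx


def md_pvalue(lambda_obs: float, null_lambdas) -> float:
    """Left-tail permutation p-value Pr(lambda <= lambda_obs), add-one corrected."""
    null_lambdas = np.asarray(null_lambdas, dtype=float)
    if null_lambdas.size == 0:
        raise ValueError("null distribution is empty")
    hits = int(np.count_nonzero(null_lambdas <= lambda_obs))
    return (1 + hits) / (1 + null_lambdas.size)


def md_test_pair(
    pair: TargetPair,
    mirna_ce: CEProfile,
    mrna_ce: CEProfile,
    cfg: PermutationConfig,
    rng: np.random.Generator | None = None,
    pseudo: np.ndarray | None = None,
) -> PairResult:
    """Score one pair with the matched-data measure (raw p only; BH and the
    final significance call happen across the tested family)."""
    if pair.mirna_id not in mirna_ce:
        raise KeyError(f"miRNA {pair.mirna_id!r} not in CE profile")
    if pair.mrna_id not in mrna_ce:
        raise KeyError(f"mRNA {pair.mrna_id!r} not in CE profile")
    x = mirna_ce.vector(pair.mirna_id)
    y = mrna_ce.vector(pair.mrna_id)
    lam = estimate_lambda(x, y)
    nulls = md_null_lambdas(x, mrna_ce.values, cfg, rng=rng, pseudo=pseudo)
    p = md_pvalue(lam, nulls)
    detail = LambdaResult(lambda_obs=lam, null_lambdas=nulls, p_raw=p)
    return PairResult(
        pair=pair,
        measure="MD",
        statistic=lam,
        p_raw=p,
        status=STATUS_TESTED,
        detail=detail,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(xc @ yc / denom)


def correlation_comparator(
    pair: TargetPair,
    mirna_ce: CEProfile,
    mrna_ce: CEProfile,
    cfg: PermutationConfig,
    rng: np.random.Generator | None = None,
    pseudo: np.ndarray | None = None,
) -> PairResult:
    """Permutation test on the Pearson correlation of the CE vectors.

    More-negative correlation means stronger repression-consistent
    association, so the p-value is the left tail against correlations with
    the same pseudo-mRNA nulls used for the slope test.  A zero-variance
    vector leaves the correlation undefined and the pair not-testable.
    """
    x = mirna_ce.vector(pair.mirna_id)
    y = mrna_ce.vector(pair.mrna_id)
    r_obs = _pearson(np.asarray(x, float), np.asarray(y, float))
    if np.isnan(r_obs):
        return PairResult(
            pair=pair,
            measure="CORR",
            statistic=float("nan"),
            p_raw=1.0,
            status=STATUS_NOT_TESTABLE,
        )
    if pseudo is None:
        if rng is None:
            rng = cfg.rng()
        pseudo = pseudo_profiles(mrna_ce.values, cfg.n_rep, rng)
    xf = np.asarray(x, dtype=float)
    xc = xf - xf.mean()
    pc = pseudo - pseudo.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (pc * pc).sum(axis=1))
    valid = denom > 0
    null_r = pc[valid] @ xc / denom[valid]
    if null_r.size == 0:
        return PairResult(
            pair=pair,
            measure="CORR",
            statistic=r_obs,
            p_raw=1.0,
            status=STATUS_NOT_TESTABLE,
        )
    p = (1 + int(np.count_nonzero(null_r <= r_obs))) / (1 + null_r.size)
    return PairResult(
        pair=pair, measure="CORR", statistic=r_obs, p_raw=p, status=STATUS_TESTED
    )
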