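"""Model/Results interface over the two association measures.

Usage mirrors the fit-then-inspect idiom of statistical modelling
packages::

    model = UnmatchedAssociation(mirna_disc, mrna_disc, pairs)
    res = model.fit(n_rep=10000, seed=1)
    print(res.summary())
    res.save("pairs.tsv")

Both models consume a candidate pair list, apply the measure-specific
direction filter, test the surviving pairs against resampled pseudo-mRNA
nulls, adjust p-values with Benjamini-Hochberg across the tested family,
and call significance at a strict ``adj p < alpha``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffexp as _diffexp
from .datatypes import DiscretizedProfile, ExpressionMatrix, GroupDesign, TargetPair
from .io import pair_results_frame, write_pair_results
from .md import CEProfile, compute_ce, correlation_comparator, md_test_pair
from .resampling import PermutationConfig, pseudo_profiles, spawn_rngs
from .selection import (
    STATUS_FILTERED,
    PairResult,
    bh_adjust,
    call_significant,
    md_direction_filter,
    opposite_conditions,
    ud_direction_filter,
)
from .ud import CHISQ_THRESHOLD, null_cell_probs, ud_test_pair

__all__ = [
    "UnmatchedAssociation",
    "MatchedAssociation",
    "AssociationResults",
    "MatchedAssociationResults",
]


def _unique_mirnas(pairs: list[TargetPair]) -> list[str]:
    seen: list[str] = []
    for p in pairs:
        if p.mirna_id not in seen:
            seen.append(p.mirna_id)
    return seen


def _apply_bh(results: list[PairResult], alpha: float) -> None:
    tested = [r for r in results if r.status == "tested"]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_adj = float(a)
            if r.detail is not None and hasattr(r.detail, "p_adj"):
                r.detail.p_adj = float(a)
    call_significant(results, alpha=alpha)
    for r in results:
        if r.detail is not None and hasattr(r.detail, "significant"):
            r.detail.significant = r.significant


class AssociationResults:
    """Container for per-pair test outcomes with a text summary."""

    _title = "miRNA-mRNA association"

    def __init__(self, results: list[PairResult], alpha: float, n_rep: int, seed):
        self.results = results
        self.alpha = alpha
        self.n_rep = n_rep
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        return pair_results_frame(self.results)

    @property
    def significant_pairs(self) -> list[TargetPair]:
        return [r.pair for r in self.results if r.significant]

    @property
    def n_tested(self) -> int:
        return sum(r.status == "tested" for r in self.results)

    def save(self, path) -> None:
        write_pair_results(self.results, path)

    def summary(self, top: int = 10) -> str:
        sig = [r for r in self.results if r.significant]
        lines = [
            self._title,
            "=" * len(self._title),
            f"candidate pairs:      {len(self.results)}",
            f"tested (post-filter): {self.n_tested}",
            f"significant (BH < {self.alpha:g}): {len(sig)}",
            f"unique miRNAs / mRNAs among significant: "
            f"{len({r.pair.mirna_id for r in sig})} / {len({r.pair.mrna_id for r in sig})}",
            f"permutation replicates: {self.n_rep}   seed: {self.seed}",
            "",
        ]
        frame = self.frame
        shown = frame[frame["status"] == "tested"].head(top)
        if len(shown):
            lines.append(shown.to_string(index=False))
        return "\n".join(lines)


class MatchedAssociationResults(AssociationResults):
    _title = "Matched-data miRNA-mRNA association (slope test)"

    def __init__(self, results, alpha, n_rep, seed, comparator_results=None):
        super().__init__(results, alpha, n_rep, seed)
        self.comparator_results: list[PairResult] | None = comparator_results

    @property
    def comparator_frame(self) -> pd.DataFrame | None:
        if self.comparator_results is None:
            return None
        return pair_results_frame(self.comparator_results)

    def plot_pair_null(self, pair: TargetPair, ax=None):
        """Histogram of the null slope distribution with the observed slope marked."""
        import matplotlib.pyplot as plt

        match = [r for r in self.results if r.pair == pair and r.detail is not None]
        if not match:
            raise KeyError(f"no tested result for pair {pair}")
        detail = match[0].detail
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(detail.null_lambdas, bins=50, color="0.7")
        ax.axvline(detail.lambda_obs, color="crimson", label=f"observed = {detail.lambda_obs:.3g}")
        ax.set_xlabel("null slope")
        ax.set_ylabel("count")
        ax.set_title(f"{pair.mirna_id}:{pair.mrna_id} (p = {match[0].p_raw:.3g})")
        ax.legend()
        return ax


class UnmatchedAssociation:
    """Unmatched-data association model over discretized profiles.

    Parameters
    ----------
    mirna_profile, mrna_profile : DiscretizedProfile
        Per-feature {-1, 0, +1} vectors over the same ordered conditions.
    pairs : list of TargetPair
        Candidate pairs (typically DE-restricted target predictions).
    alpha : float
        Significance level for the BH-adjusted calls.
    """

    def __init__(
        self,
        mirna_profile: DiscretizedProfile,
        mrna_profile: DiscretizedProfile,
        pairs: list[TargetPair],
        alpha: float = 0.05,
    ):
        if list(mirna_profile.conditions) != list(mrna_profile.conditions):
            raise ValueError("miRNA and mRNA profiles must share the same condition order")
        for p in pairs:
            if p.mirna_id not in mirna_profile:
                raise KeyError(f"miRNA {p.mirna_id!r} not in discretized profile")
            if p.mrna_id not in mrna_profile:
                raise KeyError(f"mRNA {p.mrna_id!r} not in discretized profile")
        self.mirna_profile = mirna_profile
        self.mrna_profile = mrna_profile
        self.pairs = list(pairs)
        self.alpha = alpha

    @classmethod
    def from_expression(
        cls,
        mirna_expr: ExpressionMatrix,
        mrna_expr: ExpressionMatrix,
        design: GroupDesign,
        predictions: list[TargetPair],
        fc_threshold: float = 1.5,
        de_alpha: float = 0.05,
        alpha: float = 0.05,
    ) -> "UnmatchedAssociation":
        """Run the DE + discretization preprocessing inline, restrict the
        predictions to pairs whose both members are DE somewhere, and build
        the model."""
        from .selection import candidate_pairs

        de_mi = _diffexp.de_test(mirna_expr, design, fc_threshold, de_alpha)
        de_m = _diffexp.de_test(mrna_expr, design, fc_threshold, de_alpha)
        pairs = candidate_pairs(
            predictions, _diffexp.de_feature_set(de_mi), _diffexp.de_feature_set(de_m)
        )
        return cls(
            _diffexp.discretize(de_mi), _diffexp.discretize(de_m), pairs, alpha=alpha
        )

    def fit(
        self,
        n_rep: int = 10000,
        seed: int | None = None,
        chisq_threshold: int = CHISQ_THRESHOLD,
    ) -> AssociationResults:
        cfg = PermutationConfig(n_rep=n_rep, seed=seed)
        tested_pairs = ud_direction_filter(self.pairs, self.mirna_profile, self.mrna_profile)
        tested_set = set(tested_pairs)
        mirnas = _unique_mirnas(tested_pairs)
        rngs = dict(zip(mirnas, spawn_rngs(seed, len(mirnas))))
        probs_cache = {}
        results: list[PairResult] = []
        for pair in self.pairs:
            if pair not in tested_set:
                results.append(
                    PairResult(
                        pair=pair,
                        measure="UD",
                        statistic=float("nan"),
                        p_raw=float("nan"),
                        status=STATUS_FILTERED,
                        direction_conditions=opposite_conditions(
                            pair, self.mirna_profile, self.mrna_profile
                        ),
                    )
                )
                continue
            mid = pair.mirna_id
            if mid not in probs_cache:
                probs_cache[mid] = null_cell_probs(
                    self.mirna_profile.vector(mid), self.mrna_profile, cfg, rng=rngs[mid]
                )
            results.append(
                ud_test_pair(
                    pair,
                    self.mirna_profile,
                    self.mrna_profile,
                    cfg,
                    rng=rngs[mid],
                    null_probs=probs_cache[mid],
                    chisq_threshold=chisq_threshold,
                )
            )
        _apply_bh(results, self.alpha)
        return AssociationResults(results, self.alpha, n_rep, seed)


class MatchedAssociation:
    """Matched-data association model over CE profiles of one case condition."""

    def __init__(
        self,
        mirna_ce: CEProfile,
        mrna_ce: CEProfile,
        pairs: list[TargetPair],
        alpha: float = 0.05,
    ):
        if list(mirna_ce.sample_ids) != list(mrna_ce.sample_ids):
            raise ValueError(
                "matched analysis requires identical case samples (same ids, same order) "
                "in the miRNA and mRNA CE profiles"
            )
        for p in pairs:
            if p.mirna_id not in mirna_ce:
                raise KeyError(f"miRNA {p.mirna_id!r} not in CE profile")
            if p.mrna_id not in mrna_ce:
                raise KeyError(f"mRNA {p.mrna_id!r} not in CE profile")
        self.mirna_ce = mirna_ce
        self.mrna_ce = mrna_ce
        self.pairs = list(pairs)
        self.alpha = alpha

    @classmethod
    def from_expression(
        cls,
        mirna_expr: ExpressionMatrix,
        mrna_expr: ExpressionMatrix,
        design: GroupDesign,
        condition: str,
        predictions: list[TargetPair],
        channel_mode: str = "single",
        alpha: float = 0.05,
    ) -> "MatchedAssociation":
        mirna_ce = compute_ce(mirna_expr, design, condition, channel_mode)
        mrna_ce = compute_ce(mrna_expr, design, condition, channel_mode)
        pairs = [
            p
            for p in dict.fromkeys(predictions)
            if p.mirna_id in mirna_ce and p.mrna_id in mrna_ce
        ]
        return cls(mirna_ce, mrna_ce, pairs, alpha=alpha)

    def fit(
        self,
        n_rep: int = 10000,
        seed: int | None = None,
        comparator: bool = False,
    ) -> MatchedAssociationResults:
        cfg = PermutationConfig(n_rep=n_rep, seed=seed)
        tested_pairs = set(md_direction_filter(self.pairs, self.mirna_ce, self.mrna_ce))
        mirnas = _unique_mirnas(self.pairs)
        rngs = dict(zip(mirnas, spawn_rngs(seed, len(mirnas))))
        # One pseudo-mRNA pool per miRNA, shared between the slope test and
        # the correlation comparator so both are judged on identical nulls.
        pseudo_cache: dict[str, np.ndarray] = {}

        def pseudo_for(mid: str) -> np.ndarray:
            if mid not in pseudo_cache:
                pseudo_cache[mid] = pseudo_profiles(
                    self.mrna_ce.values, cfg.n_rep, rngs[mid]
                )
            return pseudo_cache[mid]

        results: list[PairResult] = []
        comp_results: list[PairResult] | None = [] if comparator else None
        for pair in self.pairs:
            if pair in tested_pairs:
                results.append(
                    md_test_pair(
                        pair, self.mirna_ce, self.mrna_ce, cfg, pseudo=pseudo_for(pair.mirna_id)
                    )
                )
            else:
                results.append(
                    PairResult(
                        pair=pair,
                        measure="MD",
                        statistic=float("nan"),
                        p_raw=float("nan"),
                        status=STATUS_FILTERED,
                    )
                )
            if comp_results is not None:
                comp_results.append(
                    correlation_comparator(
                        pair, self.mirna_ce, self.mrna_ce, cfg, pseudo=pseudo_for(pair.mirna_id)
                    )
                )
        _apply_bh(results, self.alpha)
        if comp_results is not None:
            _apply_bh(comp_results, self.alpha)
        return MatchedAssociationResults(
            results, self.alpha, n_rep, seed, comparator_results=comp_results
        )
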