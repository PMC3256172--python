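"""Synthetic data with known ground truth for every pipeline stage.

Two generators are provided.  ``simulate_matched`` emulates a matched
case/reference cohort (the default shape, 3 reference vs 14 case samples
with 12 miRNAs and 326 mRNAs, mirrors a typical cytogenetically defined
myeloma subgroup cohort scaled down tenfold): planted target mRNAs follow
the generating model

    mRNA CE = lambda_true * miRNA CE + Gaussian(0, noise_sd)

while everything else is independent noise on log-scale expression.
``simulate_unmatched`` emulates multi-condition discretized profiles with
planted opposite-direction co-dysregulation against a sparse background.
All output is a deterministic function of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DiscretizedProfile, ExpressionMatrix, GroupDesign, TargetPair

__all__ = [
    "SimulationScenario",
    "PlantedPair",
    "SyntheticTruth",
    "simulate_matched",
    "simulate_unmatched",
    "simulate_matched_ce",
]

REFERENCE_LABEL = "healthy"
CASE_LABEL = "disease"


@dataclass
class SimulationScenario:
    """Knobs of the synthetic-data generators.

    Defaults mirror the cohort shapes the measures were designed for:
    3 reference / 14 case samples, 9 disease conditions, 12 miRNAs and
    326 mRNAs (a tenth of a typical combined-myeloma-study feature space),
    614 candidate pairs (the same tenth of the predicted-pair family),
    log2-scale baselines in [6, 12] with Gaussian noise.
    """

    n_mirna: int = 12
    n_mrna: int = 326
    n_ref: int = 3
    n_biol: int = 14
    conditions: int = 9
    n_candidate_pairs: int = 614
    n_planted: int = 6
    planted_pairs: list[tuple[TargetPair, float]] | None = None
    lambda_true: float = -1.0
    noise_sd: float = 0.2
    mirna_ce_sd: float = 1.0
    de_shift: float = 3.0
    background_nonzero_rate: float = 0.1
    min_opposite_conditions: int = 5
    baseline_range: tuple[float, float] = (6.0, 12.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.background_nonzero_rate <= 1:
            raise ValueError("background_nonzero_rate must lie in [0, 1]")
        if self.n_candidate_pairs > self.n_mirna * self.n_mrna:
            raise ValueError("more candidate pairs requested than distinct combinations")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        d = dict(d)
        if "planted_pairs" in d and d["planted_pairs"] is not None:
            d["planted_pairs"] = [
                (TargetPair(m, g), float(lam)) for m, g, lam in d["planted_pairs"]
            ]
        if "baseline_range" in d:
            d["baseline_range"] = tuple(d["baseline_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["planted_pairs"] is not None:
            d["planted_pairs"] = [
                [p.mirna_id, p.mrna_id, lam] for (p, lam) in self.planted_pairs
            ]
        d["baseline_range"] = list(d["baseline_range"])
        return d


@dataclass
class PlantedPair:
    """Ground truth for one planted pair."""

    pair: TargetPair
    lambda_true: float | None = None
    conditions: tuple[str, ...] = ()


@dataclass
class SyntheticTruth:
    """Everything the generators know that the pipeline must rediscover."""

    planted: list[PlantedPair]
    candidate_pairs: list[TargetPair]
    de_mirnas: set[str] = field(default_factory=set)
    de_mrnas: set[str] = field(default_factory=set)

    @property
    def planted_set(self) -> set[TargetPair]:
        return {p.pair for p in self.planted}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mirna_id": p.pair.mirna_id,
                    "mrna_id": p.pair.mrna_id,
                    "lambda_true": p.lambda_true if p.lambda_true is not None else "NA",
                    "conditions": ",".join(p.conditions),
                }
                for p in self.planted
            ],
            columns=["mirna_id", "mrna_id", "lambda_true", "conditions"],
        )


def _feature_ids(scenario: SimulationScenario) -> tuple[list[str], list[str]]:
    mirnas = [f"mir-{i:03d}" for i in range(1, scenario.n_mirna + 1)]
    mrnas = [f"gene-{i:04d}" for i in range(1, scenario.n_mrna + 1)]
    return mirnas, mrnas


def _pick_planted(
    scenario: SimulationScenario,
    mirnas: list[str],
    mrnas: list[str],
    rng: np.random.Generator,
) -> list[tuple[TargetPair, float]]:
    """Choose the planted pairs, each with a distinct miRNA and mRNA."""
    if scenario.planted_pairs is not None:
        known_m, known_g = set(mirnas), set(mrnas)
        for pair, _ in scenario.planted_pairs:
            if pair.mirna_id not in known_m or pair.mrna_id not in known_g:
                raise ValueError(f"planted pair {pair} references a missing feature")
        return list(scenario.planted_pairs)
    if scenario.n_planted > min(len(mirnas), len(mrnas)):
        raise ValueError(
            f"cannot plant {scenario.n_planted} pairs with distinct members among "
            f"{len(mirnas)} miRNAs and {len(mrnas)} mRNAs"
        )
    mi_pick = rng.permutation(len(mirnas))[: scenario.n_planted]
    g_pick = rng.permutation(len(mrnas))[: scenario.n_planted]
    return [
        (TargetPair(mirnas[i], mrnas[j]), scenario.lambda_true)
        for i, j in zip(mi_pick, g_pick)
    ]


def _candidate_pairs(
    scenario: SimulationScenario,
    mirnas: list[str],
    mrnas: list[str],
    planted: list[tuple[TargetPair, float]],
    rng: np.random.Generator,
) -> list[TargetPair]:
    """The planted pairs plus background pairs drawn from non-planted mRNAs.

    Planted mRNAs appear only in their own planted pair, so every
    background candidate is genuinely null under the per-miRNA null
    (its mRNA is exchangeable with the pool); planted miRNAs may still
    pair with background mRNAs.
    """
    planted_mrnas = {p.mrna_id for p, _ in planted}
    free_mrnas = [g for g in mrnas if g not in planted_mrnas]
    n_background = scenario.n_candidate_pairs - len(planted)
    if n_background < 0:
        raise ValueError("more planted pairs than candidate pairs")
    if n_background > len(mirnas) * len(free_mrnas):
        raise ValueError("more background candidates requested than distinct combinations")
    flat = rng.choice(len(mirnas) * len(free_mrnas), size=n_background, replace=False)
    background = [
        TargetPair(mirnas[k // len(free_mrnas)], free_mrnas[k % len(free_mrnas)])
        for k in flat
    ]
    candidates = [p for p, _ in planted] + background
    order = rng.permutation(len(candidates))
    return [candidates[k] for k in order]


def simulate_matched(
    scenario: SimulationScenario,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroupDesign, SyntheticTruth]:
    """Matched reference/case cohort obeying the slope model for planted pairs.

    Reference samples are baseline plus Gaussian noise.  Planted miRNAs are
    shifted by ``de_shift`` in cases (with sample-to-sample spread
    ``mirna_ce_sd``); their target mRNAs follow
    ``baseline + lambda_true * (miRNA CE) + noise``; all other features are
    independent noise around their baseline.
    """
    rng = np.random.default_rng(scenario.seed)
    mirnas, mrnas = _feature_ids(scenario)
    planted = _pick_planted(scenario, mirnas, mrnas, rng)
    candidates = _candidate_pairs(scenario, mirnas, mrnas, planted, rng)

    lo, hi = scenario.baseline_range
    base_mi = rng.uniform(lo, hi, size=scenario.n_mirna)
    base_m = rng.uniform(lo, hi, size=scenario.n_mrna)

    ref_ids = [f"ref_{i + 1}" for i in range(scenario.n_ref)]
    case_ids = [f"case_{i + 1}" for i in range(scenario.n_biol)]
    mi_ref = base_mi[:, None] + rng.normal(0, scenario.noise_sd, (scenario.n_mirna, scenario.n_ref))
    m_ref = base_m[:, None] + rng.normal(0, scenario.noise_sd, (scenario.n_mrna, scenario.n_ref))

    mi_case = base_mi[:, None] + rng.normal(
        0, scenario.noise_sd, (scenario.n_mirna, scenario.n_biol)
    )
    mi_index = {f: i for i, f in enumerate(mirnas)}
    planted_mirnas = {p.mirna_id for p, _ in planted}
    for mid in mirnas:
        if mid in planted_mirnas:
            i = mi_index[mid]
            mi_case[i] = base_mi[i] + scenario.de_shift + rng.normal(
                0, scenario.mirna_ce_sd, scenario.n_biol
            )

    m_case = base_m[:, None] + rng.normal(0, scenario.noise_sd, (scenario.n_mrna, scenario.n_biol))
    m_index = {f: i for i, f in enumerate(mrnas)}
    for pair, lam in planted:
        gi = m_index[pair.mrna_id]
        mi = mi_index[pair.mirna_id]
        ce_mi = mi_case[mi] - base_mi[mi]
        m_case[gi] = base_m[gi] + lam * ce_mi + rng.normal(0, scenario.noise_sd, scenario.n_biol)

    mirna_expr = ExpressionMatrix(
        data=pd.DataFrame(
            np.hstack([mi_ref, mi_case]), index=mirnas, columns=ref_ids + case_ids
        ),
        feature_kind="miRNA",
    )
    mrna_expr = ExpressionMatrix(
        data=pd.DataFrame(
            np.hstack([m_ref, m_case]), index=mrnas, columns=ref_ids + case_ids
        ),
        feature_kind="mRNA",
    )
    design = GroupDesign(
        sample_to_condition={
            **{s: REFERENCE_LABEL for s in ref_ids},
            **{s: CASE_LABEL for s in case_ids},
        },
        reference=REFERENCE_LABEL,
    )
    truth = SyntheticTruth(
        planted=[PlantedPair(pair=p, lambda_true=lam) for p, lam in planted],
        candidate_pairs=candidates,
        de_mirnas=set(planted_mirnas),
        de_mrnas={p.mrna_id for p, _ in planted},
    )
    return mirna_expr, mrna_expr, design, truth


def simulate_unmatched(
    scenario: SimulationScenario,
) -> tuple[DiscretizedProfile, DiscretizedProfile, SyntheticTruth]:
    """Multi-condition discretized profiles with planted co-dysregulation.

    Background entries are i.i.d. with ``P(nonzero) =
    background_nonzero_rate`` split evenly between -1 and +1.  Each
    planted pair receives opposite-signed nonzero values in a random
    subset of at least ``min_opposite_conditions`` conditions.
    """
    rng = np.random.default_rng(scenario.seed)
    mirnas, mrnas = _feature_ids(scenario)
    conditions = [f"cond_{i + 1}" for i in range(scenario.conditions)]
    rate = scenario.background_nonzero_rate
    p_draw = [rate / 2, 1 - rate, rate / 2]

    mi_vals = rng.choice([-1, 0, 1], size=(scenario.n_mirna, scenario.conditions), p=p_draw)
    m_vals = rng.choice([-1, 0, 1], size=(scenario.n_mrna, scenario.conditions), p=p_draw)

    planted = _pick_planted(scenario, mirnas, mrnas, rng)
    candidates = _candidate_pairs(scenario, mirnas, mrnas, planted, rng)

    mi_index = {f: i for i, f in enumerate(mirnas)}
    m_index = {f: i for i, f in enumerate(mrnas)}
    planted_truth: list[PlantedPair] = []
    for pair, _ in planted:
        k = int(rng.integers(scenario.min_opposite_conditions, scenario.conditions + 1))
        cond_idx = np.sort(rng.choice(scenario.conditions, size=k, replace=False))
        signs = rng.choice([-1, 1], size=k)
        mi_vals[mi_index[pair.mirna_id], cond_idx] = signs
        m_vals[m_index[pair.mrna_id], cond_idx] = -signs
        planted_truth.append(
            PlantedPair(pair=pair, conditions=tuple(conditions[j] for j in cond_idx))
        )

    mirna_disc = DiscretizedProfile(feature_ids=mirnas, conditions=conditions, values=mi_vals)
    mrna_disc = DiscretizedProfile(feature_ids=mrnas, conditions=conditions, values=m_vals)
    truth = SyntheticTruth(planted=planted_truth, candidate_pairs=candidates)
    return mirna_disc, mrna_disc, truth


def simulate_matched_ce(
    n_pairs: int,
    lambda_true: float,
    n_biol: int = 14,
    noise_sd: float = 0.2,
    mirna_ce_sd: float = 1.0,
    mirna_ce_shift: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CE-level shortcut: draw ``n_pairs`` (miRNA CE, mRNA CE) vector pairs
    straight from the slope model, bypassing baselines and medians.

    ``lambda_true = 0`` yields independent null pairs.  Returns two
    ``n_pairs x n_biol`` arrays.
    """
    rng = np.random.default_rng(seed)
    x = mirna_ce_shift + rng.normal(0, mirna_ce_sd, size=(n_pairs, n_biol))
    y = lambda_true * x + rng.normal(0, noise_sd, size=(n_pairs, n_biol))
    return x, y
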