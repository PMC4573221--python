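"""Differential abundance scoring between two biological states.

Three descriptive scores contrast each KO's abundance between the samples
of two states (no hypothesis tests, no multiplicity correction):

OR    odds-ratio score.  For KO k,

          OR_k = [ sum_{s in state1} A_sk / sum_{s in state1} sum_{i != k} A_si ]
               / [ sum_{s in state2} A_sk / sum_{s in state2} sum_{i != k} A_si ]

      on relative abundances A_sk, and the score is |log2 OR_k|.  A
      pseudocount (default 1e-6 on the relative scale) is added to every
      numerator and denominator sum so that KOs absent from one state stay
      finite; pseudocount 0 reproduces the bare formula, with infinite
      scores flagged.

RANK  within each sample KOs are ranked 1 = most abundant (average ranks on
      ties; zero-abundance KOs tie at the bottom); the score is the absolute
      difference of a KO's mean rank between the two states.

JSD   per-KO Jensen-Shannon divergence (base 2, hence in [0, 1]) between
      the Bernoulli distributions (p_k, 1-p_k) and (q_k, 1-q_k), where p_k
      and q_k are the KO's mean relative abundance in each state.

Direction is called relative to state1: "enriched" means more abundant in
state1.  A score at or below the threshold is called "unchanged".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .errors import NumericError, ValidationError
from .reference_model import MetabolicNetwork

logger = logging.getLogger(__name__)

ENRICHED, DEPLETED, UNCHANGED = "enriched", "depleted", "unchanged"

#: node colors in the exported differential network
COLORS = {ENRICHED: "#FF0000", DEPLETED: "#00AA00", UNCHANGED: "#CCCCCC"}

#: quantile of nonzero scores used when differential_analyze is given no
#: absolute threshold
DEFAULT_THRESHOLD_QUANTILE = 0.9


@dataclass
class DifferentialResult:
    """Per-KO differential scores for one method.

    ``raw`` holds the method-specific intermediates (odds ratios, mean-rank
    pairs, or the per-state mean abundances).  ``direction[k]`` is
    "unchanged" exactly when ``score[k] <= threshold_used``.
    """

    method: str
    state1: str
    state2: str
    ko_ids: list[str]
    scores: np.ndarray
    directions: list[str]
    raw: dict[str, np.ndarray] = field(default_factory=dict)
    threshold_used: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        data = {"score": self.scores, "direction": self.directions}
        for k, v in self.raw.items():
            data[k] = v
        return pd.DataFrame(data, index=self.ko_ids)

    def to_tsv(self, path: str | Path) -> None:
        out = self.to_frame()
        out.index.name = "ko"
        out.to_csv(path, sep="\t")

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.to_frame().sort_values("score", ascending=False).head(n)


def _state_rows(
    table: AbundanceTable, state1: str, state2: str
) -> tuple[list[int], list[int]]:
    idx1 = table.samples_in_state(state1)
    idx2 = table.samples_in_state(state2)
    if not idx1 or not idx2:
        raise ValidationError(
            f"each state needs >= 1 sample (got {len(idx1)} for {state1!r}, "
            f"{len(idx2)} for {state2!r})"
        )
    return idx1, idx2


def _directions(
    scores: np.ndarray, enriched_mask: np.ndarray, threshold: float
) -> list[str]:
    out = []
    for s, up in zip(scores, enriched_mask):
        if s <= threshold:
            out.append(UNCHANGED)
        else:
            out.append(ENRICHED if up else DEPLETED)
    return out


def score_or(
    table: AbundanceTable,
    state1: str,
    state2: str,
    pseudocount: float = 1e-6,
    threshold: float = 0.0,
) -> DifferentialResult:
    """Odds-ratio score |log2 OR_k| for every KO.

    Raises
    ------
    NumericError
        If a state has zero total abundance and ``pseudocount`` is 0.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    idx1, idx2 = _state_rows(table, state1, state2)
    R = table.relative
    sum1 = R[idx1].sum(axis=0)
    sum2 = R[idx2].sum(axis=0)
    if pseudocount == 0 and (sum1.sum() == 0 or sum2.sum() == 0):
        raise NumericError(
            "a state has zero total abundance; use a positive pseudocount"
        )
    # denominator for KO k: total state abundance over all other KOs
    den1 = sum1.sum() - sum1 + pseudocount
    den2 = sum2.sum() - sum2 + pseudocount
    num1 = sum1 + pseudocount
    num2 = sum2 + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        odds1 = num1 / den1
        odds2 = num2 / den2
        odds_ratio = odds1 / odds2
        log2_or = np.log2(odds_ratio)
    scores = np.abs(log2_or)
    infinite = ~np.isfinite(scores)
    if infinite.any():
        logger.warning(
            "%d KOs have an infinite OR score (zero in one state, pseudocount 0)",
            int(infinite.sum()),
        )
    directions = _directions(scores, odds_ratio > 1, threshold)
    return DifferentialResult(
        method="OR",
        state1=state1,
        state2=state2,
        ko_ids=list(table.ko_ids),
        scores=scores,
        directions=directions,
        raw={"odds_ratio": odds_ratio, "log2_or": log2_or},
        threshold_used=threshold,
    )


def score_rank(
    table: AbundanceTable,
    state1: str,
    state2: str,
    threshold: float = 0.0,
) -> DifferentialResult:
    """Mean-rank-difference score.

    Rank 1 is the most abundant KO in a sample; ties (including the block
    of zero-abundance KOs at the bottom) get the average of their ranks.
    Smaller mean rank in state1 than in state2 means enriched.
    """
    idx1, idx2 = _state_rows(table, state1, state2)
    R = table.relative
    ranks = np.vstack([stats.rankdata(-R[i], method="average") for i in range(R.shape[0])])
    mean1 = ranks[idx1].mean(axis=0)
    mean2 = ranks[idx2].mean(axis=0)
    scores = np.abs(mean1 - mean2)
    directions = _directions(scores, mean1 < mean2, threshold)
    return DifferentialResult(
        method="RANK",
        state1=state1,
        state2=state2,
        ko_ids=list(table.ko_ids),
        scores=scores,
        directions=directions,
        raw={"mean_rank_state1": mean1, "mean_rank_state2": mean2},
        threshold_used=threshold,
    )


def _entropy2(p: np.ndarray) -> np.ndarray:
    """Shannon entropy (base 2) of Bernoulli(p), with 0 log 0 = 0."""
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p * np.log2(p)) - ((1 - p) * np.log2(1 - p))
    return np.nan_to_num(h, nan=0.0)


def jensen_shannon_bernoulli(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Base-2 JSD between Bernoulli(p) and Bernoulli(q); bounded in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    jsd = _entropy2((p + q) / 2.0) - (_entropy2(p) + _entropy2(q)) / 2.0
    return np.clip(jsd, 0.0, 1.0)


def score_jsd(
    table: AbundanceTable,
    state1: str,
    state2: str,
    threshold: float = 0.0,
) -> DifferentialResult:
    """Per-KO Jensen-Shannon divergence score.

    Each KO's presence is summarized as a Bernoulli distribution over its
    mean relative abundance in a state; the score is the base-2 JSD between
    the two states' distributions, 0 iff the means agree and 1 at disjoint
    support.
    """
    idx1, idx2 = _state_rows(table, state1, state2)
    R = table.relative
    p = R[idx1].mean(axis=0)
    q = R[idx2].mean(axis=0)
    scores = jensen_shannon_bernoulli(p, q)
    directions = _directions(scores, p > q, threshold)
    return DifferentialResult(
        method="JSD",
        state1=state1,
        state2=state2,
        ko_ids=list(table.ko_ids),
        scores=scores,
        directions=directions,
        raw={"p_state1": p, "q_state2": q},
        threshold_used=threshold,
    )


_SCORERS = {"or": score_or, "rank": score_rank, "jsd": score_jsd}


def differential_analyze(
    ssns: Sequence[MetabolicNetwork],
    table: AbundanceTable,
    state_labels: Mapping[str, str],
    method: str = "or",
    threshold: float | None = None,
    pseudocount: float = 1e-6,
) -> tuple[MetabolicNetwork, DifferentialResult]:
    """Merge per-sample SSNs into a colored community-level network.

    The node set is the union of the SSN node sets and the edge set the
    union of their edges.  Every node is scored with the chosen method and
    colored red (#FF0000) when enriched in state1, green (#00AA00) when
    depleted, neutral grey otherwise.  ``state1``/``state2`` are the first
    two distinct labels of ``state_labels`` in insertion order.  When
    ``threshold`` is None it defaults to the 0.9 quantile of the nonzero
    finite scores (0 when every score is 0), so roughly the top decile of
    moving KOs gets a direction call.

    Raises
    ------
    ValidationError
        Unknown method, a state with no SSN, or SSNs of the wrong kind.
    """
    if method not in _SCORERS:
        raise ValidationError(f"unknown method {method!r}; expected or|rank|jsd")
    states: list[str] = []
    for s in state_labels.values():
        if s not in states:
            states.append(s)
    if len(states) != 2:
        raise ValidationError(
            f"need exactly 2 states in state_labels, got {states!r}"
        )
    state1, state2 = states

    for net in ssns:
        if net.kind != "ssn":
            raise ValidationError(f"expected SSNs, got kind={net.kind!r}")
    ssn_states = {state_labels.get(net.sample_id) for net in ssns}
    for st in (state1, state2):
        if st not in ssn_states:
            raise ValidationError(f"state {st!r} has no SSN")

    if method == "or":
        result = score_or(table, state1, state2, pseudocount=pseudocount, threshold=0.0)
    else:
        result = _SCORERS[method](table, state1, state2, threshold=0.0)

    finite_nonzero = result.scores[np.isfinite(result.scores) & (result.scores > 0)]
    if threshold is None:
        threshold = (
            float(np.quantile(finite_nonzero, DEFAULT_THRESHOLD_QUANTILE))
            if finite_nonzero.size
            else 0.0
        )
    # re-call directions under the resolved threshold (zero scores stay unchanged)
    up = np.array([d == ENRICHED for d in result.directions])
    result.directions = _directions(result.scores, up, threshold)
    result.threshold_used = threshold

    union = nx.DiGraph()
    for net in ssns:
        union.add_nodes_from(net.graph.nodes)
        union.add_edges_from(net.graph.edges)
    score_of = dict(zip(result.ko_ids, result.scores))
    dir_of = dict(zip(result.ko_ids, result.directions))
    for n in union.nodes:
        d = dir_of.get(n, UNCHANGED)
        union.nodes[n]["score"] = float(score_of.get(n, 0.0))
        union.nodes[n]["direction"] = d
        union.nodes[n]["color"] = COLORS[d]
    net = MetabolicNetwork(graph=union, kind="differential")
    return net, result
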