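"""Scoring inferred networks against ground truth.

Link recovery is treated as binary classification over all ordered
off-diagonal node pairs (self-pairs are excluded: self-coupling is a
dynamical parameter, not a link).  Precision, recall and specificity are
TP/(TP+FP), TP/(TP+FN) and TN/(TN+FP); ratios with a zero denominator are
reported as missing and excluded from cross-run averages.

The coupling-lag error compares, on correctly recalled links, the
representative inferred lag to the true lag, normalized by the mean
absolute difference of two independent uniform draws from the lag range —
so 1.0 is chance level and 0 is exact recovery.

The empty-network protocol validates the per-target false-positive rate:
with no true links every inferred source is a false positive, and the
fraction of targets with any inferred source should match the nominal
test level, within the sampling band of a Binomial(N, alpha) average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binom

from .greedy import InferenceSettings, NetworkResult, infer_network
from .synthetic import GroundTruthNetwork, NoiseSpec, generate_network, simulate_var

__all__ = [
    "ConfusionCounts",
    "ScoreReport",
    "confusion_counts",
    "scores",
    "expected_random_lag_error",
    "relative_lag_error",
    "score_inference",
    "binomial_fpr_band",
    "empty_network_fpr_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Link-classification counts over the N(N-1) ordered off-diagonal pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ScoreReport:
    """Classification scores; None marks an undefined (0/0) ratio."""

    precision: float | None
    recall: float | None
    specificity: float | None
    lag_error: float | None = None


def _as_adjacency(network, n: int | None = None) -> np.ndarray:
    if isinstance(network, NetworkResult):
        return network.adjacency()
    if isinstance(network, GroundTruthNetwork):
        return network.adjacency
    return np.asarray(network, dtype=bool)


def confusion_counts(inferred, truth) -> ConfusionCounts:
    """Compare two directed networks link by link, ignoring lags."""
    inf = _as_adjacency(inferred)
    tru = _as_adjacency(truth)
    if inf.shape != tru.shape:
        raise ValueError(
            f"node mismatch: inferred {inf.shape[0]} vs truth {tru.shape[0]}"
        )
    off = ~np.eye(inf.shape[0], dtype=bool)
    i, t = inf[off], tru[off]
    return ConfusionCounts(
        tp=int(np.sum(i & t)),
        fp=int(np.sum(i & ~t)),
        tn=int(np.sum(~i & ~t)),
        fn=int(np.sum(~i & t)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def scores(counts: ConfusionCounts) -> ScoreReport:
    """Precision, recall and specificity from confusion counts."""
    return ScoreReport(
        precision=_ratio(counts.tp, counts.tp + counts.fp),
        recall=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
    )


def expected_random_lag_error(lag_range=(1, 2, 3, 4, 5)) -> float:
    """Mean |l1 - l2| of two i.i.d. uniform draws from the lag range."""
    lags = np.asarray(list(lag_range))
    return float(np.abs(lags[:, None] - lags[None, :]).mean())


def relative_lag_error(
    inferred: NetworkResult,
    truth: GroundTruthNetwork,
    lag_range=(1, 2, 3, 4, 5),
) -> float | None:
    """Mean absolute lag error on recalled links, relative to chance.

    Uses one representative inferred lag per link (the selected variable
    with the largest final conditional contribution); returns None when no
    true link was recalled.
    """
    inferred_lags = inferred.representative_lags()
    adj = inferred.adjacency() & truth.adjacency
    if not adj.any():
        return None
    errors = np.abs(inferred_lags[adj] - truth.lags[adj])
    return float(errors.mean() / expected_random_lag_error(lag_range))


def score_inference(
    inferred: NetworkResult,
    truth: GroundTruthNetwork,
    lag_range=(1, 2, 3, 4, 5),
) -> ScoreReport:
    """Full scorecard of one inference run against its ground truth."""
    report = scores(confusion_counts(inferred, truth))
    return replace(report, lag_error=relative_lag_error(inferred, truth, lag_range))


def binomial_fpr_band(
    n_nodes: int,
    alpha: float,
    n_repeats: int,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> tuple[float, float]:
    """Percentile band of the mean per-target FPR under the null.

    The experiment averages X_j / N over ``n_repeats`` independent runs
    with X_j ~ Binomial(N, alpha); the sum of the X_j is
    Binomial(N * n_repeats, alpha), so the band is exact.
    """
    total = n_nodes * n_repeats
    lo, hi = (
        float(binom.ppf(p / 100.0, total, alpha)) / total for p in percentiles
    )
    return lo, hi


def empty_network_fpr_experiment(
    n_list,
    t: int,
    alpha_list,
    n_repeats: int,
    settings: InferenceSettings | None = None,
    seed: int | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Per-target false-positive rate on empty networks (complete null).

    For each (N, alpha) cell, simulates VAR dynamics on a linkless network
    (each node an independent AR(1)) ``n_repeats`` times, runs the full
    per-target inference, and reports the mean fraction of targets with at
    least one inferred source next to the exact 5th-95th percentile band
    of the matching binomial average.  The network-level FDR stage is
    disabled: the protocol validates the per-target test level itself.
    """
    if settings is None:
        settings = InferenceSettings()
    base = replace(settings, q_fdr=None)
    rows = []
    for n_nodes, alpha in product(n_list, alpha_list):
        cell = replace(base, alpha=alpha)
        ss = np.random.SeedSequence(
            entropy=seed if seed is not None else 0,
            spawn_key=(n_nodes, int(round(alpha * 1_000_000))),
        )
        rates = []
        for rep, child in enumerate(ss.spawn(n_repeats)):
            sim_seed, inf_seed = (int(s) for s in child.generate_state(2) >> 1)
            net = generate_network(n_nodes, p=0.0, seed=sim_seed)
            if net.n_links:
                raise ValueError("ground truth must be empty for this protocol")
            data = simulate_var(net, t, seed=sim_seed, noise=noise)
            result = infer_network(data, replace(cell, seed=inf_seed))
            flagged = sum(
                1
                for r in result.targets.values()
                if r.selected_sources and r.source_set_accepted
            )
            rates.append(flagged / n_nodes)
        lo, hi = binomial_fpr_band(n_nodes, alpha, n_repeats)
        rows.append(
            {
                "n_nodes": n_nodes,
                "alpha": alpha,
                "t": t,
                "n_repeats": n_repeats,
                "fpr": float(np.mean(rates)),
                "band_low": lo,
                "band_high": hi,
            }
        )
    return pd.DataFrame(rows)
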