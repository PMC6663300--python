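"""Greedy multivariate transfer-entropy network inference.

For each target process the algorithm proceeds in four steps:

1. *Target-past selection* — greedily pick lagged variables of the target
   itself that maximize I(C; Y_t | selected), i.e., optimize the target's
   active information storage, so that self-prediction is accounted for
   before any source is considered.
2. *Source selection* — greedily pick lagged source variables maximizing
   the conditional transfer-entropy contribution
   I(C; Y_t | target past, selected sources).  Conditioning on already
   selected sources blocks redundant candidates (common drivers,
   pathways) and exposes synergies.
3. *Pruning* — re-examine each selected source variable in the context of
   the final set and drop those whose contribution is no longer
   significant (minimum statistic test).
4. *Omnibus test* — test the collective transfer entropy
   T* = I(all selected sources; Y_t | target past); the source set is
   accepted only if every test passed, and the omnibus p-value feeds the
   network-level FDR correction across targets.

Steps 1 and 2 use the maximum statistic test at each iteration to control
the family-wise error rate over the comparisons across candidates; the
adaptive stopping condition is the first non-significant maximum.

Targets are analyzed independently (identical results whether run
serially or in parallel); per-target random streams are spawned
deterministically from the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .data import Candidate, Embedding, TimeSeriesData
from .estimators import (
    gaussian_cmi,
    gaussian_cmi_from_cov,
    gaussian_null_cdf,
    ksg_cmi,
)
from .stats import (
    TestResult,
    fdr_combine_targets,
    max_statistic_test,
    min_statistic_test,
    omnibus_test,
)
from .surrogates import SurrogateScheme, permute_column

log = logging.getLogger("mtenet.greedy")

__all__ = [
    "InferenceSettings",
    "SelectedVariable",
    "TargetInferenceResult",
    "Link",
    "NetworkResult",
    "select_target_past",
    "select_source_past",
    "prune_sources",
    "infer_target",
    "infer_network",
]


@dataclass(frozen=True)
class InferenceSettings:
    """Configuration of one inference run.

    ``alpha`` is used for the maximum, minimum and omnibus tests alike.
    ``analytic_null`` defaults to True for the Gaussian estimator (the
    chi-squared null replaces the surrogate loop) and is unavailable for
    the nearest-neighbor estimator.  ``q_fdr`` is the network-level
    Benjamini-Hochberg level; None disables the FDR stage.
    """

    l_target: int = 5
    l_sources: int = 5
    alpha: float = 0.001
    n_surrogates: int = 1000
    estimator: str = "gaussian"
    k: int = 4
    analytic_null: bool | None = None
    surrogate_mode: str = "shuffle_embedded_samples"
    seed: int | None = None
    q_fdr: float | None = 0.05

    def __post_init__(self) -> None:
        if self.l_target < 1 or self.l_sources < 1:
            raise ValueError("l_target and l_sources must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.estimator not in ("gaussian", "ksg"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.analytic_null and self.estimator != "gaussian":
            raise ValueError("analytic nulls are only available for gaussian")
        if not self.use_analytic_null and self.n_surrogates <= 1.0 / self.alpha:
            raise ValueError(
                f"need n_surrogates > 1/alpha = {1.0 / self.alpha:.0f} "
                f"for the empirical null, got {self.n_surrogates}"
            )

    @property
    def use_analytic_null(self) -> bool:
        if self.analytic_null is None:
            return self.estimator == "gaussian"
        return self.analytic_null

    @property
    def max_lag(self) -> int:
        return max(self.l_target, self.l_sources)


@dataclass(frozen=True)
class SelectedVariable:
    """One accepted embedded variable with its selection-time statistics.

    ``cmi`` is the conditional contribution at the iteration the variable
    was accepted; ``final_cmi`` (source variables only) is the
    contribution in the context of the full post-pruning set.
    """

    candidate: Candidate
    cmi: float
    p_value: float
    final_cmi: float | None = None


@dataclass
class TargetInferenceResult:
    """Outcome of the four inference steps for one target."""

    target: int
    selected_target_past: list[SelectedVariable]
    selected_sources: list[SelectedVariable]
    removed_in_pruning: list[SelectedVariable]
    omnibus_te: float | None
    omnibus_p: float | None
    source_set_accepted: bool
    n_effective: int

    def source_processes(self) -> list[int]:
        return sorted({v.candidate.process for v in self.selected_sources})


@dataclass(frozen=True)
class Link:
    """Directed link assembled from a target's selected source variables.

    ``lags`` collects every selected lag of the source process;
    ``representative_lag`` is the lag of the variable with the largest
    final conditional contribution.  ``te`` and ``p`` are the target-level
    collective transfer entropy and omnibus p-value.
    """

    source: int
    target: int
    lags: tuple[int, ...]
    representative_lag: int
    te: float
    p: float


@dataclass
class NetworkResult:
    """Per-target results plus the FDR-filtered directed network."""

    n_processes: int
    settings: InferenceSettings
    targets: dict[int, TargetInferenceResult]
    fdr_kept: dict[int, bool] = field(default_factory=dict)

    @property
    def links(self) -> list[Link]:
        out: list[Link] = []
        for t in sorted(self.targets):
            res = self.targets[t]
            if not res.selected_sources or not res.source_set_accepted:
                continue
            if self.fdr_kept and not self.fdr_kept.get(t, True):
                continue
            by_proc: dict[int, list[SelectedVariable]] = {}
            for v in res.selected_sources:
                by_proc.setdefault(v.candidate.process, []).append(v)
            for s in sorted(by_proc):
                variables = by_proc[s]
                best = max(
                    variables,
                    key=lambda v: (
                        v.final_cmi if v.final_cmi is not None else v.cmi
                    ),
                )
                out.append(
                    Link(
                        source=s,
                        target=t,
                        lags=tuple(sorted(v.candidate.lag for v in variables)),
                        representative_lag=best.candidate.lag,
                        te=res.omnibus_te,
                        p=res.omnibus_p,
                    )
                )
        return out

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n_processes, self.n_processes), dtype=bool)
        for link in self.links:
            adj[link.source, link.target] = True
        return adj

    def representative_lags(self) -> np.ndarray:
        lags = np.zeros((self.n_processes, self.n_processes), dtype=int)
        for link in self.links:
            lags[link.source, link.target] = link.representative_lag
        return lags


def _target_rng(settings: InferenceSettings, target: int) -> np.random.Generator:
    """Deterministic per-target stream, independent of execution order."""
    entropy = settings.seed if settings.seed is not None else 0
    return np.random.default_rng(
        np.random.SeedSequence(entropy=entropy, spawn_key=(target,))
    )


class _TargetEngine:
    """Estimation context for one target: embedding, columns, null models."""

    def __init__(
        self,
        data: TimeSeriesData,
        target: int,
        settings: InferenceSettings,
        workspace: "_GaussianWorkspace | None" = None,
    ):
        if not 0 <= target < data.n_processes:
            raise ValueError(f"target {target} out of range")
        self.settings = settings
        self.target = target
        self.embedding = Embedding(data, settings.max_lag)
        self.m = self.embedding.n_effective
        self.rng = _target_rng(settings, target)
        self.scheme = SurrogateScheme(
            mode=settings.surrogate_mode,
            rng_seed=int(self.rng.integers(2**31)),
        )
        if not settings.use_analytic_null:
            self.scheme.validate(data.n_replications, settings.n_surrogates)
        self.ws = workspace
        if settings.estimator == "gaussian" and workspace is None:
            self.ws = _GaussianWorkspace(self.embedding)
        # one fixed jitter seed per target keeps the KSG path deterministic
        self.tie_seed = int(self.rng.integers(2**31))
        self.y = self.embedding.present(target)

    # --- single-variable CMI ------------------------------------------------

    def cmi(self, cand: Candidate, conditioning: Sequence[Candidate]) -> float:
        if self.settings.estimator == "gaussian":
            return self.ws.cmi([cand], self.target, conditioning)
        x = self.embedding.column(cand)
        z = self.embedding.columns(list(conditioning))
        return ksg_cmi(
            x, self.y, z if z.shape[1] else None,
            k=self.settings.k, seed=self.tie_seed,
        ).value

    def joint_cmi(
        self, cands: Sequence[Candidate], conditioning: Sequence[Candidate]
    ) -> float:
        if self.settings.estimator == "gaussian":
            return self.ws.cmi(list(cands), self.target, conditioning)
        x = self.embedding.columns(list(cands))
        z = self.embedding.columns(list(conditioning))
        return ksg_cmi(
            x, self.y, z if z.shape[1] else None,
            k=self.settings.k, seed=self.tie_seed,
        ).value

    def _column_cmi(self, x: np.ndarray, z: np.ndarray) -> float:
        """CMI of an explicit (possibly permuted) column against the target."""
        if self.settings.estimator == "gaussian":
            return gaussian_cmi(x, self.y, z if z.shape[1] else None).value
        return ksg_cmi(
            x, self.y, z if z.shape[1] else None,
            k=self.settings.k, seed=self.tie_seed,
        ).value

    # --- null models --------------------------------------------------------

    def null_cdf(self, dim_x: int = 1):
        return lambda v: gaussian_null_cdf(v, self.m, dim_x=dim_x)

    def surrogate_matrix(
        self,
        candidates: Sequence[Candidate],
        conditionings: Sequence[Sequence[Candidate]],
    ) -> np.ndarray:
        """(n, S) surrogate CMIs; candidate j is permuted, its conditioning fixed."""
        S = self.settings.n_surrogates
        out = np.empty((len(candidates), S))
        slices = self.embedding.replication_slices
        for j, (cand, cond) in enumerate(zip(candidates, conditionings)):
            col = self.embedding.column(cand)
            z = self.embedding.columns(list(cond))
            for s in range(S):
                perm = permute_column(col, slices, self.scheme.mode, self.rng)
                out[j, s] = self._column_cmi(perm, z)
        return out

    def omnibus_surrogates(
        self,
        sources: Sequence[Candidate],
        conditioning: Sequence[Candidate],
    ) -> np.ndarray:
        """Surrogate T* values: all source rows permuted jointly."""
        S = self.settings.n_surrogates
        X = self.embedding.columns(list(sources))
        z = self.embedding.columns(list(conditioning))
        slices = self.embedding.replication_slices
        out = np.empty(S)
        for s in range(S):
            idx = permute_column(
                np.arange(self.m), slices, self.scheme.mode, self.rng
            )
            Xp = X[idx]
            if self.settings.estimator == "gaussian":
                out[s] = gaussian_cmi(
                    Xp, self.y, z if z.shape[1] else None
                ).value
            else:
                out[s] = ksg_cmi(
                    Xp, self.y, z if z.shape[1] else None,
                    k=self.settings.k, seed=self.tie_seed,
                ).value
        return out


class _GaussianWorkspace:
    """Precomputed covariance of every embedded column of a recording.

    All Gaussian CMI values for any target reduce to log-determinants of
    submatrices of one (N * (max_lag + 1))-dimensional sample covariance,
    which is computed once and shared across targets.
    """

    def __init__(self, embedding: Embedding):
        self.embedding = embedding
        n = embedding.data.n_processes
        L = embedding.max_lag
        self.index = {
            (p, lag): p * (L + 1) + lag for p in range(n) for lag in range(L + 1)
        }
        cols = np.column_stack(
            [
                embedding.column(Candidate(p, lag))
                for p in range(n)
                for lag in range(L + 1)
            ]
        )
        centred = cols - cols.mean(axis=0)
        self.cov = centred.T @ centred / cols.shape[0]

    def cmi(
        self,
        x_cands: Sequence[Candidate],
        target: int,
        z_cands: Sequence[Candidate],
    ) -> float:
        ix = [self.index[(c.process, c.lag)] for c in x_cands]
        iy = [self.index[(target, 0)]]
        iz = [self.index[(c.process, c.lag)] for c in z_cands]
        return gaussian_cmi_from_cov(self.cov, ix, iy, iz)


def _greedy_select(
    engine: _TargetEngine,
    candidates: list[Candidate],
    conditioning_base: list[Candidate],
) -> list[SelectedVariable]:
    """Shared loop of steps 1 and 2: argmax + maximum statistic test.

    Ties in the maximum break toward the lowest process index, then the
    smallest lag (the candidate list is kept sorted and argmax takes the
    first maximum).
    """
    settings = engine.settings
    remaining = sorted(candidates)
    selected: list[SelectedVariable] = []
    while remaining:
        cond = conditioning_base + [v.candidate for v in selected]
        stats = np.array([engine.cmi(c, cond) for c in remaining])
        if settings.use_analytic_null:
            result, _ = max_statistic_test(
                stats, settings.alpha, null_cdf=engine.null_cdf()
            )
        else:
            surr = engine.surrogate_matrix(
                remaining, [cond] * len(remaining)
            )
            result, _ = max_statistic_test(
                stats, settings.alpha, surrogate_stats=surr
            )
        best = int(np.argmax(stats))
        log.info(
            "target %d: candidate (%d, lag %d) max CMI %.6f nats, p=%.4g%s",
            engine.target,
            remaining[best].process,
            remaining[best].lag,
            result.statistic,
            result.p_value,
            "" if result.significant else " (stop)",
        )
        if not result.significant:
            break
        selected.append(
            SelectedVariable(
                candidate=remaining.pop(best),
                cmi=float(stats[best]),
                p_value=result.p_value,
            )
        )
    return selected


def select_target_past(
    data: TimeSeriesData, target: int, settings: InferenceSettings
) -> list[SelectedVariable]:
    """Step 1: greedy nonuniform embedding of the target's own past."""
    engine = _TargetEngine(data, target, settings)
    return _select_target_past(engine)


def _select_target_past(engine: _TargetEngine) -> list[SelectedVariable]:
    candidates = [
        Candidate(engine.target, lag)
        for lag in range(1, engine.settings.l_target + 1)
    ]
    return _greedy_select(engine, candidates, [])


def select_source_past(
    data: TimeSeriesData,
    target: int,
    selected_target_past: Sequence[SelectedVariable],
    settings: InferenceSettings,
) -> list[SelectedVariable]:
    """Step 2: greedy selection of source past variables given step 1."""
    engine = _TargetEngine(data, target, settings)
    return _select_source_past(engine, list(selected_target_past))


def _select_source_past(
    engine: _TargetEngine, selected_target_past: list[SelectedVariable]
) -> list[SelectedVariable]:
    candidates = [
        Candidate(p, lag)
        for p in range(engine.embedding.data.n_processes)
        if p != engine.target
        for lag in range(1, engine.settings.l_sources + 1)
    ]
    base = [v.candidate for v in selected_target_past]
    return _greedy_select(engine, candidates, base)


def prune_sources(
    data: TimeSeriesData,
    target: int,
    selected_target_past: Sequence[SelectedVariable],
    selected_sources: Sequence[SelectedVariable],
    settings: InferenceSettings,
) -> tuple[list[SelectedVariable], list[SelectedVariable]]:
    """Step 3: remove source variables made redundant by later selections.

    Returns (retained, removed); retained variables carry their final
    conditional contribution.
    """
    engine = _TargetEngine(data, target, settings)
    return _prune_sources(engine, list(selected_target_past), list(selected_sources))


def _prune_sources(
    engine: _TargetEngine,
    selected_target_past: list[SelectedVariable],
    selected_sources: list[SelectedVariable],
) -> tuple[list[SelectedVariable], list[SelectedVariable]]:
    settings = engine.settings
    base = [v.candidate for v in selected_target_past]
    current = list(selected_sources)
    removed: list[SelectedVariable] = []
    final_stats: np.ndarray | None = None
    while current:
        # sorted evaluation order makes the argmin tie-break deterministic
        current.sort(key=lambda v: v.candidate)
        conds = [
            base + [w.candidate for w in current if w is not v]
            for v in current
        ]
        stats = np.array(
            [engine.cmi(v.candidate, cond) for v, cond in zip(current, conds)]
        )
        if settings.use_analytic_null:
            result, _ = min_statistic_test(
                stats, settings.alpha, null_cdf=engine.null_cdf()
            )
        else:
            surr = engine.surrogate_matrix(
                [v.candidate for v in current], conds
            )
            result, _ = min_statistic_test(
                stats, settings.alpha, surrogate_stats=surr
            )
        worst = int(np.argmin(stats))
        log.info(
            "target %d: pruning min contribution (%d, lag %d) %.6f nats, "
            "p=%.4g%s",
            engine.target,
            current[worst].candidate.process,
            current[worst].candidate.lag,
            result.statistic,
            result.p_value,
            " (keep all)" if result.significant else " (remove)",
        )
        if result.significant:
            final_stats = stats
            break
        removed.append(current.pop(worst))
        final_stats = None
    retained = [
        replace(v, final_cmi=float(s))
        for v, s in zip(current, final_stats if final_stats is not None else [])
    ]
    return retained, removed


def infer_target(
    data: TimeSeriesData,
    target: int,
    settings: InferenceSettings,
    _workspace: "_GaussianWorkspace | None" = None,
) -> TargetInferenceResult:
    """Run the four inference steps for one target process."""
    engine = _TargetEngine(data, target, settings, workspace=_workspace)
    selected_t = _select_target_past(engine)
    selected_s = _select_source_past(engine, selected_t)
    retained, removed = _prune_sources(engine, selected_t, selected_s)

    omnibus_te = omnibus_p = None
    accepted = False
    if retained:
        sources = [v.candidate for v in retained]
        base = [v.candidate for v in selected_t]
        t_star = engine.joint_cmi(sources, base)
        if settings.use_analytic_null:
            result, _ = omnibus_test(
                t_star,
                settings.alpha,
                null_cdf=engine.null_cdf(dim_x=len(sources)),
            )
        else:
            surr = engine.omnibus_surrogates(sources, base)
            result, _ = omnibus_test(
                t_star, settings.alpha, surrogate_stats=surr
            )
        omnibus_te = t_star
        omnibus_p = result.p_value
        accepted = result.significant
        if not accepted:
            # set rejected collectively: no sources reported, p retained
            removed = removed + retained
            retained = []
    return TargetInferenceResult(
        target=target,
        selected_target_past=selected_t,
        selected_sources=retained,
        removed_in_pruning=removed,
        omnibus_te=omnibus_te,
        omnibus_p=omnibus_p,
        source_set_accepted=accepted,
        n_effective=engine.m,
    )


def infer_network(
    data: TimeSeriesData,
    settings: InferenceSettings,
    targets: Sequence[int] | None = None,
    n_jobs: int = 1,
) -> NetworkResult:
    """Infer the directed network: per-target inference plus network FDR.

    Targets are processed independently with deterministic per-target
    random streams, so serial and parallel execution give identical
    results.  When ``settings.q_fdr`` is set, targets whose omnibus
    p-value fails the Benjamini-Hochberg step-up lose all their links.
    """
    if data.n_processes < 2:
        raise ValueError("need at least 2 processes")
    if targets is None:
        targets = range(data.n_processes)
    targets = list(targets)

    workspace = None
    if settings.estimator == "gaussian":
        workspace = _GaussianWorkspace(Embedding(data, settings.max_lag))

    if n_jobs == 1:
        results = [
            infer_target(data, t, settings, _workspace=workspace)
            for t in targets
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(infer_target)(data, t, settings, _workspace=workspace)
            for t in targets
        )
    by_target = {r.target: r for r in results}

    fdr_kept: dict[int, bool] = {}
    if settings.q_fdr is not None:
        tested = [t for t in targets if by_target[t].omnibus_p is not None]
        if tested:
            keep = fdr_combine_targets(
                [by_target[t].omnibus_p for t in tested], settings.q_fdr
            )
            fdr_kept = dict(zip(tested, (bool(k) for k in keep)))
    return NetworkResult(
        n_processes=data.n_processes,
        settings=settings,
        targets=by_target,
        fdr_kept=fdr_kept,
    )
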