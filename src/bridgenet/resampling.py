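"""Bootstrap accuracy and stability of network estimates.

Three procedures, all keyed to a single master seed:

* nonparametric bootstrap — resample respondents with replacement,
  re-estimate the network, collect edge weights (and centrality vectors)
  per replicate; 95% percentile confidence intervals describe sampling
  variation of each edge;
* case-dropping bootstrap — re-estimate on subsets with a fraction of
  respondents dropped and correlate the subset statistic vector (EI,
  bridge EI, or edges) with the full-sample vector; the CS coefficient is
  the largest drop fraction at which that correlation stays ≥ 0.7 with
  95% probability (a CS below 0.25 means the statistic should not be
  interpreted; above 0.5 is preferable);
* bootstrapped difference tests — percentile CI of the difference of two
  statistics computed in the same replicates; significant when 0 falls
  outside the (α/2, 1−α/2) interval.

Replicate randomness is derived per replicate from the master seed, so
results are independent of execution order and bit-reproducible.

The redundant-item reduction is performed once on the full sample and the
retained node set is held fixed across replicates; re-selecting items per
replicate would change the node set and make statistic vectors
non-comparable across replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .centrality import bridge_expected_influence, expected_influence
from .network import NetworkModel, estimate_network
from .questionnaire import ItemResponseMatrix, correlation_matrix

logger = logging.getLogger(__name__)


@dataclass
class EstimatorConfig:
    """Fully specified estimation pipeline applied in every replicate."""

    corr_method: str = "spearman"
    gamma: float = 0.25
    n_points: int = 100
    min_ratio: float = 0.01
    fixed_lambda: float | None = None
    tol: float = 1e-6
    max_iter: int = 1000

    def fit(self, m: ItemResponseMatrix) -> NetworkModel:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # PSD repair is routine in resamples
            S = correlation_matrix(m, method=self.corr_method)
        return estimate_network(
            S,
            n=m.n,
            gamma=self.gamma,
            n_points=self.n_points,
            min_ratio=self.min_ratio,
            fixed_lambda=self.fixed_lambda,
            communities=m.communities,
            tol=self.tol,
            max_iter=self.max_iter,
        )


def _resample_matrix(m: ItemResponseMatrix, idx: np.ndarray) -> ItemResponseMatrix:
    return ItemResponseMatrix(
        respondent_ids=[m.respondent_ids[i] for i in idx],
        items=list(m.items),
        values=m.values[idx],
    )


def _replicate_rng(seed: int, tag: int, rep: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag, rep])


@dataclass
class BootstrapResult:
    B: int
    seed: int
    items: list[str]
    point_edges: np.ndarray          # upper-triangle edge weights, full sample
    edge_samples: np.ndarray         # B × n_edges, NaN rows = failed replicates
    ei_samples: np.ndarray           # B × p
    bridge_ei_samples: np.ndarray    # B × p
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_failed: int

    @property
    def edge_pairs(self) -> list[tuple[str, str]]:
        p = len(self.items)
        iu = np.triu_indices(p, 1)
        return [(self.items[i], self.items[j]) for i, j in zip(*iu)]


def percentile_ci(samples: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Percentile interval whose endpoints are order statistics of the draws.

    The lower endpoint takes the largest order statistic not exceeding the
    α/2 quantile and the upper the smallest not below 1−α/2, so intervals
    are (weakly) outward-conservative and exactly recomputable by sorting.
    """
    lo = np.nanquantile(samples, alpha / 2, axis=0, method="lower")
    hi = np.nanquantile(samples, 1 - alpha / 2, axis=0, method="higher")
    return lo, hi


def nonparametric_bootstrap(
    m: ItemResponseMatrix,
    estimator: EstimatorConfig,
    B: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.05,
) -> BootstrapResult:
    """Resample respondents with replacement and re-estimate the network.

    Edge weights, EI and bridge EI are collected in the same replicates so
    that downstream difference tests are paired. Replicates in which
    estimation fails (e.g., a zero-variance item after resampling) are
    recorded as NaN rows and excluded from the quantiles; more than
    ``max_failure_rate`` failures is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    model = estimator.fit(m)
    p = m.p
    iu = np.triu_indices(p, 1)
    n_edges = len(iu[0])
    edge_samples = np.full((B, n_edges), np.nan)
    ei_samples = np.full((B, p), np.nan)
    bei_samples = np.full((B, p), np.nan)
    bridged = len(set(m.communities)) >= 2  # bridge EI needs a partition
    n_failed = 0
    for b in range(B):
        rng = _replicate_rng(seed, 0, b)
        idx = rng.integers(0, m.n, size=m.n)
        try:
            rep = estimator.fit(_resample_matrix(m, idx))
        except Exception as exc:  # noqa: BLE001 — replicate-level containment
            n_failed += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
            continue
        edge_samples[b] = rep.W[iu]
        ei_samples[b] = expected_influence(rep.W, 1)
        if bridged:
            bei_samples[b] = bridge_expected_influence(rep.W, rep.communities, 1)
    if n_failed > max_failure_rate * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed "
            f"(> {max_failure_rate:.0%} allowed)"
        )
    lo, hi = percentile_ci(edge_samples)
    return BootstrapResult(
        B=B,
        seed=seed,
        items=list(m.item_ids),
        point_edges=model.W[iu],
        edge_samples=edge_samples,
        ei_samples=ei_samples,
        bridge_ei_samples=bei_samples,
        ci_lower=lo,
        ci_upper=hi,
        n_failed=n_failed,
    )


@dataclass
class StabilityResult:
    statistic: str
    drop_levels: list[float]              # levels actually evaluated
    correlations: dict[float, np.ndarray]  # level -> replicate correlations (NaN = excluded)
    B: int
    seed: int
    correlation_threshold: float = 0.7
    probability_level: float = 0.95
    skipped_levels: list[float] = field(default_factory=list)

    @property
    def cs_coefficient(self) -> float:
        return cs_coefficient(self)


def case_dropping_bootstrap_multi(
    m: ItemResponseMatrix,
    estimator: EstimatorConfig,
    statistics: tuple[str, ...] = ("ei", "bridge_ei"),
    drop_levels: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    B: int = 1000,
    seed: int = 0,
    correlation_threshold: float = 0.7,
    probability_level: float = 0.95,
) -> dict[str, StabilityResult]:
    """Case-dropping bootstrap for several statistics over shared refits.

    Each statistic is one of ``"ei"``, ``"bridge_ei"``, ``"edge"``; every
    requested statistic is extracted from the same re-estimated network,
    so the refit cost is paid once. Levels whose retained subset would
    fall below p/2 respondents are skipped with a warning. Replicates
    with an undefined correlation (constant statistic vector) are
    excluded and counted as NaN.
    """
    for statistic in statistics:
        if statistic not in ("ei", "bridge_ei", "edge"):
            raise ValueError(f"unknown statistic {statistic!r}")
    full_model = estimator.fit(m)
    full_stat = {s: _statistic_vector(full_model, s) for s in statistics}
    correlations: dict[str, dict[float, np.ndarray]] = {s: {} for s in statistics}
    evaluated: list[float] = []
    skipped: list[float] = []
    for li, level in enumerate(drop_levels):
        if not 0 < level < 1:
            raise ValueError(f"drop level {level} outside (0, 1)")
        n_keep = int(round(m.n * (1 - level)))
        if n_keep < m.p / 2 or n_keep < 3:
            warnings.warn(
                f"drop level {level:g}: retained n={n_keep} too small; skipped"
            )
            skipped.append(level)
            continue
        cors = {s: np.full(B, np.nan) for s in statistics}
        for b in range(B):
            rng = _replicate_rng(seed, 1 + li, b)
            idx = rng.choice(m.n, size=n_keep, replace=False)
            try:
                rep = estimator.fit(_resample_matrix(m, idx))
            except Exception as exc:  # noqa: BLE001
                logger.debug("case-drop replicate (%g, %d) failed: %s", level, b, exc)
                continue
            for s in statistics:
                v = _statistic_vector(rep, s)
                if np.std(v) == 0 or np.std(full_stat[s]) == 0:
                    continue
                cors[s][b] = float(np.corrcoef(full_stat[s], v)[0, 1])
        for s in statistics:
            correlations[s][level] = cors[s]
        evaluated.append(level)
    return {
        s: StabilityResult(
            statistic=s,
            drop_levels=list(evaluated),
            correlations=correlations[s],
            B=B,
            seed=seed,
            correlation_threshold=correlation_threshold,
            probability_level=probability_level,
            skipped_levels=list(skipped),
        )
        for s in statistics
    }


def case_dropping_bootstrap(
    m: ItemResponseMatrix,
    estimator: EstimatorConfig,
    statistic: str = "ei",
    drop_levels: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    B: int = 1000,
    seed: int = 0,
    correlation_threshold: float = 0.7,
    probability_level: float = 0.95,
) -> StabilityResult:
    """Case-dropping bootstrap for a single statistic (see the multi variant)."""
    return case_dropping_bootstrap_multi(
        m,
        estimator,
        statistics=(statistic,),
        drop_levels=drop_levels,
        B=B,
        seed=seed,
        correlation_threshold=correlation_threshold,
        probability_level=probability_level,
    )[statistic]


def _statistic_vector(model: NetworkModel, statistic: str) -> np.ndarray:
    if statistic == "ei":
        return expected_influence(model.W, 1)
    if statistic == "bridge_ei":
        return bridge_expected_influence(model.W, model.communities, 1)
    iu = np.triu_indices(model.p, 1)
    return model.W[iu]


def cs_coefficient(s: StabilityResult) -> float:
    """Correlation-stability coefficient.

    Largest tested drop level at which the empirical probability of a
    subset–full correlation ≥ ``correlation_threshold`` is at least
    ``probability_level``; 0 when no level qualifies.
    """
    if not s.drop_levels:
        raise ValueError("no evaluated drop levels")
    best = 0.0
    for level in sorted(s.drop_levels):
        cors = s.correlations[level]
        valid = cors[~np.isnan(cors)]
        if valid.size == 0:
            continue
        prob = float((valid >= s.correlation_threshold).mean())
        if prob >= s.probability_level:
            best = max(best, level)
    return best


@dataclass
class DifferenceTestResult:
    pair: tuple[str, str]
    estimate: float
    ci_lower: float
    ci_upper: float
    alpha: float
    significant: bool
    n_replicates: int


def difference_test(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    alpha: float = 0.05,
    pair: tuple[str, str] = ("a", "b"),
) -> DifferenceTestResult:
    """Paired bootstrap difference test between two sampled statistics.

    Both statistics must come from the same replicates (paired draws).
    Significance means 0 lies strictly outside the closed percentile
    interval; with α = 1 the interval degenerates to the median difference,
    so any pair whose median difference is nonzero is flagged.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched replicate counts: {a.shape} vs {b.shape}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    diff = a - b
    valid = diff[~np.isnan(diff)]
    if valid.size < 2:
        raise ValueError("need at least 2 valid paired replicates")
    lo, hi = percentile_ci(valid[:, None], alpha=alpha)
    lo_f, hi_f = float(lo[0]), float(hi[0])
    significant = (0.0 < lo_f) or (0.0 > hi_f)
    return DifferenceTestResult(
        pair=pair,
        estimate=float(np.median(valid)),
        ci_lower=lo_f,
        ci_upper=hi_f,
        alpha=alpha,
        significant=significant,
        n_replicates=int(valid.size),
    )


def centrality_difference_tests(
    result: BootstrapResult,
    metric: str = "ei",
    alpha: float = 0.05,
) -> list[DifferenceTestResult]:
    """Difference tests between every node pair for a centrality metric."""
    samples = {
        "ei": result.ei_samples,
        "bridge_ei": result.bridge_ei_samples,
    }.get(metric)
    if samples is None:
        raise ValueError(f"unknown metric {metric!r}")
    out = []
    p = samples.shape[1]
    for i in range(p):
        for j in range(i + 1, p):
            out.append(
                difference_test(
                    samples[:, i],
                    samples[:, j],
                    alpha=alpha,
                    pair=(result.items[i], result.items[j]),
                )
            )
    return out
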