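"""Redundant-item detection and removal ("bad pairs").

Network analysis assumes each node measures a distinct construct. Two items
whose correlation profiles with every other item are statistically
indistinguishable for a large share of comparisons are treated as redundant
measures of one construct; one member of each such pair is removed before
network estimation.

The pairwise comparison is a test for two dependent correlations sharing
one variable (Hittner, May & Silver style): with
``z1 = atanh(r_AC)``, ``z2 = atanh(r_BC)`` and the back-transformed mean
``r̄ = tanh((z1+z2)/2)``,

    c = [r_AB (1 − 2 r̄²) − ½ r̄² (1 − 2 r̄² − r_AB²)] / (1 − r̄²)²
    Z = (z1 − z2) √(n − 3) / √(2 − 2c)

with a two-sided normal p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .questionnaire import CorrelationMatrix, ItemResponseMatrix


def dependent_correlation_test(
    r_ac: float, r_bc: float, r_ab: float, n: int
) -> tuple[float, float]:
    """Test H0: ρ(A,C) = ρ(B,C) for correlations sharing variable C.

    Returns ``(z_statistic, two_sided_p)``. Antisymmetric in
    ``(r_ac, r_bc)``: swapping them negates Z.
    """
    r_ac, r_bc, r_ab = float(r_ac), float(r_bc), float(r_ab)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    for name, r in (("r_ac", r_ac), ("r_bc", r_bc), ("r_ab", r_ab)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1 (got {r}); Fisher transform degenerate")
    z1 = np.arctanh(r_ac)
    z2 = np.arctanh(r_bc)
    rbar = np.tanh((z1 + z2) / 2)
    c = _covariance_term(r_ab, rbar)
    denom = 2.0 - 2.0 * c
    if z1 == z2:
        return 0.0, 1.0
    if denom <= 0:
        # pathological near-collinear geometry; treat as maximally different
        z = np.inf if z1 > z2 else -np.inf
        return float(z), 0.0
    z = (z1 - z2) * np.sqrt(n - 3) / np.sqrt(denom)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _covariance_term(r_ab: np.ndarray | float, rbar: np.ndarray | float):
    return (
        r_ab * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_ab**2)
    ) / (1 - rbar**2) ** 2


@dataclass
class RedundancyReport:
    """Outcome of bad-pair detection and (optionally) node removal."""

    bad_pairs: list[tuple[str, str, float]]
    p_threshold: float
    share_threshold: float
    removed_items: list[str] = field(default_factory=list)
    retained_items: list[str] = field(default_factory=list)
    decisions: list[dict] = field(default_factory=list)
    abs_corr_sum: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "p_threshold": self.p_threshold,
            "share_threshold": self.share_threshold,
            "bad_pairs": [
                {"item_a": a, "item_b": b, "proportion_significantly_different": prop}
                for a, b, prop in self.bad_pairs
            ],
            "removed_items": self.removed_items,
            "retained_items": self.retained_items,
            "decisions": self.decisions,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        lines = [
            f"bad pairs (p<{self.p_threshold}, share>={self.share_threshold}): "
            f"{len(self.bad_pairs)}"
        ]
        for a, b, prop in self.bad_pairs:
            lines.append(f"  {a} ~ {b}  (significantly different: {prop:.1%})")
        if self.removed_items:
            lines.append(f"removed ({len(self.removed_items)}): "
                         + ", ".join(self.removed_items))
        return "\n".join(lines)


def _pairwise_proportions(
    S: np.ndarray, n: int, p_threshold: float
) -> np.ndarray:
    """Proportion of third-item comparisons significantly different, per pair.

    Vectorized over all (A, B, C) triples. Correlations are clipped just
    inside ±1 so exact duplicates (r = 1) are handled: equal profiles give
    Z = 0 regardless of the clip.
    """
    p = S.shape[0]
    R = np.clip(S, -1 + 1e-12, 1 - 1e-12)
    Z1 = np.arctanh(R)  # z[a, c]
    z1 = Z1[:, None, :]              # (A, 1, C)
    z2 = Z1[None, :, :]              # (1, B, C)
    rbar = np.tanh((z1 + z2) / 2)
    r_ab = R[:, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        c = _covariance_term(r_ab, rbar)
        denom = 2.0 - 2.0 * c
        zstat = np.where(
            z1 == z2,
            0.0,
            (z1 - z2) * np.sqrt(n - 3) / np.sqrt(np.where(denom > 0, denom, np.nan)),
        )
    # non-positive denominator with unequal profiles: maximally different
    zstat = np.where(np.isnan(zstat) & (z1 != z2), np.inf, zstat)
    sig = 2 * stats.norm.sf(np.abs(zstat)) < p_threshold

    idx = np.arange(p)
    valid = np.ones((p, p, p), dtype=bool)
    valid[idx, :, idx] = False   # C == A
    valid[:, idx, idx] = False   # C == B
    with np.errstate(invalid="ignore"):
        prop = (sig & valid).sum(axis=2) / valid.sum(axis=2)
    return prop


def find_bad_pairs(
    S: CorrelationMatrix,
    n: int,
    p_threshold: float = 0.05,
    share_threshold: float = 0.75,
    min_correlation: float = 0.5,
) -> RedundancyReport:
    """Flag item pairs whose correlation profiles are indistinguishable.

    A pair (A, B) is a candidate only when r(A,B) ≥ ``min_correlation``
    (two items cannot measure one construct without being strongly
    correlated; without this gate, mutually near-independent items with
    uniformly flat profiles would be declared redundant). A candidate is
    "bad" when the proportion of third items C for which ρ(A,C) and
    ρ(B,C) differ significantly (two-sided, ``p_threshold``) is below
    ``1 − share_threshold`` — i.e. the items share at least
    ``share_threshold`` of their correlations.
    """
    p = S.p
    if p < 3:
        raise ValueError("need at least 3 items")
    prop = _pairwise_proportions(S.S, n, p_threshold)
    cutoff = 1.0 - share_threshold
    pairs = []
    for i in range(p):
        for j in range(i + 1, p):
            if S.S[i, j] >= min_correlation and prop[i, j] < cutoff:
                pairs.append((S.item_ids[i], S.item_ids[j], float(prop[i, j])))
    pairs.sort(key=lambda t: (t[2], t[0], t[1]))
    abs_sum = {
        S.item_ids[i]: float(np.abs(S.S[i]).sum() - 1.0) for i in range(p)
    }
    return RedundancyReport(
        bad_pairs=pairs,
        p_threshold=p_threshold,
        share_threshold=share_threshold,
        retained_items=list(S.item_ids),
        abs_corr_sum=abs_sum,
    )


def reduce_nodes(
    m: ItemResponseMatrix,
    report: RedundancyReport,
    policy: str = "max_participation",
) -> tuple[ItemResponseMatrix, RedundancyReport]:
    """Remove one member of each bad pair until none remain.

    Policy: remove the item participating in the most remaining bad pairs;
    ties broken by lower total absolute correlation with all other items,
    then lexicographically by item_id. Every removal is recorded.
    """
    if policy != "max_participation":
        raise ValueError(f"unknown removal policy {policy!r}")
    active = [(a, b) for a, b, _ in report.bad_pairs]
    removed: list[str] = []
    decisions: list[dict] = []
    while active:
        counts: dict[str, int] = {}
        for a, b in active:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        victim = min(
            counts,
            key=lambda it: (
                -counts[it],
                report.abs_corr_sum.get(it, 0.0),
                it,
            ),
        )
        decisions.append(
            {
                "removed": victim,
                "bad_pair_count": counts[victim],
                "abs_corr_sum": report.abs_corr_sum.get(victim),
                "resolved_pairs": [list(p) for p in active if victim in p],
            }
        )
        removed.append(victim)
        active = [p for p in active if victim not in p]

    retained = [it for it in m.item_ids if it not in set(removed)]
    new_report = RedundancyReport(
        bad_pairs=list(report.bad_pairs),
        p_threshold=report.p_threshold,
        share_threshold=report.share_threshold,
        removed_items=removed,
        retained_items=retained,
        decisions=decisions,
        abs_corr_sum=dict(report.abs_corr_sum),
    )
    return m.subset_items(retained), new_report
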