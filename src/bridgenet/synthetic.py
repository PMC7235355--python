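"""Synthetic questionnaire data with known network ground truth.

Real item-level data for the two-instrument design this package targets
are not publicly available, so every pipeline stage is exercised against a
generator that emulates the study conditions: ~101 respondents answering
22 seven-point items (community "ED") and 65 four-point items (community
"ASD"), a sparse two-community partial-correlation structure with a few
planted bridge edges, a handful of near-duplicate item pairs, at least one
reverse-coded item, and ~0.08% missing cells.

The generative model is latent-Gaussian with threshold discretization:
draw multivariate-normal vectors whose precision matrix carries the
planted edge pattern, then cut each latent variable at equal-probability
normal quantiles into its item's Likert levels. The downstream estimator
assumes a monotone latent structure, so this is the natural stress model;
what it deliberately does not emulate (skewed margins, item-level response
styles, informative missingness) is discussed in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .network import NetworkModel, precision_to_partial_corr
from .questionnaire import ItemResponseMatrix, ScaleDefinition


@dataclass
class SyntheticSpec:
    """Generator configuration; the defaults are the study-like preset."""

    p_community_a: int = 22
    p_community_b: int = 65
    likert_levels_a: int = 7
    likert_levels_b: int = 4
    within_density: float = 0.1
    n_bridge_edges: int = 4
    weight_range: tuple[float, float] = (0.2, 0.4)
    n_redundant_pairs: int = 4       # split across the two communities
    redundancy_noise_sd: float = 0.1
    n_reverse_coded: int = 1
    threshold_skew: float = 0.0      # >0 shifts thresholds up: floor effects
    missing_rate: float = 0.0008
    n: int = 101
    seed: int = 0
    community_names: tuple[str, str] = ("ED", "ASD")

    def __post_init__(self) -> None:
        for name in ("within_density", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.weight_range[0] <= self.weight_range[1] < 1:
            raise ValueError("weight_range must satisfy 0 < low <= high < 1")

    @property
    def p(self) -> int:
        return self.p_community_a + self.p_community_b


@dataclass
class GroundTruth:
    """Planted structure against which recovery is scored."""

    theta: np.ndarray
    partial_corr: np.ndarray
    communities: list[str]
    item_ids: list[str]
    bridge_edges: list[tuple[int, int]]
    redundant_pairs: list[tuple[str, str]] = field(default_factory=list)
    thresholds: list[np.ndarray] = field(default_factory=list)
    latent: np.ndarray | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "item_ids": self.item_ids,
            "communities": self.communities,
            "theta": self.theta.tolist(),
            "partial_corr": self.partial_corr.tolist(),
            "bridge_edges": [list(e) for e in self.bridge_edges],
            "redundant_pairs": [list(e) for e in self.redundant_pairs],
            "thresholds": [t.tolist() for t in self.thresholds],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _block_pairs(lo: int, hi: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(lo, hi) for j in range(i + 1, hi)]


def make_precision_matrix(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> GroundTruth:
    """Sparse two-community precision matrix with planted bridge edges.

    Within-community edges are placed uniformly at random at
    ``within_density``; ``n_bridge_edges`` cross-community edges are added.
    Partial-correlation magnitudes are drawn from ``weight_range`` with
    random signs (a positive partial correlation means a negative
    precision entry). Positive definiteness is enforced by diagonal
    loading until the smallest eigenvalue reaches 0.05.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pa, p = spec.p_community_a, spec.p
    blocks = [_block_pairs(0, pa), _block_pairs(pa, p)]
    cross = [(i, j) for i in range(pa) for j in range(pa, p)]
    if spec.n_bridge_edges > len(cross):
        raise ValueError("n_bridge_edges exceeds the number of cross pairs")

    Theta = np.eye(p)

    def plant(pairs: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
        if k > len(pairs):
            raise ValueError("requested edge count exceeds available pairs")
        chosen = [pairs[t] for t in rng.choice(len(pairs), size=k, replace=False)]
        for i, j in chosen:
            mag = rng.uniform(*spec.weight_range)
            sign = rng.choice([-1.0, 1.0])
            Theta[i, j] = Theta[j, i] = -sign * mag
        return chosen

    for pairs in blocks:
        plant(pairs, int(round(spec.within_density * len(pairs))))
    bridge = plant(cross, spec.n_bridge_edges)

    w = np.linalg.eigvalsh(Theta)
    if w.min() < 0.05:
        Theta = Theta + np.eye(p) * (0.05 - w.min())

    names_a, names_b = spec.community_names
    item_ids = [f"{names_a}{i + 1:02d}" for i in range(pa)] + [
        f"{names_b}{i + 1:02d}" for i in range(spec.p_community_b)
    ]
    communities = [names_a] * pa + [names_b] * spec.p_community_b
    return GroundTruth(
        theta=Theta,
        partial_corr=precision_to_partial_corr(Theta),
        communities=communities,
        item_ids=item_ids,
        bridge_edges=bridge,
    )


def _likert_thresholds(levels: int, skew: float = 0.0) -> np.ndarray:
    """Cut points on the standard-normal latent scale.

    ``skew = 0`` gives equal-probability categories; positive values shift
    every threshold upward, piling mass into the low categories — the
    floor effect typical of symptom questionnaires in mixed samples.
    """
    return stats.norm.ppf(np.arange(1, levels) / levels) + skew


def sample_likert(
    gt: GroundTruth,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> ItemResponseMatrix:
    """Draw latent Gaussians, discretize to Likert levels, flag reverse items.

    Reverse-coded items (chosen from community B, the instrument with the
    documented reverse-keyed wording) are stored in reversed orientation
    with their flag set, so loading + reverse coding restores monotone
    alignment with the latent variable. Missing cells are injected
    completely at random at ``missing_rate``. The latent draw is kept on
    the ground truth for redundancy injection.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    p, pa = spec.p, spec.p_community_a
    Sigma = np.linalg.inv(gt.theta)
    d = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(d, d)
    L = np.linalg.cholesky(Sigma)
    Z = rng.standard_normal((spec.n, p)) @ L.T
    gt.latent = Z

    levels = [spec.likert_levels_a] * pa + [spec.likert_levels_b] * (p - pa)
    gt.thresholds = [_likert_thresholds(lv, spec.threshold_skew) for lv in levels]
    values = np.empty((spec.n, p))
    for j in range(p):
        values[:, j] = np.searchsorted(gt.thresholds[j], Z[:, j])

    n_rev = min(spec.n_reverse_coded, p - pa)
    rev_idx = set(
        int(k) for k in rng.choice(np.arange(pa, p), size=n_rev, replace=False)
    )
    items = []
    for j in range(p):
        lv = levels[j]
        reverse = j in rev_idx
        items.append(
            ScaleDefinition(
                item_id=gt.item_ids[j],
                instrument=gt.communities[j],
                community=gt.communities[j],
                likert_min=0,
                likert_max=lv - 1,
                reverse_coded=reverse,
            )
        )
        if reverse:
            values[:, j] = (lv - 1) - values[:, j]

    if spec.missing_rate > 0:
        miss = rng.random((spec.n, p)) < spec.missing_rate
        values[miss] = np.nan

    ids = [f"R{i + 1:04d}" for i in range(spec.n)]
    return ItemResponseMatrix(ids, items, values)


def inject_redundant_items(
    m: ItemResponseMatrix,
    gt: GroundTruth,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ItemResponseMatrix, GroundTruth]:
    """Overwrite chosen items with noisy copies of same-community partners.

    For each planted pair a target item's latent column is replaced by a
    source item's latent plus N(0, redundancy_noise_sd²) noise and
    re-discretized, producing the near-duplicate "bad pairs" the item
    selection step must catch. Item count is unchanged; the affected
    target's originally planted edges no longer hold.
    """
    if spec.n_redundant_pairs == 0:
        return m, gt
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    if gt.latent is None:
        raise ValueError("ground truth carries no latent draw; run sample_likert first")
    pa, p = spec.p_community_a, spec.p
    if spec.n_redundant_pairs > p // 2:
        raise ValueError("too many redundant pairs for item count")

    values = m.values.copy()
    latent = gt.latent.copy()
    pairs: list[tuple[str, str]] = []
    used: set[int] = set()
    # alternate communities so both instruments carry redundancy
    for k in range(spec.n_redundant_pairs):
        lo, hi = (0, pa) if k % 2 == 0 else (pa, p)
        candidates = [j for j in range(lo, hi) if j not in used]
        if len(candidates) < 2:
            candidates = [j for j in range(p) if j not in used]
        src, dst = (
            int(x) for x in rng.choice(candidates, size=2, replace=False)
        )
        used.update((src, dst))
        latent[:, dst] = latent[:, src] + spec.redundancy_noise_sd * rng.standard_normal(m.n)
        item = m.items[dst]
        col = np.searchsorted(gt.thresholds[dst], latent[:, dst]).astype(float)
        if item.reverse_coded:
            col = item.likert_max - col
        col[np.isnan(m.values[:, dst])] = np.nan  # keep missingness pattern
        values[:, dst] = col
        pairs.append((m.items[src].item_id, item.item_id))

    gt.latent = latent
    gt.redundant_pairs = pairs
    return ItemResponseMatrix(list(m.respondent_ids), list(m.items), values), gt


def generate_dataset(spec: SyntheticSpec) -> tuple[ItemResponseMatrix, GroundTruth]:
    """Full generation: structure → latent/Likert sampling → redundancy.

    All sub-draws derive from ``spec.seed``; the same spec yields a
    byte-identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    gt = make_precision_matrix(spec, rng)
    m = sample_likert(gt, spec, rng)
    m, gt = inject_redundant_items(m, gt, spec, rng)
    return m, gt


def write_dataset(
    m: ItemResponseMatrix, directory: str | Path, stem: str = "responses"
) -> tuple[Path, Path]:
    """Write the wide CSV + scales YAML that the loading step reads back."""
    from .questionnaire import save_scales

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{stem}.csv"
    yaml_path = directory / f"{stem}_scales.yaml"
    df = m.to_dataframe()
    df.index.name = "respondent_id"
    with np.errstate(invalid="ignore"):
        df = df.astype("Int64")  # integers with <NA> for missing
    df.to_csv(csv_path, na_rep="NA")
    save_scales(m.items, yaml_path)
    return csv_path, yaml_path


def recovery_metrics(estimated: NetworkModel, gt: GroundTruth) -> dict:
    """Edge-recovery summary against the planted pattern.

    Sensitivity/specificity of edge presence, sign agreement on recovered
    true edges, and whether any planted bridge node reaches the top-3 of
    |bridge EI1| (magnitude, not signed value: planted bridge edges carry
    random signs, and a node bridging through a negative edge is exactly
    as much a bridge as through a positive one).
    """
    if estimated.items != gt.item_ids:
        raise ValueError("item sets of estimate and ground truth differ")
    p = len(gt.item_ids)
    iu = np.triu_indices(p, 1)
    true_edge = gt.theta[iu] != 0
    est_edge = estimated.W[iu] != 0
    tp = int((true_edge & est_edge).sum())
    sens = tp / true_edge.sum() if true_edge.any() else float("nan")
    spec_ = (
        int((~true_edge & ~est_edge).sum()) / (~true_edge).sum()
        if (~true_edge).any()
        else float("nan")
    )
    rec = true_edge & est_edge
    if rec.any():
        sign_agreement = float(
            (np.sign(estimated.W[iu][rec]) == np.sign(gt.partial_corr[iu][rec])).mean()
        )
    else:
        sign_agreement = float("nan")

    from .centrality import bridge_expected_influence

    bei1 = bridge_expected_influence(estimated.W, gt.communities, 1)
    top3 = set(np.argsort(-np.abs(bei1))[:3])
    bridge_nodes = set(i for e in gt.bridge_edges for i in e)
    return {
        "sensitivity": float(sens),
        "specificity": float(spec_),
        "sign_agreement": sign_agreement,
        "n_true_edges": int(true_edge.sum()),
        "n_estimated_edges": int(est_edge.sum()),
        "bridge_top3": bool(top3 & bridge_nodes),
    }
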