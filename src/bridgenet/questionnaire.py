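"""Ordinal questionnaire data: loading, validation, reverse coding, correlation.

The analysis operates on wide person × item tables of Likert responses
(e.g., 22 eating-disorder items on a 0–6 scale plus 65 autism-trait items
on a 0–3 scale). Items carry metadata — instrument, community label used
for the bridge analysis, Likert range, reverse-coding flag — declared in a
YAML/JSON sidecar, never inferred from the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("", "NA")


class SchemaError(ValueError):
    """CSV structure does not match the declared scales."""


class ValidationError(ValueError):
    """A cell value violates its item's declared Likert range."""


@dataclass(frozen=True)
class ScaleDefinition:
    """Metadata for one questionnaire item.

    ``community`` is the cluster label used in the bridge analysis
    (instrument membership in the two-questionnaire design, e.g. ``"ED"``
    vs ``"ASD"``). ``reverse_coded`` items are reflected at load time so
    that higher values always mean more symptoms.
    """

    item_id: str
    instrument: str
    community: str
    likert_min: int
    likert_max: int
    reverse_coded: bool = False

    def __post_init__(self) -> None:
        if self.likert_min >= self.likert_max:
            raise ValueError(
                f"item {self.item_id!r}: likert_min must be < likert_max "
                f"(got {self.likert_min} >= {self.likert_max})"
            )


@dataclass
class ItemResponseMatrix:
    """Person × item grid of ordinal responses with missing cells as NaN."""

    respondent_ids: list[str]
    items: list[ScaleDefinition]
    values: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.respondent_ids), len(self.items)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.respondent_ids)} respondents × {len(self.items)} items"
            )
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in scale definitions")

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def communities(self) -> list[str]:
        return [it.community for it in self.items]

    @property
    def missing_fraction(self) -> float:
        if self.values.size == 0:
            return 0.0
        return float(np.isnan(self.values).sum()) / self.values.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.respondent_ids, columns=self.item_ids
        )

    def subset_items(self, keep: Sequence[str]) -> "ItemResponseMatrix":
        """Return a copy restricted to ``keep`` (original column order)."""
        keep_set = set(keep)
        unknown = keep_set - set(self.item_ids)
        if unknown:
            raise KeyError(f"unknown item ids: {sorted(unknown)}")
        idx = [i for i, it in enumerate(self.items) if it.item_id in keep_set]
        return ItemResponseMatrix(
            respondent_ids=list(self.respondent_ids),
            items=[self.items[i] for i in idx],
            values=self.values[:, idx].copy(),
        )


@dataclass
class CorrelationMatrix:
    """Symmetric item correlation matrix with per-pair effective sample sizes."""

    S: np.ndarray
    item_ids: list[str]
    n_effective: np.ndarray
    method: str

    @property
    def p(self) -> int:
        return self.S.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.item_ids, columns=self.item_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="item_id")


def load_scales(path: str | Path) -> list[ScaleDefinition]:
    """Read item metadata from a YAML (or JSON — YAML superset) list."""
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise SchemaError(f"{path}: expected a list of scale records")
    return [ScaleDefinition(**rec) for rec in records]


def save_scales(scales: Iterable[ScaleDefinition], path: str | Path) -> None:
    records = [
        {
            "item_id": s.item_id,
            "instrument": s.instrument,
            "community": s.community,
            "likert_min": s.likert_min,
            "likert_max": s.likert_max,
            "reverse_coded": s.reverse_coded,
        }
        for s in scales
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(records, fh, sort_keys=False)


def load_responses(
    path: str | Path,
    scales: Sequence[ScaleDefinition],
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    id_column: str = "respondent_id",
) -> ItemResponseMatrix:
    """Load a wide respondents × items CSV against declared scales.

    The header must contain exactly the declared item_ids (any order),
    optionally preceded by an ``id_column``. Cells are integers or one of
    ``missing_tokens``. Out-of-range values are rejected with the offending
    row and column named.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no columns")

    if id_column in df.columns:
        respondent_ids = df[id_column].astype(str).tolist()
        df = df.drop(columns=[id_column])
    else:
        respondent_ids = [f"R{i + 1:04d}" for i in range(len(df))]

    by_id = {s.item_id: s for s in scales}
    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise SchemaError(f"{path}: unknown item columns {unknown}")
    absent = [s.item_id for s in scales if s.item_id not in df.columns]
    if absent:
        raise SchemaError(f"{path}: missing item columns {absent}")

    items = list(scales)
    n, p = len(df), len(items)
    values = np.full((n, p), np.nan)
    token_set = set(missing_tokens)
    for j, item in enumerate(items):
        col = df[item.item_id].str.strip()
        miss = col.isin(token_set)
        raw = col.where(~miss, other="0")
        try:
            parsed = raw.astype(float)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: non-numeric value in column {item.item_id!r}: {exc}"
            ) from exc
        parsed = parsed.to_numpy()
        bad = (~miss.to_numpy()) & (
            (parsed < item.likert_min)
            | (parsed > item.likert_max)
            | (parsed != np.round(parsed))
        )
        if bad.any():
            row = int(np.argmax(bad))
            raise ValidationError(
                f"{path}: value {col.iloc[row]!r} out of range "
                f"[{item.likert_min}, {item.likert_max}] at row "
                f"{respondent_ids[row]!r}, column {item.item_id!r}"
            )
        values[:, j] = np.where(miss.to_numpy(), np.nan, parsed)

    m = ItemResponseMatrix(respondent_ids, items, values)
    logger.info(
        "loaded %d × %d responses from %s (missing fraction %.4f%%)",
        m.n, m.p, path, 100 * m.missing_fraction,
    )
    return m


def reverse_code(m: ItemResponseMatrix) -> ItemResponseMatrix:
    """Reflect reverse-coded items: v ↦ likert_min + likert_max − v.

    Missing cells stay missing. Flags are consumed (set to False on the
    returned matrix) so a second application is the identity.
    """
    values = m.values.copy()
    items = []
    for j, item in enumerate(m.items):
        if item.reverse_coded:
            values[:, j] = item.likert_min + item.likert_max - values[:, j]
            items.append(replace(item, reverse_coded=False))
        else:
            items.append(item)
    return ItemResponseMatrix(list(m.respondent_ids), items, values)


def _psd_repair(S: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and restore a unit diagonal."""
    w, V = np.linalg.eigh((S + S.T) / 2)
    if w.min() >= -floor:
        return S
    warnings.warn(
        f"correlation matrix not PSD (min eigenvalue {w.min():.3e}); "
        "projecting to nearest PSD matrix",
        stacklevel=3,
    )
    w = np.clip(w, floor, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2


def correlation_matrix(
    m: ItemResponseMatrix,
    method: str = "spearman",
    missing_policy: str = "pairwise",
    min_pairwise_n: int = 3,
    ensure_psd: bool = True,
) -> CorrelationMatrix:
    """Item × item correlation matrix, pairwise-complete over missing cells.

    Spearman is the default: the inputs are ordinal and the downstream
    penalized estimator only needs a monotone-faithful correlation.
    Respondents with isolated missing cells contribute to every pair they
    complete, mirroring the retention of partially missing respondents.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if missing_policy != "pairwise":
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    X = m.values
    obs = ~np.isnan(X)
    n_eff = obs.astype(int).T @ obs.astype(int)

    with np.errstate(invalid="ignore"):
        variances = np.nanvar(X, axis=0)
    zero_var = np.where(~(variances > 0))[0]
    if zero_var.size:
        names = [m.item_ids[j] for j in zero_var]
        raise ValueError(f"zero-variance items: {names}")

    off = ~np.eye(m.p, dtype=bool)
    if m.p > 1 and n_eff[off].min() < min_pairwise_n:
        i, j = divmod(int(np.argmin(np.where(off, n_eff, np.iinfo(int).max))), m.p)
        raise ValueError(
            f"insufficient pairwise-complete observations "
            f"({n_eff[i, j]}) for items {m.item_ids[i]!r}, {m.item_ids[j]!r}"
        )

    if obs.all():
        if method == "spearman":
            ranks = pd.DataFrame(X).rank().to_numpy()
            S = np.corrcoef(ranks, rowvar=False)
        else:
            S = np.corrcoef(X, rowvar=False)
    else:
        # pandas re-ranks within each complete pair, the correct
        # pairwise-complete Spearman
        S = m.to_dataframe().corr(method=method, min_periods=min_pairwise_n).to_numpy()

    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    if ensure_psd:
        S = _psd_repair(S)
    return CorrelationMatrix(
        S=S, item_ids=m.item_ids, n_effective=n_eff, method=method
    )
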