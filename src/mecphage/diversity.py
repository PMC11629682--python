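"""Hill-number beta diversity, PCoA, Mantel correlation, prevalence curves.

Pairwise decomposition (two assemblages, equal weights w = 1/2)
---------------------------------------------------------------
For relative-abundance vectors p1, p2 and diversity order q >= 0, with pooled
abundances pbar_i = (p1_i + p2_i)/2 and sums over non-zero entries only:

    gamma = (sum_i pbar_i^q)^(1/(1-q))
    alpha = (1/2) * (sum_{j,i} (p_ji / 2)^q)^(1/(1-q))
    beta  = gamma / alpha            (in [1, 2])

with exponential-Shannon limits at q = 1. The local overlap transform maps
beta to a dissimilarity in [0, 1]:

    d = 1 - ((1/beta)^(q-1) - (1/2)^(q-1)) / (1 - (1/2)^(q-1))   (q != 1)
    d = ln(beta) / ln(2)                                         (q = 1)

At q = 0 this reduces to d = beta - 1, the proportion of detected taxa that
differ between the two samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mecphage.errors import (
    EmptySampleError,
    InsufficientSamplesError,
    InvalidInputError,
)


@dataclass(frozen=True)
class HillDecomposition:
    q: float
    gamma: float
    alpha: float
    beta: float
    n_samples: int = 2


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    q: float
    values: np.ndarray  # symmetric, zero diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all, descending
    proportion_explained: np.ndarray  # per positive axis


@dataclass
class PrevalenceCurve:
    feature: str
    group_size: int
    groups: pd.DataFrame  # completeness_min/max, n_bins, fraction, partial


def _normalize(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or (p < 0).any():
        raise InvalidInputError("abundance vector must be 1-D and non-negative")
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        raise InvalidInputError("abundance vector cannot be normalized")
    return p / total


def pairwise_dissimilarity(
    p1: Sequence[float], p2: Sequence[float], q: float
) -> tuple[HillDecomposition, float]:
    """Hill decomposition and local dissimilarity for one sample pair.

    Inputs are renormalized to proportions; zero-abundance taxa are dropped
    (Hill numbers are support-based).
    """
    if q < 0:
        raise InvalidInputError("q must be >= 0")
    p1, p2 = _normalize(np.asarray(p1)), _normalize(np.asarray(p2))
    if p1.shape != p2.shape:
        raise InvalidInputError("abundance vectors differ in length")
    keep = (p1 > 0) | (p2 > 0)
    p1, p2 = p1[keep], p2[keep]
    pooled = (p1 + p2) / 2.0
    parts = np.concatenate([p1[p1 > 0], p2[p2 > 0]]) / 2.0

    if abs(q - 1.0) < 1e-12:
        gamma = float(np.exp(-np.sum(pooled * np.log(pooled))))
        alpha = float(0.5 * np.exp(-np.sum(parts * np.log(parts))))
    else:
        e = 1.0 / (1.0 - q)
        gamma = float(np.sum(pooled**q) ** e)
        alpha = float(0.5 * np.sum(parts**q) ** e)
    beta = min(2.0, max(1.0, gamma / alpha))

    if abs(q - 1.0) < 1e-12:
        d = np.log(beta) / np.log(2.0)
    else:
        u = 0.5 ** (q - 1.0)
        d = 1.0 - ((1.0 / beta) ** (q - 1.0) - u) / (1.0 - u)
    d = float(min(1.0, max(0.0, d)))
    return HillDecomposition(q=q, gamma=gamma, alpha=alpha, beta=beta), d


def dissimilarity_matrix(
    table: pd.DataFrame,
    q: float,
    samples: Sequence[str] | None = None,
) -> DissimilarityMatrix:
    """All-pairs local dissimilarities over the selected sample columns.

    Each column is renormalized over the included taxa before the pairwise
    computation; all-zero columns raise ``EmptySampleError``.
    """
    cols = list(samples) if samples is not None else list(table.columns)
    if len(cols) < 2:
        raise InsufficientSamplesError("need at least two samples")
    sub = table[cols].to_numpy(dtype=float)
    if (sub.sum(axis=0) <= 0).any():
        bad = [c for c, t in zip(cols, sub.sum(axis=0)) if t <= 0]
        raise EmptySampleError(f"empty sample columns: {bad}")
    n = len(cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, dij = pairwise_dissimilarity(sub[:, i], sub[:, j], q)
            d[i, j] = d[j, i] = dij
    return DissimilarityMatrix(sample_ids=cols, q=q, values=d)


def pcoa(matrix: DissimilarityMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical principal coordinate analysis (Gower double-centering).

    Negative eigenvalues are reported verbatim (no Lingoes/Cailliez
    correction); coordinates are returned only for positive eigenvalues and
    the proportion explained is relative to the positive eigenvalue sum.
    """
    d = matrix.values
    if d.shape[0] < 3:
        raise InsufficientSamplesError("PCoA needs at least three samples")
    a = -0.5 * d**2
    n = d.shape[0]
    center = np.eye(n) - np.ones((n, n)) / n
    g = center @ a @ center
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = prop[:n_axes]
    return PcoaResult(
        sample_ids=list(matrix.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def correlate_dissimilarities(
    da: DissimilarityMatrix,
    db: DissimilarityMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: Pearson r of upper triangles, permutation p-value.

    Two-sided: p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), permuting
    the sample labels of ``db``.
    """
    if len(da.sample_ids) != len(db.sample_ids):
        raise InvalidInputError("matrices have different sample sets")
    n = len(da.sample_ids)
    if n < 4:
        raise InsufficientSamplesError("Mantel test needs >= 4 samples")
    iu = np.triu_indices(n, k=1)
    x = da.values[iu]
    r_obs = _pearson(x, db.values[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y = db.values[np.ix_(perm, perm)][iu]
        if abs(_pearson(x, y)) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p


def prevalence_by_completeness(
    bins: pd.DataFrame,
    feature: str,
    group_size: int = 36,
) -> PrevalenceCurve:
    """Fraction of bins carrying a feature, in consecutive completeness groups.

    ``bins`` needs columns bin_id, completeness and a boolean ``feature``
    column. Bins are sorted by ascending completeness (ties by bin id) and
    chunked into groups of ``group_size``; a final partial group is retained
    and flagged.
    """
    df = bins.sort_values(["completeness", "bin_id"]).reset_index(drop=True)
    rows = []
    for start in range(0, len(df), group_size):
        chunk = df.iloc[start : start + group_size]
        rows.append(
            {
                "completeness_min": float(chunk["completeness"].min()),
                "completeness_max": float(chunk["completeness"].max()),
                "n_bins": int(len(chunk)),
                "fraction": float(chunk[feature].mean()),
                "partial": len(chunk) < group_size,
            }
        )
    return PrevalenceCurve(feature=feature, group_size=group_size, groups=pd.DataFrame(rows))


def shared_fraction(d: float) -> int:
    """Shared fraction of (order-q weighted) taxa, 100*(1-d) as integer %."""
    if not 0.0 <= d <= 1.0:
        raise InvalidInputError("d must be in [0, 1]")
    return int(round(100.0 * (1.0 - d)))
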