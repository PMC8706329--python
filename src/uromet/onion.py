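"""Onion D-optimal design for class balancing.

When one class greatly outnumbers the other (e.g. 170 children without
bronchiolitis vs 35 with), a classifier trained on the raw data is
biased toward the majority. Instead of random undersampling, a
representative subset of the majority class is chosen by onion
D-optimal design: candidates are described by their PCA scores plus
the Q distance-to-model coordinate, split into concentric layers
(shells) by distance from the centroid, and a D-optimal subset is
selected within each layer by Fedorov exchange. The union spans the
candidate cloud from core to periphery, keeping the subset
representative of the whole class rather than only its extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CandidateSet:
    """Candidates x (A + 1) coordinates: A PCA scores plus Q."""

    points: pd.DataFrame  # index = candidate IDs

    def __post_init__(self) -> None:
        if self.points.index.duplicated().any():
            raise ValueError("candidate IDs must be unique")

    @classmethod
    def from_scores_and_q(
        cls, scores: np.ndarray, q: np.ndarray, ids, standardize: bool = True
    ) -> "CandidateSet":
        """Build the joint (scores, Q) geometry.

        Scores and Q live on incommensurate scales, so each coordinate
        is standardized to unit variance; without this Q (a squared
        distance) would dominate the layering metric.
        """
        pts = np.column_stack([np.asarray(scores, dtype=float), np.asarray(q, float)])
        if standardize:
            sd = pts.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            pts = (pts - pts.mean(axis=0)) / sd
        cols = [f"t{i + 1}" for i in range(pts.shape[1] - 1)] + ["q"]
        return cls(pd.DataFrame(pts, index=ids, columns=cols))


@dataclass
class DesignSelection:
    """Result of an onion D-optimal selection."""

    selected_ids: list
    layer_of: pd.Series  # layer index per candidate
    layer_logdet: dict[int, float]


def assign_layers(candidates: CandidateSet, n_layers: int) -> pd.Series:
    """Concentric shells by quantiles of distance from the centroid.

    Layer 0 is innermost. Quantile edges give layer sizes within one
    candidate of equal shares.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    pts = candidates.points.to_numpy()
    n = pts.shape[0]
    if n < n_layers:
        raise ValueError("need at least n_layers candidates")
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    if n_layers > 1 and np.allclose(d, d[0]):
        raise ValueError("all candidates identical: layers are degenerate")
    order = np.argsort(d, kind="stable")
    layers = np.empty(n, dtype=int)
    # equal-count split of the distance ranking (sizes differ by <= 1)
    edges = np.floor(np.arange(1, n + 1) * n_layers / n - 1e-9).astype(int)
    layers[order] = edges
    return pd.Series(layers, index=candidates.points.index)


def _logdet_info(Xd: np.ndarray, idx: np.ndarray) -> float:
    sub = Xd[idx]
    sign, logdet = np.linalg.slogdet(sub.T @ sub)
    return logdet if sign > 0 else -np.inf


def d_optimal_select(
    candidates: CandidateSet | pd.DataFrame | np.ndarray,
    k: int,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 20,
    max_passes: int = 50,
) -> np.ndarray:
    """D-optimal subset of size ``k`` by Fedorov exchange.

    The design matrix is [1 | coordinates]; the information matrix is
    X'X of the selected rows. From a random start, the single swap
    (selected out, candidate in) that most increases log det(X'X) is
    applied until no swap improves; the best of ``n_restarts`` restarts
    is returned. Positions (integer indices into the candidate array)
    are returned, sorted.
    """
    if isinstance(candidates, CandidateSet):
        pts = candidates.points.to_numpy()
    else:
        pts = np.asarray(candidates, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
    n = pts.shape[0]
    Xd = np.column_stack([np.ones(n), pts])
    p = Xd.shape[1]
    if k > n:
        raise ValueError("k exceeds candidate count")
    if k < p:
        raise ValueError(
            f"k={k} below design-matrix column count {p}: information matrix singular"
        )
    if k == n:
        return np.arange(n)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    best_idx, best_ld = None, -np.inf
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        ld = _logdet_info(Xd, idx)
        tries = 0
        while not np.isfinite(ld) and tries < 20:
            idx = rng.choice(n, size=k, replace=False)
            ld = _logdet_info(Xd, idx)
            tries += 1
        for _ in range(max_passes):
            selected = set(idx)
            out_pool = np.array([j for j in range(n) if j not in selected])
            best_swap, best_gain = None, 1e-10
            for pos, i in enumerate(idx):
                for j in out_pool:
                    trial = idx.copy()
                    trial[pos] = j
                    ld_t = _logdet_info(Xd, trial)
                    if ld_t - ld > best_gain:
                        best_gain, best_swap = ld_t - ld, (pos, j, ld_t)
            if best_swap is None:
                break
            pos, j, ld = best_swap
            idx = idx.copy()
            idx[pos] = j
        if ld > best_ld:
            best_ld, best_idx = ld, np.sort(idx)
    if best_idx is None:
        raise ValueError("no non-singular start found")
    return best_idx


def _apportion(layer_sizes: pd.Series, k: int) -> dict[int, int]:
    """Largest-remainder apportionment of k across layers, each >= 1."""
    n = layer_sizes.sum()
    quota = layer_sizes * k / n
    base = np.floor(quota).astype(int)
    # every layer contributes at least one point when k allows
    if k >= len(layer_sizes):
        base = base.clip(lower=1)
    while base.sum() > k:
        j = (base - quota).idxmax()
        base[j] -= 1
    rem = quota - base
    while base.sum() < k:
        order = rem.sort_values(ascending=False).index
        bumped = False
        for j in order:
            if base[j] < layer_sizes[j]:
                base[j] += 1
                rem[j] = -np.inf
                bumped = True
                break
        if not bumped:
            raise ValueError("infeasible apportionment")
    if (base > layer_sizes).any():
        raise ValueError("infeasible apportionment")
    return {int(j): int(v) for j, v in base.items()}


def onion_select(
    candidates: CandidateSet,
    k: int,
    n_layers: int = 3,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 20,
) -> DesignSelection:
    """Layered D-optimal selection of ``k`` candidates.

    ``k`` is apportioned across the concentric layers proportionally to
    layer size (largest-remainder rounding, each layer >= 1 when
    feasible); an independent Fedorov-exchange D-optimal selection runs
    within each layer and the union is returned.
    """
    if k < n_layers:
        raise ValueError("k must be >= n_layers")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    layers = assign_layers(candidates, n_layers)
    counts = layers.value_counts().sort_index()
    alloc = _apportion(counts, k)
    d = candidates.points.shape[1] + 1  # design columns incl. intercept
    selected: list = []
    layer_logdet: dict[int, float] = {}
    for layer, k_layer in alloc.items():
        ids = layers.index[layers == layer]
        pts = candidates.points.loc[ids]
        if k_layer >= d and k_layer < len(ids):
            pos = d_optimal_select(pts.to_numpy(), k_layer, rng, n_restarts)
        elif k_layer >= len(ids):
            pos = np.arange(len(ids))
        else:
            # too few slots for a non-singular design: spread over the
            # layer by distance ranking instead
            dist = np.linalg.norm(
                pts.to_numpy() - candidates.points.to_numpy().mean(axis=0), axis=1
            )
            pos = np.argsort(dist, kind="stable")[
                np.linspace(0, len(ids) - 1, k_layer).round().astype(int)
            ]
        chosen = list(ids[pos])
        selected.extend(chosen)
        Xd = np.column_stack([np.ones(len(pos)), pts.to_numpy()[pos]])
        sign, ld = np.linalg.slogdet(Xd.T @ Xd)
        layer_logdet[int(layer)] = float(ld if sign > 0 else -np.inf)
    return DesignSelection(selected_ids=selected, layer_of=layers, layer_logdet=layer_logdet)
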