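"""Collection-level analysis: metric matrix, PCA ordination and summaries.

A collection of networks is reduced to a networks x 12 matrix of scaled
fingerprint dimensions.  Principal component analysis of that matrix gives
an ordination in which networks of similar topological origin cluster
together; loadings say which dimensions drive the separation, and an
optional varimax rotation redistributes them for interpretability.
Per-group median/range summaries and a robust centroid-distance outlier
screen complete the toolbox.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .metrics import DIMENSION_NAMES, GhustVector, MetricConfig, compute_ghust
from .synthetic import LabeledGraph

logger = logging.getLogger(__name__)

__all__ = [
    "MetricMatrix",
    "OrdinationResult",
    "build_matrix",
    "run_pca",
    "varimax",
    "group_summary",
    "detect_outliers",
]


@dataclass(frozen=True)
class MetricMatrix:
    """Networks x 12 matrix of scaled dimensions with labels and provenance.

    ``data`` is indexed by network name with the fixed column order
    rho1..rho12; ``groups`` aligns with the rows; ``flags`` records, per
    network, which dimensions carry their degenerate fill value.
    """

    data: pd.DataFrame
    groups: pd.Series
    flags: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(DIMENSION_NAMES):
            raise ValueError("metric matrix must have columns rho1..rho12")
        if self.data.isna().any().any():
            raise ValueError("metric matrix contains missing entries")

    @property
    def n_networks(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class OrdinationResult:
    """PCA ordination of a metric matrix.

    ``loadings`` (12 x k) holds the weight of each dimension in each
    component; ``scores`` (networks x k) the coordinates of each network;
    ``explained_variance_fraction`` the share of total variance per
    component.  ``mean`` and ``scale`` record the centering/standardization
    applied so the ordination is exactly reproducible, and ``names`` /
    ``groups`` align with the score rows.
    """

    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    rotation: str
    names: tuple[str, ...]
    groups: tuple[str, ...]
    degenerate: bool = False


def build_matrix(
    graphs: Sequence[LabeledGraph],
    config: MetricConfig = MetricConfig(),
    on_error: str = "abort",
) -> MetricMatrix:
    """Compute the fingerprint of every graph and stack the scaled vectors.

    Row order equals input order.  ``on_error='skip'`` drops graphs whose
    computation fails (logging the name); the default aborts with the graph
    name attached to the exception.
    """
    if not graphs:
        raise ValueError("empty graph collection")
    if on_error not in ("abort", "skip"):
        raise ValueError("on_error must be 'abort' or 'skip'")
    rows: list[np.ndarray] = []
    names: list[str] = []
    groups: list[str] = []
    flags: dict[str, frozenset[str]] = {}
    for name, group, g in graphs:
        try:
            vec: GhustVector = compute_ghust(g, config)
        except Exception as exc:
            if on_error == "abort":
                raise RuntimeError(f"fingerprint failed for network {name!r}: {exc}") from exc
            logger.warning("skipping network %r: %s", name, exc)
            continue
        rows.append(vec.as_array())
        names.append(name)
        groups.append(group)
        flags[name] = vec.degenerate_flags
    if not rows:
        raise ValueError("no graph in the collection could be processed")
    data = pd.DataFrame(rows, index=names, columns=list(DIMENSION_NAMES))
    return MetricMatrix(data, pd.Series(groups, index=names, name="group"), flags)


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Varimax rotation of a loading matrix (Kaiser-normalized by default).

    Returns the orthogonal rotation matrix R such that ``loadings @ R``
    maximizes the varimax criterion.
    """
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    a = loadings.copy()
    if normalize:
        comm = np.sqrt((a**2).sum(axis=1))
        comm[comm == 0] = 1.0
        a = a / comm[:, None]
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = a @ rot
        u, s, vt = np.linalg.svd(
            a.T @ (lam**3 - lam * (lam**2).sum(axis=0) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return rot


def run_pca(
    m: MetricMatrix,
    k: int = 3,
    standardize: bool = False,
    rotation: str = "none",
) -> OrdinationResult:
    """Ordinate the collection by PCA on the 12 scaled dimensions.

    The matrix is mean-centered (and optionally z-scored; zero-variance
    columns are centered only, keeping their loading at zero).  Components
    are sign-fixed so the largest-magnitude loading of each is positive,
    making output deterministic across platforms.  With
    ``rotation='varimax'`` the retained components are varimax-rotated and
    their variance shares re-attributed from the rotated scores.
    """
    if k > len(DIMENSION_NAMES):
        raise ValueError(f"k must be <= 12, got {k}")
    if m.n_networks < 2:
        raise ValueError("need at least 2 networks for an ordination")
    if rotation not in ("none", "varimax"):
        raise ValueError("rotation must be 'none' or 'varimax'")
    x = m.values()
    mean = x.mean(axis=0)
    scale = np.ones(x.shape[1])
    if standardize:
        std = x.std(axis=0, ddof=1)
        scale = np.where(std > 0, std, 1.0)
    xc = (x - mean) / scale
    total_var = xc.var(axis=0, ddof=1).sum()
    names = tuple(m.data.index)
    groups = tuple(m.groups)
    if total_var <= 1e-30:
        logger.warning("metric matrix has zero variance; no components extracted")
        return OrdinationResult(
            loadings=np.zeros((x.shape[1], k)),
            explained_variance_fraction=np.zeros(k),
            scores=np.zeros((x.shape[0], k)),
            mean=mean,
            scale=scale,
            rotation=rotation,
            names=names,
            groups=groups,
            degenerate=True,
        )
    n_comp = min(k, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(xc)
    loadings = pca.components_.T  # columns orthonormal
    frac = pca.explained_variance_ratio_

    if rotation == "varimax" and n_comp >= 2:
        rot = varimax(loadings)
        loadings = loadings @ rot
        scores = scores @ rot
        frac = scores.var(axis=0, ddof=1) / total_var

    # sign convention: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    if n_comp < k:  # pad so the caller always gets k columns
        pad = k - n_comp
        loadings = np.hstack([loadings, np.zeros((loadings.shape[0], pad))])
        scores = np.hstack([scores, np.zeros((scores.shape[0], pad))])
        frac = np.concatenate([frac, np.zeros(pad)])

    return OrdinationResult(
        loadings=loadings,
        explained_variance_fraction=frac,
        scores=scores,
        mean=mean,
        scale=scale,
        rotation=rotation,
        names=names,
        groups=groups,
    )


def group_summary(m: MetricMatrix) -> pd.DataFrame:
    """Median, min and max of every dimension within every group.

    The tidy frame (group, dimension, median, min, max) serializes directly
    for radar-style per-group profiles.
    """
    if m.groups.isna().any() or (m.groups == "").any():
        raise ValueError("every network needs a group label")
    df = m.data.copy()
    df["group"] = m.groups
    long = df.melt(id_vars="group", var_name="dimension", value_name="value")
    out = (
        long.groupby(["group", "dimension"], sort=False)["value"]
        .agg(median="median", min="min", max="max")
        .reset_index()
    )
    order = {d: i for i, d in enumerate(DIMENSION_NAMES)}
    out["_o"] = out["dimension"].map(order)
    return out.sort_values(["group", "_o"]).drop(columns="_o").reset_index(drop=True)


def detect_outliers(ordination: OrdinationResult, threshold: float = 10.0) -> list[str]:
    """Flag networks far from their group centroid in score space.

    For each group, distances of member scores to the group centroid are
    computed; a network is flagged when its distance exceeds ``threshold``
    times the median absolute deviation of the group's distances (with a
    fall-back to "any nonzero distance" when the MAD is exactly zero, i.e.
    the rest of the group is perfectly tight).  Centroid distances of
    same-class networks routinely reach several MADs — the MAD of a
    centered cloud is small relative to its tail — so the default cutoff is
    deliberately high to keep false positives rare; genuinely foreign
    networks land one to two orders of magnitude out.
    """
    if not np.isfinite(threshold):
        return []
    flagged: list[str] = []
    groups = np.asarray(ordination.groups)
    names = np.asarray(ordination.names)
    scores = ordination.scores
    for grp in dict.fromkeys(ordination.groups):
        mask = groups == grp
        pts = scores[mask]
        centroid = pts.mean(axis=0)
        dist = np.linalg.norm(pts - centroid, axis=1)
        mad = float(np.median(np.abs(dist - np.median(dist))))
        cutoff = threshold * mad
        if mad == 0.0:
            hits = dist > 1e-12
        else:
            hits = dist > cutoff
        flagged.extend(names[mask][hits].tolist())
    return flagged
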