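"""Non-target community analysis: distances, PCoA, MRPP and one-way ANOVA.

The safety question — did the biocontrol agents change the invertebrate
community emerging from treated stumps? — is answered three ways:
univariate one-way ANOVA of total abundance and taxon richness, a principal
co-ordinates ordination of the trap x taxon matrix, and the multi-response
permutation procedure (MRPP) comparing mean within-group distances against
a Monte-Carlo relabelling null, summarised by the chance-corrected
within-group agreement A = 1 - delta_observed/delta_expected (0 under
random grouping, 1 for identical within-group traps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

_METRICS = ("bray_curtis", "sorensen", "euclidean")


@dataclass
class CommunityMatrix:
    """Trap x taxon count matrix with block/treatment trap attributes."""

    counts: pd.DataFrame
    meta: pd.DataFrame
    granularity: str = "broad"

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("community counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate trap labels")

    @property
    def traps(self) -> list:
        return list(self.counts.index)

    def grouping(self, variable: str) -> pd.Series:
        return self.meta[variable]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with trap labels."""

    labels: tuple
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("distances must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class MRPPResult:
    """Multi-response permutation procedure outcome."""

    delta_observed: float
    delta_expected: float
    A: float
    p: float
    n_permutations: int
    seed: int | None
    grouping: str = ""

    def summary(self) -> str:
        from .report import format_p

        return (
            f"MRPP ({self.grouping}): delta_obs = {self.delta_observed:.4f}, "
            f"delta_exp = {self.delta_expected:.4f}, A = {self.A:.3f}, "
            f"p = {format_p(self.p)} ({self.n_permutations} permutations)"
        )


@dataclass(frozen=True)
class PCoAResult:
    """Principal co-ordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    def summary(self) -> str:
        k = self.coordinates.shape[1]
        lines = [f"PCoA: {k} positive axes"]
        for i in range(min(k, 3)):
            lines.append(
                f"  axis {i + 1}: eigenvalue {self.eigenvalues[i]:.4f} "
                f"({100 * self.proportion_explained[i]:.1f}%)"
            )
        if self.negative_eigenvalues.size:
            lines.append(
                f"  {self.negative_eigenvalues.size} negative eigenvalue(s) dropped "
                f"(most negative {self.negative_eigenvalues.min():.4f})"
            )
        return "\n".join(lines)


def distance_matrix(m: CommunityMatrix | pd.DataFrame, metric: str = "sorensen") -> DistanceMatrix:
    """Pairwise trap distances.

    bray_curtis works on counts, sorensen on presence/absence (equivalently
    Bray-Curtis of the binarised matrix), euclidean on raw counts. A pair of
    all-zero traps is undefined under bray_curtis/sorensen and is set to 0
    with a warning.
    """
    counts = m.counts if isinstance(m, CommunityMatrix) else m
    x = np.asarray(counts, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two traps")
    if metric == "bray_curtis":
        d = pdist(x, metric="braycurtis")
    elif metric == "sorensen":
        d = pdist((x > 0).astype(float), metric="braycurtis")
    elif metric == "euclidean":
        d = pdist(x, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if np.isnan(d).any():
        warnings.warn("all-zero trap pair(s); distance defined as 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(tuple(counts.index), squareform(d), metric)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centres -1/2 D^2 about row/column means, eigendecomposes, and
    scales eigenvectors by the square root of their (positive) eigenvalues.
    Negative eigenvalues — possible for semi-metric distances — are
    reported and their axes dropped, not corrected.
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-8 * max(abs(eigval.max(initial=0.0)), 1e-12), 0.0)
    pos = eigval > tol
    neg = eigval[eigval < -tol]
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            warnings.warn(
                f"requested {n_axes} axes but only {coords.shape[1]} positive; truncated",
                stacklevel=2,
            )
        coords = coords[:, :n_axes]
        lam_shown = lam[: coords.shape[1]]
    else:
        lam_shown = lam
    total = lam.sum() if lam.size else 1.0
    frame = pd.DataFrame(
        coords,
        index=list(dm.labels),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PCoAResult(
        coordinates=frame,
        eigenvalues=lam_shown,
        proportion_explained=lam_shown / total,
        negative_eigenvalues=neg,
    )


def _delta(d: np.ndarray, codes: np.ndarray, groups: np.ndarray, weighting: str) -> float:
    n = len(codes)
    delta = 0.0
    for g in groups:
        idx = np.flatnonzero(codes == g)
        ng = len(idx)
        sub = d[np.ix_(idx, idx)]
        mean_within = sub[np.triu_indices(ng, 1)].mean()
        w = ng / n if weighting == "group_size" else (ng - 1) / (n - len(groups))
        delta += w * mean_within
    return delta


def mrpp(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 9999,
    seed: int | None = None,
    weighting: str = "group_size",
) -> MRPPResult:
    """Multi-response permutation procedure.

    delta_observed is the group-size-weighted (C_g = n_g/N by default;
    ``weighting="df"`` uses (n_g-1)/(N-k)) mean within-group distance; the
    null relabels traps at random preserving group sizes. The p-value uses
    the add-one estimator (1 + #{delta_perm <= delta_obs}) / (1 + B), so it
    is never zero; A = 1 - delta_obs/delta_exp.
    """
    labels = pd.Series(list(grouping), index=list(dm.labels)) if not isinstance(grouping, pd.Series) else grouping
    codes, groups = pd.factorize(labels.loc[list(dm.labels)])
    groups = np.arange(len(groups))
    sizes = np.bincount(codes)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        raise ValueError("every group needs at least two members (singleton group found)")
    d = dm.values
    delta_obs = _delta(d, codes, groups, weighting)
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_permutations)
    work = codes.copy()
    for i in range(n_permutations):
        rng.shuffle(work)
        perm_deltas[i] = _delta(d, work, groups, weighting)
    delta_exp = float(perm_deltas.mean())
    if delta_exp == 0.0:
        a = 0.0
        p = 1.0
    else:
        a = 1.0 - delta_obs / delta_exp
        p = (1 + int((perm_deltas <= delta_obs + 1e-12).sum())) / (1 + n_permutations)
    return MRPPResult(
        delta_observed=float(delta_obs),
        delta_expected=delta_exp,
        A=float(a),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        grouping=getattr(grouping, "name", "") or "",
    )


def oneway_anova(values, grouping) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df_between, df_within, p)."""
    values = np.asarray(values, dtype=float)
    codes, groups = pd.factorize(pd.Series(list(grouping)))
    k = len(groups)
    n = len(values)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 1).any() or n - k < 1:
        raise ValueError("need at least one group with two or more values")
    samples = [values[codes == g] for g in range(k)]
    f, p = stats.f_oneway(*samples)
    return float(f), k - 1, n - k, float(p)


def richness_abundance(m: CommunityMatrix) -> pd.DataFrame:
    """Per-trap total abundance (row sum) and taxon richness (nonzero taxa)."""
    counts = m.counts
    return pd.DataFrame(
        {
            "abundance": counts.sum(axis=1),
            "richness": (counts > 0).sum(axis=1),
        },
        index=counts.index,
    )
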