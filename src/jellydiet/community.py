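"""Permutation-based community comparison on dissimilarity matrices.

Implements the spatial-comparison toolkit used on fourth-root-transformed
RRA matrices: Bray-Curtis dissimilarity, one-way PERMANOVA with permutation
p-values, pairwise tests with Bonferroni adjustment, homogeneity of
multivariate dispersion (PERMDISP), and non-metric multidimensional scaling
(NMDS) minimizing Kruskal stress-1 by iterative majorization with isotonic
regression.

The permutation p-value estimator throughout is (1 + #{stat_perm >=
stat_obs}) / (1 + n_permutations), which includes the observed labelling and
therefore never returns 0.  All permutation draws are seeded and
deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .io import ContractError


def fourth_root(matrix) -> pd.DataFrame | np.ndarray:
    """Elementwise fourth-root transform, the usual severe down-weighting of
    dominant taxa before Bray-Curtis in read-abundance data."""
    arr = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if (arr < 0).any():
        raise ContractError("fourth_root requires non-negative values")
    out = np.power(arr, 0.25)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows (samples).

    d(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik), in [0, 1]; 1 when
    two samples share no taxa.  All-zero samples are rejected by name since
    their dissimilarity is undefined.
    """
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ContractError("bray_curtis requires non-negative values")
    zero = matrix.index[arr.sum(axis=1) == 0].tolist()
    if zero:
        raise ContractError(f"all-zero samples have undefined Bray-Curtis: {zero}")
    condensed = pdist(arr, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in matrix.index])


def _group_arrays(dm: DistanceMatrix, grouping) -> tuple[np.ndarray, np.ndarray, list]:
    """Align grouping to the matrix ids; return (d^2 matrix, integer labels,
    group levels)."""
    if isinstance(grouping, pd.Series):
        missing = [i for i in dm.ids if i not in grouping.index]
        if missing:
            raise ContractError(f"grouping missing samples: {missing}")
        labels = [grouping.loc[i] for i in dm.ids]
    else:
        labels = list(grouping)
        if len(labels) != len(dm.ids):
            raise ContractError("grouping length does not match distance matrix")
    levels = sorted(set(labels))
    codes = np.array([levels.index(g) for g in labels])
    counts = np.bincount(codes, minlength=len(levels))
    if len(levels) < 2:
        raise ContractError("need at least 2 groups")
    small = [levels[i] for i in range(len(levels)) if counts[i] < 2]
    if small:
        raise ContractError(f"groups with fewer than 2 samples: {small}")
    return dm.data**2, codes, levels


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group labels.

    SS_total = (1/N) sum_{j<k} d^2;  SS_within = sum_g (1/n_g) sum_{j<k in g} d^2;
    pseudo-F = (SS_among/(a-1)) / (SS_within/(N-a)).
    """
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


@dataclass
class PermanovaResult:
    pseudo_F: float
    R_squared: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    permutation_scheme: str
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def permanova(
    dm: DistanceMatrix, grouping, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Decomposes the total sum of squared distances into among- and
    within-group components and assesses the pseudo-F by unrestricted random
    label permutations.  Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    d2, codes, levels = _group_arrays(dm, grouping)
    n_groups = len(levels)
    f_obs, r2 = _permanova_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_f(d2, perm, n_groups)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    sizes = {lvl: int((codes == i).sum()) for i, lvl in enumerate(levels)}
    return PermanovaResult(
        pseudo_F=float(f_obs), R_squared=float(r2), p_value=float(p),
        n_permutations=n_permutations, group_sizes=sizes,
        permutation_scheme="unrestricted label permutation", seed=seed,
    )


@dataclass
class PairwiseResult:
    comparisons: list[dict]
    correction: str
    n_comparisons: int

    def to_dict(self) -> dict:
        return asdict(self)


def pairwise_permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    correction: str = "bonferroni",
) -> PairwiseResult:
    """PERMANOVA on every group pair's submatrix, with Bonferroni-adjusted
    p-values (adjusted p = min(1, m * p), m = number of pairs)."""
    if correction != "bonferroni":
        raise ContractError(f"unknown correction {correction!r}")
    _, codes, levels = _group_arrays(dm, grouping)
    ids = np.array(dm.ids)
    pairs = list(itertools.combinations(range(len(levels)), 2))
    m = len(pairs)
    comparisons = []
    for k, (i, j) in enumerate(pairs):
        mask = (codes == i) | (codes == j)
        sub = dm.filter(ids[mask])
        sub_groups = pd.Series(
            [levels[c] for c in codes[mask]], index=ids[mask]
        )
        res = permanova(sub, sub_groups, n_permutations=n_permutations, seed=seed + k)
        comparisons.append({
            "group_a": levels[i],
            "group_b": levels[j],
            "pseudo_F": res.pseudo_F,
            "p_value": res.p_value,
            "p_adjusted": min(1.0, m * res.p_value),
        })
    return PairwiseResult(comparisons=comparisons, correction=correction,
                          n_comparisons=m)


# ---------------------------------------------------------------------------
# dispersion homogeneity (PERMDISP)
# ---------------------------------------------------------------------------


def _pcoa_axes(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split by eigenvalue sign.

    Returns (real-axis coordinates, imaginary-axis coordinates); squared
    distances in the embedding are real-part^2 - imaginary-part^2, the
    standard correction for the negative eigenvalues a semimetric like
    Bray-Curtis produces.
    """
    d2 = dm.data**2
    n = len(d2)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-10 * max(1.0, np.abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


@dataclass
class DispersionResult:
    group_mean_distances: dict[str, float]
    F: float
    p_value: float
    n_permutations: int
    seed: int
    distances: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "group_mean_distances": self.group_mean_distances,
            "F": self.F, "p_value": self.p_value,
            "n_permutations": self.n_permutations, "seed": self.seed,
        }


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_among = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ss_among += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within == 0:
        return 0.0 if ss_among == 0 else np.inf
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def dispersion(
    dm: DistanceMatrix, grouping, n_permutations: int = 999, seed: int = 0
) -> DispersionResult:
    """Homogeneity of multivariate dispersion across groups (PERMDISP).

    Embeds the distance matrix by principal coordinates (keeping negative-
    eigenvalue axes with the imaginary-part correction), measures each
    sample's distance to its group centroid, and compares group means with a
    one-way F whose null distribution is built by permuting the
    distance-to-centroid values across groups.
    """
    _, codes, levels = _group_arrays(dm, grouping)
    real, imag = _pcoa_axes(dm)
    n_groups = len(levels)
    dists = np.zeros(len(codes))
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        for i in idx:
            z2 = ((real[i] - c_real) ** 2).sum()
            if imag.size:
                z2 -= ((imag[i] - c_imag) ** 2).sum()
            dists[i] = np.sqrt(max(z2, 0.0))
    f_obs = _anova_f(dists, codes, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _anova_f(dists, perm, n_groups) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    means = {lvl: float(dists[codes == i].mean()) for i, lvl in enumerate(levels)}
    return DispersionResult(
        group_mean_distances=means, F=float(f_obs), p_value=float(p),
        n_permutations=n_permutations, seed=seed,
        distances=pd.Series(dists, index=list(dm.ids)),
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool
    seed: int
    stress_trace: list[float] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stress": self.stress, "n_restarts": self.n_restarts,
            "converged": self.converged, "seed": self.seed,
        }


def _nmds_once(
    delta: np.ndarray, n: int, k: int, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    """One NMDS run: alternate isotonic disparities and Guttman updates.

    Stress-1 = sqrt(sum (d - dhat)^2 / sum d^2), with dhat the isotonic
    (rank-monotone) regression of configuration distances d on the input
    dissimilarities.  The trace is non-increasing by construction: the run
    stops (keeping the previous configuration) if an update fails to
    improve.
    """
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    x = x0.copy()
    order = np.argsort(delta, kind="stable")
    trace: list[float] = []
    prev_stress = np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(x)
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
        denom = (d**2).sum()
        if denom == 0:
            trace.append(0.0)
            converged = True
            break
        stress = np.sqrt(((d - dhat) ** 2).sum() / denom)
        if stress > prev_stress:  # majorization stalled; keep previous config
            x = x_prev
            break
        trace.append(stress)
        if prev_stress - stress < tol:
            converged = True
            break
        prev_stress = stress
        x_prev = x.copy()
        # Guttman transform with disparities dhat, rescaled to the current
        # configuration norm so the (scale-invariant) iteration cannot
        # collapse the coordinates toward the origin
        dhat_sum = (dhat**2).sum()
        scaled = dhat * np.sqrt(denom / dhat_sum) if dhat_sum > 0 else dhat
        dm_sq = squareform(d)
        dhat_sq = squareform(scaled)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dm_sq > 0, dhat_sq / np.where(dm_sq > 0, dm_sq, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
        # stress-1 is scale-invariant, so pin the configuration to the input
        # dissimilarity scale to stop it drifting toward the origin
        d_norm = np.linalg.norm(pdist(x))
        if d_norm > 0:
            x *= np.linalg.norm(delta) / d_norm
    final = trace[-1] if trace else 0.0
    return x, float(final), converged, trace


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NmdsResult:
    """Non-metric MDS of a dissimilarity matrix into ``k`` dimensions.

    Minimizes Kruskal stress-1 by iterative majorization (Guttman
    transforms) alternated with isotonic regression of configuration
    distances on dissimilarity ranks.  The first restart starts from the
    principal-coordinate solution, the rest from seeded random
    configurations; the lowest-stress run is returned.  Non-convergence is
    reported via ``converged=False``, never silently.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    n = len(dm.ids)
    delta = squareform(dm.data, checks=False)
    rng = np.random.default_rng(seed)

    real, _ = _pcoa_axes(dm)
    if real.shape[1] >= k:
        x_pcoa = real[:, np.argsort(-np.var(real, axis=0))[:k]]
    else:
        x_pcoa = np.hstack([real, np.zeros((n, k - real.shape[1]))])

    best = None
    for r in range(max(1, n_restarts)):
        x0 = x_pcoa if r == 0 else rng.normal(size=(n, k))
        x, stress, converged, trace = _nmds_once(delta, n, k, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, converged, trace)
    x, stress, converged, trace = best
    coords = pd.DataFrame(
        x, index=list(dm.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(coordinates=coords, stress=stress, n_restarts=max(1, n_restarts),
                      converged=converged, seed=seed, stress_trace=trace)
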