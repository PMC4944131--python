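"""Case/control comparison of SPKMG matrices under a negative-binomial model.

The continuous SPKMG values are rounded to pseudocounts, normalized by
library size and a trimmed-mean-of-M-values (TMM) factor, a common
negative-binomial dispersion is estimated by profile maximum likelihood,
and each gene is tested with a conditional exact test: conditioning on
the gene's total count across both groups, the two-sided p-value sums
the probabilities of all splits of the total between the groups that are
no more likely than the observed one.  With dispersion 0 the split
distribution reduces to the binomial (Poisson counts); with dispersion
phi > 0 the group sums are negative binomial with shape n_g / phi.

Also provided: Benjamini-Hochberg adjustment, leading-log-fold-change
MDS coordinates for population structure, and average-linkage
hierarchical clustering of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


@dataclass
class GroupDesign:
    """Two-group design: parallel lists of sample ids and group labels."""

    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups must align")
        levels = sorted(set(self.groups))
        if len(levels) != 2:
            raise ValueError(f"exactly 2 groups required, got {levels}")
        for level in levels:
            if self.groups.count(level) < 2:
                raise ValueError(f"group {level!r} needs >= 2 samples for dispersion")
        self.levels = levels

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        g = np.asarray(self.groups)
        return g == self.levels[0], g == self.levels[1]


def to_pseudocounts(matrix: pd.DataFrame, scale: float = 1.0) -> pd.DataFrame:
    """Round scale * SPKMG to integers so a count model applies."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return (matrix * scale).round().astype(np.int64)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed mean of M-values normalization factors.

    The reference is the highest-depth sample.  For each sample, genes
    expressed in both it and the reference contribute a log-ratio M and
    a log-abundance A; the top and bottom ``trim_m`` of M and ``trim_a``
    of A are discarded and the remaining M values are averaged with
    inverse-variance (delta-method binomial) weights.  Factors are
    rescaled to geometric mean 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive library size")
    ref_name = lib.idxmax()
    ref = counts[ref_name].to_numpy(dtype=float)
    ref_lib = lib[ref_name]

    factors = {}
    for name in counts.columns:
        obs = counts[name].to_numpy(dtype=float)
        obs_lib = lib[name]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0 or name == ref_name:
            factors[name] = 1.0
            continue
        p_obs = obs[keep] / obs_lib
        p_ref = ref[keep] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic variance of M (binomial delta method)
        w = (obs_lib - obs[keep]) / (obs_lib * obs[keep]) + \
            (ref_lib - ref[keep]) / (ref_lib * ref[keep])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        mask = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if mask.sum() == 0:
            factors[name] = 1.0
            continue
        mean_m = np.sum(m[mask] / w[mask]) / np.sum(1.0 / w[mask])
        factors[name] = float(2.0 ** mean_m)
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.mean(np.log(f)))


def _nb_loglik(y: np.ndarray, mu: float, phi: float) -> float:
    """Sum of NB log pmf with mean mu and dispersion phi (var = mu + phi mu^2)."""
    if mu <= 0:
        return 0.0 if np.all(y == 0) else -np.inf
    if phi < 1e-12:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    ))


def estimate_common_dispersion(
    counts: pd.DataFrame,
    design: GroupDesign,
    bounds: tuple[float, float] = (1e-6, 10.0),
    grid_size: int = 25,
) -> float:
    """Common NB dispersion by profile ML summed over genes.

    Counts are first scaled to a common effective library size; per-gene
    group means are profiled out (the group sample mean maximizes the NB
    likelihood in the mean for any fixed dispersion).  A log-spaced grid
    locates the optimum, refined by bounded scalar minimization.
    """
    y = _equalize_libsizes(counts)
    mask_a, mask_b = design.masks()
    ya, yb = y[:, mask_a], y[:, mask_b]

    def neg_profile(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        total = 0.0
        for row_a, row_b in zip(ya, yb):
            total += _nb_loglik(row_a, float(row_a.mean()), phi)
            total += _nb_loglik(row_b, float(row_b.mean()), phi)
        return -total

    grid = np.log(np.logspace(np.log10(bounds[0]), np.log10(bounds[1]), grid_size))
    values = [neg_profile(g) for g in grid]
    best = int(np.argmin(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    res = minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded")
    if not res.success:
        log.warning("dispersion refinement did not converge; using grid optimum")
        return float(np.exp(grid[best]))
    return float(np.exp(res.x))


def _equalize_libsizes(counts: pd.DataFrame, factors: pd.Series | None = None) -> np.ndarray:
    """Rescale counts so every sample has the geometric-mean effective depth."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    target = float(np.exp(np.mean(np.log(lib))))
    scaled = counts.to_numpy(dtype=float) * (target / lib.to_numpy())
    return np.rint(scaled)


def _log_split_probs(total: int, r1: float, r2: float) -> np.ndarray:
    """Log P(Y1 = s | Y1 + Y2 = total) for s = 0..total.

    Y_g are NB group sums with common success probability; conditioning
    cancels it, leaving a negative-hypergeometric-type mass determined
    by the shapes r1, r2 (r_g = n_g / phi).  The Poisson limit
    (phi -> 0) is the binomial with weight n1 / (n1 + n2).
    """
    s = np.arange(total + 1)
    logp = (gammaln(s + r1) - gammaln(s + 1) - gammaln(r1)
            + gammaln(total - s + r2) - gammaln(total - s + 1) - gammaln(r2))
    return logp - logsumexp(logp)


def _log_binom_split(total: int, n1: int, n2: int) -> np.ndarray:
    s = np.arange(total + 1)
    p = n1 / (n1 + n2)
    logp = (gammaln(total + 1) - gammaln(s + 1) - gammaln(total - s + 1)
            + s * np.log(p) + (total - s) * np.log(1 - p))
    return logp - logsumexp(logp)


def nb_exact_test(
    counts: pd.DataFrame,
    design: GroupDesign,
    dispersion: float,
    factors: pd.Series | None = None,
) -> np.ndarray:
    """Two-sided conditional exact p-value per gene.

    After equalizing effective library sizes, each gene's total count is
    split between the groups; the p-value is the sum of split
    probabilities not exceeding that of the observed split
    (probability-mass ordering, Fisher style).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    y = _equalize_libsizes(counts, factors)
    mask_a, mask_b = design.masks()
    n1, n2 = int(mask_a.sum()), int(mask_b.sum())
    pvals = np.ones(y.shape[0])
    for i, row in enumerate(y):
        t = int(row.sum())
        if t == 0:
            continue
        s_obs = int(row[mask_a].sum())
        if dispersion < 1e-12:
            logp = _log_binom_split(t, n1, n2)
        else:
            logp = _log_split_probs(t, n1 / dispersion, n2 / dispersion)
        # sum of all outcomes no more probable than the observed one
        tol = 1e-12  # treat near-equal masses as ties
        p = float(np.exp(logsumexp(logp[logp <= logp[s_obs] + tol])))
        pvals[i] = min(p, 1.0)
    return pvals


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_analysis(
    matrix: pd.DataFrame,
    design: GroupDesign,
    scale: float = 1.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full pipeline: pseudocounts -> TMM -> dispersion -> exact test -> BH.

    Returns a table with log2 fold change (second group level vs first),
    group means of SPKMG, raw and adjusted p-values.
    """
    counts = to_pseudocounts(matrix, scale)
    factors = tmm_factors(counts)
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, design)
    pvals = nb_exact_test(counts, design, dispersion, factors)
    padj = bh_adjust(pvals)
    mask_a, mask_b = design.masks()
    prior = 0.5
    mean_a = matrix.loc[:, mask_a].mean(axis=1)
    mean_b = matrix.loc[:, mask_b].mean(axis=1)
    logfc = np.log2((mean_b + prior) / (mean_a + prior))
    return pd.DataFrame({
        "locus_id": matrix.index,
        "logFC": logfc.to_numpy(),
        f"mean_{design.levels[0]}": mean_a.to_numpy(),
        f"mean_{design.levels[1]}": mean_b.to_numpy(),
        "pvalue": pvals,
        "padj": padj,
    }).set_index("locus_id")


def mds_coordinates(
    matrix: pd.DataFrame, top_genes: int = 500, prior: float = 2.0
) -> pd.DataFrame:
    """Leading-log-fold-change MDS of samples.

    The distance between two samples is the root mean square of the
    ``top_genes`` largest absolute log2 fold changes between them
    (moderated by ``prior``); classical metric MDS embeds the distance
    matrix and the first two dimensions are returned.
    """
    if matrix.shape[1] < 3:
        raise ValueError("MDS requires at least 3 samples")
    lib = matrix.sum(axis=0).to_numpy(dtype=float)
    lib = np.where(lib <= 0, 1.0, lib)
    # moderated log abundance per sample
    logs = np.log2((matrix.to_numpy(dtype=float) + prior) /
                   (lib + 2 * prior)[None, :])
    n = matrix.shape[1]
    dist = np.zeros((n, n))
    k = min(top_genes, matrix.shape[0])
    for i in range(n):
        for j in range(i + 1, n):
            fc = np.abs(logs[:, i] - logs[:, j])
            top = np.sort(fc)[-k:]
            dist[i, j] = dist[j, i] = float(np.sqrt(np.mean(top ** 2)))
    if np.allclose(dist, 0):
        coords = np.zeros((n, 2))
    else:
        # classical MDS: double-center the squared distances
        d2 = dist ** 2
        j_mat = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j_mat @ d2 @ j_mat
        w, v = np.linalg.eigh(b)
        idx = np.argsort(w)[::-1][:2]
        coords = v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))
    return pd.DataFrame(coords, index=matrix.columns, columns=["dim1", "dim2"])


def hierarchical_cluster(matrix: pd.DataFrame, log_transform: bool = True) -> np.ndarray:
    """Average-linkage tree over samples (scipy linkage matrix).

    Distances are Euclidean over log2(SPKMG + 1) profiles by default.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    x = matrix.to_numpy(dtype=float).T
    if log_transform:
        x = np.log2(x + 1.0)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    return linkage(squareform(d, checks=False), method="average")
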