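"""Group-level statistics: intersubject correlation of MDF matrices, the
paired cluster-based permutation test (CBPT) over window lengths, and the
paired Wilcoxon signed-rank test.

The CBPT controls family-wise error across an ordered axis (window lengths)
for a paired design: a paired t statistic is computed per window length,
contiguous runs with |t| above a cluster-forming threshold become clusters
with mass = sum of t, and cluster p-values are computed against the null
distribution of the maximum |mass| under random per-subject sign flips of
the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mdf import MDFMatrix

__all__ = [
    "ISCMatrix",
    "ClusterTestResult",
    "isc_matrix",
    "cbpt_paired",
    "wilcoxon_paired",
]


@dataclass
class ISCMatrix:
    """Subjects x subjects correlation of flattened MDF matrices."""

    values: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("ISC must be symmetric")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def mean_offdiagonal(self) -> float:
        iu = np.triu_indices(self.n_subjects, k=1)
        return float(np.mean(self.values[iu]))


def isc_matrix(mdfs: list[MDFMatrix], condition: str | None = None) -> ISCMatrix:
    """Intersubject correlation of MDF matrices.

    Each subject's MDF is flattened to its strict upper triangle (the
    matrix is symmetric, so the lower half is redundant); entry (a, b) is
    the Pearson correlation between subjects a and b.  All matrices must
    share the same shape, i.e. the same condition duration and window
    parameters.
    """
    if len(mdfs) < 2:
        raise ValueError("need at least 2 subjects")
    shapes = {m.values.shape for m in mdfs}
    if len(shapes) != 1:
        raise ValueError(f"MDF shape mismatch across subjects: {sorted(shapes)}")
    vecs = np.stack([m.upper_triangle() for m in mdfs])
    values = np.corrcoef(vecs)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return ISCMatrix(values=values, condition=condition)


@dataclass
class ClusterTestResult:
    """Clusters as inclusive index ranges with mass and permutation p."""

    clusters: list[tuple[int, int, float]]
    p_values: np.ndarray
    n_permutations: int
    cluster_threshold: float
    seed: int
    t_observed: np.ndarray = field(default=None, repr=False)

    def min_p(self) -> float:
        """Smallest cluster p-value, or 1.0 when no cluster formed."""
        return float(self.p_values.min()) if len(self.p_values) else 1.0


def _t_paired(diff: np.ndarray) -> np.ndarray:
    """Paired t statistic per column of an (S, K) difference matrix."""
    s = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(s))
        t = np.where(sd > 0, t, np.where(m == 0, 0.0, np.sign(m) * np.inf))
    return t


def _clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Contiguous runs with |t| > threshold; mass = sum of t in the run."""
    above = np.abs(t) > threshold
    out: list[tuple[int, int, float]] = []
    k = 0
    n = t.size
    while k < n:
        if above[k]:
            j = k
            while j + 1 < n and above[j + 1]:
                j += 1
            out.append((k, j, float(np.sum(t[k : j + 1]))))
            k = j + 1
        else:
            k += 1
    return out


def _max_abs_mass(t: np.ndarray, threshold: float) -> float:
    cl = _clusters(t, threshold)
    return max((abs(m) for _, _, m in cl), default=0.0)


def cbpt_paired(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    cluster_threshold: float = 1.0,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ClusterTestResult:
    """Paired cluster-based permutation test over an ordered axis.

    Parameters
    ----------
    cond_a, cond_b : ndarray, shape (n_subjects, n_points)
        Matched per-subject measurements (e.g. MDF std per window length).
    cluster_threshold : float
        Cluster-forming threshold on the paired t statistic (default 1).
    n_permutations : int
        Random per-subject sign flips of the paired differences
        (default 10,000).
    seed : int
        RNG seed; results are reproducible.

    The test is two-sided: observed cluster |mass| is compared against the
    null max |mass|, and p = (1 + #null >= observed) / (1 + n_permutations),
    so p is never 0.  All-zero differences produce no clusters and no error.
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"condition shapes differ: {a.shape} vs {b.shape}")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    diff = a - b
    s, k = diff.shape
    t_obs = _t_paired(diff)
    clusters = _clusters(t_obs, cluster_threshold)
    if not clusters:
        return ClusterTestResult(
            clusters=[],
            p_values=np.array([]),
            n_permutations=n_permutations,
            cluster_threshold=cluster_threshold,
            seed=seed,
            t_observed=t_obs,
        )

    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_permutations, s))
    # mean and variance under sign flips: sum(d^2) is flip-invariant
    m_perm = (signs @ diff) / s
    ssq = np.sum(diff**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_perm = (ssq[None, :] - s * m_perm**2) / (s - 1)
        var_perm = np.clip(var_perm, 0.0, None)
        t_perm = m_perm / np.sqrt(var_perm / s)
        t_perm = np.where(
            var_perm > 0, t_perm, np.where(m_perm == 0, 0.0, np.sign(m_perm) * np.inf)
        )
    null = np.array(
        [_max_abs_mass(t_perm[p], cluster_threshold) for p in range(n_permutations)]
    )
    p_values = np.array(
        [(1 + np.sum(null >= abs(mass))) / (1 + n_permutations) for _, _, mass in clusters]
    )
    return ClusterTestResult(
        clusters=clusters,
        p_values=p_values,
        n_permutations=n_permutations,
        cluster_threshold=cluster_threshold,
        seed=seed,
        t_observed=t_obs,
    )


def wilcoxon_paired(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (delegates to scipy).

    Requires equal lengths and at least 5 non-zero differences; all-zero
    differences raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    diff = x - y
    n_nonzero = int(np.sum(diff != 0))
    if n_nonzero == 0:
        raise ValueError("all paired differences are zero")
    if n_nonzero < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n_nonzero}")
    stat, p = stats.wilcoxon(x, y, alternative=alternative)
    return float(stat), float(p)
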