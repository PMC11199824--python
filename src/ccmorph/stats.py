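"""Vertex-wise multivariate group comparison with permutation inference.

At every grid vertex the two groups' feature vectors (d = 1 for det J or
MAD, 3 for mTBM, 4 for MADMTBM) are compared with the Mahalanobis form of
the two-sample Hotelling T^2 statistic

    M = (N_S N_T / (N_S + N_T)) (S_bar - T_bar)' Sigma^-1 (S_bar - T_bar)

where Sigma is the pooled unbiased covariance of the two groups.  Instead
of the F-distribution, inference is by permutation: group labels are
randomly reassigned (the same reassignment at every vertex, preserving the
spatial correlation of the maps) and the observed M is ranked within the
permutation distribution.  A second, map-level permutation corrects for
multiple comparisons: the number of suprathreshold vertices (uncorrected
p below ``alpha_vertex``) of the observed labeling is ranked within the
suprathreshold counts of the permuted labelings, each scored against the
same permutation pool.  A max-statistic FWER variant is available as an
alternative correction.

All p-values use the add-one convention (b + 1)/(B + 1), so no p-value is
exactly zero, and every routine is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "GroupSample",
    "StatMaps",
    "mahalanobis_stat",
    "vertex_permutation_test",
    "omnibus_correction",
    "permutation_analysis",
    "ratio_map",
]

_RIDGE_EPS = 1e-8
_COND_MAX = 1e12


@dataclass
class GroupSample:
    """Feature arrays of two groups: ``a`` is (N_S, V, d), ``b`` is (N_T, V, d)."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.a.ndim == 2:
            self.a = self.a[:, :, None]
        if self.b.ndim == 2:
            self.b = self.b[:, :, None]
        if self.a.shape[1:] != self.b.shape[1:]:
            raise ValueError("groups must share vertex count and feature dimension")
        if len(self.a) < 2 or len(self.b) < 2:
            raise ValueError("each group needs at least 2 subjects")
        d = self.a.shape[2]
        if len(self.a) + len(self.b) - 2 <= d:
            raise ValueError(
                f"too few subjects ({len(self.a)}+{len(self.b)}) for feature "
                f"dimension {d}: pooled covariance is singular"
            )
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("features contain non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.a.shape[1]

    @property
    def dim(self) -> int:
        return self.a.shape[2]

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.a, self.b], axis=0)


def _m_from_masks(x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Mahalanobis M for many label assignments at once.

    ``x`` is (N, V, d); ``masks`` is (B, N) boolean, True = group S.
    Returns (B, V).  Chunked over B to bound memory.
    """
    n, v, d = x.shape
    n_s = int(masks[0].sum())
    n_t = n - n_s
    coef = n_s * n_t / (n_s + n_t)
    xx = np.einsum("nvd,nve->nvde", x, x).reshape(n, v * d * d)
    tot_xx = xx.sum(axis=0).reshape(v, d, d)
    tot_mean = x.sum(axis=0)
    xf = x.reshape(n, v * d)

    out = np.empty((len(masks), v))
    chunk = max(1, int(2.5e8 / (v * d * d * 8)))
    eye = np.eye(d)
    for lo in range(0, len(masks), chunk):
        g = masks[lo:lo + chunk].astype(np.float64)  # (B_c, N)
        sum_s = (g @ xf).reshape(-1, v, d)
        mean_s = sum_s / n_s
        mean_t = (tot_mean[None] - sum_s) / n_t
        xx_s = (g @ xx).reshape(-1, v, d, d)
        xx_t = tot_xx[None] - xx_s
        scat_s = xx_s - n_s * np.einsum("bvd,bve->bvde", mean_s, mean_s)
        scat_t = xx_t - n_t * np.einsum("bvd,bve->bvde", mean_t, mean_t)
        sigma = (scat_s + scat_t) / (n_s + n_t - 2)
        diff = mean_s - mean_t
        try:
            sol = np.linalg.solve(sigma, diff[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = None
        if sol is None or not np.all(np.isfinite(sol)):
            # ridge fallback for (near-)singular pooled covariances
            tr = np.einsum("...ii", sigma)
            sigma = sigma + (_RIDGE_EPS * tr / d)[..., None, None] * eye
            sol = np.linalg.solve(sigma, diff[..., None])[..., 0]
        out[lo:lo + chunk] = coef * np.einsum("bvd,bvd->bv", diff, sol)
    # snap numerically-zero statistics to exactly zero so that identical
    # group means tie exactly in the permutation ranking
    out[np.abs(out) < 1e-12] = 0.0
    return out


def mahalanobis_stat(sample: GroupSample, vertex: int | None = None):
    """Observed Mahalanobis M, per vertex (or at one vertex).

    Uses the pooled unbiased covariance
    ``((N_S - 1) Sigma_S + (N_T - 1) Sigma_T) / (N_S + N_T - 2)``.  The
    plain inverse is used whenever the pooled covariance is well
    conditioned; a small ridge (``1e-8 * tr(Sigma)/d``) is added only if
    the solve fails, so regular problems match the textbook statistic
    exactly.
    """
    x = sample.stacked()
    mask = np.zeros((1, len(x)), dtype=bool)
    mask[0, :len(sample.a)] = True
    m = _m_from_masks(x, mask)[0]
    # guard against ill-conditioned vertices that solved to garbage
    bad = ~np.isfinite(m) | (m < -1e-6)
    if np.any(bad):
        raise FloatingPointError(
            f"singular pooled covariance at vertex {int(np.where(bad)[0][0])}"
        )
    m = np.maximum(m, 0.0)
    if vertex is not None:
        return float(m[vertex])
    return m


def _perm_masks(n: int, n_s: int, n_perms: int, seed: int) -> np.ndarray:
    """Observed mask followed by ``n_perms`` random label permutations."""
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perms + 1, n), dtype=bool)
    masks[0, :n_s] = True
    base = np.zeros(n, dtype=bool)
    base[:n_s] = True
    for b in range(1, n_perms + 1):
        masks[b] = rng.permutation(base)
    return masks


@dataclass
class StatMaps:
    """Vertex-wise statistics of one group comparison."""

    m: np.ndarray            # Mahalanobis M per vertex
    p: np.ndarray            # uncorrected permutation p per vertex
    alpha_vertex: float
    c_obs: int               # suprathreshold vertex count
    p_corrected: float       # omnibus corrected p
    n_perms: int
    seed: int
    correction: str = "count"

    def mask(self) -> np.ndarray:
        return self.p < self.alpha_vertex


def permutation_analysis(sample: GroupSample, n_perms: int = 1000,
                         seed: int = 0, alpha_vertex: float = 0.05,
                         correction: str = "count") -> StatMaps:
    """Vertex-wise permutation p-values plus the map-level correction.

    One pool of ``n_perms`` label permutations (shared across vertices)
    drives both levels: per-vertex p ranks the observed M within the pool,
    and the correction ranks the observed map summary — the suprathreshold
    count (``correction='count'``) or the map maximum of M
    (``correction='max'``) — within the summaries of the permuted maps,
    each evaluated against the same pool.
    """
    if n_perms < 100:
        raise ValueError("need at least 100 permutations")
    x = sample.stacked()
    masks = _perm_masks(len(x), len(sample.a), n_perms, seed)
    m_all = _m_from_masks(x, masks)  # (B+1, V)
    b = n_perms

    # count >= including self: row 0 reproduces (1 + #{M_b >= M_obs})/(1 + B)
    ge_counts = rankdata(-m_all, axis=0, method="max")
    p_all = ge_counts / (b + 1)
    p_obs = p_all[0]

    if correction == "count":
        c_all = (p_all < alpha_vertex).sum(axis=1)
        c_obs = int(c_all[0])
        p_corr = float((1 + np.sum(c_all[1:] >= c_obs)) / (1 + b))
    elif correction == "max":
        mx = m_all.max(axis=1)
        c_obs = int((p_all[0] < alpha_vertex).sum())
        p_corr = float((1 + np.sum(mx[1:] >= mx[0])) / (1 + b))
    else:
        raise ValueError(f"unknown correction {correction!r}")

    return StatMaps(m=m_all[0], p=p_obs, alpha_vertex=alpha_vertex,
                    c_obs=c_obs, p_corrected=p_corr, n_perms=b, seed=seed,
                    correction=correction)


def vertex_permutation_test(sample: GroupSample, n_perms: int = 1000,
                            seed: int = 0) -> np.ndarray:
    """Uncorrected per-vertex permutation p-values, (1 + k)/(1 + B)."""
    return permutation_analysis(sample, n_perms=n_perms, seed=seed).p


def omnibus_correction(sample: GroupSample, n_perms: int = 1000,
                       alpha_vertex: float = 0.05, seed: int = 0) -> tuple[int, float]:
    """Suprathreshold-count omnibus test; returns (C_obs, corrected p)."""
    maps = permutation_analysis(sample, n_perms=n_perms, seed=seed,
                                alpha_vertex=alpha_vertex)
    return maps.c_obs, maps.p_corrected


def ratio_map(younger: np.ndarray, older: np.ndarray) -> np.ndarray:
    """Per-vertex ratio of group means, older over younger.

    Values above 1 mean expansion (or thickening) from the younger to the
    older group.  Vertices whose younger-group mean is not positive are
    masked with NaN.
    """
    younger = np.asarray(younger, dtype=np.float64)
    older = np.asarray(older, dtype=np.float64)
    mean_y = younger.mean(axis=0) if younger.ndim > 1 else younger
    mean_o = older.mean(axis=0) if older.ndim > 1 else older
    out = np.full(mean_y.shape, np.nan)
    ok = mean_y > 0
    out[ok] = mean_o[ok] / mean_y[ok]
    return out


def group_sample_from_fields(fields_a, fields_b, feature: str = "madmtbm") -> GroupSample:
    """Stack two groups' :class:`~ccmorph.morphometry.FeatureField`s.

    Vertices are flattened in row-major (u, v) order.
    """
    def stack(fields):
        return np.stack([f.feature(feature).reshape(-1, f.feature(feature).shape[-1])
                         for f in fields])
    return GroupSample(stack(fields_a), stack(fields_b))
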