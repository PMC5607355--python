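"""Point-wise GLM on skeleton maps with permutation cluster inference.

The model is an ordinary least-squares regression fitted independently at
every skeleton vertex:

    y_v = b0 + b1 * predictor + (nuisance terms) + e,   e ~ N(0, s^2)

with the t-statistic of the predictor as the per-vertex test statistic.
Multiple comparisons across the skeleton are handled by non-parametric
suprathreshold cluster analysis with family-wise error rate control: the
observed clusters are connected components of vertices whose t exceeds a
primary threshold, and their sizes are referred to the permutation null
distribution of the maximum cluster size.  Nuisance covariates are handled
under permutation with the Freedman-Lane scheme (residuals of the
nuisance-only model are permuted and the nuisance fit added back).

Usage follows the Model/Results pattern::

    model = SkeletonGLM(maps, cohort, DesignSpec("PMA_scan", ["GA_birth"]))
    res = model.fit()
    clusters = res.cluster_permutation(edges, n_perm=5000, seed=7)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

from .types import CohortTable, ValidationError

T_SENTINEL = 1e6  # cap for t when the fit is exact (zero residual variance)


@dataclass
class DesignSpec:
    """Which covariate is tested, which are nuisance, and the contrast sign."""

    predictor: str
    nuisances: list[str] = field(default_factory=list)
    contrast: str = "positive"  # positive | negative | two_sided

    def __post_init__(self) -> None:
        if self.predictor in self.nuisances:
            raise ValidationError("predictor cannot also be a nuisance covariate")
        if self.contrast not in ("positive", "negative", "two_sided"):
            raise ValidationError("contrast must be positive, negative or two_sided")


@dataclass
class ClusterResult:
    """Suprathreshold clusters with FWER-corrected permutation p-values."""

    clusters: list[np.ndarray]       # vertex index arrays
    sizes: np.ndarray                # (C,)
    peak_t: np.ndarray               # (C,)
    corrected_p: np.ndarray          # (C,)
    primary_threshold: float
    n_permutations: int
    seed: int
    null_max_sizes: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [i for i, p in enumerate(self.corrected_p) if p <= alpha]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(len(self.clusters)),
            "size": self.sizes,
            "peak_t": self.peak_t,
            "corrected_p": self.corrected_p,
        })


def _design_matrix(cohort: CohortTable | pd.DataFrame, design: DesignSpec) -> np.ndarray:
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    cols = [design.predictor] + list(design.nuisances)
    for c in cols:
        if c not in df.columns:
            raise ValidationError(f"covariate {c!r} not in cohort table")
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cols])
    # name columns for rank diagnostics
    names = ["intercept"] + cols
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        raise ValidationError(
            f"rank-deficient design matrix (rank {r} < {X.shape[1]}); "
            f"columns {names} are collinear")
    return X


def _ols_t(X: np.ndarray, Y: np.ndarray, cidx: int = 1):
    """Vectorized per-column OLS; returns (beta, se, t) for column ``cidx``.

    Y is (n, V); exact fits (zero residual variance) yield t = +/-T_SENTINEL.
    """
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y                               # (p, V)
    resid = Y - X @ beta
    df = n - p
    rss = np.einsum("nv,nv->v", resid, resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    var = sigma2 * xtx_inv[cidx, cidx]
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[cidx] / se
    exact = se < np.abs(beta[cidx]) / T_SENTINEL
    t = np.where(exact, np.sign(beta[cidx]) * T_SENTINEL, t)
    t = np.where(np.isnan(t), 0.0, t)
    return beta, se, t, df


class SkeletonGLM:
    """Per-vertex linear model of skeleton maps on cohort covariates.

    Parameters
    ----------
    maps : ndarray (n_subjects, n_vertices)
        Projected metric values; NaN marks vertices missing for a subject
        (outside the brain after registration).
    cohort : CohortTable or DataFrame
        One row per subject, aligned with ``maps`` rows.
    design : DesignSpec
    min_complete : float
        A vertex is analysed only if at least this fraction of subjects has
        data there (complete-case per vertex); default 0.9.
    """

    def __init__(self, maps: np.ndarray, cohort, design: DesignSpec,
                 min_complete: float = 0.9):
        self.maps = np.asarray(maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValidationError("maps must be (n_subjects, n_vertices)")
        self.cohort = cohort
        self.design = design
        self.X = _design_matrix(cohort, design)
        n, p = self.X.shape
        if self.maps.shape[0] != n:
            raise ValidationError("maps rows must match cohort rows")
        if n < p + 3:
            raise ValidationError(
                f"need at least {p + 3} subjects for {p} regressors, got {n}")
        observed = ~np.isnan(self.maps)
        self.vertex_mask = observed.mean(axis=0) >= min_complete
        self.min_complete = min_complete

    @classmethod
    def from_maps(cls, skeleton_maps, cohort, design: DesignSpec, **kw) -> "SkeletonGLM":
        """Build from a list of SkeletonMap objects (cohort row order)."""
        rows = []
        for m in skeleton_maps:
            v = m.values.copy()
            v[m.missing] = np.nan
            rows.append(v)
        return cls(np.vstack(rows), cohort, design, **kw)

    def fit(self) -> "SkeletonGLMResults":
        Y = self.maps[:, self.vertex_mask]
        nv_total = self.maps.shape[1]
        any_nan = np.isnan(Y).any()
        if not any_nan:
            beta, se, t, df = _ols_t(self.X, Y)
        else:
            # per-vertex complete case
            p = self.X.shape[1]
            beta = np.zeros((p, Y.shape[1]))
            se = np.zeros(Y.shape[1])
            t = np.zeros(Y.shape[1])
            df = self.X.shape[0] - p
            for j in range(Y.shape[1]):
                ok = ~np.isnan(Y[:, j])
                bj, sj, tj, _ = _ols_t(self.X[ok], Y[ok, j:j + 1])
                beta[:, j], se[j], t[j] = bj[:, 0], sj[0], tj[0]
        tmap = np.full(nv_total, np.nan)
        tmap[self.vertex_mask] = t
        beta_full = np.full((self.X.shape[1], nv_total), np.nan)
        beta_full[:, self.vertex_mask] = beta
        se_full = np.full(nv_total, np.nan)
        se_full[self.vertex_mask] = se
        return SkeletonGLMResults(model=self, params=beta_full, bse=se_full,
                                  tvalues=tmap, df_resid=df)


@dataclass
class SkeletonGLMResults:
    """Fitted per-vertex estimates and the cluster-permutation interface."""

    model: SkeletonGLM
    params: np.ndarray    # (p, V): intercept, predictor, nuisances
    bse: np.ndarray       # (V,) SE of the predictor coefficient
    tvalues: np.ndarray   # (V,) predictor t-statistic, NaN where excluded
    df_resid: int

    @property
    def predictor_betas(self) -> np.ndarray:
        return self.params[1]

    def default_primary_threshold(self, p_unc: float = 0.01) -> float:
        """t for an uncorrected one-sided p at the residual df (convention)."""
        return float(sps.t.isf(p_unc, self.df_resid))

    def _signed_t(self) -> np.ndarray:
        c = self.model.design.contrast
        t = self.tvalues
        if c == "positive":
            return t
        if c == "negative":
            return -t
        return np.abs(t)

    def cluster_permutation(self, edges: np.ndarray, n_perm: int = 1000,
                            seed: int = 0, primary_threshold: float | None = None
                            ) -> ClusterResult:
        """Suprathreshold cluster analysis with a permutation FWER null.

        ``edges`` is the (E, 2) vertex adjacency of the skeleton mesh.  The
        null distribution is the maximum suprathreshold cluster size under
        Freedman-Lane permutation of nuisance-model residuals; corrected
        p = (1 + #{null max >= observed size}) / (1 + n_perm), the +1 terms
        standing for the always-included identity permutation.
        """
        if n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        model = self.model
        if primary_threshold is None:
            primary_threshold = self.default_primary_threshold()
        vm = model.vertex_mask
        Y = model.maps[:, vm]
        if np.isnan(Y).any():
            # permutation machinery needs a rectangular matrix; restrict to
            # vertices observed in every subject
            full = ~np.isnan(Y).any(axis=0)
            vm = vm.copy()
            vm[np.flatnonzero(vm)[~full]] = False
            Y = model.maps[:, vm]
        n = Y.shape[0]
        X = model.X
        # adjacency restricted to analysed vertices, relabelled compactly
        keep = np.flatnonzero(vm)
        pos = -np.ones(model.maps.shape[1], dtype=int)
        pos[keep] = np.arange(len(keep))
        e = edges[np.all(vm[edges], axis=1)]
        e = pos[e]
        graph = sp.coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(keep), len(keep))).tocsr()
        graph = graph + graph.T

        signed_obs = self._signed_t()[vm]
        obs_clusters = _clusters(signed_obs > primary_threshold, graph)

        # Freedman-Lane: permute residuals of the nuisance-only model
        Z = np.delete(X, 1, axis=1)  # intercept + nuisances
        Zpinv = np.linalg.pinv(Z)
        fitted = Z @ (Zpinv @ Y)
        resid = Y - fitted
        rng = np.random.default_rng(seed)
        null_max = np.zeros(n_perm, dtype=int)
        contrast = model.design.contrast
        for b in range(n_perm):
            perm = rng.permutation(n)
            Yb = fitted + resid[perm]
            _, _, tb, _ = _ols_t(X, Yb)
            if contrast == "negative":
                tb = -tb
            elif contrast == "two_sided":
                tb = np.abs(tb)
            null_max[b] = _max_cluster_size(tb > primary_threshold, graph)

        sizes = np.array([len(c) for c in obs_clusters], dtype=int)
        pvals = np.array([
            (1 + int(np.sum(null_max >= s))) / (1 + n_perm) for s in sizes])
        peak = np.array([signed_obs[c].max() for c in obs_clusters]) if obs_clusters else np.empty(0)
        clusters_global = [keep[c] for c in obs_clusters]
        return ClusterResult(clusters=clusters_global, sizes=sizes, peak_t=peak,
                             corrected_p=pvals, primary_threshold=float(primary_threshold),
                             n_permutations=n_perm, seed=seed, null_max_sizes=null_max)

    def summary(self) -> str:
        d = self.model.design
        t = self.tvalues[~np.isnan(self.tvalues)]
        lines = [
            "Skeleton GLM Results",
            "=" * 44,
            f"Predictor:          {d.predictor}",
            f"Nuisances:          {', '.join(d.nuisances) or '(none)'}",
            f"Contrast:           {d.contrast}",
            f"Subjects:           {self.model.X.shape[0]}",
            f"Vertices analysed:  {t.size} / {self.tvalues.size}",
            f"Residual df:        {self.df_resid}",
            f"t range:            [{t.min():.3f}, {t.max():.3f}]" if t.size else "t range:            (none)",
            f"mean predictor b:   {np.nanmean(self.predictor_betas):.6g}",
            "=" * 44,
        ]
        return "\n".join(lines)


def _clusters(mask: np.ndarray, graph: sp.csr_matrix) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = graph[idx][:, idx]
    _, labels = connected_components(sub, directed=False)
    return [idx[labels == k] for k in range(labels.max() + 1)]


def _max_cluster_size(mask: np.ndarray, graph: sp.csr_matrix) -> int:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0
    sub = graph[idx][:, idx]
    _, labels = connected_components(sub, directed=False)
    return int(np.bincount(labels).max())


__all__ = ["DesignSpec", "SkeletonGLM", "SkeletonGLMResults", "ClusterResult", "T_SENTINEL"]
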