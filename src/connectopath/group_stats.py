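"""Element-wise general linear models and inference for group comparisons.

Vertex-wise (gradient) and edge-wise (connectivity) responses are fitted
with ordinary least squares against a design containing the group contrast
and nuisance covariates (age, acquisition site, head motion, optionally
sex).  Family-wise error over vertices is controlled by permutation of the
maximum supra-threshold cluster mass with Freedman-Lane residual shuffling
under the nuisance model; edge-wise tests use Benjamini-Hochberg FDR.
All tests are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .mesh import SurfaceMesh

__all__ = [
    "make_design",
    "GLMResult",
    "ClusterResult",
    "fit_glm",
    "cluster_correction_permutation",
    "fdr_bh",
    "interaction_ftest",
    "partial_correlation",
    "two_sample_t_from_summary",
    "MassUnivariateGLM",
    "PermutationClusterTest",
]


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


def make_design(
    covariates: pd.DataFrame,
    *,
    group_col: str = "group",
    case_label: str = "case",
    continuous: tuple[str, ...] = ("age", "fd"),
    categorical: tuple[str, ...] = ("site",),
    interaction: bool = False,
) -> pd.DataFrame:
    """Build a named design matrix from a covariate table.

    Columns: intercept, binary group (case=1), the continuous covariates,
    dummy columns for each categorical covariate (reference level = first
    alphabetically), and optionally ``age_x_group`` (centered age times
    group).  Raises on rank deficiency, naming the collinear columns.
    """
    n = len(covariates)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    group = (covariates[group_col].to_numpy() == case_label).astype(float)
    cols["group"] = group
    for c in continuous:
        cols[c] = covariates[c].to_numpy(dtype=float)
    for c in categorical:
        levels = sorted(covariates[c].astype(str).unique())
        for lev in levels[1:]:
            cols[f"{c}_{lev}"] = (covariates[c].astype(str) == lev).to_numpy(dtype=float)
    if interaction:
        if "age" not in cols:
            raise ValueError("interaction requires an 'age' column")
        age_c = cols["age"] - cols["age"].mean()
        cols["age_x_group"] = age_c * group
    design = pd.DataFrame(cols)
    _check_full_rank(design.to_numpy(), list(design.columns))
    return design


@dataclass
class GLMResult:
    beta: np.ndarray          # (p, E)
    t: np.ndarray             # (E,)
    p: np.ndarray             # (E,)
    cohens_d: np.ndarray | None
    df_resid: int
    contrast: str
    column_names: list[str]
    sigma2: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"t": self.t, "p": self.p})
        if self.cohens_d is not None:
            out["cohens_d"] = self.cohens_d
        for i, name in enumerate(self.column_names):
            out[f"beta_{name}"] = self.beta[i]
        return out


def _as_design(design) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        return design
    raise TypeError("design must be a pandas DataFrame with named columns")


def fit_glm(response: np.ndarray, design: pd.DataFrame, contrast: str = "group") -> GLMResult:
    """Ordinary least squares per response element with a single contrast.

    ``response`` is (N, E) (or (N,) for one element).  The contrast t is
    ``beta / SE(beta)`` with two-tailed p from Student t on the residual
    degrees of freedom.  For a binary group contrast, Cohen's d is computed
    from the covariate-adjusted t as ``t * sqrt(1/n1 + 1/n2)``.
    """
    design = _as_design(design)
    y = np.asarray(response, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    if contrast not in names:
        raise ValueError(f"contrast {contrast!r} not among design columns {names}")
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError(f"response has {y.shape[0]} rows but design has {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    _check_full_rank(x, names)
    if n <= p:
        raise ValueError(f"need N > rank(design) = {p}, got N = {n}")
    c = names.index(contrast)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[c, c])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[c] / se
    pval = 2.0 * sps.t.sf(np.abs(t), df)
    d = None
    gvals = x[:, c]
    if set(np.unique(gvals)) <= {0.0, 1.0} and len(np.unique(gvals)) == 2:
        n1 = int(gvals.sum())
        n2 = n - n1
        d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    if squeeze:
        t, pval = float(t[0]), float(pval[0])
        d = float(d[0]) if d is not None else None
    return GLMResult(
        beta=beta[:, 0] if squeeze else beta,
        t=t, p=pval, cohens_d=d, df_resid=df, contrast=contrast,
        column_names=names, sigma2=sigma2,
    )


# --------------------------------------------------------------------------
# permutation cluster inference
# --------------------------------------------------------------------------

def _cluster_labels(mask_batch: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Connected-component labels for batched vertex masks.

    ``mask_batch`` is (B, V) boolean; components are computed on the
    subgraph induced by each row's True vertices via min-label propagation
    over the shared edge list.  Non-member vertices get the sentinel V.
    """
    b, v = mask_batch.shape
    labels = np.where(mask_batch, np.arange(v)[None, :], v)
    if edges.size == 0:
        return labels
    u, w = edges[:, 0], edges[:, 1]
    rows = np.arange(b)[:, None]
    both = mask_batch[:, u] & mask_batch[:, w]
    for _ in range(v):
        prev = labels.copy()
        m = np.where(both, np.minimum(labels[:, u], labels[:, w]), v)
        np.minimum.at(labels, (rows, u[None, :].repeat(b, axis=0)), m)
        np.minimum.at(labels, (rows, w[None, :].repeat(b, axis=0)), m)
        if np.array_equal(labels, prev):
            break
    return labels


def _max_cluster_masses(tmaps: np.ndarray, edges: np.ndarray, threshold: float) -> np.ndarray:
    """Maximum signed-cluster |t| mass per row of a (B, V) t-map batch."""
    b, v = tmaps.shape
    out = np.zeros(b)
    for mask in (tmaps > threshold, tmaps < -threshold):
        if not mask.any():
            continue
        labels = _cluster_labels(mask, edges)
        flat = (np.arange(b)[:, None] * (v + 1) + labels).ravel()
        weights = np.where(mask, np.abs(tmaps), 0.0).ravel()
        masses = np.bincount(flat, weights=weights, minlength=b * (v + 1)).reshape(b, v + 1)
        masses[:, v] = 0.0  # sentinel bucket
        out = np.maximum(out, masses.max(axis=1))
    return out


def _contrast_t_batch(ystar: np.ndarray, x: np.ndarray, c: int) -> np.ndarray:
    """Contrast t-maps for a batch of response matrices (B, N, V)."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    h = xtx_inv @ x.T                      # (p, N)
    beta = np.einsum("pn,bnv->bpv", h, ystar)
    resid = ystar - np.einsum("np,bpv->bnv", x, beta)
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df   # (B, V)
    se = np.sqrt(sigma2 * xtx_inv[c, c])
    with np.errstate(divide="ignore", invalid="ignore"):
        return beta[:, c, :] / se


@dataclass
class ClusterResult:
    clusters: list[dict]            # vertex indices, mass, sign, p_fwe
    cluster_defining_p: float
    alpha: float
    n_permutations: int
    t_threshold: float
    t_observed: np.ndarray
    null_max_mass: np.ndarray = field(repr=False)

    def significant_vertices(self) -> np.ndarray:
        verts: list[int] = []
        for cl in self.clusters:
            if cl["p_fwe"] <= self.alpha:
                verts.extend(cl["vertices"])
        return np.asarray(sorted(verts), dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster": i,
                    "size": len(cl["vertices"]),
                    "mass": cl["mass"],
                    "sign": cl["sign"],
                    "p_fwe": cl["p_fwe"],
                }
                for i, cl in enumerate(self.clusters)
            ]
        )


def cluster_correction_permutation(
    response: np.ndarray,
    design: pd.DataFrame,
    mesh: SurfaceMesh,
    contrast: str = "group",
    *,
    cluster_p: float = 0.025,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    batch_size: int = 250,
) -> ClusterResult:
    """Family-wise cluster inference by Freedman-Lane permutation.

    Vertices whose two-tailed contrast p falls below ``cluster_p`` are
    grouped into mesh-connected, sign-consistent clusters scored by the sum
    of |t| (cluster mass).  The null distribution of the maximum mass is
    built by permuting the residuals of the nuisance-only model and adding
    back the nuisance fit (Freedman-Lane), then refitting the full model.
    Cluster ``p_fwe`` is the (add-one) proportion of null maxima at or
    above the observed mass.
    """
    design = _as_design(design)
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if not mesh.is_connected():
        raise ValueError("mesh adjacency graph is disconnected")
    y = np.asarray(response, dtype=float)
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    c = names.index(contrast)
    n, p = x.shape
    df = n - p
    t_thresh = float(sps.t.ppf(1.0 - cluster_p / 2.0, df))
    edges = mesh.edges()

    t_obs = _contrast_t_batch(y[None], x, c)[0]

    # observed clusters, per sign
    clusters: list[dict] = []
    for sign, mask in (("pos", t_obs > t_thresh), ("neg", t_obs < -t_thresh)):
        if not mask.any():
            continue
        labels = _cluster_labels(mask[None], edges)[0]
        for lab in np.unique(labels[mask]):
            verts = np.where(labels == lab)[0]
            clusters.append(
                {"vertices": verts.tolist(), "mass": float(np.abs(t_obs[verts]).sum()), "sign": sign}
            )

    # Freedman-Lane null: permute nuisance-model residuals
    z = np.delete(x, c, axis=1)
    hz = z @ np.linalg.pinv(z)
    fitted = hz @ y
    resid = y - fitted
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        perm = np.stack([rng.permutation(n) for _ in range(b)])
        ystar = resid[perm] + fitted[None]
        t_null = _contrast_t_batch(ystar, x, c)
        null_max[done : done + b] = _max_cluster_masses(t_null, edges, t_thresh)
        done += b

    for cl in clusters:
        cl["p_fwe"] = float((1 + np.sum(null_max >= cl["mass"])) / (n_perm + 1))
    clusters.sort(key=lambda cl: cl["p_fwe"])
    return ClusterResult(
        clusters=clusters,
        cluster_defining_p=cluster_p,
        alpha=alpha,
        n_permutations=n_perm,
        t_threshold=t_thresh,
        t_observed=t_obs,
        null_max_mass=null_max,
    )


def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def interaction_ftest(response: np.ndarray, design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Partial F-test for the age-by-group interaction column.

    ``design`` must contain ``age_x_group`` (centered age times group); the
    statistic compares the models with and without that column and follows
    F(1, residual df), identical to the squared interaction t.
    """
    design = _as_design(design)
    if "age_x_group" not in design.columns:
        raise ValueError("design must contain an 'age_x_group' column (see make_design)")
    res = fit_glm(response, design, contrast="age_x_group")
    t = np.asarray(res.t, dtype=float)
    f = t**2
    p = sps.f.sf(f, 1, res.df_resid)
    if np.ndim(res.t) == 0:
        return float(f), float(p)
    return f, p


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates.

    Both variables are residualized on an intercept plus the covariates;
    the two-tailed p uses df = N - n_covariates - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need N > n_covariates + 2 ({k + 2}), got N = {n}")
    z = np.column_stack([np.ones(n), cov])
    h = z @ np.linalg.pinv(z)
    rx = x - h @ x
    ry = y - h @ y
    if rx.std() < 1e-12 * max(1.0, x.std()):
        raise ValueError("a covariate is collinear with x; partial correlation undefined")
    if ry.std() == 0:
        raise ValueError("y has no residual variance after covariate removal")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - k - 2
    if 1.0 - r**2 < 1e-15:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    return r, float(2.0 * sps.t.sf(abs(t), df))


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df), float(2.0 * sps.t.sf(abs(t), df))


class MassUnivariateGLM(BaseEstimator):
    """Scikit-learn style wrapper around :func:`fit_glm`.

    Parameters
    ----------
    contrast : str
        Design column to test (default the binary group indicator).

    Attributes
    ----------
    result_ : GLMResult
    t_, p_, cohens_d_ : per-element statistics
    """

    def __init__(self, contrast: str = "group"):
        self.contrast = contrast

    def fit(self, X: pd.DataFrame, y: np.ndarray):
        self.result_ = fit_glm(y, X, contrast=self.contrast)
        self.t_ = self.result_.t
        self.p_ = self.result_.p
        self.cohens_d_ = self.result_.cohens_d
        self.df_resid_ = self.result_.df_resid
        return self


class PermutationClusterTest(BaseEstimator):
    """Estimator interface for permutation cluster FWE correction."""

    def __init__(
        self,
        contrast: str = "group",
        cluster_p: float = 0.025,
        alpha: float = 0.05,
        n_perm: int = 1000,
        seed: int = 0,
    ):
        self.contrast = contrast
        self.cluster_p = cluster_p
        self.alpha = alpha
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: np.ndarray, *, mesh: SurfaceMesh):
        self.result_ = cluster_correction_permutation(
            y, X, mesh, self.contrast,
            cluster_p=self.cluster_p, alpha=self.alpha,
            n_perm=self.n_perm, seed=self.seed,
        )
        return self
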