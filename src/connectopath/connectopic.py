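"""Connectopic gradient mapping of a region of interest.

The map is computed in four steps:

1. a lossless SVD reduction of the reference (rest-of-cortex) time-series,
2. connectivity fingerprints: Pearson correlation of every ROI vertex
   time-series with every retained reference component,
3. an eta-squared similarity matrix between fingerprints, and
4. Laplacian eigenmaps of the similarity graph; the smallest nontrivial
   generalized eigenvectors are the connectopic gradients.

Per-subject maps are aligned to a group template (built from the averaged
control-group similarity matrix) by orthogonal Procrustes rotation.

The eta-squared coefficient between fingerprint rows a and b uses the
paired-profile form: with m_i = (a_i + b_i)/2 and Mbar = mean(m),

    eta2(a, b) = 1 - sum_i[(a_i - m_i)^2 + (b_i - m_i)^2]
                     / sum_i[(a_i - Mbar)^2 + (b_i - Mbar)^2]

which lies in [0, 1] and equals 1 exactly when a == b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ReducedReference",
    "Fingerprints",
    "SimilarityMatrix",
    "ConnectopicMap",
    "GradientTemplate",
    "svd_reduce_reference",
    "connectivity_fingerprints",
    "eta2_similarity",
    "laplacian_eigenmaps",
    "build_group_template",
    "align_to_template",
    "ConnectopicMapping",
    "ProcrustesAlignment",
]


@dataclass
class ReducedReference:
    """SVD factorization of the centered reference time-series."""

    component_ts: np.ndarray        # (T, r) left singular vectors scaled by singular values
    singular_values: np.ndarray     # (r,)
    rank: int
    right_vectors: np.ndarray = field(repr=False)   # (r, V_kept)
    column_means: np.ndarray = field(repr=False)    # (V_kept,)
    kept_columns: np.ndarray = field(repr=False)    # indices into the original columns

    def reconstruct(self) -> np.ndarray:
        """Centered reference matrix rebuilt from the stored factors."""
        return self.component_ts @ self.right_vectors


@dataclass
class Fingerprints:
    values: np.ndarray  # (V_roi, r) Pearson correlations


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # (V_roi, V_roi) eta-squared coefficients


@dataclass
class ConnectopicMap:
    gradients: np.ndarray       # (V_roi, k), columns ordered by ascending eigenvalue
    eigenvalues: np.ndarray     # (k,), ascending
    aligned: bool = False
    template_id: str | None = None
    residual: float | None = None


@dataclass
class GradientTemplate:
    gradients: np.ndarray
    eigenvalues: np.ndarray | None = None
    provenance: str = ""


def svd_reduce_reference(reference_ts: np.ndarray) -> ReducedReference:
    """Losslessly factor the column-centered reference time-series.

    Columns with zero variance are dropped (with a warning reporting the
    count); all components with singular value above numerical tolerance
    are retained, so the centered input can be reconstructed exactly.
    """
    x = np.asarray(reference_ts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("reference time-series must be a (T >= 2, V) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("reference time-series contains non-finite values")
    kept = np.where(np.ptp(x, axis=0) > 0)[0]
    if kept.size == 0:
        raise ValueError("all reference columns are constant; nothing to reduce")
    if kept.size < x.shape[1]:
        warnings.warn(f"dropping {x.shape[1] - kept.size} constant reference column(s)")
    x = x[:, kept]
    mu = x.mean(axis=0)
    u, s, vt = np.linalg.svd(x - mu, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    return ReducedReference(
        component_ts=u[:, :r] * s[:r],
        singular_values=s[:r],
        rank=r,
        right_vectors=vt[:r],
        column_means=mu,
        kept_columns=kept,
    )


def connectivity_fingerprints(roi_ts: np.ndarray, reduced: ReducedReference) -> Fingerprints:
    """Correlate every ROI vertex with every retained reference component."""
    roi = np.asarray(roi_ts, dtype=float)
    comp = reduced.component_ts
    if roi.shape[0] != comp.shape[0]:
        raise ValueError(
            f"time dimension mismatch: ROI has T={roi.shape[0]}, reference components T={comp.shape[0]}"
        )
    bad = np.where(np.ptp(roi, axis=0) == 0)[0]
    if bad.size:
        raise ValueError(f"constant ROI time-series at vertex/vertices {bad.tolist()}")
    rc = roi - roi.mean(axis=0)
    cc = comp - comp.mean(axis=0)
    num = rc.T @ cc
    denom = np.outer(np.sqrt((rc**2).sum(axis=0)), np.sqrt((cc**2).sum(axis=0)))
    vals = np.clip(num / denom, -1.0, 1.0)
    return Fingerprints(values=vals)


def eta2_similarity(fp: Fingerprints | np.ndarray) -> SimilarityMatrix:
    """Pairwise eta-squared similarity between fingerprint rows.

    Vectorized evaluation of the paired-profile formula in the module
    docstring; for rows a, b it reduces to
    ``1 - (||a - b||^2 / 2) / (S2_a + S2_b - 2 r mu_ab^2)`` where S2 are raw
    sums of squares, mu_ab the mean of the pooled profile and r the
    fingerprint length.  Identical rows (including the equal-constant
    degenerate pair, where the denominator vanishes) get similarity 1.
    """
    a = fp.values if isinstance(fp, Fingerprints) else np.asarray(fp, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("fingerprints must be a (V >= 2, r >= 2) matrix")
    if not np.all(np.isfinite(a)):
        raise ValueError("fingerprints contain non-finite values")
    v, r = a.shape
    sq = (a**2).sum(axis=1)                       # S2_i
    gram = a @ a.T
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram   # ||a_i - a_j||^2
    np.clip(d2, 0.0, None, out=d2)
    row_mean = a.mean(axis=1)
    mu = 0.5 * (row_mean[:, None] + row_mean[None, :])
    den = sq[:, None] + sq[None, :] - 2.0 * r * mu**2
    num = 0.5 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = 1.0 - num / den
    # identical rows (incl. the zero-denominator equal-constant pair) are 1 by
    # definition; detect them exactly rather than through the cancellation-
    # prone num == 0 test
    _, inverse = np.unique(a, axis=0, return_inverse=True)
    eta[inverse[:, None] == inverse[None, :]] = 1.0
    np.fill_diagonal(eta, 1.0)
    eta = 0.5 * (eta + eta.T)
    return SimilarityMatrix(values=np.clip(eta, 0.0, 1.0))


def _check_connected(w: np.ndarray) -> None:
    n_comp, labels = connected_components(sparse.csr_matrix(w > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"similarity graph is disconnected: component sizes {sizes}")


def _orient_sign(grad: np.ndarray, orient: np.ndarray | None) -> np.ndarray:
    """Fix per-column sign: nonnegative correlation with ``orient`` when
    given, otherwise the entry of largest magnitude is made positive."""
    out = grad.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if orient is not None and np.std(orient) > 0:
            s = np.corrcoef(col, orient)[0, 1]
        else:
            s = col[np.argmax(np.abs(col))]
        if s < 0:
            out[:, j] = -col
    return out


def laplacian_eigenmaps(
    sim: SimilarityMatrix | np.ndarray,
    k: int = 3,
    *,
    normalization: str = "random_walk",
    epsilon: float | None = None,
    orient: np.ndarray | None = None,
) -> ConnectopicMap:
    """Spectral embedding of the similarity graph.

    Solves the generalized eigenproblem ``L v = lambda D v`` (random-walk
    normalization; ``L = D - W``, ``D`` the degree matrix) or the plain
    ``L v = lambda v`` when ``normalization='unnormalized'``.  The trivial
    constant eigenvector (eigenvalue ~ 0) is discarded; the ``k`` smallest
    nontrivial eigenvectors, eigenvalues ascending, form the gradients.

    ``epsilon`` optionally zeroes edges with weight below the threshold; the
    call aborts if that disconnects the graph.
    """
    w = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    v = w.shape[0]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("similarity matrix is asymmetric beyond tolerance")
    if k < 1 or k >= v:
        raise ValueError(f"k must satisfy 1 <= k < V ({v}), got {k}")
    w = 0.5 * (w + w.T)
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    if epsilon is not None:
        thresholded = np.where(w >= epsilon, w, 0.0)
        _check_connected(thresholded)
        w = thresholded
    _check_connected(w)
    d = w.sum(axis=1)
    lap = np.diag(d) - w
    if normalization == "random_walk":
        evals, evecs = linalg.eigh(lap, np.diag(d))
    elif normalization == "unnormalized":
        evals, evecs = linalg.eigh(lap)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    # eigh returns ascending eigenvalues; index 0 is the trivial constant mode
    grads = _orient_sign(evecs[:, 1 : k + 1], orient)
    return ConnectopicMap(gradients=grads, eigenvalues=np.maximum(evals[1 : k + 1], 0.0))


def build_group_template(
    sims: list[SimilarityMatrix | np.ndarray],
    k: int = 3,
    *,
    normalization: str = "random_walk",
    orient: np.ndarray | None = None,
    provenance: str = "",
) -> GradientTemplate:
    """Eigenmap of the element-wise mean similarity matrix.

    The per-entry values are sorted before summation, making the template
    bitwise invariant to the order of the contributing subjects.
    """
    if not sims:
        raise ValueError("need at least one similarity matrix")
    mats = [m.values if isinstance(m, SimilarityMatrix) else np.asarray(m, float) for m in sims]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError(f"similarity matrices differ in shape: {m.shape} vs {shape}")
    stack = np.sort(np.stack(mats, axis=0), axis=0)
    mean = np.add.reduce(stack, axis=0) / len(mats)
    cmap = laplacian_eigenmaps(mean, k, normalization=normalization, orient=orient)
    return GradientTemplate(
        gradients=cmap.gradients,
        eigenvalues=cmap.eigenvalues,
        provenance=provenance or f"mean of {len(mats)} similarity matrices",
    )


def align_to_template(cmap: ConnectopicMap, template: GradientTemplate) -> ConnectopicMap:
    """Orthogonally rotate/reflect the subject map onto the template.

    Single-pass orthogonal Procrustes: the transform R minimizing
    ``||G R - T||_F`` over orthogonal matrices, applied across gradient
    columns.  Rows with missing values (dropped vertices) are excluded from
    the fit and carried through unchanged.
    """
    g = cmap.gradients
    t = template.gradients
    if g.shape[0] != t.shape[0]:
        raise ValueError(f"vertex count mismatch: map {g.shape[0]} vs template {t.shape[0]}")
    if g.shape[1] != t.shape[1]:
        raise ValueError(f"gradient count mismatch: map {g.shape[1]} vs template {t.shape[1]}")
    ok = np.all(np.isfinite(g), axis=1) & np.all(np.isfinite(t), axis=1)
    rot, _ = orthogonal_procrustes(g[ok], t[ok])
    aligned = np.full_like(g, np.nan)
    aligned[ok] = g[ok] @ rot
    residual = float(np.linalg.norm(aligned[ok] - t[ok]))
    return ConnectopicMap(
        gradients=aligned,
        eigenvalues=cmap.eigenvalues,
        aligned=True,
        template_id=template.provenance or "template",
        residual=residual,
    )


class ConnectopicMapping(BaseEstimator):
    """Per-subject connectopic gradient estimator.

    Parameters
    ----------
    n_gradients : int
        Number of nontrivial eigenvectors to keep (default 3; analyses
        typically use the first).
    normalization : {'random_walk', 'unnormalized'}
        Graph Laplacian form.
    epsilon : float or None
        Optional edge-weight threshold on the similarity graph.
    drop_zero_variance : bool
        Remove constant ROI vertices before mapping and reinsert them as
        NaN rows in the output.

    Attributes
    ----------
    fingerprints_ : (V, r) ndarray
    similarity_ : (V, V) ndarray
    gradients_ : (V, n_gradients) ndarray (NaN rows for dropped vertices)
    eigenvalues_ : (n_gradients,) ndarray, ascending
    """

    def __init__(
        self,
        n_gradients: int = 3,
        normalization: str = "random_walk",
        epsilon: float | None = None,
        drop_zero_variance: bool = True,
    ):
        self.n_gradients = n_gradients
        self.normalization = normalization
        self.epsilon = epsilon
        self.drop_zero_variance = drop_zero_variance

    def fit(self, X: np.ndarray, y: np.ndarray = None, *, orient: np.ndarray | None = None):
        """Fit on a subject.

        ``X`` is the ROI time-series (T, V_roi); ``y`` the reference
        time-series (T, V_ref). ``orient`` optionally fixes gradient signs
        against a canonical axis (e.g. the mesh axis coordinate).
        """
        if y is None:
            raise ValueError("reference time-series required as the second argument")
        roi = np.asarray(X, dtype=float)
        n_vertices = roi.shape[1]
        keep = np.arange(n_vertices)
        if self.drop_zero_variance:
            keep = np.where(np.ptp(roi, axis=0) > 0)[0]
            if keep.size < n_vertices:
                warnings.warn(f"dropping {n_vertices - keep.size} zero-variance ROI vertex(es)")
        reduced = svd_reduce_reference(y)
        fp = connectivity_fingerprints(roi[:, keep], reduced)
        sim = eta2_similarity(fp)
        sub_orient = orient[keep] if orient is not None else None
        cmap = laplacian_eigenmaps(
            sim, self.n_gradients, normalization=self.normalization,
            epsilon=self.epsilon, orient=sub_orient,
        )
        self.n_vertices_ = n_vertices
        self.kept_vertices_ = keep
        self.reduced_ = reduced
        fp_full = np.full((n_vertices, fp.values.shape[1]), np.nan)
        fp_full[keep] = fp.values
        self.fingerprints_ = fp_full
        sim_full = np.full((n_vertices, n_vertices), np.nan)
        sim_full[np.ix_(keep, keep)] = sim.values
        self.similarity_ = sim_full
        grads = np.full((n_vertices, self.n_gradients), np.nan)
        grads[keep] = cmap.gradients
        self.gradients_ = grads
        self.eigenvalues_ = cmap.eigenvalues
        return self

    def to_map(self) -> ConnectopicMap:
        return ConnectopicMap(gradients=self.gradients_, eigenvalues=self.eigenvalues_)


class ProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Align subject gradient maps to a fixed group template.

    ``fit`` takes the template gradients; ``transform`` rotates each subject
    map (``(V, k)`` array or :class:`ConnectopicMap`) onto it.
    """

    def fit(self, X, y=None):
        t = X.gradients if isinstance(X, (ConnectopicMap, GradientTemplate)) else np.asarray(X, float)
        self.template_ = GradientTemplate(gradients=t, provenance="fitted template")
        return self

    def transform(self, X):
        if not hasattr(self, "template_"):
            raise ValueError("ProcrustesAlignment is not fitted")
        single = isinstance(X, (ConnectopicMap, np.ndarray))
        items = [X] if single else list(X)
        out = []
        for item in items:
            cmap = item if isinstance(item, ConnectopicMap) else ConnectopicMap(
                gradients=np.asarray(item, float),
                eigenvalues=np.zeros(np.asarray(item).shape[1]),
            )
            out.append(align_to_template(cmap, self.template_))
        return out[0] if single else out
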