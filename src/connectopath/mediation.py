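"""Product-of-coefficients mediation with percentile-bootstrap inference.

The model relates an averaged low-level (sensory/motor) connectivity
predictor X, an averaged high-order (transmodal) connectivity mediator M,
and a symptom-severity outcome Y through two nested regressions:

    M = a X + covariates + e_M
    Y = c' X + b M + covariates + e_Y
    Y = c X + covariates + e    (total effect)

The indirect effect is a*b, which for nested linear models with identical
covariate sets equals c - c'.  Significance of a*b uses a case-resampling
percentile bootstrap; a, b, c, c' carry parametric OLS p-values.  Variables
are z-scored before fitting, so all paths are standardized slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .group_stats import fdr_bh

__all__ = [
    "MediationResult",
    "TriadSpec",
    "mediation_fit",
    "mediation_bootstrap",
    "run_model_variants",
    "select_edges_by_association",
    "Mediation",
]


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    p_ab: float | None = None
    ci_ab: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None
    outcome_name: str = ""

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome_name, "a": self.a, "b": self.b, "c": self.c,
            "c_prime": self.c_prime, "ab": self.ab, "p_a": self.p_a, "p_b": self.p_b,
            "p_c": self.p_c, "p_c_prime": self.p_c_prime, "p_ab": self.p_ab,
            "ci_ab_lo": self.ci_ab[0] if self.ci_ab else np.nan,
            "ci_ab_hi": self.ci_ab[1] if self.ci_ab else np.nan,
            "n_boot": self.n_boot,
        }
        return d


@dataclass
class TriadSpec:
    """Names of the triad columns inside a subject-level table."""

    predictor: str
    mediator: str
    outcomes: list[str]
    covariates: list[str] = field(default_factory=list)
    subcortical_predictor: str | None = None


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def _ols(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and two-tailed p-values of an OLS fit."""
    n, p = design.shape
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - p
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    return beta, 2.0 * sps.t.sf(np.abs(t), df)


def _prepare(x, m, y, covariates, standardize: bool):
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if m.size != n or y.size != n:
        raise ValueError("x, m and y must have the same length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if n <= cov.shape[1] + 3:
        raise ValueError(f"need N > n_covariates + 3, got N = {n}")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 0.999:
        raise ValueError(f"x and m are collinear (|r| = {abs(r_xm):.4f} > 0.999)")
    if standardize:
        x, m, y = _zscore(x), _zscore(m), _zscore(y)
    return x, m, y, cov


def mediation_fit(
    x, m, y, covariates=None, *, standardize: bool = True, outcome_name: str = ""
) -> MediationResult:
    """Point estimates of the mediation paths (no bootstrap)."""
    x, m, y, cov = _prepare(x, m, y, covariates, standardize)
    n = x.size
    ones = np.ones(n)
    xa = np.column_stack([ones, x, *cov.T])
    beta_a, p_a = _ols(m, xa)
    xb = np.column_stack([ones, x, m, *cov.T])
    beta_b, p_b = _ols(y, xb)
    beta_c, p_c = _ols(y, xa)
    a = float(beta_a[1])
    b = float(beta_b[2])
    c_prime = float(beta_b[1])
    c = float(beta_c[1])
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, ab=a * b,
        p_a=float(p_a[1]), p_b=float(p_b[2]), p_c=float(p_c[1]), p_c_prime=float(p_b[1]),
        outcome_name=outcome_name,
    )


def _bootstrap_ab(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, cov: np.ndarray,
    n_boot: int, rng: np.random.Generator, batch: int = 20000,
) -> np.ndarray:
    """Vectorized case-resampling draws of a*b."""
    n = x.size
    ones = np.ones(n)
    xa = np.column_stack([ones, x, *cov.T])
    xb = np.column_stack([ones, x, m, *cov.T])
    out = np.empty(n_boot)
    done = 0
    while done < n_boot:
        bsize = min(batch, n_boot - done)
        idx = rng.integers(0, n, size=(bsize, n))
        da = xa[idx]                                   # (B, n, pa)
        ga = np.einsum("bnp,bnq->bpq", da, da)
        ra = np.einsum("bnp,bn->bp", da, m[idx])
        db = xb[idx]
        gb = np.einsum("bnp,bnq->bpq", db, db)
        rb = np.einsum("bnp,bn->bp", db, y[idx])
        try:
            a_star = np.linalg.solve(ga, ra[..., None])[:, 1, 0]
            b_star = np.linalg.solve(gb, rb[..., None])[:, 2, 0]
        except np.linalg.LinAlgError:
            # degenerate resample(s); fall back to per-draw least squares
            a_star = np.array([np.linalg.lstsq(da[i], m[idx[i]], rcond=None)[0][1] for i in range(bsize)])
            b_star = np.array([np.linalg.lstsq(db[i], y[idx[i]], rcond=None)[0][2] for i in range(bsize)])
        out[done : done + bsize] = a_star * b_star
        done += bsize
    return out


def mediation_bootstrap(
    x, m, y, covariates=None,
    *,
    n_boot: int = 100_000,
    seed: int | np.random.SeedSequence = 0,
    standardize: bool = True,
    outcome_name: str = "",
    allow_small: bool = False,
    ci_level: float = 0.95,
) -> MediationResult:
    """Mediation with a percentile bootstrap for the indirect effect.

    Subjects are resampled with replacement ``n_boot`` times; the CI is the
    percentile interval of a*b and the two-tailed p-value is
    ``2 * min(P(ab* <= 0), P(ab* >= 0))`` with the add-one small-sample
    correction.  Deterministic under a fixed seed.
    """
    if n_boot < 1000 and not allow_small:
        raise ValueError("n_boot must be >= 1000 (pass allow_small=True to override)")
    res = mediation_fit(x, m, y, covariates, standardize=standardize, outcome_name=outcome_name)
    xs, ms, ys, cov = _prepare(x, m, y, covariates, standardize)
    rng = np.random.default_rng(seed)
    ab_star = _bootstrap_ab(xs, ms, ys, cov, n_boot, rng)
    lo_q = 100 * (1 - ci_level) / 2
    res.ci_ab = (
        float(np.percentile(ab_star, lo_q)),
        float(np.percentile(ab_star, 100 - lo_q)),
    )
    p_lo = (1 + np.sum(ab_star <= 0)) / (n_boot + 1)
    p_hi = (1 + np.sum(ab_star >= 0)) / (n_boot + 1)
    res.p_ab = float(min(1.0, 2.0 * min(p_lo, p_hi)))
    res.n_boot = n_boot
    res.seed = seed if isinstance(seed, int) else None
    return res


def select_edges_by_association(
    edge_values: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    alpha: float = 0.05,
    split_half: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Mask of edges whose partial correlation with the outcome is nominal.

    ``edge_values`` is (N subjects, E edges).  Selecting edges on the same
    subjects later used for mediation is circular; ``split_half=True``
    selects on a random half (fit then happens on the other half, handled by
    the caller).  Falls back to the single strongest edge when none pass.
    """
    from .group_stats import partial_correlation

    ev = np.asarray(edge_values, dtype=float)
    y = np.asarray(outcome, dtype=float)
    rows = np.arange(ev.shape[0])
    if split_half:
        rng = np.random.default_rng(seed)
        rows = rng.permutation(ev.shape[0])[: ev.shape[0] // 2]
    ps = np.empty(ev.shape[1])
    rs = np.empty(ev.shape[1])
    cv = covariates[rows] if covariates is not None else None
    for e in range(ev.shape[1]):
        rs[e], ps[e] = partial_correlation(ev[rows, e], y[rows], cv)
    mask = ps < alpha
    if not mask.any():
        mask[np.argmax(np.abs(rs))] = True
    return mask


def run_model_variants(
    triad: TriadSpec,
    data: pd.DataFrame,
    *,
    n_boot: int = 100_000,
    seed: int | np.random.SeedSequence = 0,
    allow_small: bool = False,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Forward, reversed and (optionally) subcortical-predictor mediations.

    One row per variant x outcome; within each variant, p_ab is FDR
    corrected across the outcomes (Benjamini-Hochberg at ``fdr_q``).
    """
    missing = [c for c in [triad.predictor, triad.mediator, *triad.outcomes, *triad.covariates]
               if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing column(s): {missing}")
    variants: list[tuple[str, str, str]] = [
        ("forward", triad.predictor, triad.mediator),
        ("reversed", triad.mediator, triad.predictor),
    ]
    if triad.subcortical_predictor is not None:
        if triad.subcortical_predictor not in data.columns:
            raise ValueError(f"data is missing column(s): [{triad.subcortical_predictor!r}]")
        variants.append(("subcortical", triad.subcortical_predictor, triad.mediator))
    cov = data[triad.covariates].to_numpy(dtype=float) if triad.covariates else None
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = iter(root.spawn(len(variants) * len(triad.outcomes)))
    rows = []
    for vname, xcol, mcol in variants:
        var_rows = []
        for outcome in triad.outcomes:
            sub = data[[xcol, mcol, outcome] + triad.covariates].dropna()
            res = mediation_bootstrap(
                sub[xcol], sub[mcol], sub[outcome],
                sub[triad.covariates].to_numpy(dtype=float) if triad.covariates else None,
                n_boot=n_boot, seed=next(streams), allow_small=allow_small,
                outcome_name=outcome,
            )
            row = res.to_dict()
            row["variant"] = vname
            var_rows.append(row)
        rej = fdr_bh([r["p_ab"] for r in var_rows], q=fdr_q)
        for r, sig in zip(var_rows, rej):
            r["p_ab_fdr_significant"] = bool(sig)
        rows.extend(var_rows)
    cols = ["variant", "outcome", "a", "b", "c", "c_prime", "ab", "ci_ab_lo", "ci_ab_hi",
            "p_a", "p_b", "p_c", "p_c_prime", "p_ab", "p_ab_fdr_significant", "n_boot"]
    return pd.DataFrame(rows)[cols]


class Mediation(BaseEstimator):
    """Scikit-learn style mediation estimator.

    ``fit(X, y)`` expects ``X`` with the predictor in column 0, the mediator
    in column 1 and any covariates in the remaining columns; ``y`` is the
    outcome.  Attributes ``a_``, ``b_``, ``c_``, ``c_prime_``, ``ab_``,
    ``ci_ab_`` and ``p_ab_`` expose the fitted paths.
    """

    def __init__(
        self,
        n_boot: int = 100_000,
        seed: int = 0,
        standardize: bool = True,
        allow_small: bool = False,
    ):
        self.n_boot = n_boot
        self.seed = seed
        self.standardize = standardize
        self.allow_small = allow_small

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must have at least two columns (predictor, mediator)")
        cov = X[:, 2:] if X.shape[1] > 2 else None
        self.result_ = mediation_bootstrap(
            X[:, 0], X[:, 1], y, cov,
            n_boot=self.n_boot, seed=self.seed,
            standardize=self.standardize, allow_small=self.allow_small,
        )
        for name in ("a", "b", "c", "c_prime", "ab", "ci_ab", "p_ab"):
            setattr(self, name + "_", getattr(self.result_, name))
        return self
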