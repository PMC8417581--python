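"""Synthetic resting-state cohorts with known ground truth.

Every downstream stage of the package (connectopic mapping, stratified
functional connectivity, group statistics, mediation) is exercised on data
produced here, so the generator encodes the phenomena the analyses are meant
to detect:

* ROI time-series whose connectivity fingerprints vary smoothly along a
  latent spatial axis, with a focal exaggeration of that axis in the case
  group (an "excessively segregated" gradient).
* Parcel time-series drawn from group-specific block covariance matrices
  implementing within-sensory hypoconnectivity, subcortico-cortical
  hyperconnectivity, and within-transmodal hypoconnectivity that grows along
  the cortical hierarchy.
* Case-group symptom scores generated from an explicit mediation path model
  (latent predictor X -> mediator M -> outcome Y) whose path coefficients
  are recoverable by the mediation module.

Ground truth (the latent axis, X, M) lives in a sidecar table that analysis
modules never read; only tests do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh, read_mesh, write_mesh

__all__ = [
    "GradientSpec",
    "GroupCovarianceSpec",
    "MediationPathSpec",
    "SubjectRecord",
    "Cohort",
    "make_default_covariance_spec",
    "ground_truth_axis",
    "simulate_subject_timeseries",
    "simulate_parcel_timeseries",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "read_truth",
]

CASE = "case"
CONTROL = "control"

# Classic ADOS calibration (module totals on the classic algorithm):
# population mean/SD used to map the latent outcome onto the score scale.
ADOS_TOTAL_MEAN, ADOS_TOTAL_SD = 12.7, 3.68
ADOS_SOCIAL_MEAN, ADOS_COMM_MEAN = 8.40, 4.25
ADOS_RRB_MEAN, ADOS_RRB_SD = 2.02, 1.50

SITES = ("siteA", "siteB", "siteC")
_SITE_OFFSET = 0.1  # additive offset on the time-series mean per site index


@dataclass
class GradientSpec:
    """Ground-truth description of a gradient-structured ROI.

    ``n_sources`` latent unit-variance signals live in the reference block;
    each ROI vertex mixes the first two of them with weight ``g(v)`` equal to
    the mesh axis coordinate, so connectivity fingerprints vary smoothly
    along the axis.  In the case group ``g`` is warped away from the midpoint
    by ``group_shift`` inside ``shift_region``, exaggerating the gradient.
    """

    n_sources: int = 5
    snr: float = 3.0
    group_shift: float = 0.5
    shift_region: tuple[float, float] = (0.6, 1.0)
    n_reference: int = 60
    ar_phi: float = 0.0  # AR(1) coefficient of the latent signals

    def validate(self) -> None:
        if self.n_sources < 2:
            raise ValueError("n_sources must be >= 2")
        if not np.isfinite(self.snr) and not np.isinf(self.snr):
            raise ValueError("snr must be finite or +inf")
        if not (self.snr > 0):
            raise ValueError(f"snr must be positive, got {self.snr}")
        if not np.isfinite(self.group_shift):
            raise ValueError("group_shift must be finite")
        lo, hi = self.shift_region
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"shift_region must be within [0, 1], got {self.shift_region}")
        if self.n_reference < self.n_sources:
            raise ValueError("n_reference must be >= n_sources")
        if not (-1.0 < self.ar_phi < 1.0):
            raise ValueError("ar_phi must lie in (-1, 1)")


@dataclass
class GroupCovarianceSpec:
    """Parcel layout plus one positive-semidefinite covariance per group."""

    parcel_names: list[str]
    network_assignment: dict[str, str]
    hierarchy_order: dict[str, int]
    stratum: dict[str, str]
    cov_by_group: dict[str, np.ndarray]

    def validate(self) -> None:
        p = len(self.parcel_names)
        for name in self.parcel_names:
            if name not in self.network_assignment or name not in self.stratum:
                raise ValueError(f"parcel {name!r} missing network or stratum assignment")
        for grp, cov in self.cov_by_group.items():
            cov = np.asarray(cov)
            if cov.shape != (p, p):
                raise ValueError(f"covariance for group {grp!r} has shape {cov.shape}, expected {(p, p)}")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance for group {grp!r} is not symmetric")
            w = np.linalg.eigvalsh(cov)
            if w[0] < -1e-8 * max(1.0, w[-1]):
                raise ValueError(
                    f"covariance for group {grp!r} is not positive semidefinite "
                    f"(smallest eigenvalue {w[0]:.3e})"
                )

    def parcels_in_stratum(self, stratum: str) -> list[str]:
        return [p for p in self.parcel_names if self.stratum[p] == stratum]


@dataclass
class MediationPathSpec:
    """Linear path model X -> M -> Y with direct effect c'.

    Defaults follow the effect sizes characteristic of a complete-mediation
    pattern (standardized a ~ 0.5, b ~ -0.6, no direct effect); residual SDs
    are chosen so that M and the latent outcome have unit variance.
    """

    a: float = 0.51
    b: float = -0.62
    c_prime: float = 0.0
    noise_m: float = 0.8602
    noise_y: float = 0.7846

    def validate(self) -> None:
        for name in ("a", "b", "c_prime", "noise_m", "noise_y"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_m <= 0 or self.noise_y <= 0:
            raise ValueError("noise_m and noise_y must be positive")


@dataclass
class SubjectRecord:
    """One subject's time-series blocks, nuisance covariates and phenotypes."""

    id: str
    group: str
    age: float
    site: str
    fd: float
    sex: str
    roi_ts: np.ndarray | None
    reference_ts: np.ndarray | None
    parcel_ts: np.ndarray
    phenotypes: dict[str, float] | None = None

    def validate(self) -> None:
        lengths = {
            blk.shape[0]
            for blk in (self.roi_ts, self.reference_ts, self.parcel_ts)
            if blk is not None
        }
        if len(lengths) > 1:
            raise ValueError(f"subject {self.id}: time-series blocks differ in length {lengths}")
        if self.phenotypes is not None:
            tot = self.phenotypes.get("ados_total")
            soc = self.phenotypes.get("ados_social")
            com = self.phenotypes.get("ados_communication")
            if tot is not None and soc is not None and com is not None:
                if abs(tot - (soc + com)) > 0.5:
                    raise ValueError(
                        f"subject {self.id}: ADOS total {tot} != social+communication {soc + com}"
                    )


@dataclass
class Cohort:
    """List-like container of subjects plus the ground-truth sidecar."""

    subjects: list[SubjectRecord]
    truth: pd.DataFrame = field(repr=False)
    mesh: SurfaceMesh | None = None
    cov_spec: GroupCovarianceSpec | None = None

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __getitem__(self, idx):
        return self.subjects[idx]

    def covariates(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"id": s.id, "group": s.group, "age": s.age, "site": s.site,
                   "fd": s.fd, "sex": s.sex}
            if s.phenotypes:
                row.update(s.phenotypes)
            rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# default parcel layout / block covariances
# --------------------------------------------------------------------------

_SENSORY = ["M1_upper", "M1_lower", "S1_upper", "S1_lower", "V1_central", "V1_peripheral", "A1"]
_SUBCORTICAL = ["thalamus", "caudate", "pallidum", "putamen"]
_TRANSMODAL_NETWORKS = {
    "dorsal_attention": (["DA_A", "DA_B"], 1),
    "ventral_attention": (["VA"], 2),
    "salience": (["Sal"], 3),
    "control": (["Con_A", "Con_B", "Con_C"], 4),
    "default_mode": (["DMN_A", "DMN_B", "DMN_C", "DMN_D"], 5),
    "limbic": (["Lim_A", "Lim_B"], 6),
}


def _network_of(parcel: str) -> str:
    if parcel in ("M1_upper", "M1_lower", "S1_upper", "S1_lower"):
        return "somatomotor"
    if parcel.startswith("V1"):
        return "visual"
    if parcel == "A1":
        return "auditory"
    if parcel in _SUBCORTICAL:
        return "subcortical"
    for net, (members, _) in _TRANSMODAL_NETWORKS.items():
        if parcel in members:
            return net
    raise KeyError(parcel)


def make_default_covariance_spec(
    *,
    sensory_r: float = 0.45,
    sensory_hypo: float = 0.10,
    subcortical_r: float = 0.35,
    cross_subcortical_r: float = 0.10,
    subcortical_hyper: float = 0.10,
    within_network_r: float = 0.55,
    between_network_r: float = 0.25,
    hierarchy_hypo_slope: float = 0.015,
    background_r: float = 0.12,
) -> GroupCovarianceSpec:
    """Build the default two-group block covariance.

    The control matrix places homogeneous correlation inside each stratum;
    the case matrix lowers within-sensory correlations (``sensory_hypo``),
    raises sensory-subcortical ones (``subcortical_hyper``), and lowers
    transmodal correlations by an amount that grows linearly with the mean
    hierarchy rank of the two parcels' networks (``hierarchy_hypo_slope``
    per rank unit), so the proportion of hypoconnected edges rises along
    the hierarchy.
    """
    parcels = list(_SENSORY) + list(_SUBCORTICAL)
    hierarchy: dict[str, int] = {"somatomotor": 0, "visual": 0, "auditory": 0, "subcortical": 0}
    for net, (members, rank) in _TRANSMODAL_NETWORKS.items():
        parcels.extend(members)
        hierarchy[net] = rank
    p = len(parcels)
    stratum = {}
    for name in parcels:
        if name in _SENSORY:
            stratum[name] = "sensory_motor"
        elif name in _SUBCORTICAL:
            stratum[name] = "subcortical"
        else:
            stratum[name] = "transmodal"
    network = {name: _network_of(name) for name in parcels}

    def base_corr(case: bool) -> np.ndarray:
        c = np.full((p, p), background_r)
        for i in range(p):
            for j in range(p):
                si, sj = stratum[parcels[i]], stratum[parcels[j]]
                ni, nj = network[parcels[i]], network[parcels[j]]
                if si == "sensory_motor" and sj == "sensory_motor":
                    c[i, j] = sensory_r - (sensory_hypo if case else 0.0)
                elif {si, sj} == {"sensory_motor", "subcortical"}:
                    c[i, j] = cross_subcortical_r + (subcortical_hyper if case else 0.0)
                elif si == "subcortical" and sj == "subcortical":
                    c[i, j] = subcortical_r
                elif si == "transmodal" and sj == "transmodal":
                    r = within_network_r if ni == nj else between_network_r
                    if case:
                        r -= hierarchy_hypo_slope * 0.5 * (hierarchy[ni] + hierarchy[nj])
                    c[i, j] = r
        np.fill_diagonal(c, 1.0)
        return c

    spec = GroupCovarianceSpec(
        parcel_names=parcels,
        network_assignment=network,
        hierarchy_order=hierarchy,
        stratum=stratum,
        cov_by_group={CONTROL: base_corr(False), CASE: base_corr(True)},
    )
    spec.validate()
    return spec


# --------------------------------------------------------------------------
# time-series generators
# --------------------------------------------------------------------------

def ground_truth_axis(mesh: SurfaceMesh, spec: GradientSpec, group: str) -> np.ndarray:
    """Effective mixing weight g(v) per vertex for the given group.

    Controls use the raw mesh axis coordinate; in cases the axis is pushed
    away from 0.5 (toward the extremes) inside ``shift_region``.
    """
    g = mesh.axis_coordinate.copy()
    if group == CASE and spec.group_shift != 0.0:
        lo, hi = spec.shift_region
        inside = (g >= lo) & (g <= hi)
        g[inside] = 0.5 + (1.0 + spec.group_shift) * (g[inside] - 0.5)
        np.clip(g, 0.0, 1.0, out=g)
    return g


def _latent_signals(rng: np.random.Generator, T: int, n: int, phi: float) -> np.ndarray:
    s = rng.standard_normal((T, n))
    if phi != 0.0:
        for t in range(1, T):
            s[t] = phi * s[t - 1] + np.sqrt(1 - phi**2) * s[t]
    return s


def simulate_subject_timeseries(
    mesh: SurfaceMesh,
    spec: GradientSpec,
    group: str,
    T: int,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (roi_ts, reference_ts) for one subject.

    ``reference_ts`` holds the ``n_sources`` latent signals in its first
    columns plus pure-noise channels.  Each ROI vertex is the convex mixture
    ``(1 - g) * s1 + g * s2`` of the first two latents plus Gaussian noise
    with standard deviation ``1 / snr``.
    """
    spec.validate()
    if T < 2 * spec.n_sources:
        raise ValueError(f"T={T} too short; need at least 2 * n_sources = {2 * spec.n_sources}")
    if group not in (CASE, CONTROL):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    s = _latent_signals(rng, T, spec.n_sources, spec.ar_phi)
    n_noise = spec.n_reference - spec.n_sources
    reference_ts = np.column_stack([s, rng.standard_normal((T, n_noise))])
    g = ground_truth_axis(mesh, spec, group)
    clean = np.outer(s[:, 0], 1.0 - g) + np.outer(s[:, 1], g)
    noise_sd = 0.0 if np.isinf(spec.snr) else 1.0 / spec.snr
    roi_ts = clean + noise_sd * rng.standard_normal((T, mesh.n_vertices))
    return roi_ts, reference_ts


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD matrix; rejects non-PSD input."""
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w, v = np.linalg.eigh(cov)
    if w[0] < -1e-8 * max(1.0, w[-1]):
        raise ValueError(f"covariance is not positive semidefinite (smallest eigenvalue {w[0]:.3e})")
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_parcel_timeseries(
    spec: GroupCovarianceSpec,
    group: str,
    T: int,
    seed: int | np.random.SeedSequence,
    *,
    cov: np.ndarray | None = None,
) -> np.ndarray:
    """Draw a (T, P) parcel time-series from the group's covariance.

    ``cov`` overrides the group matrix (used for per-subject modulation).
    """
    if cov is None:
        if group not in spec.cov_by_group:
            raise ValueError(f"no covariance defined for group {group!r}")
        cov = spec.cov_by_group[group]
    p = len(spec.parcel_names)
    if T < p + 1:
        raise ValueError(f"T={T} must exceed the parcel count P={p}")
    factor = _psd_factor(cov)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((T, p)) @ factor.T


def _nearest_corr_psd(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore a unit diagonal."""
    c = 0.5 * (c + c.T)
    w, v = np.linalg.eigh(c)
    if w[0] >= 1e-10:
        return c
    c = (v * np.clip(w, 1e-8, None)) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def _modulated_case_cov(
    spec: GroupCovarianceSpec, x: float, m: float, dx: float = 0.4, dm: float = 0.4
) -> np.ndarray:
    """Shift within-sensory (by X) and within-transmodal (by M) blocks on the z scale."""
    c = spec.cov_by_group[CASE].copy()
    strata = np.array([spec.stratum[p] for p in spec.parcel_names])
    sens = strata == "sensory_motor"
    trans = strata == "transmodal"
    for mask, shift in ((sens, dx * x), (trans, dm * m)):
        idx = np.where(mask)[0]
        block = c[np.ix_(idx, idx)]
        off = ~np.eye(len(idx), dtype=bool)
        z = np.arctanh(np.clip(block[off], -0.97, 0.97)) + shift
        block[off] = np.tanh(z)
        c[np.ix_(idx, idx)] = block
    return _nearest_corr_psd(c)


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

def simulate_cohort(
    n_case: int,
    n_control: int,
    mesh: SurfaceMesh | None = None,
    gradient_spec: GradientSpec | None = None,
    cov_spec: GroupCovarianceSpec | None = None,
    path_spec: MediationPathSpec | None = None,
    T: int = 200,
    seed: int | np.random.SeedSequence = 0,
    *,
    with_roi: bool = True,
) -> Cohort:
    """Generate a full synthetic cohort with ground-truth sidecar.

    Ages are uniform on [8, 40] years, framewise displacement is
    half-normal (sigma = 0.1 mm), and subjects cycle through three synthetic
    sites whose index adds a small offset to the time-series mean.  For case
    subjects a truncated-normal latent X modulates the within-sensory
    covariance block, the mediator M = a*X + eps_M modulates the
    within-transmodal block, and ADOS scores derive from the latent outcome
    Y = c'*X + b*M + eps_Y.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    gradient_spec = gradient_spec or GradientSpec()
    cov_spec = cov_spec or make_default_covariance_spec()
    path_spec = path_spec or MediationPathSpec()
    gradient_spec.validate()
    cov_spec.validate()
    path_spec.validate()
    if mesh is None and with_roi:
        from .mesh import make_mesh

        mesh = make_mesh(50, 2)

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    groups = [CASE] * n_case + [CONTROL] * n_control
    children = root.spawn(len(groups) + 1)
    meta_rng = np.random.default_rng(children[-1])

    subjects: list[SubjectRecord] = []
    truth_rows: list[dict] = []
    for i, (grp, child) in enumerate(zip(groups, children)):
        age = float(meta_rng.uniform(8.0, 40.0))
        fd = float(abs(meta_rng.normal(0.0, 0.1)))
        site = SITES[i % len(SITES)]
        x = m = y_lat = np.nan
        phen = None
        cov = None
        if grp == CASE:
            x = float(np.clip(meta_rng.standard_normal(), -2.5, 2.5))
            m = path_spec.a * x + path_spec.noise_m * meta_rng.standard_normal()
            y_lat = (
                path_spec.c_prime * x
                + path_spec.b * m
                + path_spec.noise_y * meta_rng.standard_normal()
            )
            total = max(0.0, ADOS_TOTAL_MEAN + ADOS_TOTAL_SD * y_lat)
            frac_social = ADOS_SOCIAL_MEAN / (ADOS_SOCIAL_MEAN + ADOS_COMM_MEAN)
            rrb = max(0.0, ADOS_RRB_MEAN + ADOS_RRB_SD * meta_rng.standard_normal())
            phen = {
                "ados_total": total,
                "ados_social": total * frac_social,
                "ados_communication": total * (1.0 - frac_social),
                "ados_rrb": rrb,
            }
            cov = _modulated_case_cov(cov_spec, x, m)
        parcel_seed, roi_seed = child.spawn(2)
        parcel_ts = simulate_parcel_timeseries(cov_spec, grp, T, parcel_seed, cov=cov)
        roi_ts = reference_ts = None
        if with_roi:
            roi_ts, reference_ts = simulate_subject_timeseries(
                mesh, gradient_spec, grp, T, roi_seed
            )
        offset = _SITE_OFFSET * SITES.index(site)
        parcel_ts = parcel_ts + offset
        if roi_ts is not None:
            roi_ts = roi_ts + offset
        rec = SubjectRecord(
            id=f"sub-{i:04d}", group=grp, age=age, site=site, fd=fd, sex="M",
            roi_ts=roi_ts, reference_ts=reference_ts, parcel_ts=parcel_ts, phenotypes=phen,
        )
        rec.validate()
        subjects.append(rec)
        truth_rows.append({"id": rec.id, "group": grp, "X": x, "M": m, "Y_latent": y_lat})

    truth = pd.DataFrame(truth_rows)
    if with_roi:
        for grp in (CONTROL, CASE):
            g = ground_truth_axis(mesh, gradient_spec, grp)
            truth.attrs[f"axis_{grp}"] = g
    return Cohort(subjects=subjects, truth=truth, mesh=mesh, cov_spec=cov_spec)


# --------------------------------------------------------------------------
# cohort I/O (TSV + plain-text mesh)
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        base = outdir / "timeseries" / s.id
        names = cohort.cov_spec.parcel_names if cohort.cov_spec else None
        pd.DataFrame(s.parcel_ts, columns=names).to_csv(
            base.with_suffix(".parcel.tsv"), sep="\t", index=False
        )
        if s.roi_ts is not None:
            np.savetxt(base.with_suffix(".roi.tsv"), s.roi_ts, delimiter="\t", fmt="%.8g")
        if s.reference_ts is not None:
            np.savetxt(base.with_suffix(".reference.tsv"), s.reference_ts, delimiter="\t", fmt="%.8g")
    cohort.covariates().to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    truth = cohort.truth.copy()
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    for key, arr in cohort.truth.attrs.items():
        np.savetxt(outdir / f"truth_{key}.tsv", np.asarray(arr), delimiter="\t", fmt="%.8g")
    if cohort.mesh is not None:
        write_mesh(cohort.mesh, outdir / "mesh.txt")
    if cohort.cov_spec is not None:
        meta = {
            "parcel_names": cohort.cov_spec.parcel_names,
            "network_assignment": cohort.cov_spec.network_assignment,
            "hierarchy_order": cohort.cov_spec.hierarchy_order,
            "stratum": cohort.cov_spec.stratum,
        }
        (outdir / "parcellation.json").write_text(json.dumps(meta, indent=2))


def read_cohort(outdir: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (without ground truth)."""
    outdir = Path(outdir)
    phen = pd.read_csv(outdir / "phenotypes.tsv", sep="\t")
    meta_path = outdir / "parcellation.json"
    cov_spec = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        cov_spec = GroupCovarianceSpec(
            parcel_names=meta["parcel_names"],
            network_assignment=meta["network_assignment"],
            hierarchy_order={k: int(v) for k, v in meta["hierarchy_order"].items()},
            stratum=meta["stratum"],
            cov_by_group={},
        )
    mesh = read_mesh(outdir / "mesh.txt") if (outdir / "mesh.txt").exists() else None
    subjects = []
    phen_cols = {"ados_total", "ados_social", "ados_communication", "ados_rrb"}
    for _, row in phen.iterrows():
        base = outdir / "timeseries" / str(row["id"])
        parcel_ts = pd.read_csv(base.with_suffix(".parcel.tsv"), sep="\t").to_numpy()
        roi_path = base.with_suffix(".roi.tsv")
        ref_path = base.with_suffix(".reference.tsv")
        roi_ts = np.loadtxt(roi_path, delimiter="\t") if roi_path.exists() else None
        ref_ts = np.loadtxt(ref_path, delimiter="\t") if ref_path.exists() else None
        ph = None
        if row["group"] == CASE:
            ph = {c: float(row[c]) for c in phen_cols if c in row and pd.notna(row[c])}
        subjects.append(
            SubjectRecord(
                id=str(row["id"]), group=str(row["group"]), age=float(row["age"]),
                site=str(row["site"]), fd=float(row["fd"]), sex=str(row["sex"]),
                roi_ts=roi_ts, reference_ts=ref_ts, parcel_ts=parcel_ts, phenotypes=ph,
            )
        )
    return Cohort(subjects=subjects, truth=pd.DataFrame(), mesh=mesh, cov_spec=cov_spec)


def read_truth(outdir: str | Path) -> pd.DataFrame:
    """Load the ground-truth sidecar (tests only)."""
    return pd.read_csv(Path(outdir) / "truth.tsv", sep="\t")
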