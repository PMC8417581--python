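"""Configured, seed-reproducible pipeline: simulate -> gradient -> ifc -> stats -> mediate.

A :class:`PipelineConfig` (YAML or JSON) selects stages and parameters; the
master seed fans out to per-stage seeds through ``numpy.random.SeedSequence``
with a fixed spawn key per stage, so stages can be re-run independently and
the full bundle is bit-reproducible under identical config and inputs.
Every stage writes its outputs plus a JSON provenance record (parameters,
seed, input hashes, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectopic import ConnectopicMapping, ProcrustesAlignment, build_group_template
from .group_stats import (
    cluster_correction_permutation,
    fdr_bh,
    fit_glm,
    make_design,
)
from .ifc import altered_proportion, global_signal_regress, ifc_matrix, parcellation_from_names
from .mesh import make_mesh
from .synthetic import (
    CASE,
    CONTROL,
    Cohort,
    GradientSpec,
    MediationPathSpec,
    make_default_covariance_spec,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from .mediation import TriadSpec, run_model_variants, select_edges_by_association

log = logging.getLogger("connectopath")

STAGES = ("simulate", "gradient", "ifc", "stats", "mediate")
# fixed spawn key per stage so re-running one stage reuses its exact stream
_STAGE_SPAWN_KEY = {name: i for i, name in enumerate(STAGES)}

_DEFAULTS: dict[str, dict] = {
    "simulate": {
        "n_case": 20, "n_control": 20, "T": 200, "n_axis": 25, "n_width": 2,
        "snr": 3.0, "group_shift": 0.5, "with_roi": True,
    },
    "gradient": {"k": 3},
    "ifc": {"gsr": False},
    "stats": {"cluster_p": 0.025, "alpha": 0.05, "n_perm": 1000, "fdr_q": 0.05},
    "mediate": {
        "n_boot": 100_000, "variants": ["forward", "reversed", "subcortical"],
        "selection_alpha": 0.05,
    },
}


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict[str, dict] = field(default_factory=dict)
    log_level: str = "INFO"

    def stage_params(self, stage: str) -> dict:
        merged = dict(_DEFAULTS[stage])
        merged.update(self.params.get(stage, {}))
        return merged

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=(_STAGE_SPAWN_KEY[stage],))

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError(f"stages must respect dependency order {STAGES}, got {self.stages}")
        for stage, block in self.params.items():
            if stage not in STAGES:
                raise ValueError(f"parameter block for unknown stage {stage!r}")
            bad = set(block) - set(_DEFAULTS[stage])
            if bad:
                raise ValueError(f"unknown parameter(s) for stage {stage!r}: {sorted(bad)}")


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = {"out_dir", "seed", "stages", "params", "log_level"}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config key(s): {sorted(bad)}")
    if "out_dir" not in raw:
        raise ValueError("config must set out_dir")
    cfg = PipelineConfig(
        out_dir=Path(raw["out_dir"]),
        seed=int(raw.get("seed", 0)),
        stages=list(raw.get("stages", STAGES)),
        params={k: dict(v) for k, v in (raw.get("params") or {}).items()},
        log_level=str(raw.get("log_level", "INFO")),
    )
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_provenance(stage_dir: Path, stage: str, params: dict, seed_entropy, inputs: list[Path]) -> None:
    rec = {
        "stage": stage,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "seed_entropy": seed_entropy,
        "input_hashes": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": sorted(str(p.relative_to(stage_dir)) for p in stage_dir.rglob("*") if p.is_file()),
        "version": __version__,
    }
    (stage_dir / "provenance.json").write_text(json.dumps(rec, indent=2, sort_keys=True))


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig) -> Cohort:
    p = cfg.stage_params("simulate")
    mesh = make_mesh(p["n_axis"], p["n_width"]) if p["with_roi"] else None
    gspec = GradientSpec(snr=p["snr"], group_shift=p["group_shift"])
    cohort = simulate_cohort(
        p["n_case"], p["n_control"], mesh=mesh, gradient_spec=gspec,
        cov_spec=make_default_covariance_spec(), path_spec=MediationPathSpec(),
        T=p["T"], seed=cfg.stage_seed("simulate"), with_roi=p["with_roi"],
    )
    out = cfg.out_dir / "cohort"
    write_cohort(cohort, out)
    _write_provenance(out, "simulate", p, cfg.seed, [])
    return cohort


def _load_cohort(cfg: PipelineConfig) -> Cohort:
    path = cfg.out_dir / "cohort"
    if not (path / "phenotypes.tsv").exists():
        raise FileNotFoundError(f"missing phenotype file {path / 'phenotypes.tsv'}; run the simulate stage first")
    return read_cohort(path)


def _stage_gradient(cfg: PipelineConfig, cohort: Cohort) -> pd.DataFrame:
    p = cfg.stage_params("gradient")
    out = cfg.out_dir / "gradient"
    out.mkdir(parents=True, exist_ok=True)
    k = p["k"]
    axis = cohort.mesh.axis_coordinate if cohort.mesh is not None else None
    mappers: dict[str, ConnectopicMapping] = {}
    for s in cohort:
        if s.roi_ts is None:
            raise ValueError(f"subject {s.id} has no ROI time-series; simulate with with_roi=True")
        mappers[s.id] = ConnectopicMapping(n_gradients=k).fit(s.roi_ts, s.reference_ts, orient=axis)
    control_sims = [mappers[s.id].similarity_ for s in cohort if s.group == CONTROL]
    template = build_group_template(control_sims, k, orient=axis, provenance="control-group mean")
    aligner = ProcrustesAlignment().fit(template.gradients)
    rows = []
    for s in cohort:
        cmap = aligner.transform(mappers[s.id].to_map())
        df = pd.DataFrame(cmap.gradients, columns=[f"gradient_{j + 1}" for j in range(k)])
        df.insert(0, "vertex", np.arange(df.shape[0]))
        df.to_csv(out / f"{s.id}.gradients.tsv", sep="\t", index=False)
        sidecar = {
            "eigenvalues": [float(v) for v in cmap.eigenvalues],
            "alignment_residual": cmap.residual,
            "aligned": cmap.aligned,
        }
        (out / f"{s.id}.gradients.json").write_text(json.dumps(sidecar, indent=2))
        rows.append({"id": s.id, "group": s.group, **{f"v{v}": g for v, g in enumerate(cmap.gradients[:, 0])}})
    table = pd.DataFrame(rows)
    table.to_csv(out / "first_gradient_by_subject.tsv", sep="\t", index=False)
    np.savetxt(out / "template_gradients.tsv", template.gradients, delimiter="\t", fmt="%.8g")
    _write_provenance(out, "gradient", p, cfg.seed, [cfg.out_dir / "cohort" / "phenotypes.tsv"])
    return table


def _stage_ifc(cfg: PipelineConfig, cohort: Cohort) -> dict[str, pd.DataFrame]:
    p = cfg.stage_params("ifc")
    out = cfg.out_dir / "ifc"
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.cov_spec
    parc = parcellation_from_names(
        spec.parcel_names, spec.network_assignment, spec.hierarchy_order, spec.stratum
    )
    low = parc.parcels_in_stratum("sensory_motor") + parc.parcels_in_stratum("subcortical")
    high = parc.parcels_in_stratum("transmodal")
    tables: dict[str, list] = {"low": [], "high": []}
    for s in cohort:
        ts = s.parcel_ts
        if p["gsr"]:
            ts = global_signal_regress(ts)
        for key, subset in (("low", low), ("high", high)):
            m = ifc_matrix(ts, parc, subset)
            m.to_frame().to_csv(out / f"{s.id}.{key}.z.tsv", sep="\t")
            tables[key].append(m.z_values)
    result = {}
    for key, subset in (("low", low), ("high", high)):
        stack = np.stack(tables[key])
        iu, ju = np.triu_indices(len(subset), k=1)
        edges = stack[:, iu, ju]
        cols = [f"{subset[i]}__{subset[j]}" for i, j in zip(iu, ju)]
        df = pd.DataFrame(edges, columns=cols)
        df.insert(0, "id", [s.id for s in cohort])
        df.to_csv(out / f"edges_{key}.tsv", sep="\t", index=False)
        result[key] = df
    _write_provenance(out, "ifc", p, cfg.seed, [cfg.out_dir / "cohort" / "phenotypes.tsv"])
    return result


def _stage_stats(cfg: PipelineConfig, cohort: Cohort, gradient_table: pd.DataFrame | None,
                 edge_tables: dict[str, pd.DataFrame]) -> dict:
    p = cfg.stage_params("stats")
    out = cfg.out_dir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    cov = cohort.covariates()
    design = make_design(cov)
    results: dict = {}

    if gradient_table is not None:
        vcols = [c for c in gradient_table.columns if c.startswith("v")]
        y = gradient_table[vcols].to_numpy(dtype=float)
        ok = np.all(np.isfinite(y), axis=0)
        cres = cluster_correction_permutation(
            y[:, ok], design, cohort.mesh, "group",
            cluster_p=p["cluster_p"], alpha=p["alpha"], n_perm=p["n_perm"],
            seed=cfg.stage_seed("stats"),
        )
        cres.to_frame().to_csv(out / "gradient_clusters.tsv", sep="\t", index=False)
        glm = fit_glm(y[:, ok], design, "group")
        glm.to_frame().to_csv(out / "gradient_glm.tsv", sep="\t", index=False)
        results["gradient_clusters"] = cres

    spec = cohort.cov_spec
    parc = parcellation_from_names(
        spec.parcel_names, spec.network_assignment, spec.hierarchy_order, spec.stratum
    )
    for key, df in edge_tables.items():
        ecols = [c for c in df.columns if c != "id"]
        y = df[ecols].to_numpy(dtype=float)
        glm = fit_glm(y, design, "group")
        stat = glm.to_frame()
        stat.insert(0, "edge", ecols)
        stat["fdr_significant"] = fdr_bh(glm.p, q=p["fdr_q"])
        stat.to_csv(out / f"edges_{key}_glm.tsv", sep="\t", index=False)
        results[f"edges_{key}"] = stat
        if key == "high":
            subset = parc.parcels_in_stratum("transmodal")
            pmat = np.zeros((len(subset), len(subset)))
            smat = np.zeros_like(pmat, dtype=bool)
            iu, ju = np.triu_indices(len(subset), k=1)
            pmat[iu, ju] = pmat[ju, iu] = glm.t
            smat[iu, ju] = smat[ju, iu] = stat["fdr_significant"].to_numpy()
            prop = altered_proportion(pmat, smat, parc, "hypo", parcel_names=subset)
            prop.to_csv(out / "altered_proportion_high.tsv", sep="\t", index=False)
            results["altered_proportion_high"] = prop
    _write_provenance(out, "stats", p, cfg.seed, [cfg.out_dir / "cohort" / "phenotypes.tsv"])
    return results


def _stage_mediate(cfg: PipelineConfig, cohort: Cohort, edge_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    p = cfg.stage_params("mediate")
    out = cfg.out_dir / "mediate"
    out.mkdir(parents=True, exist_ok=True)
    cov = cohort.covariates()
    cases = cov[cov["group"] == CASE].reset_index(drop=True)
    spec = cohort.cov_spec
    site_d = pd.get_dummies(cases["site"], drop_first=True, dtype=float)
    cov_mat = np.column_stack([cases["age"], cases["fd"], site_d.to_numpy()])
    cov_names = ["age", "fd"] + list(site_d.columns)

    def stratum_edges(df: pd.DataFrame, s1: str, s2: str) -> pd.DataFrame:
        cols = []
        for c in df.columns:
            if c == "id":
                continue
            a, b = c.split("__")
            if {spec.stratum[a], spec.stratum[b]} == ({s1, s2} if s1 != s2 else {s1}):
                cols.append(c)
        return df.set_index("id").loc[cases["id"], cols]

    low_within = stratum_edges(edge_tables["low"], "sensory_motor", "sensory_motor")
    low_sub = stratum_edges(edge_tables["low"], "sensory_motor", "subcortical")
    high_within = stratum_edges(edge_tables["high"], "transmodal", "transmodal")
    outcome = cases["ados_total"].to_numpy(dtype=float)
    alpha = p["selection_alpha"]
    seed0 = cfg.stage_seed("mediate")
    data = cases[["id", "age", "fd"] + [c for c in cases.columns if c.startswith("ados_")]].copy()
    for name, block in (("x_low", low_within), ("m_high", high_within), ("x_subcortical", low_sub)):
        mask = select_edges_by_association(block.to_numpy(dtype=float), outcome, cov_mat, alpha=alpha)
        data[name] = block.to_numpy(dtype=float)[:, mask].mean(axis=1)
    for cname, cvals in zip(cov_names, cov_mat.T):
        data[cname] = cvals
    triad = TriadSpec(
        predictor="x_low", mediator="m_high",
        outcomes=["ados_total", "ados_social", "ados_communication", "ados_rrb"],
        covariates=cov_names,
        subcortical_predictor="x_subcortical" if "subcortical" in p["variants"] else None,
    )
    table = run_model_variants(
        triad, data, n_boot=p["n_boot"], seed=seed0, allow_small=p["n_boot"] < 1000
    )
    wanted = [v for v in p["variants"] if v in set(table["variant"])]
    table = table[table["variant"].isin(wanted)].reset_index(drop=True)
    table.to_csv(out / "mediation_results.tsv", sep="\t", index=False)
    (out / "mediation_results.json").write_text(table.to_json(orient="records", indent=2))
    data.to_csv(out / "triad_table.tsv", sep="\t", index=False)
    _write_provenance(out, "mediate", p, cfg.seed, [cfg.out_dir / "cohort" / "phenotypes.tsv"])
    return table


def run_pipeline(config: PipelineConfig | str | Path, *, dry_run: bool = False) -> dict:
    """Execute the configured stages in order; returns the results bundle."""
    cfg = load_config(config) if not isinstance(config, PipelineConfig) else config
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    if dry_run:
        plan = {s: cfg.stage_params(s) for s in cfg.stages}
        log.info("dry run; resolved plan: %s", json.dumps(plan, default=str))
        return {"plan": plan}
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    cohort: Cohort | None = None
    gradient_table = None
    edge_tables: dict[str, pd.DataFrame] | None = None
    for stage in cfg.stages:
        log.info("running stage %s", stage)
        try:
            if stage == "simulate":
                cohort = _stage_simulate(cfg)
                bundle["cohort"] = cohort
            elif stage == "gradient":
                cohort = cohort or _load_cohort(cfg)
                gradient_table = _stage_gradient(cfg, cohort)
                bundle["gradient"] = gradient_table
            elif stage == "ifc":
                cohort = cohort or _load_cohort(cfg)
                edge_tables = _stage_ifc(cfg, cohort)
                bundle["ifc"] = edge_tables
            elif stage == "stats":
                cohort = cohort or _load_cohort(cfg)
                if edge_tables is None:
                    edge_tables = _read_edge_tables(cfg)
                if gradient_table is None:
                    gradient_table = _read_gradient_table(cfg)
                bundle["stats"] = _stage_stats(cfg, cohort, gradient_table, edge_tables)
            elif stage == "mediate":
                cohort = cohort or _load_cohort(cfg)
                if edge_tables is None:
                    edge_tables = _read_edge_tables(cfg)
                bundle["mediation"] = _stage_mediate(cfg, cohort, edge_tables)
        except Exception:
            log.error("stage %s failed; partial outputs under %s are preserved", stage, cfg.out_dir)
            raise
    return bundle


def _read_edge_tables(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    out = cfg.out_dir / "ifc"
    tables = {}
    for key in ("low", "high"):
        path = out / f"edges_{key}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing {path}; run the ifc stage first")
        tables[key] = pd.read_csv(path, sep="\t")
    return tables


def _read_gradient_table(cfg: PipelineConfig) -> pd.DataFrame | None:
    path = cfg.out_dir / "gradient" / "first_gradient_by_subject.tsv"
    return pd.read_csv(path, sep="\t") if path.exists() else None
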