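"""Stratified parcel-wise intrinsic functional connectivity (iFC).

Parcel time-series are unweighted means of member-vertex series; pairwise
Pearson correlations are Fisher r-to-z transformed into a symmetric matrix
with a masked diagonal.  The module also provides global-signal regression
and the per-network altered-connectivity proportion used to trace how
dysconnectivity changes along the cortical hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "IFCMatrix",
    "parcellation_from_names",
    "ifc_matrix",
    "global_signal_regress",
    "altered_proportion",
]


@dataclass
class Parcellation:
    """Vertex labels plus parcel/network/stratum metadata.

    ``labels[v]`` is the 1-based parcel index of vertex v (0 = unassigned);
    ``parcel_names[i]`` names parcel index ``i + 1``.
    """

    labels: np.ndarray
    parcel_names: list[str]
    network_assignment: dict[str, str]
    hierarchy_order: dict[str, int] = field(default_factory=dict)
    stratum: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = set(np.unique(self.labels)) - {0}
        n = len(self.parcel_names)
        if present - set(range(1, n + 1)):
            raise ValueError("labels refer to parcels outside parcel_names")
        for i, name in enumerate(self.parcel_names, start=1):
            if i not in present:
                raise ValueError(f"parcel {name!r} has no vertices")
            if name not in self.network_assignment:
                raise ValueError(f"parcel {name!r} has no network assignment")

    def vertices_of(self, name: str) -> np.ndarray:
        idx = self.parcel_names.index(name) + 1
        return np.where(self.labels == idx)[0]

    def parcels_in_stratum(self, stratum: str) -> list[str]:
        return [p for p in self.parcel_names if self.stratum.get(p) == stratum]


def parcellation_from_names(
    parcel_names: list[str],
    network_assignment: dict[str, str],
    hierarchy_order: dict[str, int] | None = None,
    stratum: dict[str, str] | None = None,
) -> Parcellation:
    """One-vertex-per-parcel parcellation for data already at parcel level."""
    return Parcellation(
        labels=np.arange(1, len(parcel_names) + 1),
        parcel_names=list(parcel_names),
        network_assignment=dict(network_assignment),
        hierarchy_order=dict(hierarchy_order or {}),
        stratum=dict(stratum or {}),
    )


@dataclass
class IFCMatrix:
    """Symmetric Fisher-z connectivity matrix, diagonal masked (NaN)."""

    z_values: np.ndarray
    parcel_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z_values, index=self.parcel_names, columns=self.parcel_names)


def ifc_matrix(
    ts: np.ndarray,
    parcellation: Parcellation,
    parcel_subset: list[str] | None = None,
    *,
    clip_perfect: bool = False,
) -> IFCMatrix:
    """Pairwise Fisher-z connectivity between parcel mean time-series.

    A pair correlating at |r| >= 1 - 1e-12 indicates duplicated parcels and
    raises by default; ``clip_perfect`` instead clips r to that bound before
    the atanh transform.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time-series must be a (T >= 3, V) matrix")
    names = list(parcel_subset) if parcel_subset is not None else list(parcellation.parcel_names)
    cols = []
    for name in names:
        verts = parcellation.vertices_of(name)
        if verts.size == 0:
            raise ValueError(f"parcel {name!r} has no vertices")
        mean_ts = ts[:, verts].mean(axis=1)
        if np.ptp(mean_ts) == 0:
            raise ValueError(f"parcel {name!r} has a zero-variance mean time-series")
        cols.append(mean_ts)
    x = np.column_stack(cols)
    r = np.corrcoef(x, rowvar=False)
    off = ~np.eye(len(names), dtype=bool)
    bound = 1.0 - 1e-12
    if np.any(np.abs(r[off]) >= bound):
        if not clip_perfect:
            i, j = np.argwhere((np.abs(r) >= bound) & off)[0]
            raise ValueError(
                f"degenerate perfect correlation between parcels {names[i]!r} and {names[j]!r}; "
                "pass clip_perfect=True to clip"
            )
        r = np.clip(r, -bound, bound)
    z = np.arctanh(np.where(off, r, 0.0))
    z[~off] = np.nan
    z = np.where(off, 0.5 * (z + z.T), z)
    return IFCMatrix(z_values=z, parcel_names=names)


def global_signal_regress(ts: np.ndarray) -> np.ndarray:
    """Residualize every column on the spatial-mean (global) signal.

    Each column is replaced by its residual after regressing on an intercept
    and the across-column mean series, leaving residuals exactly orthogonal
    to the global signal.  Idempotent.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time-series must be a (T >= 3, V) matrix")
    g = ts.mean(axis=1)
    if np.ptp(g) == 0:
        raise ValueError("global mean signal is constant; nothing to regress")
    design = np.column_stack([np.ones(ts.shape[0]), g])
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def altered_proportion(
    tmap: np.ndarray,
    sig_mask: np.ndarray,
    parcellation: Parcellation,
    sign: str = "hypo",
    *,
    parcel_names: list[str] | None = None,
    scope: str = "incident",
) -> pd.DataFrame:
    """Percentage of significantly altered edges per network.

    For each network the statistic is 100 x (unique significant edges of the
    requested sign incident to any parcel of the network) / (unique edges
    incident to any parcel of the network).  ``sign='hypo'`` counts negative
    t-values (case < control), ``'hyper'`` positive ones.  ``scope='within'``
    restricts both counts to edges whose two parcels belong to the network.

    Returns a frame with columns network, hierarchy_rank, n_edges,
    n_significant, percent — sorted by hierarchy rank for trend plots.
    """
    tmap = np.asarray(tmap, dtype=float)
    sig = np.asarray(sig_mask, dtype=bool)
    if tmap.shape != sig.shape or tmap.shape[0] != tmap.shape[1]:
        raise ValueError("tmap and sig_mask must be square matrices of equal shape")
    if sign not in ("hypo", "hyper"):
        raise ValueError("sign must be 'hypo' or 'hyper'")
    if scope not in ("incident", "within"):
        raise ValueError("scope must be 'incident' or 'within'")
    names = list(parcel_names) if parcel_names is not None else list(parcellation.parcel_names)
    if len(names) != tmap.shape[0]:
        raise ValueError("parcel name count does not match matrix size")
    nets = np.array([parcellation.network_assignment[p] for p in names])
    iu, ju = np.triu_indices(len(names), k=1)
    edge_sig = sig[iu, ju] & ((tmap[iu, ju] < 0) if sign == "hypo" else (tmap[iu, ju] > 0))
    rows = []
    for net in dict.fromkeys(nets):  # preserve first-appearance order
        members = nets == net
        if scope == "incident":
            in_net = members[iu] | members[ju]
        else:
            in_net = members[iu] & members[ju]
        n_edges = int(in_net.sum())
        if n_edges == 0:
            warnings.warn(f"network {net!r} has no edges in scope; omitted")
            continue
        n_sig = int((in_net & edge_sig).sum())
        rows.append(
            {
                "network": net,
                "hierarchy_rank": parcellation.hierarchy_order.get(net, 0),
                "n_edges": n_edges,
                "n_significant": n_sig,
                "percent": 100.0 * n_sig / n_edges,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["hierarchy_rank", "network"], kind="stable").reset_index(drop=True)
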