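"""Feature-matrix assembly and Ward hierarchical clustering with
silhouette-based selection of the cluster number.

Features are min-max normalised before Euclidean distances are computed,
matching the heatmap convention (each property scaled to its minimum and
maximum) and preventing unit dominance.  The cluster number is chosen as
the deepest cut at which no per-sample silhouette is negative while the
next cut introduces one; if no negative silhouette appears up to ``kmax``
the mean-silhouette maximiser is reported with a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_samples

from .core import FeatureTable

__all__ = [
    "ClusterTree",
    "ClusterResult",
    "DEFAULT_FEATURE_PANEL",
    "assemble_feature_table",
    "minmax_normalize",
    "ward_linkage",
    "cut_tree",
    "silhouette_select_k",
    "export_dendrogram_newick",
    "cluster_purity",
]

#: default panel of continuous electrophysiological features used for
#: clustering; discharge-pattern and AHP-profile categories are annotations
#: only, not distance features
DEFAULT_FEATURE_PANEL = [
    "cm_pf", "rin_mohm", "rmp_mv", "rheobase_pa",
    "ap_threshold_mv", "ap_peak_amplitude_mv", "ap_rise_ms", "ap_base_width_ms",
    "ahp_amplitude_mv", "ahp_latency_ms",
    "first_spike_latency_ms", "mean_frequency_hz", "mean_inst_frequency_hz",
    "adaptation", "attenuation_pct", "discharge_duration_ms",
    "sepsc_frequency_hz", "sepsc_amplitude_pa", "sepsc_tau_ms",
    "subthreshold_peak_pa",
]


@dataclass
class ClusterTree:
    """Ward merge tree in scipy linkage form (n-1 rows: id, id, height, size)."""

    linkage: np.ndarray
    n_leaves: int
    method: str = "ward"

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=np.float64)
        if self.linkage.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage must have n_leaves - 1 rows")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")


@dataclass
class ClusterResult:
    chosen_k: int
    labels: dict[int, np.ndarray]            # labels per k in 2..kmax
    silhouettes: dict[int, np.ndarray]       # per-sample silhouettes per k
    mean_silhouette: dict[int, float]
    normalized: np.ndarray
    fallback: bool = False
    flags: list[str] = field(default_factory=list)


def assemble_feature_table(
    feature_records: dict[str, dict[str, float]],
    feature_names: list[str] | None = None,
) -> FeatureTable:
    """Build a per-cell feature matrix; undefined values are imputed with
    the per-feature median and recorded in the missingness mask."""
    if feature_names is None:
        feature_names = list(DEFAULT_FEATURE_PANEL)
    cell_ids = list(feature_records)
    n, p = len(cell_ids), len(feature_names)
    values = np.full((n, p), np.nan)
    for i, cid in enumerate(cell_ids):
        rec = feature_records[cid]
        for j, name in enumerate(feature_names):
            val = rec.get(name, np.nan)
            values[i, j] = np.nan if val is None else float(val)
    mask = np.isnan(values)
    for j in range(p):
        col = values[:, j]
        if np.all(np.isnan(col)):
            raise ValueError(f"feature {feature_names[j]!r} absent from all cells")
        med = float(np.nanmedian(col))
        col[np.isnan(col)] = med
    return FeatureTable(cell_ids=cell_ids, feature_names=feature_names,
                        values=values, mask=mask)


def minmax_normalize(table: FeatureTable) -> FeatureTable:
    """Map each feature column to [0, 1]; a constant column maps to 0.5."""
    x = table.values.copy()
    for j in range(x.shape[1]):
        lo, hi = float(np.min(x[:, j])), float(np.max(x[:, j]))
        if hi == lo:
            warnings.warn(f"feature {table.feature_names[j]!r} is constant; normalised to 0.5")
            x[:, j] = 0.5
        else:
            x[:, j] = (x[:, j] - lo) / (hi - lo)
    return FeatureTable(cell_ids=list(table.cell_ids),
                        feature_names=list(table.feature_names),
                        values=x, mask=table.mask.copy())


def ward_linkage(matrix: np.ndarray) -> ClusterTree:
    """Agglomerative merges minimising the increase in total within-cluster
    sum of squares (Lance-Williams Ward update; singleton-pair height equals
    the Euclidean distance)."""
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    z = hierarchy.linkage(x, method="ward")
    return ClusterTree(linkage=z, n_leaves=x.shape[0])


def cut_tree(tree: ClusterTree, k: int) -> np.ndarray:
    """Flat labels (0..k-1) from removing the k-1 highest merges."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k={k} out of range 1..{tree.n_leaves}")
    return hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()


def silhouette_select_k(
    matrix: np.ndarray,
    tree: ClusterTree | None = None,
    kmax: int = 8,
) -> ClusterResult:
    """Choose the cluster number from per-sample silhouettes.

    Cuts at k = 2..kmax are scored with Euclidean silhouettes; the chosen k
    is the deepest cut such that every silhouette at k' <= k is
    non-negative while the k+1 cut contains a negative one.  If no negative
    silhouette appears up to kmax, the mean-silhouette maximiser is
    returned with the fallback flag set.
    """
    x = np.asarray(matrix, dtype=np.float64)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to select a cluster number")
    if tree is None:
        tree = ward_linkage(x)
    kmax = min(kmax, n - 1)
    labels, sils, means = {}, {}, {}
    for k in range(2, kmax + 1):
        lab = cut_tree(tree, k)
        labels[k] = lab
        s = silhouette_samples(x, lab, metric="euclidean")
        sils[k] = s
        means[k] = float(np.mean(s))
    chosen, fallback, flags = None, False, []
    for k in range(2, kmax + 1):
        if np.min(sils[k]) < 0:
            chosen = k - 1
            break
    if chosen is None:
        chosen = max(means, key=means.get)
        fallback = True
        flags.append("no negative silhouette found up to kmax; mean-silhouette maximiser reported")
    elif chosen < 2:
        # already the first cut introduces a negative silhouette: the data
        # support no more than one cluster
        chosen = 1
        labels[1] = np.zeros(n, dtype=int)
        flags.append("negative silhouette at k=2; single cluster supported")
    return ClusterResult(chosen_k=chosen, labels=labels, silhouettes=sils,
                         mean_silhouette=means, normalized=x,
                         fallback=fallback, flags=flags)


def _newick_name(name: str) -> str:
    if any(c in name for c in ":;,()[]' \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def export_dendrogram_newick(tree: ClusterTree, leaf_names: list[str] | None = None) -> str:
    """Serialise the merge tree as Newick with ultrametric branch lengths.

    Each internal node is placed at half its merge height (midpoint
    convention), leaves at zero; branch lengths are the height differences.
    Leaf names containing Newick metacharacters are quoted.
    """
    n = tree.n_leaves
    if leaf_names is None:
        leaf_names = [f"leaf_{i}" for i in range(n)]
    if len(leaf_names) != n:
        raise ValueError("one name per leaf required")
    pos = {i: 0.0 for i in range(n)}
    rep: dict[int, str] = {i: _newick_name(leaf_names[i]) for i in range(n)}
    for row_i, (a, b, h, _) in enumerate(tree.linkage):
        a, b = int(a), int(b)
        node = n + row_i
        pos[node] = h / 2.0
        la = pos[node] - pos[a]
        lb = pos[node] - pos[b]
        rep[node] = f"({rep[a]}:{la:g},{rep[b]}:{lb:g})"
    return rep[2 * n - 2] + ";"


def cluster_purity(labels: np.ndarray, identities: list[str]) -> dict[int, float]:
    """Per-cluster purity: the largest identity fraction in each cluster."""
    labels = np.asarray(labels)
    if labels.size != len(identities):
        raise ValueError("labels and identities must be aligned")
    idents = np.asarray(identities)
    out: dict[int, float] = {}
    for lab in np.unique(labels):
        members = idents[labels == lab]
        assert members.size > 0
        _, counts = np.unique(members, return_counts=True)
        out[int(lab)] = float(counts.max() / members.size)
    return out
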