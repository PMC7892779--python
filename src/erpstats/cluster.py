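"""Non-parametric spatio-temporal cluster-based permutation testing.

Pointwise repeated-measures ANOVA (k >= 3) or paired t (k = 2) statistics are
computed on per-subject condition-average maps over (electrode, time);
suprathreshold points (uncorrected p < 0.05) are clustered under
spatio-temporal adjacency, cluster statistics are summed, and summed
statistics are referred to a permutation null of maximum cluster sums
obtained by shuffling condition labels within subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .epochs import EpochSet
from .montage import AdjacencyGraph, build_adjacency
from .preprocess import BaselineWindow, baseline_correct

__all__ = [
    "SubjectConditionMaps",
    "PointwiseStatMap",
    "Cluster",
    "PermutationNull",
    "ClusterTestResult",
    "ClusterConfig",
    "condition_maps",
    "pointwise_rm_anova",
    "pointwise_paired_t",
    "find_clusters",
    "permutation_null",
    "cluster_p_values",
    "run_cluster_test",
]


@dataclass
class SubjectConditionMaps:
    """Per-subject, per-condition average maps: ``(n, k, E, T)`` in microvolts."""

    data: np.ndarray
    conditions: tuple[str, ...]
    electrode_ids: tuple[int, ...]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("maps must be 4-D (subject, condition, electrode, time)")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("condition axis mismatch")
        if self.data.shape[2] != len(self.electrode_ids):
            raise ValueError("electrode axis mismatch")
        if self.data.shape[3] != np.asarray(self.times).size:
            raise ValueError("time axis mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]


def condition_maps(
    epochs: EpochSet,
    conditions=None,
    electrode_scope=None,
    time_window=None,
    baseline: BaselineWindow | None = None,
) -> SubjectConditionMaps:
    """Average trials into per-subject condition maps, with optional
    baseline correction (applied before cropping) and electrode/time scoping."""
    ep = epochs
    if conditions is not None:
        ep = ep.select_conditions(conditions)
    if baseline is not None:
        ep = baseline_correct(ep, baseline)
    if time_window is not None:
        sl = ep.time_slice(time_window)
    else:
        sl = slice(0, ep.n_times)
    if electrode_scope is not None:
        e_ids = tuple(int(e) for e in electrode_scope)
        e_idx = ep.layout.indices_of(e_ids)
    else:
        e_ids = ep.layout.ids
        e_idx = np.arange(ep.n_electrodes)
    data = ep.data[:, :, :, e_idx, sl].mean(axis=2)
    return SubjectConditionMaps(data, ep.conditions, e_ids, ep.times[sl])


@dataclass
class PointwiseStatMap:
    """Statistic and uncorrected p per (electrode, time) point."""

    stat: np.ndarray  # (E, T)
    p: np.ndarray  # (E, T)
    df: tuple[int, ...]
    kind: str  # "F" | "t"
    electrode_ids: tuple[int, ...]
    times: np.ndarray


@dataclass
class Cluster:
    """A connected set of suprathreshold (electrode, time) points."""

    electrode_idx: np.ndarray
    time_idx: np.ndarray
    sum: float  # signed sum of member statistics
    sign: int  # +1 / -1 for t clusters; +1 for F
    p_corrected: float | None = None

    @property
    def size(self) -> int:
        return int(self.electrode_idx.size)

    def members(self) -> set[tuple[int, int]]:
        return set(zip(self.electrode_idx.tolist(), self.time_idx.tolist()))


@dataclass
class PermutationNull:
    """Max-cluster-sum magnitudes, one per permutation."""

    values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_permutations(self) -> int:
        return self.values.size


@dataclass
class ClusterTestResult:
    stat_map: PointwiseStatMap
    clusters: list[Cluster]
    null: PermutationNull
    alpha: float = 0.05

    @property
    def min_p(self) -> float:
        """Smallest corrected cluster p (1.0 when no cluster was formed)."""
        if not self.clusters:
            return 1.0
        return float(min(c.p_corrected for c in self.clusters))

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < self.alpha]

    @property
    def any_significant(self) -> bool:
        return len(self.significant_clusters) > 0

    def summary(self) -> dict:
        return {
            "stat_kind": self.stat_map.kind,
            "df": list(self.stat_map.df),
            "n_clusters": len(self.clusters),
            "min_p": self.min_p,
            "alpha": self.alpha,
            "n_significant": len(self.significant_clusters),
            "n_permutations": self.null.n_permutations,
            "seed": int(self.null.seed),
            "clusters": [
                {
                    "size": c.size,
                    "sum": float(c.sum),
                    "sign": int(c.sign),
                    "p": float(c.p_corrected),
                    "electrodes": sorted(
                        {int(self.stat_map.electrode_ids[i]) for i in c.electrode_idx}
                    ),
                    "time_range_s": [
                        float(self.stat_map.times[c.time_idx.min()]),
                        float(self.stat_map.times[c.time_idx.max()]),
                    ],
                }
                for c in sorted(self.clusters, key=lambda c: c.p_corrected)
            ],
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.summary(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def to_table(self) -> pd.DataFrame:
        rows = self.summary()["clusters"]
        return pd.DataFrame(
            rows, columns=["size", "sum", "sign", "p", "electrodes", "time_range_s"]
        )


@dataclass(frozen=True)
class ClusterConfig:
    """Settings for a cluster permutation test."""

    stat: str = "auto"  # "auto" | "F" | "t"
    threshold_p: float = 0.05
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    adjacency_scale: float = 1.5


# -- pointwise statistics ----------------------------------------------------

def _rm_anova_stat(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F = MS_condition / MS_(condition x subject) over trailing axes.

    ``data``: (n, k, ...).  Returns (F, SS_interaction) with F = 0 where both
    sums of squares vanish and +inf where only the error term vanishes.
    """
    n, k = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=1)
    cond = data.mean(axis=0)
    ss_cond = n * ((cond - grand) ** 2).sum(axis=0)
    resid = data - subj[:, None] - cond[None, :] + grand
    ss_int = (resid**2).sum(axis=(0, 1))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / (ss_int / df2)
    # sums of squares indistinguishable from 0 at float precision are 0
    ss_tot = ((data - grand) ** 2).sum(axis=(0, 1))
    zero_cond = ss_cond <= 1e-24 * ss_tot
    zero_err = ss_int <= 1e-24 * ss_tot
    f = np.where(zero_err & ~zero_cond, np.inf, f)
    f = np.where(zero_err & zero_cond, 0.0, f)
    f = np.where(zero_cond & ~zero_err, 0.0, f)
    return f, ss_int


def pointwise_rm_anova(maps: SubjectConditionMaps) -> PointwiseStatMap:
    """One-way repeated-measures ANOVA at every (electrode, time) point."""
    n, k = maps.n_subjects, maps.n_conditions
    if k < 2 or n < 2:
        raise ValueError("need at least 2 conditions and 2 subjects")
    f, ss_int = _rm_anova_stat(maps.data)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if np.any(np.isinf(f)):
        warnings.warn("zero error variance at some points; F set to +inf", RuntimeWarning)
    p = sps.f.sf(f, df1, df2)
    return PointwiseStatMap(f, p, (df1, df2), "F", tuple(maps.electrode_ids), maps.times)


def _paired_t_stat(data: np.ndarray) -> np.ndarray:
    """Paired t over trailing axes for ``data`` of shape (n, 2, ...)."""
    n = data.shape[0]
    d = data[:, 0] - data[:, 1]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    # a difference SD indistinguishable from 0 at float precision is 0
    scale = np.sqrt((d**2).mean(axis=0))
    zero = sd <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(zero & (mean != 0), np.sign(mean) * np.inf, t)
    t = np.where(zero & (mean == 0), 0.0, t)
    return t


def pointwise_paired_t(maps: SubjectConditionMaps) -> PointwiseStatMap:
    """Classic paired t (condition 0 minus condition 1), two-sided p."""
    n, k = maps.n_subjects, maps.n_conditions
    if k != 2:
        raise ValueError("paired t requires exactly 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    t = _paired_t_stat(maps.data)
    if np.any(np.isinf(t)):
        warnings.warn(
            "zero variance of differences at some points; t set to +/-inf", RuntimeWarning
        )
    p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    return PointwiseStatMap(t, p, (n - 1,), "t", tuple(maps.electrode_ids), maps.times)


# -- clustering --------------------------------------------------------------

class _Clusterer:
    """Connected-component labeling over an (E, T) grid.

    Two points are adjacent iff they share the electrode and are one sample
    apart, or they share the sample and their electrodes are spatial
    neighbors.
    """

    def __init__(self, adjacency: AdjacencyGraph, n_times: int):
        self.n_e = len(adjacency.ids)
        self.n_t = n_times
        rows, cols = np.nonzero(np.triu(adjacency.matrix, 1))
        self._pairs_a = rows
        self._pairs_b = cols

    def _edges(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        T = self.n_t
        tm = mask[:, :-1] & mask[:, 1:]
        te, tt = np.nonzero(tm)
        ti = te * T + tt
        tj = ti + 1
        sm = mask[self._pairs_a] & mask[self._pairs_b]
        sp, st = np.nonzero(sm)
        si = self._pairs_a[sp] * T + st
        sj = self._pairs_b[sp] * T + st
        return np.concatenate([ti, si]), np.concatenate([tj, sj])

    def label(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        """Return (node flat indices, component label per node, n components)."""
        nodes = np.flatnonzero(mask.ravel())
        if nodes.size == 0:
            return nodes, np.empty(0, dtype=int), 0
        compact = np.full(self.n_e * self.n_t, -1, dtype=int)
        compact[nodes] = np.arange(nodes.size)
        ei, ej = self._edges(mask)
        graph = csr_matrix(
            (np.ones(ei.size, dtype=np.int8), (compact[ei], compact[ej])),
            shape=(nodes.size, nodes.size),
        )
        n_comp, labels = connected_components(graph, directed=False)
        return nodes, labels, n_comp

    def cluster_sums(self, stat: np.ndarray, mask: np.ndarray) -> np.ndarray:
        nodes, labels, n_comp = self.label(mask)
        if n_comp == 0:
            return np.empty(0)
        return np.bincount(labels, weights=stat.ravel()[nodes], minlength=n_comp)

    def max_cluster_sum(self, stat: np.ndarray, mask: np.ndarray) -> float:
        """Largest |cluster sum| over sign-split masks is handled by callers;
        here the plain max of sums on one mask (0.0 when empty)."""
        sums = self.cluster_sums(stat, mask)
        return float(sums.max()) if sums.size else 0.0

    def clusters(self, stat: np.ndarray, mask: np.ndarray, sign: int) -> list[Cluster]:
        nodes, labels, n_comp = self.label(mask)
        out: list[Cluster] = []
        if n_comp == 0:
            return out
        sums = np.bincount(labels, weights=stat.ravel()[nodes], minlength=n_comp)
        e_idx_all, t_idx_all = np.divmod(nodes, self.n_t)
        for c in range(n_comp):
            sel = labels == c
            out.append(
                Cluster(
                    electrode_idx=e_idx_all[sel],
                    time_idx=t_idx_all[sel],
                    sum=float(sums[c]),
                    sign=sign,
                )
            )
        return out


def _stat_threshold(kind: str, df: tuple[int, ...], threshold_p: float) -> float:
    if kind == "F":
        return float(sps.f.isf(threshold_p, df[0], df[1]))
    return float(sps.t.isf(threshold_p / 2.0, df[0]))


def find_clusters(
    stat_map: PointwiseStatMap,
    threshold_p: float = 0.05,
    adjacency: AdjacencyGraph = None,
) -> list[Cluster]:
    """Group suprathreshold points (uncorrected p < ``threshold_p``) into
    spatio-temporally connected clusters; t clusters are split by sign."""
    if adjacency is None:
        raise ValueError("adjacency is required")
    if tuple(adjacency.ids) != tuple(stat_map.electrode_ids):
        adjacency = adjacency.reorder(stat_map.electrode_ids)
    cl = _Clusterer(adjacency, stat_map.times.size)
    supra = stat_map.p < threshold_p
    if stat_map.kind == "F":
        return cl.clusters(stat_map.stat, supra, sign=+1)
    out = cl.clusters(stat_map.stat, supra & (stat_map.stat > 0), sign=+1)
    out += cl.clusters(stat_map.stat, supra & (stat_map.stat < 0), sign=-1)
    return out


def _stat_fn(kind: str):
    if kind == "F":
        return lambda d: _rm_anova_stat(d)[0]
    return _paired_t_stat


def _max_cluster_stat(stat: np.ndarray, kind: str, crit: float, cl: _Clusterer) -> float:
    if kind == "F":
        return cl.max_cluster_sum(stat, stat > crit)
    pos = cl.max_cluster_sum(stat, stat > crit)
    neg = cl.max_cluster_sum(-stat, stat < -crit)
    return max(pos, neg)


def permutation_null(
    maps: SubjectConditionMaps,
    stat_kind: str,
    adjacency: AdjacencyGraph,
    n_permutations: int = 1000,
    seed: int = 0,
    threshold_p: float = 0.05,
) -> PermutationNull:
    """Distribution of max cluster-sum magnitudes under within-subject
    condition-label shuffling.

    Each permutation draws, per subject, an independent random permutation of
    the k condition labels, recomputes the pointwise map, clusters it, and
    records the maximum cluster sum (maximum |signed sum| for t; 0 when no
    cluster forms).  Per-permutation random substreams are derived from the
    master seed, so the null is reproducible and order-independent.
    """
    n, k = maps.n_subjects, maps.n_conditions
    if stat_kind not in ("F", "t"):
        raise ValueError("stat_kind must be 'F' or 't'")
    if stat_kind == "t" and k != 2:
        raise ValueError("t permutation null requires k = 2")
    data = maps.data.reshape(n, k, -1)
    df = (k - 1, (k - 1) * (n - 1)) if stat_kind == "F" else (n - 1,)
    crit = _stat_threshold(stat_kind, df, threshold_p)
    cl = _Clusterer(adjacency.reorder(maps.electrode_ids), maps.times.size)
    stat_fn = _stat_fn(stat_kind)

    children = np.random.SeedSequence(seed).spawn(n_permutations)
    rows = np.arange(n)[:, None]
    values = np.empty(n_permutations)
    shape = (len(maps.electrode_ids), maps.times.size)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        perms = np.argsort(rng.random((n, k)), axis=1)
        stat = stat_fn(data[rows, perms]).reshape(shape)
        values[i] = _max_cluster_stat(stat, stat_kind, crit, cl)
    return PermutationNull(values, seed=seed)


def cluster_p_values(
    clusters: list[Cluster],
    null: PermutationNull,
    alpha: float = 0.05,
    stat_map: PointwiseStatMap = None,
) -> ClusterTestResult:
    """Attach corrected p-values: p = (1 + #{null >= |sum|}) / (1 + P)."""
    if null.n_permutations == 0:
        raise ValueError("empty permutation null")
    out = []
    for c in clusters:
        b = int(np.sum(null.values >= abs(c.sum)))
        p = (1.0 + b) / (1.0 + null.n_permutations)
        out.append(
            Cluster(c.electrode_idx, c.time_idx, c.sum, c.sign, p_corrected=p)
        )
    return ClusterTestResult(stat_map=stat_map, clusters=out, null=null, alpha=alpha)


def run_cluster_test(
    epochs: EpochSet,
    conditions,
    electrode_scope=None,
    time_window=None,
    baseline: BaselineWindow | None = None,
    config: ClusterConfig = ClusterConfig(),
    adjacency: AdjacencyGraph | None = None,
) -> ClusterTestResult:
    """Full pipeline: baseline -> condition averaging -> pointwise statistic
    -> clustering -> permutation null -> corrected p-values."""
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ValueError("cluster test requires at least 2 conditions")
    maps = condition_maps(epochs, conditions, electrode_scope, time_window, baseline)
    kind = config.stat
    if kind == "auto":
        kind = "t" if maps.n_conditions == 2 else "F"
    if kind == "t":
        stat_map = pointwise_paired_t(maps)
    elif kind == "F":
        stat_map = pointwise_rm_anova(maps)
    else:
        raise ValueError(f"unknown statistic kind {config.stat!r}")
    if adjacency is None:
        adjacency = build_adjacency(
            epochs.layout.subset(stat_map.electrode_ids), scale=config.adjacency_scale
        )
    clusters = find_clusters(stat_map, config.threshold_p, adjacency)
    null = permutation_null(
        maps, kind, adjacency, config.n_permutations, config.seed, config.threshold_p
    )
    return cluster_p_values(clusters, null, config.alpha, stat_map=stat_map)
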