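"""Effect-injection power simulation on single-trial epochs.

The sensitivity of the group analysis is assessed directly on (real or
synthetic) single-trial data: per subject, all trials are pooled and
randomly split into three pseudo-conditions; a stochastic effect
``E ~ Normal(mu, sigma_subject)`` — with sigma estimated from the subject's
own trials at a reference (electrode, 250 ms) point — is added to a fixed
electrode set in one pseudo-condition; the pseudo-conditions are averaged
and submitted to the same cluster permutation test used for the experimental
comparisons.  Repeating this yields detection rates over a grid of effect
sizes (microvolts) and sample sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .cluster import (
    ClusterConfig,
    SubjectConditionMaps,
    cluster_p_values,
    find_clusters,
    permutation_null,
    pointwise_rm_anova,
)
from .epochs import EpochSet
from .montage import AdjacencyGraph, RegionMap, build_adjacency

__all__ = [
    "InjectionSpec",
    "SimulationCellResult",
    "PowerGrid",
    "SAN_MU_GRID",
    "P600_MU_GRID",
    "DEFAULT_N_GRID",
    "partition_trials",
    "estimate_sigma",
    "inject_effect",
    "run_simulation_cell",
    "power_grid",
]

SAN_MU_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
P600_MU_GRID = (0.5, 1.0, 1.5, 2.0)
DEFAULT_N_GRID = (20, 30, 37)


@dataclass(frozen=True)
class InjectionSpec:
    """What to inject and where.

    ``mu`` is the mean injected amplitude in microvolts (non-negative; the
    applied polarity is ``sign``: -1 for negativities such as the SAN, +1
    for positivities such as the P600).  ``sigma_electrode`` /
    ``sigma_time_s`` locate the point at which the per-subject across-trial
    SD is estimated.  ``draw_level`` sets the granularity of the stochastic
    effect draw.
    """

    component: str
    mu: float
    electrode_set: tuple[int, ...]
    time_window: tuple[float, float]
    sign: int = 1
    sigma_electrode: int = 1
    sigma_time_s: float = 0.250
    draw_level: str = "per_trial"  # "per_trial" | "per_subject"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative (polarity is carried by sign)")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")
        if self.draw_level not in ("per_trial", "per_subject"):
            raise ValueError(f"unknown draw_level {self.draw_level!r}")
        object.__setattr__(self, "electrode_set", tuple(int(e) for e in self.electrode_set))

    @classmethod
    def san(cls, region_map: RegionMap, mu: float, time_window=(0.0, 2.2), **kw) -> "InjectionSpec":
        """Negative-going injection over the 24 anterior electrodes."""
        return cls("SAN", mu, tuple(sorted(region_map.anterior)), time_window, sign=-1, **kw)

    @classmethod
    def p600(cls, region_map: RegionMap, mu: float, time_window=(0.5, 0.7), **kw) -> "InjectionSpec":
        """Positive-going injection over the 20 posterior electrodes."""
        return cls("P600", mu, tuple(sorted(region_map.posterior)), time_window, sign=1, **kw)


def partition_trials(epochs: EpochSet, subject: int, k: int = 3, seed: int = 0):
    """Pool the subject's trials across all conditions and split them into
    ``k`` near-equal random partitions (sizes differ by at most 1).

    Returns a list of ``(n_i, 2)`` integer arrays of (condition index,
    trial index) pairs; their union is exactly the subject's trial set.
    """
    n_total = epochs.n_conditions * epochs.n_trials
    if n_total < k:
        raise ValueError(f"subject has {n_total} trials; need at least {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_total)
    parts = np.array_split(order, k)
    return [np.column_stack(np.divmod(p, epochs.n_trials)) for p in parts]


def estimate_sigma(
    epochs: EpochSet, subject: int, electrode: int, time: float = 0.250
) -> float:
    """Across-trial sample SD (all conditions pooled) of the amplitude at the
    single (electrode, nearest-sample-to-``time``) point, in microvolts."""
    ei = epochs.layout.index_of(electrode)
    ti = epochs.time_index(time)
    vals = epochs.data[subject, :, :, ei, ti].ravel()
    if vals.size < 2:
        raise ValueError("need at least 2 trials to estimate sigma")
    return float(vals.std(ddof=1))


def inject_effect(
    trials: np.ndarray,
    times: np.ndarray,
    electrode_idx: np.ndarray,
    spec: InjectionSpec,
    sigma: float,
    seed: int = 0,
) -> np.ndarray:
    """Add the stochastic effect to a stack of trials ``(n_trials, E, T)``.

    Draws ``E_eff ~ Normal(mu, sigma)`` per trial (or once per subject for
    ``draw_level='per_subject'``) and adds ``sign * E_eff``, constant over
    ``spec.time_window``, on the rows in ``electrode_idx``.  Returns a copy.
    """
    t0, t1 = spec.time_window
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError(f"injection window {spec.time_window} outside epoch")
    tmask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    rng = np.random.default_rng(seed)
    n_tr = trials.shape[0]
    if spec.draw_level == "per_trial":
        eff = spec.sign * (spec.mu + sigma * rng.standard_normal(n_tr))
    else:
        eff = np.full(n_tr, spec.sign * (spec.mu + sigma * rng.standard_normal()))
    out = trials.copy()
    out[:, electrode_idx[:, None], tmask] += eff[:, None, None]
    return out


@dataclass
class SimulationCellResult:
    """Detection summary for one (mu, N) cell."""

    component: str
    mu: float
    n_subjects: int
    repetitions: int
    detections: int
    seed: int

    @property
    def detection_rate(self) -> float:
        return self.detections / self.repetitions

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "mu": self.mu,
            "n": self.n_subjects,
            "repetitions": self.repetitions,
            "detections": self.detections,
            "rate": self.detection_rate,
            "seed": int(self.seed),
        }


def _pseudo_condition_maps(
    epochs: EpochSet,
    subjects: np.ndarray,
    spec: InjectionSpec,
    sigma_by_subject: np.ndarray,
    e_scope_idx: np.ndarray,
    inject_e_idx_local: np.ndarray,
    rng: np.random.Generator,
    k: int = 3,
) -> SubjectConditionMaps:
    """Partition, inject (into pseudo-condition 0), and average per subject."""
    n_e = e_scope_idx.size
    n_t = epochs.n_times
    maps = np.empty((subjects.size, k, n_e, n_t))
    flat = epochs.data.reshape(
        epochs.n_subjects, epochs.n_conditions * epochs.n_trials, epochs.n_electrodes, n_t
    )
    for row, s in enumerate(subjects):
        parts = partition_trials(epochs, s, k=k, seed=rng.integers(2**63))
        for j, part in enumerate(parts):
            idx = part[:, 0] * epochs.n_trials + part[:, 1]
            trials = flat[s][idx][:, e_scope_idx, :]
            if j == 0:
                trials = inject_effect(
                    trials,
                    epochs.times,
                    inject_e_idx_local,
                    spec,
                    sigma_by_subject[s],
                    seed=rng.integers(2**63),
                )
            maps[row, j] = trials.mean(axis=0)
    e_ids = tuple(epochs.layout.ids[i] for i in e_scope_idx)
    return SubjectConditionMaps(maps, tuple(f"pseudo{j}" for j in range(k)), e_ids, epochs.times)


def run_simulation_cell(
    epochs: EpochSet,
    spec: InjectionSpec,
    n_subjects: int,
    repetitions: int = 100,
    analysis_config: ClusterConfig = ClusterConfig(),
    seed: int = 0,
    electrode_scope=None,
    adjacency: AdjacencyGraph | None = None,
    strict_overlap: bool = False,
) -> SimulationCellResult:
    """Detection rate of the injected effect over ``repetitions`` replicates.

    Each replicate subsamples ``n_subjects`` subjects without replacement,
    partitions each subject's pooled trials into three pseudo-conditions,
    injects into one, averages, and runs the three-condition cluster
    permutation test; a detection is >= 1 significant cluster (restricted to
    clusters overlapping the injected electrode set when
    ``strict_overlap``).  Deterministic given ``seed``.
    """
    if n_subjects > epochs.n_subjects:
        raise ValueError("n_subjects exceeds available subjects")
    if electrode_scope is not None:
        e_scope_idx = epochs.layout.indices_of(electrode_scope)
    else:
        e_scope_idx = np.arange(epochs.n_electrodes)
    scope_ids = [epochs.layout.ids[i] for i in e_scope_idx]
    inject_ids = [e for e in spec.electrode_set if e in set(scope_ids)]
    if not inject_ids:
        raise ValueError("injection electrode set disjoint from analysis scope")
    inject_local = np.array([scope_ids.index(e) for e in inject_ids])
    if adjacency is None:
        adjacency = build_adjacency(
            epochs.layout.subset(scope_ids), scale=analysis_config.adjacency_scale
        )
    sigma_by_subject = np.array(
        [
            estimate_sigma(epochs, s, spec.sigma_electrode, spec.sigma_time_s)
            for s in range(epochs.n_subjects)
        ]
    )

    detections = 0
    children = np.random.SeedSequence(seed).spawn(repetitions)
    for child in children:
        rng = np.random.default_rng(child)
        if n_subjects < epochs.n_subjects:
            subjects = rng.choice(epochs.n_subjects, size=n_subjects, replace=False)
        else:
            subjects = np.arange(epochs.n_subjects)
        maps = _pseudo_condition_maps(
            epochs, subjects, spec, sigma_by_subject, e_scope_idx, inject_local, rng
        )
        stat_map = pointwise_rm_anova(maps)
        clusters = find_clusters(stat_map, analysis_config.threshold_p, adjacency)
        null = permutation_null(
            maps,
            "F",
            adjacency,
            analysis_config.n_permutations,
            seed=rng.integers(2**63),
            threshold_p=analysis_config.threshold_p,
        )
        result = cluster_p_values(clusters, null, analysis_config.alpha, stat_map=stat_map)
        sig = result.significant_clusters
        if strict_overlap:
            inject_set = set(inject_local.tolist())
            sig = [c for c in sig if inject_set & set(c.electrode_idx.tolist())]
        if sig:
            detections += 1
    return SimulationCellResult(
        component=spec.component,
        mu=spec.mu,
        n_subjects=n_subjects,
        repetitions=repetitions,
        detections=detections,
        seed=seed,
    )


@dataclass
class PowerGrid:
    """Detection-rate surface over effect sizes x sample sizes."""

    component: str
    mu_grid: tuple[float, ...]
    n_grid: tuple[int, ...]
    cells: list[SimulationCellResult]

    def cell(self, mu: float, n: int) -> SimulationCellResult:
        for c in self.cells:
            if c.mu == mu and c.n_subjects == n:
                return c
        raise KeyError(f"no cell (mu={mu}, n={n})")

    def rate_matrix(self) -> np.ndarray:
        """Rates as a (len(mu_grid), len(n_grid)) array."""
        return np.array(
            [[self.cell(mu, n).detection_rate for n in self.n_grid] for mu in self.mu_grid]
        )

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "mu_grid": list(self.mu_grid),
            "n_grid": list(self.n_grid),
            "cells": [c.to_dict() for c in self.cells],
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("component\tmu\tn\trepetitions\tdetections\trate\tseed\n")
            for c in self.cells:
                fh.write(
                    f"{c.component}\t{c.mu:g}\t{c.n_subjects}\t{c.repetitions}"
                    f"\t{c.detections}\t{c.detection_rate:.6g}\t{c.seed}\n"
                )

    def plot(self, path) -> None:
        """Detection-rate curves per sample size (one panel)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for n in self.n_grid:
            rates = [self.cell(mu, n).detection_rate for mu in self.mu_grid]
            ax.plot(self.mu_grid, rates, marker="o", label=f"N = {n}")
        ax.set_xlabel("injected effect size (µV)")
        ax.set_ylabel("detection rate")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(self.component)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def power_grid(
    epochs: EpochSet,
    spec_template: InjectionSpec,
    mu_grid,
    n_grid,
    analysis_config: ClusterConfig = ClusterConfig(),
    seed: int = 0,
    repetitions: int = 100,
    electrode_scope=None,
    strict_overlap: bool = False,
) -> PowerGrid:
    """Full factorial of :func:`run_simulation_cell` over mu x N."""
    mu_grid = tuple(float(m) for m in mu_grid)
    n_grid = tuple(int(n) for n in n_grid)
    if not mu_grid or not n_grid:
        raise ValueError("grids must be non-empty")
    children = np.random.SeedSequence(seed).spawn(len(mu_grid) * len(n_grid))
    cells = []
    i = 0
    for mu in mu_grid:
        for n in n_grid:
            cell_seed = int(children[i].generate_state(1)[0])
            i += 1
            spec = replace(spec_template, mu=mu)
            cells.append(
                run_simulation_cell(
                    epochs,
                    spec,
                    n,
                    repetitions=repetitions,
                    analysis_config=analysis_config,
                    seed=cell_seed,
                    electrode_scope=electrode_scope,
                    strict_overlap=strict_overlap,
                )
            )
    return PowerGrid(spec_template.component, mu_grid, n_grid, cells)
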