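"""End-to-end orchestration of the study's analysis roster.

Runs the five evoked comparisons (interval three-way, whether-question
overlap, per-word re-baselined, target-word three-way, and the two length
contrasts) plus the window-averaged Bayes-factor suite and, optionally, the
injection power grids, from a single config + seed; emits a deterministic
JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .bayes import WindowBFSpec, windowed_bf_suite
from .cluster import ClusterConfig, ClusterTestResult, run_cluster_test
from .epochs import EpochSet
from .montage import build_default_layout, build_region_map
from .power import (
    DEFAULT_N_GRID,
    P600_MU_GRID,
    SAN_MU_GRID,
    InjectionSpec,
    PowerGrid,
    power_grid,
)
from .preprocess import BaselineWindow
from .synth import LENGTHS, NoiseSpec, StudyDesign, preset_components, simulate_study

__all__ = [
    "AnalysisConfig",
    "RunReport",
    "COMPARISONS",
    "merge_lengths",
    "target_locked",
    "run_interval_analysis",
    "run_whether_overlap",
    "run_per_word_analysis",
    "run_target_word_analysis",
    "run_length_analysis",
    "run_power_analysis",
    "run_full_study",
    "default_bf_suite",
]

COMPARISONS = (
    "interval_3way",
    "whether_overlap",
    "per_word",
    "target_word_3way",
    "length_short",
    "length_long",
)
POWER_COMPARISONS = ("power_san", "power_p600")


@dataclass(frozen=True)
class AnalysisConfig:
    """Study-level configuration.

    The default comparison roster covers the evoked analyses; power grids
    are opt-in (they dominate runtime).  ``preset`` controls the synthetic
    dataset: ``null`` (noise only), ``paper`` (P2 at the target word in
    question conditions, optional SAN/P600), or ``demo`` (a 6-subject
    miniature of ``paper``).
    """

    preset: str = "demo"
    comparisons: tuple[str, ...] = COMPARISONS
    seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 1000
    threshold_p: float = 0.05
    adjacency_scale: float = 1.5
    bf_draws: int = 10_000
    san_uv: float = 0.0
    p600_uv: float = 0.0
    p2_uv: float = 2.0
    noise: NoiseSpec = NoiseSpec()
    power_repetitions: int = 100
    power_mu_grid: tuple[float, ...] = ()
    power_n_grid: tuple[int, ...] = DEFAULT_N_GRID
    epochs_path: str | None = None

    def design(self) -> StudyDesign:
        if self.preset == "demo":
            return StudyDesign.demo()
        return StudyDesign.default()

    def cluster_config(self, seed: int) -> ClusterConfig:
        return ClusterConfig(
            threshold_p=self.threshold_p,
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            seed=seed,
            adjacency_scale=self.adjacency_scale,
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        kw = dict(raw)
        if "noise" in kw and isinstance(kw["noise"], dict):
            kw["noise"] = NoiseSpec(**kw["noise"])
        for key in ("comparisons", "power_mu_grid", "power_n_grid"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        unknown = set(kw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"] = dataclasses.asdict(self.noise)
        for key in ("comparisons", "power_mu_grid", "power_n_grid"):
            d[key] = list(d[key])
        return d


def merge_lengths(epochs: EpochSet, types) -> EpochSet:
    """Collapse the length factor: concatenate short + long trials per type."""
    pieces = []
    for t in types:
        idx = [epochs.condition_index(f"{t}_{l}") for l in LENGTHS]
        pieces.append(np.concatenate([epochs.data[:, i] for i in idx], axis=1))
    data = np.stack(pieces, axis=1)
    return dataclasses.replace(
        epochs, data=data, conditions=tuple(types), provenance={**epochs.provenance}
    )


def target_locked(epochs: EpochSet, design: StudyDesign, window=(-0.3, 1.0)) -> EpochSet:
    """Re-epoch every condition around its own target-word onset."""
    per_cond = []
    times = None
    for ci, cond in enumerate(epochs.conditions):
        onset = design.target_onset(cond)
        sl = epochs.time_slice((onset + window[0], onset + window[1]))
        per_cond.append(epochs.data[:, ci : ci + 1, :, :, sl])
        t = epochs.times[sl] - onset
        if times is None:
            times = t
        elif t.size != times.size:
            raise ValueError("target windows differ in length across conditions")
    data = np.concatenate(per_cond, axis=1)
    return dataclasses.replace(
        epochs,
        data=data,
        times=times,
        provenance={**epochs.provenance, "locked_to": "target_word"},
    )


# -- individual comparisons --------------------------------------------------

def run_interval_analysis(
    epochs: EpochSet, design: StudyDesign, config: AnalysisConfig, seed: int
) -> ClusterTestResult:
    """Three-way (indirect/direct/declarative) cluster test over the
    verb-to-target interval, lengths averaged, all electrodes; 100 ms
    baseline at the start of the interval epoch."""
    for t in ("indirectQ", "directQ", "declarative"):
        for l in LENGTHS:
            epochs.condition_index(f"{t}_{l}")  # KeyError if missing
    merged = merge_lengths(epochs, ("indirectQ", "directQ", "declarative"))
    return run_cluster_test(
        merged,
        conditions=("indirectQ", "directQ", "declarative"),
        time_window=(-0.3, 2.2),
        baseline=BaselineWindow(-0.3, -0.2),
        config=config.cluster_config(seed),
    )


def run_whether_overlap(
    epochs: EpochSet, design: StudyDesign, config: AnalysisConfig, seed: int
) -> ClusterTestResult:
    """Paired-t cluster test of indirect vs whether questions over the
    sub-interval shared by both (adverb + embedded subject)."""
    merged = merge_lengths(epochs, ("indirectQ", "whetherQ"))
    ons = design.intervening_onsets("indirectQ_short")
    window = (ons[0], ons[1] + design.soa)
    return run_cluster_test(
        merged,
        conditions=("indirectQ", "whetherQ"),
        time_window=window,
        baseline=BaselineWindow(-0.3, -0.2),
        config=config.cluster_config(seed),
    )


def run_per_word_analysis(
    epochs: EpochSet, design: StudyDesign, config: AnalysisConfig, seed: int
) -> list[tuple[str, ClusterTestResult]]:
    """One three-way cluster test per intervening word (short design: adverb,
    embedded subject, embedded verb), re-baselined 100 ms before each word."""
    merged = merge_lengths(epochs, ("indirectQ", "directQ", "declarative"))
    results = []
    names = ("adverb", "embedded_subject", "embedded_verb")
    children = np.random.SeedSequence(seed).spawn(len(names))
    for name, onset, child in zip(
        names, design.intervening_onsets("indirectQ_short"), children
    ):
        res = run_cluster_test(
            merged,
            conditions=("indirectQ", "directQ", "declarative"),
            time_window=(onset, onset + design.soa),
            baseline=BaselineWindow(onset - 0.1, onset),
            config=config.cluster_config(int(child.generate_state(1)[0])),
        )
        results.append((name, res))
    return results


def run_target_word_analysis(
    epochs: EpochSet, design: StudyDesign, config: AnalysisConfig, seed: int
) -> ClusterTestResult:
    """Three-way cluster test on target-word epochs (-0.3 to 1.0 s), 100 ms
    pre-stimulus baseline, lengths averaged."""
    locked = target_locked(epochs, design)
    merged = merge_lengths(locked, ("indirectQ", "directQ", "declarative"))
    return run_cluster_test(
        merged,
        conditions=("indirectQ", "directQ", "declarative"),
        time_window=(-0.3, 1.0),
        baseline=BaselineWindow(-0.1, 0.0),
        config=config.cluster_config(seed),
    )


def run_length_analysis(
    epochs: EpochSet, design: StudyDesign, config: AnalysisConfig, seed: int, length: str
) -> ClusterTestResult:
    """Indirect vs direct paired-t cluster test over the interval of one
    length condition (2.2 s short / 3.0 s long), 100 ms pre-verb baseline."""
    if length not in LENGTHS:
        raise ValueError(f"unknown length {length!r}")
    window = (-0.3, design.interval_window(f"indirectQ_{length}")[1])
    return run_cluster_test(
        epochs,
        conditions=(f"indirectQ_{length}", f"directQ_{length}"),
        time_window=window,
        baseline=BaselineWindow(-0.1, 0.0),
        config=config.cluster_config(seed),
    )


def default_bf_suite(
    design: StudyDesign, region_map=None
) -> tuple[list[WindowBFSpec], list[WindowBFSpec]]:
    """The window-averaged BF comparisons.

    Returns (verb-locked specs, target-locked specs): the interval SAN ANOVA
    (anterior, lengths collapsed), per-word 300-500 ms anterior ANOVAs, the
    interval length contrasts (t), plus — on target-locked epochs — the
    P600 posterior 500-700 ms ANOVA and per-length target contrasts (t).
    """
    if region_map is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            region_map = build_region_map()
    anterior = tuple(sorted(region_map.anterior))
    posterior = tuple(sorted(region_map.posterior))
    three_merged = tuple(
        (f"{t}_short", f"{t}_long") for t in ("indirectQ", "directQ", "declarative")
    )
    verb_specs = [
        WindowBFSpec(
            "interval_san",
            conditions=three_merged,
            electrode_set=anterior,
            time_window=(0.0, 2.2),
            kind="anova",
            region_label="anterior",
        )
    ]
    for name, onset in zip(
        ("adverb", "embedded_subject", "embedded_verb"),
        design.intervening_onsets("indirectQ_short"),
    ):
        verb_specs.append(
            WindowBFSpec(
                f"word_{name}",
                conditions=three_merged,
                electrode_set=anterior,
                time_window=(onset + 0.3, onset + 0.5),
                kind="anova",
                region_label="anterior",
            )
        )
    for length in LENGTHS:
        verb_specs.append(
            WindowBFSpec(
                f"length_interval_{length}",
                conditions=(f"indirectQ_{length}", f"directQ_{length}"),
                electrode_set=anterior,
                time_window=design.interval_window(f"indirectQ_{length}"),
                kind="ttest",
                region_label="anterior",
            )
        )
    target_specs = [
        WindowBFSpec(
            "p600_target",
            conditions=three_merged,
            electrode_set=posterior,
            time_window=(0.5, 0.7),
            kind="anova",
            region_label="posterior",
        )
    ]
    for length in LENGTHS:
        target_specs.append(
            WindowBFSpec(
                f"length_target_{length}",
                conditions=(f"indirectQ_{length}", f"directQ_{length}"),
                electrode_set=posterior,
                time_window=(0.5, 0.7),
                kind="ttest",
                region_label="posterior",
            )
        )
    return verb_specs, target_specs


def run_power_analysis(
    epochs: EpochSet, config: AnalysisConfig, component: str, seed: int
) -> PowerGrid:
    """Injection power grid for ``power_san`` / ``power_p600``."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rm = build_region_map()
    if component == "power_san":
        template = InjectionSpec.san(rm, mu=0.0)
        mu_grid = config.power_mu_grid or SAN_MU_GRID
    elif component == "power_p600":
        template = InjectionSpec.p600(rm, mu=0.0)
        mu_grid = config.power_mu_grid or P600_MU_GRID
    else:
        raise ValueError(f"unknown power component {component!r}")
    n_grid = [n for n in config.power_n_grid if n <= epochs.n_subjects] or [epochs.n_subjects]
    return power_grid(
        epochs,
        template,
        mu_grid,
        n_grid,
        analysis_config=config.cluster_config(seed),
        seed=seed,
        repetitions=config.power_repetitions,
    )


@dataclass
class RunReport:
    """Deterministic study report: one entry per configured comparison."""

    config: dict
    comparisons: dict = field(default_factory=dict)
    bf_table: list = field(default_factory=list)
    power: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "comparisons": self.comparisons,
            "bayes_factors": self.bf_table,
            "power": self.power,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _build_epochs(config: AnalysisConfig, design: StudyDesign) -> EpochSet:
    if config.epochs_path:
        return EpochSet.load_hdf5(config.epochs_path)
    layout = build_default_layout()
    if config.preset in ("paper", "demo"):
        comps = preset_components(
            "paper", design, san_uv=config.san_uv, p600_uv=config.p600_uv, p2_uv=config.p2_uv
        )
    elif config.preset == "null":
        comps = []
    else:
        raise ValueError(f"unknown preset {config.preset!r}")
    return simulate_study(design, config.noise, comps, seed=config.seed, layout=layout)


def run_full_study(config: AnalysisConfig, epochs: EpochSet | None = None) -> RunReport:
    """Execute every configured comparison plus the BF suite.

    Fully reproducible: every random stream is derived from ``config.seed``.
    Raises on unknown comparison ids; failures in a stage are re-raised with
    the stage name attached.
    """
    design = config.design()
    if epochs is None:
        epochs = _build_epochs(config, design)
    report = RunReport(config=config.to_dict())
    known = set(COMPARISONS) | set(POWER_COMPARISONS)
    unknown = set(config.comparisons) - known
    if unknown:
        raise ValueError(f"unknown comparison ids: {sorted(unknown)}")

    ss = np.random.SeedSequence(config.seed)
    seeds = {c: int(child.generate_state(1)[0]) for c, child in
             zip(sorted(known), ss.spawn(len(known)))}
    bf_seed = int(ss.spawn(1)[0].generate_state(1)[0])

    for comp in config.comparisons:
        try:
            if comp == "interval_3way":
                res = run_interval_analysis(epochs, design, config, seeds[comp])
                report.comparisons[comp] = res.summary()
            elif comp == "whether_overlap":
                res = run_whether_overlap(epochs, design, config, seeds[comp])
                report.comparisons[comp] = res.summary()
            elif comp == "per_word":
                for name, res in run_per_word_analysis(epochs, design, config, seeds[comp]):
                    report.comparisons[f"per_word_{name}"] = res.summary()
            elif comp == "target_word_3way":
                res = run_target_word_analysis(epochs, design, config, seeds[comp])
                report.comparisons[comp] = res.summary()
            elif comp in ("length_short", "length_long"):
                res = run_length_analysis(
                    epochs, design, config, seeds[comp], comp.removeprefix("length_")
                )
                report.comparisons[comp] = res.summary()
            elif comp in POWER_COMPARISONS:
                grid = run_power_analysis(epochs, config, comp, seeds[comp])
                report.power[comp] = grid.to_dict()
        except Exception as exc:
            raise RuntimeError(f"analysis stage {comp!r} failed: {exc}") from exc

    try:
        verb_specs, target_specs = default_bf_suite(design)
        bf_verb = windowed_bf_suite(epochs, verb_specs, draws=config.bf_draws, seed=bf_seed)
        bf_target = windowed_bf_suite(
            target_locked(epochs, design), target_specs, draws=config.bf_draws, seed=bf_seed + 1
        )
        report.bf_table = bf_verb.to_dict(orient="records") + bf_target.to_dict(orient="records")
    except Exception as exc:
        raise RuntimeError(f"analysis stage 'bayes' failed: {exc}") from exc
    return report
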