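"""End-to-end pipeline configuration and execution.

A :class:`RunConfig` describes one full run: simulate a cohort, preprocess
and epoch it, evaluate the requested (method, strategy, task) cells, run
the accuracy statistics, and (optionally) the CCA feature analysis.  The
config round-trips losslessly through YAML, and every output file embeds
the config hash and base seed for traceability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .containers import State
from .evaluation import (NETWORK_METHODS, SVM_METHODS, Strategy, run_cell,
                         summarize_results)
from .features import cca_analysis, handcrafted_features
from .montage import make_compact_montage, make_montage
from .preprocess import STATE_TASKS, TASKS, PreprocConfig, assemble_task, cohort_to_trialset
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)

_ALL_METHODS = SVM_METHODS + NETWORK_METHODS


@dataclass
class RunConfig:
    n_subjects: int = 3
    dispersion: float = 0.3
    seed: int = 0
    n_reps: int = 1
    methods: tuple[str, ...] = ("csp", "fbcsp")
    strategies: tuple[str, ...] = ("mix",)
    tasks: tuple[str, ...] = ("MBSR1_REST1",)
    compact_montage: int = 0  # 0 => full 128-channel montage
    raw_rate: float = 1000.0
    segment_duration: float = 600.0
    target_rate: float = 250.0
    trial_len: int = 1251
    trial_hop: int = 1250
    net_params: dict = field(default_factory=dict)
    run_cca: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        unknown = set(self.methods) - set(_ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        for s in self.strategies:
            Strategy(s)
        unknown_tasks = set(self.tasks) - set(TASKS)
        if unknown_tasks:
            raise ValueError(f"unknown tasks {sorted(unknown_tasks)}")
        self.methods = tuple(self.methods)
        self.strategies = tuple(self.strategies)
        self.tasks = tuple(self.tasks)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ValueError("run config YAML must contain a mapping")
        payload = {k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()}
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def valid_cells(self):
        for strategy in self.strategies:
            strategy = Strategy(strategy)
            for task in self.tasks:
                if strategy in (Strategy.INTRA, Strategy.TRANSFER) and task not in STATE_TASKS:
                    continue
                for method in self.methods:
                    if strategy is Strategy.TRANSFER and method in SVM_METHODS:
                        continue
                    yield method, strategy, task


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute simulate -> preprocess -> evaluate -> statistics (-> CCA).

    Writes ``results.csv`` (long format), ``summary.json`` and the config
    itself into ``out_dir``; returns the result bundle as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("run %s: simulating %d subjects", chash, config.n_subjects)

    montage = (make_compact_montage(config.compact_montage)
               if config.compact_montage else make_montage())
    sim = SimConfig(raw_rate=config.raw_rate,
                    segment_duration=config.segment_duration,
                    rng_seed=config.seed)
    recordings = simulate_cohort(config.n_subjects, sim, config.dispersion,
                                 montage=montage)
    pre = PreprocConfig(
        bad_channels=tuple(montage.bad_channels),
        target_rate=config.target_rate,
        trial_len=config.trial_len,
        trial_hop=config.trial_hop,
    )
    logger.info("run %s: preprocessing %d recordings", chash, len(recordings))
    trialset = cohort_to_trialset(recordings, pre)

    frames = []
    for method, strategy, task in config.valid_cells():
        logger.info("run %s: cell %s/%s/%s", chash, method, strategy.value, task)
        frames.append(
            run_cell(method, strategy, task, trialset, n_reps=config.n_reps,
                     base_seed=config.seed, net_params=config.net_params)
        )
    results = pd.concat(frames, ignore_index=True)
    results["config_hash"] = chash
    summary = summarize_results(results)
    summary["config_hash"] = chash
    summary["base_seed"] = config.seed

    if config.run_cca and any(m in config.methods for m in NETWORK_METHODS):
        summary["cca"] = _cca_block(config, trialset)

    results.to_csv(out_dir / "results.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    config.to_yaml(out_dir / "config.yaml")
    return {"results": results, "summary": summary}


def _cca_block(config: RunConfig, trialset) -> dict:
    """Train a shallow net on the meditation-vs-rest contrast and correlate
    its penultimate features with the handcrafted band-power ratios."""
    from .evaluation import build_method

    subset, y = assemble_task(trialset, "MBSR_REST")
    net = build_method("shallow", subset.rate, config.seed,
                       net_params=config.net_params)
    net.fit(subset.trials, y)
    out = {}
    for state in State:
        mask = subset.states == state.value
        if mask.sum() < 12:
            continue
        feats = net.extract_penultimate(subset.trials[mask])
        hand = handcrafted_features(subset.select(mask)).to_numpy()
        res = cca_analysis(feats, hand, seed=config.seed)
        out[state.value] = {
            "r": res.r,
            "chance_mean": res.chance_mean,
            "chance_sd": res.chance_sd,
            "significant": res.significant,
        }
    return out
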