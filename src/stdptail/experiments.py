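"""End-to-end experiment orchestration.

``run_experiment`` executes one configuration: dataset generation (or
loading), training, class assignment, accuracy and generalization error,
training-loss curve, and the BG index of the learning trajectory.  The
grid runners sweep the scaling-function ratio (SFR = c+/c-) or the
learning rate across STDP rules and collect one result row per cell,
mirroring the structure of the rule x hyperparameter comparison tables.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import training as tr
from .config import ExperimentConfig, config_hash, desk_config, network_stdp_config
from .encoding import (
    LabeledImageSet,
    generate_synthetic_patterns,
    normalize_intensity_sum,
    read_idx_dataset,
    train_test_split,
)
from .heavytail import bg_index
from .lif import NeuronParams, build_network
from .stdp import STDPConfig
from .training import TrainSchedule

__all__ = [
    "load_dataset",
    "repeat_stream",
    "run_experiment",
    "sfr_grid",
    "learning_rate_grid",
    "rule_bg_comparison",
    "sfr_generalization_sweep",
    "bo_base_config",
    "bo_benchmark",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "config_hash", "seed", "rule", "sfr", "eta", "bg_index",
    "train_accuracy", "test_accuracy", "generalization_error",
    "train_loss", "train_loss_spread", "status",
]


def load_dataset(config: ExperimentConfig) -> LabeledImageSet:
    d = config.dataset
    if d.kind == "synthetic":
        return generate_synthetic_patterns(
            n_classes=d.n_classes,
            image_size=tuple(d.image_size),
            samples_per_class=d.samples_per_class,
            stroke_density=d.stroke_density,
            noise_sd=d.noise_sd,
            dropout=d.dropout,
            blur_sigma=d.blur_sigma,
            seed=config.seed,
        )
    dataset = read_idx_dataset(d.images_path, d.labels_path, seed=config.seed)
    return normalize_intensity_sum(dataset)


def repeat_stream(dataset: LabeledImageSet, n_presentations: int, seed: int) -> LabeledImageSet:
    """Cycle the dataset into a training stream of the requested length.

    Each epoch is reshuffled so repeats do not present identical runs of
    images; this is the desk-scale stand-in for a larger training set.
    """
    rng = np.random.default_rng(seed)
    n = len(dataset)
    epochs = -(-n_presentations // n)
    flat = np.concatenate([rng.permutation(n) for _ in range(epochs)])[:n_presentations]
    return LabeledImageSet(dataset.images[flat], dataset.labels[flat])


def _build_stdp(config: ExperimentConfig) -> STDPConfig:
    doc = dict(config.stdp)
    rule = doc.pop("rule", "log")
    return network_stdp_config(rule, **doc)


def run_experiment(config: ExperimentConfig, compute_loss: bool = True) -> dict:
    """Run one full cell: train, evaluate, measure the BG index.

    Returns a result-row dict (see RESULT_COLUMNS).  Failures inside the
    cell are caught and reported through the ``status`` column so grid
    sweeps continue past individual divergences.
    """
    chash = config_hash(config)
    stdp_cfg = _build_stdp(config)
    row = {
        "config_hash": chash, "seed": config.seed, "rule": stdp_cfg.rule,
        "sfr": stdp_cfg.sfr, "eta": stdp_cfg.eta,
        "bg_index": np.nan, "train_accuracy": np.nan, "test_accuracy": np.nan,
        "generalization_error": np.nan, "train_loss": np.nan,
        "train_loss_spread": np.nan, "status": "ok",
    }
    try:
        dataset = load_dataset(config)
        train_set, test_set = train_test_split(
            dataset, config.dataset.test_fraction, seed=config.seed
        )
        stream = repeat_stream(
            train_set, config.dataset.n_train_presentations, seed=config.seed + 1
        )
        exc_params = NeuronParams.excitatory(**config.neuron)
        inh_params = NeuronParams.inhibitory()
        schedule = TrainSchedule(**config.schedule)
        topo = build_network(
            dataset.n_pixels, config.network.n_exc,
            fixed_weights=(config.network.w_ei, config.network.w_ie),
            init_seed=config.seed + 2,
            w_min=config.network.w_min, w_max=config.network.w_max,
        )
        run = tr.train(stream, topo, exc_params, inh_params, stdp_cfg, schedule,
                       seed=config.seed + 3)
        n_inc = run.trajectory.snapshots.shape[0] - 1
        row["bg_index"] = bg_index(run.trajectory, last_k=min(3, n_inc)).bg_index

        ev = config.evaluation
        assign_set = train_set.subset(np.arange(0, len(train_set), ev.assign_subsample))
        class_map = tr.assign_classes(run, assign_set, seed=config.seed + 4)
        acc_set = train_set.subset(np.arange(0, len(train_set), ev.accuracy_subsample))
        train_acc = tr.accuracy(run, class_map, acc_set, seed=config.seed + 5)
        test_eval = test_set.subset(np.arange(0, len(test_set), ev.test_subsample))
        test_acc = tr.accuracy(run, class_map, test_eval, seed=config.seed + 6)
        row.update(
            train_accuracy=train_acc, test_accuracy=test_acc,
            generalization_error=tr.generalization_error(train_acc, test_acc),
        )
        if compute_loss:
            loss, spread = tr.training_loss(
                run, class_map, test_set, n_repeats=ev.n_repeats,
                seed=config.seed + 7,
            )
            row.update(train_loss=loss, train_loss_spread=spread)
    except Exception as err:  # noqa: BLE001 - cell failures feed the status column
        row["status"] = f"{type(err).__name__}: {err}"
    return row


def rule_bg_comparison(seeds=(0, 1, 2), progress=None) -> pd.DataFrame:
    """BG index of the three STDP rules at matched desk-scale settings.

    One training run per (seed, rule) under the desk study conditions;
    the BG index pools the final three iterations' increments.  Returns a
    tidy frame with one row per run.
    """
    rows = []
    for seed in seeds:
        for rule in ("log", "mult", "add"):
            cfg = desk_config(rule, seed=seed)
            dataset = load_dataset(cfg)
            train_set, _ = train_test_split(dataset, cfg.dataset.test_fraction, seed=seed)
            stream = repeat_stream(train_set, cfg.dataset.n_train_presentations, seed=seed + 1)
            topo = build_network(
                dataset.n_pixels, cfg.network.n_exc,
                fixed_weights=(cfg.network.w_ei, cfg.network.w_ie),
                init_seed=seed + 2,
            )
            run = tr.train(
                stream, topo, NeuronParams.excitatory(**cfg.neuron),
                NeuronParams.inhibitory(), _build_stdp(cfg),
                TrainSchedule(**cfg.schedule), seed=seed + 3,
            )
            n_inc = run.trajectory.snapshots.shape[0] - 1
            bg = bg_index(run.trajectory, last_k=min(3, n_inc)).bg_index
            rows.append({"seed": seed, "rule": rule, "bg_index": bg})
            if progress:
                progress(rows[-1])
    return pd.DataFrame(rows)


def sfr_generalization_sweep(
    seeds=(0, 1, 2),
    sfr_values=(0.9, 1.2, 1.7, 2.1),
    progress=None,
) -> pd.DataFrame:
    """Log-rule SFR sweep measuring BG index and generalization error.

    Runs in the single-epoch regime (every training image unique and
    presented once), which is where memorization effects of the
    LTP/LTD amplitude ratio show up as a train-test accuracy gap; with a
    small image pool repeated for several epochs, repetition-driven
    memorization swamps the SFR effect.
    """
    ref = network_stdp_config("log")
    rows = []
    for seed in seeds:
        for sfr in sfr_values:
            cfg = desk_config("log", seed=seed)
            stdp = dict(cfg.stdp)
            stdp["rule"] = "log"
            stdp["c_plus"] = sfr * ref.c_minus
            stdp["c_minus"] = ref.c_minus
            # one-epoch regime: as many unique training images as presentations
            n_pres = cfg.dataset.n_train_presentations
            cfg = replace(cfg, stdp=stdp)
            cfg.dataset.samples_per_class = int(
                math.ceil(n_pres / (1 - cfg.dataset.test_fraction) / cfg.dataset.n_classes)
            )
            cfg.evaluation.assign_subsample = 8
            cfg.evaluation.accuracy_subsample = 6
            cfg.evaluation.test_subsample = 3
            row = run_experiment(cfg, compute_loss=False)
            rows.append({k: row[k] for k in
                         ("seed", "rule", "sfr", "bg_index", "train_accuracy",
                          "test_accuracy", "generalization_error", "status")})
            if progress:
                progress(rows[-1])
    return pd.DataFrame(rows)


def bo_base_config(seed: int = 0) -> ExperimentConfig:
    """Reduced-cost experiment base for hyperparameter optimization."""
    cfg = desk_config("log", seed=seed)
    cfg.dataset.n_train_presentations = 600  # split across folds
    cfg.schedule = dict(images_per_iteration=100)
    return cfg


def bo_benchmark(
    seeds=(0, 1, 2),
    budget: int = 15,
    n_init: int = 5,
    n_random: int = 15,
    progress=None,
) -> pd.DataFrame:
    """BO incumbent vs the median of random configurations, per seed.

    For each seed: run SMBO for ``budget`` evaluations of the
    cross-validated BG objective, then evaluate ``n_random`` uniformly
    random configurations of the same space, and compare the incumbent
    against the random median.
    """
    from .hyperopt import default_search_space, objective, smbo_loop

    rows = []
    space = default_search_space()
    for seed in seeds:
        base = bo_base_config(seed)

        def fn(lam, _seed=seed, _base=base):
            return objective(lam, base=_base, K_folds=2, seed=_seed,
                             record_train_accuracy=False)

        run = smbo_loop(space, fn, n_init=n_init, budget=budget, seed=seed)
        rng = np.random.default_rng(10_000 + seed)
        random_vals = []
        for _ in range(n_random):
            val, _aux = fn(space.sample(rng))
            random_vals.append(val)
        rows.append({
            "seed": seed,
            "incumbent_bg": run.f_min,
            "random_median_bg": float(np.median(random_vals)),
            "random_min_bg": float(np.min(random_vals)),
            "n_evaluations": len(run.values),
        })
        if progress:
            progress(rows[-1])
    return pd.DataFrame(rows)


def sfr_grid(
    rules=("log", "mult", "add"),
    sfr_values=(0.9, 1.2, 1.7, 2.1),
    seeds=(0,),
    base: ExperimentConfig | None = None,
    compute_loss: bool = False,
) -> pd.DataFrame:
    """Rule x SFR sweep: c_plus is scaled so c+/c- hits each SFR value."""
    rows = []
    for seed in seeds:
        for rule in rules:
            for sfr in sfr_values:
                cfg = base or desk_config(rule, seed=seed)
                stdp = dict(cfg.stdp)
                stdp["rule"] = rule
                ref = network_stdp_config(rule)
                stdp["c_plus"] = sfr * ref.c_minus
                stdp["c_minus"] = ref.c_minus
                cell = replace(cfg, stdp=stdp, seed=seed)
                rows.append(run_experiment(cell, compute_loss=compute_loss))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def learning_rate_grid(
    rules=("log", "mult", "add"),
    eta_values=(0.05, 0.1, 0.15, 0.2),
    seeds=(0,),
    base: ExperimentConfig | None = None,
    compute_loss: bool = False,
) -> pd.DataFrame:
    """Rule x learning-rate sweep at each rule's default calibration."""
    rows = []
    for seed in seeds:
        for rule in rules:
            for eta in eta_values:
                cfg = base or desk_config(rule, seed=seed)
                stdp = dict(cfg.stdp)
                stdp["rule"] = rule
                stdp["eta"] = eta
                cell = replace(cfg, stdp=stdp, seed=seed)
                rows.append(run_experiment(cell, compute_loss=compute_loss))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
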