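"""Training/evaluation strategies, split plans, leakage guards and statistics.

Four strategies cover the application scenarios:

* ``INTER`` -- leave-one-subject-out cross-validation: each subject in turn
  is held out entirely; the others provide training (networks: 80/20
  train/validation; SVM methods: all trials).
* ``MIX`` -- trials from all subjects pooled and split at random
  (networks 60/20/20 train/val/test, SVM methods 80/20), repeated
  ``n_reps`` times (default 11).
* ``INTRA`` -- the same random split applied within each subject separately;
  one accuracy row per repetition is the mean over subjects.
* ``TRANSFER`` -- an inter-subject network pretrained without the target
  subject is fine-tuned on the target subject's own split (learning rate
  /10, up to 30 epochs); network methods only.

INTRA and TRANSFER are restricted to the meditation-vs-rest ("state") tasks.
Accuracies are compared with a Mann-Whitney U test (two methods) and a
Kruskal-Wallis test (across tasks).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import CSPSVMClassifier
from .containers import TrialSet
from .nets import DeepConvNet, ShallowConvNet
from .preprocess import STATE_TASKS, assemble_task

__all__ = [
    "Strategy",
    "Fold",
    "SplitPlan",
    "make_split",
    "check_no_leakage",
    "LeakageError",
    "build_method",
    "run_cell",
    "transfer_finetune",
    "MannWhitneyResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "summarize_results",
    "NETWORK_METHODS",
    "SVM_METHODS",
]

NETWORK_METHODS = ("shallow", "deep")
SVM_METHODS = ("csp", "fbcsp")


class Strategy(str, Enum):
    INTER = "inter"
    MIX = "mix"
    INTRA = "intra"
    TRANSFER = "transfer"


class LeakageError(RuntimeError):
    """A test trial (or test subject) reached a training or validation set."""


def _seed_tuple(seed) -> tuple:
    return tuple(seed) if isinstance(seed, (tuple, list)) else (int(seed),)


@dataclass
class Fold:
    train: np.ndarray
    test: np.ndarray
    val: np.ndarray | None = None
    held_out_subject: object = None


@dataclass
class SplitPlan:
    strategy: Strategy
    folds: list[Fold] = field(default_factory=list)


def _stratified_partition(y, fractions, rng):
    """Split indices per class into len(fractions) groups with the given
    target fractions (last group absorbs rounding leftovers)."""
    groups = [[] for _ in fractions]
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        members = members[rng.permutation(len(members))]
        n = len(members)
        cuts, start = [], 0
        for frac in fractions[:-1]:
            k = int(round(frac * n))
            cuts.append(members[start:start + k])
            start += k
        cuts.append(members[start:])
        for g, part in zip(groups, cuts):
            g.extend(part)
    return [np.sort(np.array(g, dtype=int)) for g in groups]


def check_no_leakage(fold: Fold, subjects=None) -> None:
    """Raise :class:`LeakageError` on any train/val/test overlap, and -- when
    the fold holds out a subject -- on any of that subject's trials appearing
    in train or val."""
    train = set(fold.train.tolist())
    test = set(fold.test.tolist())
    val = set(fold.val.tolist()) if fold.val is not None else set()
    if train & test or val & test:
        raise LeakageError("test trials overlap the training or validation set")
    if train & val:
        raise LeakageError("training and validation sets overlap")
    if fold.held_out_subject is not None and subjects is not None:
        subjects = np.asarray(subjects, dtype=object)
        seen = np.union1d(fold.train, fold.val if fold.val is not None else [])
        if np.any(subjects[np.asarray(sorted(seen), dtype=int)] == fold.held_out_subject):
            raise LeakageError(
                f"held-out subject {fold.held_out_subject!r} has trials in train/val"
            )


def make_split(strategy: Strategy, labels, subjects, method_family: str,
               seed: int, n_reps: int = 11) -> SplitPlan:
    """Build the per-repetition (or per-fold) index sets for a strategy.

    ``method_family`` is ``'net'`` (train/val/test) or ``'svm'`` (train/test).
    For ``INTRA``, ``labels``/``subjects`` must come from a single subject.
    All folds are stratified by class and deterministic given ``seed``.
    """
    strategy = Strategy(strategy)
    y = np.asarray(labels)
    subj = np.asarray(subjects, dtype=object)
    if method_family not in ("net", "svm"):
        raise ValueError("method_family must be 'net' or 'svm'")
    plan = SplitPlan(strategy)

    if strategy is Strategy.INTER:
        unique_subjects = sorted(set(subj.tolist()))
        if len(unique_subjects) < 2:
            raise ValueError("inter-subject evaluation needs at least 2 subjects")
        for i, target in enumerate(unique_subjects):
            test = np.flatnonzero(subj == target)
            rest = np.flatnonzero(subj != target)
            if method_family == "net":
                rng = np.random.default_rng(_seed_tuple(seed) + (i,))
                tr_rel, va_rel = _stratified_partition(y[rest], (0.8, 0.2), rng)
                fold = Fold(rest[tr_rel], test, rest[va_rel], held_out_subject=target)
            else:
                fold = Fold(rest, test, None, held_out_subject=target)
            check_no_leakage(fold, subj)
            plan.folds.append(fold)
        return plan

    if strategy in (Strategy.MIX, Strategy.INTRA):
        if strategy is Strategy.INTRA:
            if len(set(subj.tolist())) != 1:
                raise ValueError("intra-subject splits are built per single subject")
            if np.unique(y).size < 2:
                raise ValueError("subject data holds fewer than 2 classes")
        for rep in range(n_reps):
            rng = np.random.default_rng(_seed_tuple(seed) + (rep,))
            if method_family == "net":
                tr, va, te = _stratified_partition(y, (0.6, 0.2, 0.2), rng)
                fold = Fold(tr, te, va)
            else:
                tr, te = _stratified_partition(y, (0.8, 0.2), rng)
                fold = Fold(tr, te, None)
            check_no_leakage(fold)
            plan.folds.append(fold)
        return plan

    raise ValueError(
        "TRANSFER splits are composed from INTER pretraining and INTRA "
        "fine-tuning folds; use run_cell"
    )


def build_method(method: str, sfreq: float, seed: int = 0,
                 net_params: dict | None = None, svm_params: dict | None = None):
    """Instantiate a classifier by short method name."""
    net_params = dict(net_params or {})
    svm_params = dict(svm_params or {})
    if method == "csp":
        return CSPSVMClassifier("csp", sfreq=sfreq, **svm_params)
    if method == "fbcsp":
        return CSPSVMClassifier("fbcsp", sfreq=sfreq, **svm_params)
    if method == "shallow":
        net_params.setdefault("seed", seed)
        return ShallowConvNet(**net_params)
    if method == "deep":
        net_params.setdefault("seed", seed)
        return DeepConvNet(**net_params)
    raise ValueError(f"unknown method {method!r}")


def _fit_and_score(model, X, y, fold: Fold) -> float:
    if fold.val is not None:
        model.fit(X[fold.train], y[fold.train], X_val=X[fold.val], y_val=y[fold.val])
    else:
        model.fit(X[fold.train], y[fold.train])
    return float((model.predict(X[fold.test]) == y[fold.test]).mean())


def _validate_cell(method: str, strategy: Strategy, task: str) -> None:
    if method not in NETWORK_METHODS + SVM_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if strategy is Strategy.TRANSFER and method in SVM_METHODS:
        raise ValueError(
            "subject-transfer fine-tuning applies only to the network methods; "
            "CSP/FBCSP + SVM cannot be fine-tuned"
        )
    if strategy in (Strategy.INTRA, Strategy.TRANSFER) and task not in STATE_TASKS:
        raise ValueError(
            f"strategy {strategy.value!r} is restricted to the state tasks "
            f"{sorted(STATE_TASKS)}"
        )


def run_cell(method: str, strategy: Strategy, task: str, trialset: TrialSet,
             n_reps: int = 11, base_seed: int = 0,
             net_params: dict | None = None,
             svm_params: dict | None = None,
             finetune_epochs: int = 30) -> pd.DataFrame:
    """Evaluate one (method, strategy, task) cell.

    Returns a long-format DataFrame with one accuracy row per repetition
    (MIX/INTRA) or per held-out subject (INTER/TRANSFER), each row carrying
    its seed.
    """
    strategy = Strategy(strategy)
    _validate_cell(method, strategy, task)
    family = "net" if method in NETWORK_METHODS else "svm"
    subset, y = assemble_task(trialset, task)
    X = subset.trials
    subjects = subset.subjects
    rows = []

    def row(rep, acc, seed):
        return dict(method=method, strategy=strategy.value, task=task,
                    rep=rep, accuracy=acc, seed=seed)

    if strategy in (Strategy.INTER, Strategy.MIX):
        if strategy is Strategy.INTER:
            plan = make_split(strategy, y, subjects, family, base_seed)
        else:
            plan = make_split(strategy, y, subjects, family, base_seed, n_reps)
        for rep, fold in enumerate(plan.folds):
            check_no_leakage(fold, subjects)
            seed = base_seed + rep
            model = build_method(method, subset.rate, seed,
                                 net_params=net_params, svm_params=svm_params)
            rows.append(row(rep, _fit_and_score(model, X, y, fold), seed))

    elif strategy is Strategy.INTRA:
        unique_subjects = sorted(set(subjects.tolist()))
        for rep in range(n_reps):
            seed = base_seed + rep
            accs = []
            for target in unique_subjects:
                mask = subjects == target
                Xs, ys = X[mask], y[mask]
                plan = make_split(strategy, ys, subjects[mask], family,
                                  (seed, zlib.crc32(str(target).encode())), n_reps=1)
                model = build_method(method, subset.rate, seed,
                                     net_params=net_params, svm_params=svm_params)
                accs.append(_fit_and_score(model, Xs, ys, plan.folds[0]))
            rows.append(row(rep, float(np.mean(accs)), seed))

    else:  # TRANSFER
        inter_plan = make_split(Strategy.INTER, y, subjects, "net", base_seed)
        for rep, fold in enumerate(inter_plan.folds):
            check_no_leakage(fold, subjects)
            target = fold.held_out_subject
            seed = base_seed + rep
            net = build_method(method, subset.rate, seed, net_params=net_params)
            net.fit(X[fold.train], y[fold.train],
                    X_val=X[fold.val], y_val=y[fold.val])
            mask = subjects == target
            acc = transfer_finetune(
                net, X[mask], y[mask],
                pretrain_subjects=set(subjects[fold.train]) | set(subjects[fold.val]),
                target_subject=target,
                seed=(base_seed, rep),
                max_epochs=finetune_epochs,
            )
            rows.append(row(rep, acc, seed))

    return pd.DataFrame(rows)


def transfer_finetune(pretrained_net, X_target, y_target, pretrain_subjects,
                      target_subject, seed, max_epochs: int = 30) -> float:
    """Fine-tune a pretrained network on the target subject's own split and
    return the accuracy on that subject's held-out test trials.

    All layers are updated at one tenth of the base learning rate.  Raises
    :class:`LeakageError` if the target subject contributed to pretraining.
    """
    if target_subject in set(pretrain_subjects):
        raise LeakageError(
            f"target subject {target_subject!r} is present in the pretraining data"
        )
    rng = np.random.default_rng(seed)
    tr, va, te = _stratified_partition(np.asarray(y_target), (0.6, 0.2, 0.2), rng)
    fold = Fold(tr, te, va)
    check_no_leakage(fold)
    if max_epochs > 0:
        pretrained_net.finetune(X_target[tr], np.asarray(y_target)[tr],
                                X_target[va], np.asarray(y_target)[va],
                                max_epochs=max_epochs)
    pred = pretrained_net.predict(X_target[te])
    return float((pred == np.asarray(y_target)[te]).mean())


# ---------------------------------------------------------------------------
# statistics

@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    z: float  # signed normal approximation (positive => first sample ranks higher)
    p: float  # two-sided


def mann_whitney_u(acc_group_a, acc_group_b) -> MannWhitneyResult:
    """Two-sample Mann-Whitney U test, normal approximation with tie correction.

    ``z`` is signed by the rank sum of the first sample, so swapping the
    arguments negates it while the two-sided p-value is unchanged.
    """
    a = np.asarray(acc_group_a, dtype=float)
    b = np.asarray(acc_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(float(u1), 0.0, 1.0)
    z = (u1 - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(float(u1), float(z), float(p))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across k groups (tie-corrected chi-square,
    k-1 degrees of freedom)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # scipy rejects the all-identical case
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def summarize_results(results: pd.DataFrame) -> dict:
    """Per-strategy summary: mean accuracy per cell, a shallow-vs-deep
    Mann-Whitney test (accuracies pooled across tasks), and a Kruskal-Wallis
    test across tasks (methods pooled)."""
    out: dict = {"cells": {}, "tests": {}}
    means = results.groupby(["strategy", "method", "task"])["accuracy"].mean()
    out["cells"] = {"|".join(k): float(v) for k, v in means.items()}
    for strategy, block in results.groupby("strategy"):
        tests: dict = {}
        sh = block.loc[block.method == "shallow", "accuracy"].to_numpy()
        dp = block.loc[block.method == "deep", "accuracy"].to_numpy()
        if sh.size and dp.size:
            mw = mann_whitney_u(dp, sh)
            tests["deep_vs_shallow"] = {"z": mw.z, "p": mw.p}
        task_groups = [g["accuracy"].to_numpy() for _, g in block.groupby("task")]
        if len(task_groups) >= 2:
            h, p = kruskal_wallis(task_groups)
            tests["across_tasks"] = {"h": h, "p": p}
        out["tests"][strategy] = tests
    return out
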