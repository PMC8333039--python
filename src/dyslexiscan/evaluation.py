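"""Constrained cross-validation protocol, metrics and experiment runner.

The evaluation protocol draws many small balanced test folds from the
cohort rather than partitioning it once: 100 test folds of 16 subjects
(8 HR, 8 LR) with at most 50% pairwise overlap between any two folds.
For each fold the remaining subjects are split 90% / 10% into training
and validation (stratified, largest-remainder rounding), the model is
fitted on the training split with early stopping on validation
accuracy, and accuracy / TPR / TNR are measured on the held-out fold.
Per-fold rates are aggregated as mean ± sample standard deviation.

Nothing derived from a fold's test subjects (cohort target length,
threshold, network weights) ever enters that fold's fit: see
:func:`fit_fold`, which receives only non-test data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .classifiers import (
    LABEL_TO_INDEX,
    CnnSpec,
    ThresholdModel,
    TrainConfig,
    build_cnn,
    fit_reading_time_threshold,
    predict,
    train_cnn,
)
from .datamodel import CohortManifest, PreparedSignal, Recording
from .errors import InfeasibleFoldsError, ValidationError
from .preprocess import Branch, build_representation, prepare_signal, representation_length


@dataclass
class Fold:
    test: list[str]
    train: list[str]
    val: list[str]


@dataclass
class FoldPlan:
    folds: list[Fold]
    seed: int
    test_per_class: int = 8
    max_overlap_frac: float = 0.5

    def __len__(self) -> int:
        return len(self.folds)

    def max_pairwise_overlap(self) -> int:
        """Largest |A ∩ B| over all unordered pairs of test folds."""
        sets = [set(f.test) for f in self.folds]
        best = 0
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                best = max(best, len(sets[i] & sets[j]))
        return best


def _stratified_val_counts(n_by_class: dict[str, int], val_frac: float) -> dict[str, int]:
    """Largest-remainder rounding of per-class validation counts."""
    exact = {c: n * val_frac for c, n in n_by_class.items()}
    counts = {c: int(math.floor(v)) for c, v in exact.items()}
    total_target = int(round(sum(exact.values())))
    remainders = sorted(
        n_by_class, key=lambda c: (exact[c] - counts[c], c), reverse=True
    )
    i = 0
    while sum(counts.values()) < total_target and i < len(remainders):
        counts[remainders[i]] += 1
        i += 1
    return counts


def generate_folds(
    manifest: CohortManifest,
    n_folds: int = 100,
    test_per_class: int = 8,
    max_overlap_frac: float = 0.5,
    val_frac: float = 0.1,
    seed: int = 0,
    max_retries: int = 10_000,
) -> FoldPlan:
    """Draw ``n_folds`` balanced test folds under the pairwise-overlap bound.

    Each fold is a stratified sample without replacement
    (``test_per_class`` per class); a candidate violating the running
    overlap bound against any accepted fold is rejected and redrawn, up
    to ``max_retries`` times, after which a deterministic greedy repair
    (swapping the most-shared subjects) is attempted.  If the bound
    still cannot be met an :class:`InfeasibleFoldsError` is raised — the
    constraint is never silently relaxed.
    """
    hr_ids = sorted(manifest.ids_by_label("HR"))
    lr_ids = sorted(manifest.ids_by_label("LR"))
    for name, pool in (("HR", hr_ids), ("LR", lr_ids)):
        if len(pool) < test_per_class:
            raise ValidationError(
                f"class {name} has {len(pool)} subjects; need >= {test_per_class}"
            )
    fold_size = 2 * test_per_class
    max_overlap = int(math.floor(max_overlap_frac * fold_size))
    if (
        n_folds > 1
        and len(hr_ids) == test_per_class
        and len(lr_ids) == test_per_class
        and max_overlap < fold_size
    ):
        raise InfeasibleFoldsError(
            "every fold must contain the entire cohort; overlap bound unattainable"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    accepted: list[set[str]] = []

    def draw() -> set[str]:
        test = list(rng.choice(hr_ids, test_per_class, replace=False))
        test += list(rng.choice(lr_ids, test_per_class, replace=False))
        return set(test)

    for fold_idx in range(n_folds):
        candidate = None
        for _ in range(max_retries):
            cand = draw()
            if all(len(cand & prev) <= max_overlap for prev in accepted):
                candidate = cand
                break
        if candidate is None:
            candidate = _greedy_repair(
                draw(), accepted, hr_ids, lr_ids, max_overlap, rng
            )
        if candidate is None:
            raise InfeasibleFoldsError(
                f"could not place fold {fold_idx} within the overlap bound"
            )
        accepted.append(candidate)

    folds = []
    for test_set in accepted:
        remaining_hr = [s for s in hr_ids if s not in test_set]
        remaining_lr = [s for s in lr_ids if s not in test_set]
        val_counts = _stratified_val_counts(
            {"HR": len(remaining_hr), "LR": len(remaining_lr)}, val_frac
        )
        val, train = [], []
        for label, pool in (("HR", remaining_hr), ("LR", remaining_lr)):
            pool = list(rng.permutation(pool))
            val += pool[: val_counts[label]]
            train += pool[val_counts[label] :]
        folds.append(Fold(test=sorted(test_set), train=sorted(train), val=sorted(val)))
    return FoldPlan(
        folds=folds,
        seed=seed,
        test_per_class=test_per_class,
        max_overlap_frac=max_overlap_frac,
    )


def _greedy_repair(candidate, accepted, hr_ids, lr_ids, max_overlap, rng, budget=1000):
    """Swap most-shared members of *candidate* for unused ones."""
    candidate = set(candidate)
    for _ in range(budget):
        offending = [prev for prev in accepted if len(candidate & prev) > max_overlap]
        if not offending:
            return candidate
        share = {
            s: sum(1 for prev in offending if s in prev) for s in candidate
        }
        worst = max(share, key=lambda s: (share[s], s))
        if share[worst] == 0:
            return None
        pool = hr_ids if worst in hr_ids else lr_ids
        replacements = [s for s in pool if s not in candidate]
        if not replacements:
            return None
        candidate.remove(worst)
        candidate.add(replacements[int(rng.integers(len(replacements)))])
    return None


# ---------------------------------------------------------------------------
# metrics


@dataclass
class FoldMetrics:
    accuracy: float
    tpr: float | None
    tnr: float | None


def compute_metrics(y_true, y_pred, positive: str = "HR") -> FoldMetrics:
    """Accuracy / TPR / TNR in percent; undefined rates reported as None."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValidationError("empty input")
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred must have equal length")
    pos = y_true == positive
    neg = ~pos
    correct = y_true == y_pred
    accuracy = 100.0 * float(np.mean(correct))
    tpr = 100.0 * float(np.mean(correct[pos])) if pos.any() else None
    tnr = 100.0 * float(np.mean(correct[neg])) if neg.any() else None
    return FoldMetrics(accuracy=accuracy, tpr=tpr, tnr=tnr)


@dataclass
class EvalReport:
    """Per-fold and aggregate accuracy / TPR / TNR (percent, mean ± std)."""

    per_fold: list[FoldMetrics]
    metadata: dict = field(default_factory=dict)

    def _values(self, name: str) -> np.ndarray:
        vals = [getattr(m, name) for m in self.per_fold]
        return np.array([v for v in vals if v is not None], dtype=float)

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def std(self, name: str) -> float:
        v = self._values(name)
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def summary(self) -> str:
        head = self.metadata.get("method", "experiment")
        lines = [
            f"{head}",
            f"{'':<12}{'Accuracy (%)':>16}{'TNR (%)':>16}{'TPR (%)':>16}",
            (
                f"{'mean ± std':<12}"
                f"{self.mean('accuracy'):>10.1f} ± {self.std('accuracy'):<4.1f}"
                f"{self.mean('tnr'):>10.1f} ± {self.std('tnr'):<4.1f}"
                f"{self.mean('tpr'):>10.1f} ± {self.std('tpr'):<4.1f}"
            ),
            f"folds: {len(self.per_fold)}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "aggregate": {
                name: {"mean": self.mean(name), "std": self.std(name)}
                for name in ("accuracy", "tpr", "tnr")
            },
            "per_fold": [
                {"accuracy": m.accuracy, "tpr": m.tpr, "tnr": m.tnr}
                for m in self.per_fold
            ],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# experiment runner


@dataclass
class FoldFit:
    """Everything fitted for one fold — derived from non-test subjects only."""

    target_length: int
    input_length: int
    model: object
    history: dict


def _fold_seed(master_seed: int, fold_idx: int) -> int:
    return int(
        np.random.SeedSequence((master_seed, fold_idx)).generate_state(1)[0] % (2**31)
    )


def fit_fold(
    prepared: dict[str, PreparedSignal],
    fold: Fold,
    branch: Branch | str,
    arch: CnnSpec | str,
    train_cfg: TrainConfig,
    energy_correction: str = "ratio",
    target_length: int | None = None,
    seed: int = 0,
) -> FoldFit:
    """Fit one fold's CNN from its train/validation subjects.

    ``target_length`` overrides the per-fold cohort length (global-N
    mode); by default N is the longest trimmed signal among the
    non-test subjects.
    """
    branch = Branch(branch)
    non_test = fold.train + fold.val
    if target_length is None:
        target_length = max(prepared[s].original_length for s in non_test)

    def matrix(ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        reps = [
            build_representation(prepared[s], branch, target_length, energy_correction)
            for s in ids
        ]
        X = np.vstack([r.values for r in reps])
        y = np.array([LABEL_TO_INDEX[prepared[s].label] for s in ids])
        return X, y

    X_train, y_train = matrix(fold.train)
    X_val, y_val = matrix(fold.val)
    model = build_cnn(arch, input_length=X_train.shape[1], seed=seed)
    history = train_cnn(model, X_train, y_train, X_val, y_val, train_cfg)
    return FoldFit(
        target_length=target_length,
        input_length=X_train.shape[1],
        model=model,
        history=history,
    )


def run_experiment(
    cohort: list[Recording],
    branch: Branch | str,
    arch: CnnSpec | str,
    fold_plan: FoldPlan,
    train_cfg: TrainConfig | None = None,
    energy_correction: str = "ratio",
    target_length_policy: str = "per_fold",
    seed: int = 0,
) -> EvalReport:
    """Train and evaluate one (branch, architecture) cell over a fold plan.

    With ``target_length_policy='per_fold'`` (default) the cohort target
    length N is recomputed from each fold's non-test subjects, so the
    test fold cannot influence the fit; ``'global'`` fixes N to the
    slowest reader of the whole cohort (the replication mode, required
    for zero-padding branches when a test subject may be the slowest).
    """
    branch = Branch(branch)
    train_cfg = train_cfg or TrainConfig()
    if target_length_policy not in ("per_fold", "global"):
        raise ValidationError(f"unknown target_length_policy {target_length_policy!r}")
    prepared = {rec.subject_id: prepare_signal(rec) for rec in cohort}
    global_n = max(s.original_length for s in prepared.values())

    per_fold = []
    for fold_idx, fold in enumerate(fold_plan.folds):
        try:
            fit = fit_fold(
                prepared,
                fold,
                branch,
                arch,
                replace_seed(train_cfg, _fold_seed(seed, fold_idx)),
                energy_correction=energy_correction,
                target_length=global_n if target_length_policy == "global" else None,
                seed=_fold_seed(seed, fold_idx),
            )
            X_test = np.vstack(
                [
                    build_representation(
                        prepared[s], branch, fit.target_length, energy_correction
                    ).values
                    for s in fold.test
                ]
            )
        except Exception as exc:  # add fold context, re-raise
            raise type(exc)(f"fold {fold_idx}: {exc}") from exc
        pred_idx, _ = predict(fit.model, X_test)
        y_true = [prepared[s].label for s in fold.test]
        y_pred = ["HR" if i == 1 else "LR" for i in pred_idx]
        per_fold.append(compute_metrics(y_true, y_pred))
    return EvalReport(
        per_fold=per_fold,
        metadata={
            "method": f"{Branch(branch).value} + "
            f"{arch if isinstance(arch, str) else f'cnn{arch.n_conv_layers}'}",
            "branch": Branch(branch).value,
            "arch": arch if isinstance(arch, str) else f"cnn{arch.n_conv_layers}",
            "n_folds": len(fold_plan.folds),
            "energy_correction": energy_correction,
            "target_length_policy": target_length_policy,
            "seed": seed,
            "fold_plan_seed": fold_plan.seed,
        },
    )


def replace_seed(cfg: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


def reading_time_baseline(
    cohort: list[Recording],
    fold_plan: FoldPlan,
    resubstitution: bool = False,
) -> EvalReport:
    """Threshold-on-reading-time baseline over a fold plan.

    Per fold the threshold is fitted on the non-test subjects' reading
    times and applied to the test subjects.  With
    ``resubstitution=True`` a single threshold is instead fitted on the
    whole cohort and every fold is scored with it (the in-sample variant
    of the single-threshold claim).
    """
    times = {r.subject_id: r.reading_time_s for r in cohort}
    labels = {r.subject_id: r.label for r in cohort}
    global_model: ThresholdModel | None = None
    if resubstitution:
        ids = sorted(times)
        global_model = fit_reading_time_threshold(
            [times[s] for s in ids], [labels[s] for s in ids]
        )
    per_fold = []
    for fold in fold_plan.folds:
        if global_model is None:
            fit_ids = fold.train + fold.val
            model = fit_reading_time_threshold(
                [times[s] for s in fit_ids], [labels[s] for s in fit_ids]
            )
        else:
            model = global_model
        y_pred = model.predict([times[s] for s in fold.test])
        y_true = [labels[s] for s in fold.test]
        per_fold.append(compute_metrics(y_true, y_pred))
    return EvalReport(
        per_fold=per_fold,
        metadata={
            "method": "reading-time threshold"
            + (" (resubstitution)" if resubstitution else ""),
            "n_folds": len(fold_plan.folds),
        },
    )


def reading_time_threshold_resubstitution(cohort: list[Recording]) -> float:
    """Accuracy (%) of a single threshold fitted on the whole cohort."""
    times = [r.reading_time_s for r in cohort]
    labels = [r.label for r in cohort]
    model = fit_reading_time_threshold(times, labels)
    return 100.0 * model.train_accuracy
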