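"""1-D CNN organ classification of 100-band median spectra.

Architecture: three convolution blocks (64/32/16 filters, kernel 5, valid
padding, each conv -> batch norm -> ELU -> average pooling of kernel 2),
two fully connected blocks (100 and 50 neurons, each linear -> batch norm
-> ELU -> dropout) and a final linear layer to the class logits; softmax is
applied only when probabilities are requested.  With 100 input bands and
20 classes this network has 34,326 trainable weights.

Evaluation follows a leave-one-pig-out (LOPO) protocol: one network per
training fold, each validated on its held-out pig; test-set predictions
ensemble the fold networks by averaging their logits before the argmax
(ties go to the lowest class index).  The evaluation unit is the
annotation; metrics are computed per pig and per class, then aggregated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .hsi_core import ORGAN_CLASSES, SpectraTable

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "Split",
    "FoldResult",
    "EvaluationReport",
    "DEFAULT_GRIDS",
    "build_model",
    "class_weights",
    "split_train_test",
    "table_classes",
    "train_fold",
    "run_lopo",
    "lopo_validation_accuracy",
    "grid_search",
    "ensemble_predict",
    "evaluate",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    conv_filters: tuple[int, int, int] = (64, 32, 16)
    conv_kernel: int = 5
    pool_kernel: int = 2
    fc_sizes: tuple[int, int] = (100, 50)
    n_classes: int = 20
    dropout_p: float = 0.2
    input_bands: int = 100

    def __post_init__(self) -> None:
        sizes = (*self.conv_filters, *self.fc_sizes, self.n_classes,
                 self.conv_kernel, self.pool_kernel, self.input_bands)
        if any(s < 1 for s in sizes):
            raise ValueError("all architecture sizes must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    def conv_output_length(self) -> int:
        """Spectral length after the three conv/pool stages; raises with the
        minimal admissible input length if the input is too short."""
        L = self.input_bands
        for _ in self.conv_filters:
            L = (L - self.conv_kernel + 1)
            if L < 1:
                break
            L = L // self.pool_kernel
            if L < 1:
                break
        if L < 1:
            raise ValueError(
                f"input of {self.input_bands} bands is too short for three "
                f"conv/pool stages; minimum is {self._min_input_length()} bands"
            )
        return L

    def _min_input_length(self) -> int:
        L = 1
        for _ in self.conv_filters:
            L = L * self.pool_kernel + self.conv_kernel - 1
        return L

    def parameter_count(self) -> int:
        """Closed-form trainable-parameter count (conv: out*(in*k+1),
        batch norm: 2*channels, fully connected: out*(in+1))."""
        total = 0
        c_in = 1
        for c_out in self.conv_filters:
            total += c_out * (c_in * self.conv_kernel + 1) + 2 * c_out
            c_in = c_out
        f_in = self.conv_filters[-1] * self.conv_output_length()
        for f_out in self.fc_sizes:
            total += f_out * (f_in + 1) + 2 * f_out
            f_in = f_out
        total += self.n_classes * (f_in + 1)
        return total


@dataclass(frozen=True)
class TrainingConfig:
    """Desk-scale defaults; :meth:`full_scale` gives the production-size
    schedule (1e7 samples/epoch for 10 epochs, batch 20,000)."""

    lr: float = 1e-4
    lr_decay: float = 0.9
    batch_size: int = 512
    samples_per_epoch: int = 100_000
    epochs: int = 5
    class_weighting: bool = True
    oversampling: bool = False
    seed: int = 0
    betas: tuple[float, float] = (0.9, 0.999)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.batch_size < 1 or self.samples_per_epoch < 1 or self.epochs < 1:
            raise ValueError("batch/epoch sizes must be positive")

    @classmethod
    def full_scale(cls, **overrides) -> "TrainingConfig":
        base = dict(lr=1e-4, lr_decay=0.9, batch_size=20_000,
                    samples_per_epoch=10_000_000, epochs=10,
                    class_weighting=True, oversampling=False)
        base.update(overrides)
        return cls(**base)


#: Hyperparameter grids of the exhaustive search (96 combinations).
DEFAULT_GRIDS: dict[str, list] = {
    "dropout_p": [0.1, 0.2],
    "lr": [1e-3, 1e-4],
    "lr_decay": [0.75, 0.9, 1.0],
    "batch_size": [20_000, 40_000],
    "class_weighting": [True, False],
    "oversampling": [True, False],
}


def build_model(arch: ArchitectureSpec, seed: int) -> nn.Sequential:
    """Assemble the CNN with seeded initialization.

    Block order: conv -> batch norm -> ELU -> average pool (three times);
    flatten; linear -> batch norm -> ELU -> dropout (twice); final linear
    to the class logits.
    """
    arch.conv_output_length()  # raises for too-short inputs
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for c_out in arch.conv_filters:
        layers += [
            nn.Conv1d(c_in, c_out, arch.conv_kernel, rng),
            nn.BatchNorm(c_out),
            nn.ELU(),
            nn.AvgPool1d(arch.pool_kernel),
        ]
        c_in = c_out
    layers.append(nn.Flatten())
    f_in = arch.conv_filters[-1] * arch.conv_output_length()
    for f_out in arch.fc_sizes:
        layers += [
            nn.Linear(f_in, f_out, rng),
            nn.BatchNorm(f_out),
            nn.ELU(),
            nn.Dropout(arch.dropout_p, rng),
        ]
        f_in = f_out
    layers.append(nn.Linear(f_in, arch.n_classes, rng))
    return nn.Sequential(layers)


def class_weights(counts: np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights normalized to mean 1."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    inv = 1.0 / counts
    return inv * len(counts) / inv.sum()


@dataclass
class Split:
    train_pigs: tuple[str, ...]
    test_pigs: tuple[str, ...]
    constraint_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.train_pigs) & set(self.test_pigs):
            raise ValueError("train and test pigs must be disjoint")


def _covers_all_organs(pigs, organs_per_pig, organs) -> bool:
    covered = set()
    for p in pigs:
        covered |= set(organs_per_pig.get(p, ()))
    return organs <= covered


def split_train_test(
    pig_ids,
    standardized_ids,
    organs_per_pig: dict,
    n_test: int = 8,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> Split:
    """Randomly select ``n_test`` test pigs from the standardized subset.

    Rejection sampling until every organ class in the cohort is represented
    on both sides of the split (the test side consists of standardized pigs
    only; the training side is every remaining pig).  Rejected draws are
    recorded in the constraint log.  An organ held by a single standardized
    pig therefore forces that pig to the side that cannot otherwise cover
    the organ, or makes the split unsatisfiable.
    """
    pig_ids = list(pig_ids)
    standardized = list(standardized_ids)
    if len(standardized) < n_test:
        raise ValueError(f"cannot pick {n_test} test pigs from {len(standardized)}")
    organs = set()
    for p in pig_ids:
        organs |= set(organs_per_pig.get(p, ()))
    rng = np.random.default_rng(seed)
    log = []
    for attempt in range(max_attempts):
        test = tuple(sorted(rng.choice(standardized, size=n_test, replace=False)))
        train_all = [p for p in pig_ids if p not in test]
        if _covers_all_organs(test, organs_per_pig, organs) and _covers_all_organs(
            train_all, organs_per_pig, organs
        ):
            train = tuple(sorted(p for p in pig_ids if p not in test))
            return Split(train, test, constraint_log=log)
        log.append({"attempt": attempt, "rejected": list(test)})
    raise RuntimeError(
        f"organ-coverage constraint unsatisfiable in {max_attempts} attempts "
        f"({len(log)} rejections)"
    )


def _encode(table: SpectraTable, classes: tuple[str, ...]):
    X = table.band_matrix[:, None, :]  # (n, 1, bands)
    class_of = {c: i for i, c in enumerate(classes)}
    unknown = set(table.df["organ"]) - set(classes)
    if unknown:
        raise ValueError(f"organs not in class list: {sorted(unknown)}")
    y = table.df["organ"].map(class_of).to_numpy(dtype=int)
    return X, y


def table_classes(table: SpectraTable) -> tuple[str, ...]:
    """Observed organ classes in canonical atlas order."""
    present = set(table.df["organ"])
    ordered = [o for o in ORGAN_CLASSES if o in present]
    ordered += sorted(present - set(ordered))
    return tuple(ordered)


@dataclass
class FoldResult:
    held_out_pig: str
    model: nn.Sequential
    logits: np.ndarray  # held-out predictions
    labels: np.ndarray
    loss_history: list[float]

    @property
    def accuracy(self) -> float:
        return float((self.logits.argmax(axis=1) == self.labels).mean())


def train_fold(
    train_table: SpectraTable,
    held_out_pig: str,
    arch: ArchitectureSpec,
    config: TrainingConfig,
    classes: tuple[str, ...] | None = None,
) -> FoldResult:
    """Train one LOPO fold and predict the held-out pig.

    Each epoch draws ``samples_per_epoch`` annotations with replacement
    (uniformly, or with equal class probabilities when oversampling is on);
    the loss is multiclass cross-entropy, optionally weighted inversely to
    the per-class training counts; the learning rate is multiplied by the
    decay factor after each epoch.
    """
    pigs = set(train_table.df["pig_id"])
    if held_out_pig not in pigs:
        raise ValueError(f"held-out pig {held_out_pig!r} not in training table")
    classes = classes or table_classes(train_table)
    fit_tab = train_table.subset(train_table.df["pig_id"] != held_out_pig)
    val_tab = train_table.subset(train_table.df["pig_id"] == held_out_pig)
    X, y = _encode(fit_tab, classes)
    Xval, yval = _encode(val_tab, classes)

    counts = np.bincount(y, minlength=len(classes))
    weights = None
    if config.class_weighting:
        present = counts > 0
        if not present.all():
            warnings.warn(
                f"{(~present).sum()} classes absent from the training fold; "
                "their weight terms are dropped"
            )
        weights = np.zeros(len(classes))
        weights[present] = class_weights(counts[present])

    model = build_model(arch, seed=config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr, betas=config.betas)
    rng = np.random.default_rng(config.seed + 1)
    sample_p = None
    if config.oversampling:
        inv = np.where(counts[y] > 0, 1.0 / counts[y], 0.0)
        sample_p = inv / inv.sum()

    n_batches = int(np.ceil(config.samples_per_epoch / config.batch_size))
    losses: list[float] = []
    for _epoch in range(config.epochs):
        for _ in range(n_batches):
            idx = rng.choice(len(y), size=config.batch_size, replace=True, p=sample_p)
            logits = model.forward(X[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx], weights)
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
        opt.lr *= config.lr_decay

    nn.calibrate_batchnorm(model, X)
    val_logits = model.forward(Xval, train=False)
    return FoldResult(held_out_pig, model, val_logits, yval, losses)


def run_lopo(
    train_table: SpectraTable,
    arch: ArchitectureSpec,
    config: TrainingConfig,
    classes: tuple[str, ...] | None = None,
) -> list[FoldResult]:
    """Leave-one-pig-out cross-validation over all pigs in the table."""
    classes = classes or table_classes(train_table)
    folds = []
    for k, pig in enumerate(sorted(set(train_table.df["pig_id"]))):
        fold_config = replace(config, seed=config.seed + 101 * k)
        folds.append(train_fold(train_table, pig, arch, fold_config, classes))
    return folds


def lopo_validation_accuracy(folds: list[FoldResult]) -> float:
    """Micro accuracy of the aggregated held-out predictions."""
    correct = sum((f.logits.argmax(axis=1) == f.labels).sum() for f in folds)
    total = sum(len(f.labels) for f in folds)
    return float(correct) / total


def grid_search(
    train_table: SpectraTable,
    grids: dict | None = None,
    base_arch: ArchitectureSpec | None = None,
    base_config: TrainingConfig | None = None,
) -> tuple[ArchitectureSpec, TrainingConfig, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by aggregated LOPO accuracy.

    Returns the winning architecture/config and the full result table
    (one row per combination).  Ties keep the first-evaluated combination.
    """
    grids = grids or DEFAULT_GRIDS
    base_arch = base_arch or ArchitectureSpec()
    base_config = base_config or TrainingConfig()
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be non-empty")
    arch_keys = {"dropout_p"}
    names = list(grids)
    rows = []
    best = None
    for combo in itertools.product(*(grids[k] for k in names)):
        params = dict(zip(names, combo))
        arch = replace(base_arch, **{k: v for k, v in params.items() if k in arch_keys})
        cfg = replace(base_config, **{k: v for k, v in params.items() if k not in arch_keys})
        folds = run_lopo(train_table, arch, cfg)
        acc = lopo_validation_accuracy(folds)
        rows.append({**params, "validation_accuracy": acc})
        if best is None or acc > best[0]:
            best = (acc, arch, cfg)
    return best[1], best[2], pd.DataFrame(rows)


def ensemble_predict(models: list[nn.Sequential], X: np.ndarray):
    """Mean-logit ensembling: average per-model logits, then argmax.

    Ties are broken by the lowest class index (numpy argmax convention).
    Returns (labels, mean_logits, probabilities).
    """
    if not models:
        raise ValueError("need at least one model")
    if X.ndim == 2:
        X = X[:, None, :]
    logits = np.mean([m.forward(X, train=False) for m in models], axis=0)
    return logits.argmax(axis=1), logits, nn.softmax(logits)


@dataclass
class EvaluationReport:
    micro_accuracy: float
    n_misclassified: int
    n_annotations: int
    per_class: pd.DataFrame  # sensitivity/specificity/f1 averaged across pigs
    macro: dict[str, float]  # macro means and across-pig SDs
    confusion_mean: pd.DataFrame  # column-normalized, averaged across pigs
    confusion_per_pig: dict[str, pd.DataFrame]
    classes: tuple[str, ...]


def _per_pig_metrics(pred: np.ndarray, truth: np.ndarray, n_classes: int):
    """One-vs-rest sensitivity/specificity/F1 per class; NaN where undefined
    (no true positives+negatives of that kind in the pig)."""
    sens = np.full(n_classes, np.nan)
    spec = np.full(n_classes, np.nan)
    f1 = np.full(n_classes, np.nan)
    for c in range(n_classes):
        tp = int(((pred == c) & (truth == c)).sum())
        fn = int(((pred != c) & (truth == c)).sum())
        fp = int(((pred == c) & (truth != c)).sum())
        tn = int(((pred != c) & (truth != c)).sum())
        if tp + fn > 0:
            sens[c] = tp / (tp + fn)
            denom = 2 * tp + fp + fn
            f1[c] = 2 * tp / denom if denom > 0 else np.nan
        if tn + fp > 0:
            spec[c] = tn / (tn + fp)
    return sens, spec, f1


def evaluate(
    predictions: np.ndarray,
    truth: np.ndarray,
    pig_ids: np.ndarray,
    classes: tuple[str, ...],
) -> EvaluationReport:
    """Per-pig, per-class evaluation of annotation-level predictions.

    Confusion matrices (rows: predicted, columns: true) are column-
    normalized per pig; a column is missing for pigs without that true
    class and the across-pig average ignores missing entries.  Macro
    metrics average per-class values within each pig, then report the mean
    and SD across pigs.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    pig_ids = np.asarray(pig_ids)
    if not (len(predictions) == len(truth) == len(pig_ids)):
        raise ValueError("predictions, truth and pig_ids must be aligned")
    K = len(classes)
    micro = float((predictions == truth).mean())

    per_pig_sens, per_pig_spec, per_pig_f1 = [], [], []
    confusion_per_pig = {}
    pigs = sorted(set(pig_ids.tolist()))
    for pig in pigs:
        sel = pig_ids == pig
        p, t = predictions[sel], truth[sel]
        sens, spec, f1 = _per_pig_metrics(p, t, K)
        per_pig_sens.append(sens)
        per_pig_spec.append(spec)
        per_pig_f1.append(f1)
        counts = np.zeros((K, K))
        np.add.at(counts, (p, t), 1)
        col = counts.sum(axis=0)
        norm = np.where(col > 0, counts / np.where(col > 0, col, 1), np.nan)
        confusion_per_pig[pig] = pd.DataFrame(norm, index=classes, columns=classes)

    sens_m = np.vstack(per_pig_sens)
    spec_m = np.vstack(per_pig_spec)
    f1_m = np.vstack(per_pig_f1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        per_class = pd.DataFrame(
            {
                "sensitivity": np.nanmean(sens_m, axis=0),
                "specificity": np.nanmean(spec_m, axis=0),
                "f1": np.nanmean(f1_m, axis=0),
            },
            index=pd.Index(classes, name="organ"),
        )
        pig_macro = {
            "sensitivity": np.nanmean(sens_m, axis=1),
            "specificity": np.nanmean(spec_m, axis=1),
            "f1": np.nanmean(f1_m, axis=1),
        }
    macro = {}
    for name, vals in pig_macro.items():
        vals = vals[~np.isnan(vals)]
        macro[f"{name}_mean"] = float(np.mean(vals))
        macro[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    stacked = np.stack([confusion_per_pig[p].to_numpy() for p in pigs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_conf = np.nanmean(stacked, axis=0)
    confusion_mean = pd.DataFrame(mean_conf, index=classes, columns=classes)

    return EvaluationReport(
        micro_accuracy=micro,
        n_misclassified=int((predictions != truth).sum()),
        n_annotations=len(truth),
        per_class=per_class,
        macro=macro,
        confusion_mean=confusion_mean,
        confusion_per_pig=confusion_per_pig,
        classes=tuple(classes),
    )
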