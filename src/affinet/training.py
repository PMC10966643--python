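"""Training workflows: direct learning, k-fold ensembling, transfer learning.

The loss is mean-squared error on pK. A single integer seed fans out into
independent streams (parameter init, shuffling, augmentation, dropout) via
numpy SeedSequence spawning, so every run is exactly reproducible.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .egnn import EncoderParams, ModelConfig
from .graphs import GraphPair, RadialBasisConfig, build_graphs
from .io_structures import AtomicComplex, InputError
from .nnkit import Adam, Tensor, flatten_params
from .readout import ReadoutParams, collate, forward_collated

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    lr: float = 5e-3
    warmup_steps: int = 50
    epochs: int = 200
    batch_size: int = 16
    max_steps: int | None = None  # hard cap across epochs; None = unlimited
    dropout: float = 0.0
    weight_decay: float = 0.0  # decoupled; shift parameter is never decayed
    augment_radius: float = 0.1  # Angstrom; 0 disables
    seed: int = 0
    mode: str = "full"  # or "ligand_only"
    optimizer: str = "adam"
    lr_schedule: str = "constant"  # or "cosine" (decay after warm-up)
    retain_shift: bool = False  # transfer: keep the global shift parameter

    def __post_init__(self):
        if self.augment_radius < 0:
            raise ValueError("augment_radius must be >= 0")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be >= 0")
        if self.mode not in ("full", "ligand_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


@dataclass
class Metrics:
    rmse: float
    mue: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mue": self.mue, "r2": self.r2, "n": self.n}


@dataclass
class Checkpoint:
    """A trained model: encoder + readout + the config that shaped them."""

    encoder: EncoderParams
    readout: ReadoutParams
    model_cfg: ModelConfig
    label_mean: float
    mode: str = "full"
    seed: int = 0
    fold_id: int | None = None
    loss_history: list[float] = field(default_factory=list)

    def config_hash(self) -> str:
        return self.model_cfg.hash()

    def all_params(self) -> dict[str, Tensor]:
        out = {f"enc.{k}": v for k, v in flatten_params(self.encoder.params()).items()}
        out.update(
            {f"ro.{k}": v for k, v in flatten_params(self.readout.params()).items()}
        )
        return out

    def save(self, path) -> None:
        meta = {
            "model_cfg": self.model_cfg.to_dict(),
            "label_mean": self.label_mean,
            "mode": self.mode,
            "seed": self.seed,
            "fold_id": self.fold_id,
            "config_hash": self.config_hash(),
        }
        arrays = {k: p.data for k, p in self.all_params().items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        cfg_dict = meta["model_cfg"]
        cfg_dict["vocabulary"] = tuple(cfg_dict["vocabulary"])
        cfg = ModelConfig(**cfg_dict)
        rng = np.random.default_rng(0)  # shapes only; data overwritten below
        ckpt = cls(
            encoder=EncoderParams(cfg, rng),
            readout=ReadoutParams(cfg, rng, shift=meta["label_mean"]),
            model_cfg=cfg,
            label_mean=meta["label_mean"],
            mode=meta["mode"],
            seed=meta["seed"],
            fold_id=meta["fold_id"],
        )
        params = ckpt.all_params()
        if set(params) != set(arrays):
            raise ValueError(f"checkpoint {path} does not match its declared config")
        for k, p in params.items():
            if p.data.shape != arrays[k].shape:
                raise ValueError(f"shape mismatch for {k} in {path}")
            p.data = arrays[k].astype(np.float64)
        return ckpt


@dataclass
class Ensemble:
    """Average of independently trained members (default: 5-fold CV)."""

    members: list[Checkpoint]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        h = {m.config_hash() for m in self.members}
        if len(h) > 1:
            raise ValueError("ensemble members have mismatched architectures")

    @property
    def model_cfg(self) -> ModelConfig:
        return self.members[0].model_cfg

    @property
    def mode(self) -> str:
        return self.members[0].mode


# ---------------------------------------------------------------------------
# dataset utilities


def stratified_split(
    labels,
    train_frac: float = 0.8,
    seed: int = 0,
    n_bins: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Activity-stratified train/test split.

    Labels are ranked and cut into `n_bins` equal-size activity bins; the
    train quota (round(train_frac * n) overall) is spread across bins by
    largest remainder, and members are drawn per-bin under the seeded
    generator. Falls back to a plain seeded split when there are fewer
    labels than bins.
    """
    labels = np.asarray(labels, dtype=np.float64)
    n = len(labels)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 labels to split")
    rng = np.random.default_rng(seed)
    n_train_total = int(np.floor(train_frac * n + 0.5))
    if n < n_bins:
        warnings.warn(
            f"only {n} labels for {n_bins} bins; falling back to a plain split",
            stacklevel=2,
        )
        perm = rng.permutation(n)
        return np.sort(perm[:n_train_total]), np.sort(perm[n_train_total:])

    order = np.argsort(labels, kind="stable")
    bins = np.array_split(order, n_bins)
    base = [int(np.floor(train_frac * len(b))) for b in bins]
    remainder = [train_frac * len(b) - q for b, q in zip(bins, base)]
    short = n_train_total - sum(base)
    for idx in sorted(range(n_bins), key=lambda i: (-remainder[i], i))[:short]:
        base[idx] += 1
    train, test = [], []
    for b, quota in zip(bins, base):
        perm = rng.permutation(len(b))
        train.extend(b[perm[:quota]])
        test.extend(b[perm[quota:]])
    return np.sort(np.array(train, dtype=np.int64)), np.sort(
        np.array(test, dtype=np.int64)
    )


def augment_coordinates(
    coords: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Displace each atom independently, uniformly within a ball of `radius`."""
    if radius < 0:
        raise ValueError("augmentation radius must be >= 0")
    coords = np.asarray(coords, dtype=np.float64)
    if radius == 0 or len(coords) == 0:
        return coords.copy()
    direction = rng.normal(size=coords.shape)
    norm = np.linalg.norm(direction, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    magnitude = radius * rng.random(len(coords)) ** (1.0 / 3.0)
    return coords + direction / norm * magnitude[:, None]


def prepare_graphs(
    complexes: list[AtomicComplex], cfg: ModelConfig
) -> list[GraphPair]:
    rbf_cfg = RadialBasisConfig(cfg.n_rbf, cfg.r_msg, cfg.envelope_order)
    return [build_graphs(cx, cfg.r_msg, cfg.r_pair, rbf_cfg) for cx in complexes]


# ---------------------------------------------------------------------------
# prediction / evaluation


def predict_totals(
    model: Checkpoint | Ensemble,
    complexes: list[AtomicComplex],
    graphs: list[GraphPair] | None = None,
) -> np.ndarray:
    """Predicted pK per complex (ensembles: arithmetic mean over members)."""
    if isinstance(model, Ensemble):
        stack = predict_totals_members(model, complexes, graphs)
        return stack.mean(axis=0)
    if graphs is None:
        graphs = prepare_graphs(complexes, model.model_cfg)
    batch = collate(complexes, graphs, model.mode)
    totals, _, _ = forward_collated(batch, model.encoder, model.readout, model.mode)
    return totals.data.copy()


def predict_totals_members(
    ensemble: Ensemble,
    complexes: list[AtomicComplex],
    graphs: list[GraphPair] | None = None,
) -> np.ndarray:
    if graphs is None:
        graphs = prepare_graphs(complexes, ensemble.model_cfg)
    return np.stack([predict_totals(m, complexes, graphs) for m in ensemble.members])


def compute_metrics(predictions, labels) -> Metrics:
    """RMSE, MUE, and squared Pearson correlation between pred and label pK."""
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if len(predictions) == 0:
        raise ValueError("cannot compute metrics on an empty set")
    err = predictions - labels
    rmse = float(np.sqrt(np.mean(err**2)))
    mue = float(np.mean(np.abs(err)))
    if np.std(labels) == 0 or np.std(predictions) == 0:
        warnings.warn("zero variance in predictions or labels; r2 reported as 0")
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(predictions, labels)[0, 1] ** 2)
    return Metrics(rmse=rmse, mue=mue, r2=r2, n=len(predictions))


def evaluate(
    model: Checkpoint | Ensemble,
    dataset: list[AtomicComplex],
    graphs: list[GraphPair] | None = None,
) -> Metrics:
    """Evaluate on a labeled dataset (augmentation is never applied here)."""
    if not dataset:
        raise ValueError("cannot evaluate on an empty dataset")
    labels = [cx.label for cx in dataset]
    if any(l is None for l in labels):
        raise ValueError("evaluate requires labels on every complex")
    preds = predict_totals(model, dataset, graphs)
    return compute_metrics(preds, np.asarray(labels))


# ---------------------------------------------------------------------------
# training loops


def _train_loop(
    encoder: EncoderParams,
    readout: ReadoutParams,
    dataset: list[AtomicComplex],
    config: TrainingConfig,
    model_cfg: ModelConfig,
    seed_seq: np.random.SeedSequence,
) -> list[float]:
    shuffle_ss, aug_ss, drop_ss = seed_seq.spawn(3)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    aug_rng = np.random.default_rng(aug_ss)
    drop_rng = np.random.default_rng(drop_ss) if config.dropout > 0 else None
    if config.dropout > 0:
        readout.atom_mlp.dropout = config.dropout
        readout.pair_mlp.dropout = config.dropout

    params = flatten_params({"enc": encoder.params(), "ro": readout.params()})
    opt = Adam(
        params,
        lr=config.lr,
        warmup_steps=config.warmup_steps,
        weight_decay=config.weight_decay,
        decay_exclude=("shift",),
    )
    labels = np.array([cx.label for cx in dataset], dtype=np.float64)
    static_graphs = (
        prepare_graphs(dataset, model_cfg) if config.augment_radius == 0 else None
    )
    rbf_cfg = RadialBasisConfig(model_cfg.n_rbf, model_cfg.r_msg, model_cfg.envelope_order)

    n = len(dataset)
    steps_per_epoch = max(1, -(-n // config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    if config.max_steps is not None:
        total_steps = min(total_steps, config.max_steps)

    history: list[float] = []
    steps = 0
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if config.augment_radius > 0:
                batch_cx = [
                    replace(
                        dataset[i],
                        coords=augment_coordinates(
                            dataset[i].coords, config.augment_radius, aug_rng
                        ),
                    )
                    for i in idx
                ]
                batch_graphs = [
                    build_graphs(cx, model_cfg.r_msg, model_cfg.r_pair, rbf_cfg)
                    for cx in batch_cx
                ]
            else:
                batch_cx = [dataset[i] for i in idx]
                batch_graphs = [static_graphs[i] for i in idx]
            col = collate(batch_cx, batch_graphs, config.mode)
            totals, _, _ = forward_collated(
                col, encoder, readout, config.mode, train_rng=drop_rng
            )
            err = totals - Tensor(labels[idx])
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    "non-finite loss at step "
                    f"{steps}; batch ids: {[dataset[i].id for i in idx]}"
                )
            if config.lr_schedule == "cosine" and total_steps > config.warmup_steps:
                progress = max(0, steps - config.warmup_steps) / max(
                    1, total_steps - config.warmup_steps
                )
                opt.lr = config.lr * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * progress)))
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(float(loss.data))
            steps += 1
            if config.max_steps is not None and steps >= config.max_steps:
                return history
    return history


def _check_labeled(dataset: list[AtomicComplex], minimum: int = 2) -> np.ndarray:
    if len(dataset) < minimum:
        raise InputError(f"need at least {minimum} labeled complexes, got {len(dataset)}")
    labels = [cx.label for cx in dataset]
    if any(l is None for l in labels):
        missing = [cx.id for cx in dataset if cx.label is None]
        raise InputError(f"unlabeled complexes in training set: {missing[:5]}")
    return np.asarray(labels, dtype=np.float64)


def train_direct(
    dataset: list[AtomicComplex],
    config: TrainingConfig,
    model_cfg: ModelConfig | None = None,
) -> Checkpoint:
    """Train from random initialization; shift starts at the label mean."""
    labels = _check_labeled(dataset)
    if model_cfg is None:
        model_cfg = ModelConfig()
    root = np.random.SeedSequence(config.seed)
    init_ss, loop_ss = root.spawn(2)
    init_rng = np.random.default_rng(init_ss)
    encoder = EncoderParams(model_cfg, init_rng)
    label_mean = float(labels.mean())
    readout = ReadoutParams(model_cfg, init_rng, shift=label_mean)
    history = _train_loop(encoder, readout, dataset, config, model_cfg, loop_ss)
    return Checkpoint(
        encoder=encoder,
        readout=readout,
        model_cfg=model_cfg,
        label_mean=label_mean,
        mode=config.mode,
        seed=config.seed,
        loss_history=history,
    )


def transfer_learn(
    base: Checkpoint,
    dataset: list[AtomicComplex],
    config: TrainingConfig,
) -> Checkpoint:
    """Continue training a pretrained model on a local dataset.

    All weights stay trainable (nothing frozen), optimizer momenta start at
    zero, and the warm-up schedule is re-applied. Unless `config.retain_shift`
    the shift is re-initialized for the local label range: it is set so the
    model's mean prediction on the local training set equals the local label
    mean (the role the shift plays at direct-training initialization, where
    all other readout outputs are zero).
    """
    labels = _check_labeled(dataset, minimum=1)
    if config.mode != base.mode:
        raise ValueError(
            f"transfer mode {config.mode!r} does not match base mode {base.mode!r}"
        )
    encoder = copy.deepcopy(base.encoder)
    readout = copy.deepcopy(base.readout)
    label_mean = float(labels.mean())
    if config.retain_shift:
        label_mean = base.label_mean
    else:
        base_preds = predict_totals(base, dataset)
        readout.shift.data = readout.shift.data + (label_mean - float(base_preds.mean()))
    history = _train_loop(
        encoder,
        readout,
        dataset,
        config,
        base.model_cfg,
        np.random.SeedSequence(config.seed).spawn(2)[1],
    )
    return Checkpoint(
        encoder=encoder,
        readout=readout,
        model_cfg=base.model_cfg,
        label_mean=label_mean,
        mode=base.mode,
        seed=config.seed,
        loss_history=history,
    )


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded disjoint fold index sets whose union is range(n)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise InputError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def train_kfold_ensemble(
    dataset: list[AtomicComplex],
    k: int = 5,
    config: TrainingConfig | None = None,
    model_cfg: ModelConfig | None = None,
    base: Checkpoint | None = None,
) -> Ensemble:
    """k-fold cross-validation ensemble; prediction = mean of the members.

    When `base` is given each member is transfer-learned from it instead of
    trained from scratch.
    """
    if config is None:
        config = TrainingConfig()
    _check_labeled(dataset, minimum=k)
    folds = kfold_indices(len(dataset), k, config.seed)
    fold_seeds = np.random.SeedSequence(config.seed).spawn(k)
    members = []
    for fold_id, (holdout, fold_ss) in enumerate(zip(folds, fold_seeds)):
        train_idx = np.setdiff1d(np.arange(len(dataset)), holdout)
        subset = [dataset[i] for i in train_idx]
        fold_cfg = replace(config, seed=int(fold_ss.generate_state(1)[0] % 2**31))
        if base is not None:
            ckpt = transfer_learn(base, subset, fold_cfg)
        else:
            ckpt = train_direct(subset, fold_cfg, model_cfg)
        ckpt.fold_id = fold_id
        members.append(ckpt)
    return Ensemble(members=members)


def ensemble_spread(
    ensemble: Ensemble, dataset: list[AtomicComplex]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-complex (mean, std) of member predictions."""
    stack = predict_totals_members(ensemble, dataset)
    return stack.mean(axis=0), stack.std(axis=0)
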