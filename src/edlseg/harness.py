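"""Training and experiment orchestration for the evidential segmenter.

The recipe: Adam (lr 3e-4, batch size 1), an epoch-annealed KL coefficient,
and a ReLU evidence head — no softmax/sigmoid on the output path.  Training
maximizes evidence for correct classes through the region-based Dirichlet
objective; inference is a single deterministic forward pass (no sampling),
from which both the probability map and the normalized-predictive-entropy
uncertainty map fall out.

``run_experiment`` mirrors the clean-train / corrupted-test robustness
design: one model is trained on clean phantoms and evaluated on the clean
test split plus blurred / noisy / gamma-corrected variants of it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from autograd import value_and_grad

from .evidential import alpha_from_evidence, normalized_predictive_entropy
from .losses import (
    LossConfig,
    annealing_lambda,
    class_weights_from_labels,
    edl_total,
    loss_ce,
    loss_dice,
    loss_edl,
    loss_ml,
    loss_mse,
    loss_wdice,
)
from .metrics import dice_score, evaluate_case, sueo
from .model import Adam, EvidenceNet
from .synthetic import (
    CorruptionSpec,
    apply_corruption,
    load_manifest,
    make_dataset,
    phantoms_from_manifest,
)

__all__ = ["RunConfig", "TrainLog", "build_model", "train", "predict", "run_experiment"]

DEFAULT_CORRUPTIONS = (
    {"kind": "blur", "parameter": 1.5},
    {"kind": "noise", "parameter": 1.5},
    {"kind": "gamma", "parameter": 5.0},
)


@dataclass
class RunConfig:
    """Fully serializable description of one training/evaluation run."""

    objective: str = "edl"  # edl | dice | wdice | ce | mse | ml
    region_term: str = "dice"  # region term inside the edl objective
    parameterization: str = "squared"
    epochs: int = 50
    learning_rate: float = 3e-4
    batch_size: int = 1
    seed: int = 0
    width: int = 8
    kl_max: float = 0.1
    kl_ramp_epochs: int = 25
    kl_exponent: int = 2
    smoothing: float = 1e-5
    weight_clamp: float = 1e-3
    # data
    n_cases: int = 40
    shape: tuple = (96, 96)
    n_channels: int = 4
    n_classes: int = 2
    contrast: float = 1.0
    noise_sd: float = 0.08
    split: tuple = (0.6, 0.2, 0.2)
    manifest_path: str | None = None
    # evaluation
    corruptions: tuple = DEFAULT_CORRUPTIONS
    ece_bins: int = 10
    tau_steps: int = 101
    val_interval: int = 5
    out_dir: str | None = None

    def loss_config(self) -> LossConfig:
        return LossConfig(
            region_term=self.region_term,
            smoothing=self.smoothing,
            weight_clamp=self.weight_clamp,
            kl_max=self.kl_max,
            kl_ramp_epochs=self.kl_ramp_epochs,
            kl_exponent=self.kl_exponent,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["split"] = list(self.split)
        d["corruptions"] = [dict(c) for c in self.corruptions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "split" in d:
            d["split"] = tuple(d["split"])
        if "corruptions" in d:
            d["corruptions"] = tuple(dict(c) for c in d["corruptions"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class TrainLog:
    """Per-epoch objective breakdown and validation metrics."""

    epochs: list = field(default_factory=list)  # dicts: total/dice/kl/lambda
    validation: list = field(default_factory=list)  # dicts: epoch/dice
    best_epoch: int | None = None
    best_val_dice: float | None = None


def build_model(config: RunConfig) -> EvidenceNet:
    """Deterministically initialized network matching the run config."""
    return EvidenceNet(
        in_channels=config.n_channels,
        n_classes=config.n_classes,
        width=config.width,
        seed=config.seed,
    )


def _objective_scalar(alpha, y, epoch, config: RunConfig):
    obj = config.objective
    if obj == "edl":
        return edl_total(alpha, y, epoch, config.loss_config())
    if obj == "dice":
        return loss_dice(alpha, y, config.smoothing)
    if obj == "wdice":
        w = class_weights_from_labels(y, config.weight_clamp)
        return loss_wdice(alpha, y, w, config.smoothing)
    if obj == "ce":
        import autograd.numpy as anp

        return anp.mean(loss_ce(alpha, y))
    if obj == "mse":
        import autograd.numpy as anp

        return anp.mean(loss_mse(alpha, y))
    if obj == "ml":
        import autograd.numpy as anp

        return anp.mean(loss_ml(alpha, y))
    raise ValueError(f"unknown objective {obj!r}")


def _loss_value_and_grad(y: np.ndarray, epoch: int, config: RunConfig):
    def f(e):
        alpha = alpha_from_evidence(e, config.parameterization)
        return _objective_scalar(alpha, y, epoch, config)

    return value_and_grad(f)


def _dataset(config: RunConfig):
    """(manifest, {split: [Phantom, ...]}) for the run, clean everywhere."""
    if config.manifest_path:
        manifest = load_manifest(config.manifest_path)
    else:
        seeds = [config.seed * 100_000 + i for i in range(config.n_cases)]
        manifest = make_dataset(
            seeds,
            split=config.split,
            shape=config.shape,
            n_channels=config.n_channels,
            n_classes=config.n_classes,
            contrast=config.contrast,
            noise_sd=config.noise_sd,
        )
    splits = {}
    for part in ("train", "val", "test"):
        splits[part] = [ph for _, ph in phantoms_from_manifest(manifest, split=part)]
    return manifest, splits


def train(config: RunConfig, dataset: dict | None = None):
    """Optimize the configured objective; returns (model, TrainLog).

    ``dataset`` maps split names to Phantom lists; when omitted it is
    generated from the config.  The best-validation parameters (mean Dice
    on the val split, argmax masks) are restored before returning.
    """
    if dataset is None:
        _, dataset = _dataset(config)
    train_set, val_set = dataset["train"], dataset.get("val", [])
    if not train_set:
        raise ValueError("empty training split")
    model = build_model(config)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    log = TrainLog()
    best_state = model.state_dict()
    best_dice = -1.0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        totals = []
        breakdown = None
        for idx in order:
            ph = train_set[idx]
            cache = {}
            evidence = model.forward(ph.image, cache)
            vag = _loss_value_and_grad(ph.labels.onehot, epoch, config)
            value, g_e = vag(evidence.astype(np.float64))
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, case seed "
                    f"{ph.recipe['seed']}"
                )
            grads = model.backward(cache, g_e)
            opt.step(model.params, grads)
            totals.append(float(value))
        lam = annealing_lambda(epoch, config.loss_config().schedule)
        # breakdown on the last case for logging
        alpha = alpha_from_evidence(
            model.forward(train_set[order[-1]].image), config.parameterization
        )
        breakdown = loss_edl(
            alpha, train_set[order[-1]].labels.onehot, epoch, config.loss_config()
        )
        log.epochs.append(
            {
                "epoch": epoch,
                "mean_total": float(np.mean(totals)),
                "dice_term": breakdown.dice_term,
                "kl_term": breakdown.kl_term,
                "lambda": lam,
            }
        )
        last = epoch == config.epochs - 1
        if val_set and (epoch % config.val_interval == 0 or last):
            dices = []
            for ph in val_set:
                p, _ = predict(model, ph.image, config.parameterization)
                pred = p.argmax(axis=0)
                dices.append(
                    np.mean(
                        [
                            dice_score(pred == j, ph.labels.onehot[j] > 0)
                            for j in range(1, config.n_classes)
                        ]
                    )
                )
            vdice = float(np.mean(dices))
            log.validation.append({"epoch": epoch, "dice": vdice})
            if vdice > best_dice:
                best_dice = vdice
                best_state = model.state_dict()
                log.best_epoch = epoch
                log.best_val_dice = vdice
    if val_set:
        model.load_state_dict(best_state)
    return model, log


def predict(model: EvidenceNet, image: np.ndarray, parameterization: str = "squared"):
    """Single forward pass -> (probability tensor, UncertaintyMap).

    Evidence maps to Dirichlet parameters, whose mean gives the class
    probabilities and whose normalized predictive entropy gives the
    uncertainty.  Deterministic: repeated calls return identical output.
    """
    evidence = model.forward(np.asarray(image, dtype=np.float32))
    alpha = alpha_from_evidence(evidence.astype(np.float64), parameterization)
    p = alpha / alpha.sum(axis=0, keepdims=True)
    return p, normalized_predictive_entropy(p)


def _evaluate_split(model, phantoms, config: RunConfig, corruption=None):
    """Mean metrics over a phantom list, optionally corrupting images first."""
    rows = []
    for i, ph in enumerate(phantoms):
        image = ph.image
        if corruption is not None:
            spec = CorruptionSpec(
                corruption["kind"],
                corruption["parameter"],
                int(corruption.get("seed", ph.recipe["seed"] + 7)),
            )
            image = apply_corruption(image, spec)
        p, u = predict(model, image, config.parameterization)
        rep = evaluate_case(
            p, ph.labels, ph.brain, n_bins=config.ece_bins, tau_steps=config.tau_steps
        )
        pred = p.argmax(axis=0)
        err_any = (pred != ph.labels.onehot.argmax(axis=0)).astype(np.uint8)
        uniform = np.full(u.values.shape, 0.5)
        row = dict(rep["mean"])
        row["sueo_uniform"] = sueo(uniform, err_any)
        rows.append(row)
    return {
        "mean": {
            k: float(np.mean([r[k] for r in rows])) for k in rows[0]
        },
        "per_case": rows,
    }


def run_experiment(config: RunConfig) -> dict:
    """Clean-train / corrupted-test experiment; one row per test variant.

    Trains once on the clean training split, then evaluates the same model
    on the clean test split and on each corrupted variant of it.  The
    report is a pure function of the config (seed included).
    """
    manifest, splits = _dataset(config)
    model, log = train(config, splits)
    variants = {"clean": None}
    for c in config.corruptions:
        variants[f"{c['kind']}_{c['parameter']:g}"] = dict(c)
    report = {
        "config": config.to_dict(),
        "train_log": {
            "final_loss": log.epochs[-1]["mean_total"] if log.epochs else None,
            "best_epoch": log.best_epoch,
            "best_val_dice": log.best_val_dice,
        },
        "variants": {},
    }
    for name, corruption in variants.items():
        report["variants"][name] = _evaluate_split(
            model, splits["test"], config, corruption
        )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
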