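"""Kohonen self-organizing map classifier of text type.

A 6 x 6 hexagonal-grid SOM is trained competitively on stimulus-level
spectral feature vectors: at each of 10,000 iterations a random training
row ``x`` is drawn, its best-matching unit (BMU) ``c = argmin_j ||x - w_j||``
found, and every unit within the current neighborhood radius of ``c`` on
the grid moves toward ``x`` by the current learning rate (bubble
neighborhood — all-or-nothing).  Learning rate and radius decay linearly;
the starting radius is the 2/3 quantile of pairwise unit distances.
After training each unit takes the majority text-type label of the
training rows it captures; prediction assigns a row the label of its BMU
(falling back to the nearest labeled unit).  The train/test split is done
at the *participant* level so no reader's stimuli straddle the split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TEXT_TYPES, ContractError

__all__ = [
    "SOMConfig",
    "SOMModel",
    "ClassificationReport",
    "split_participant_holdout",
    "train_som",
    "predict",
    "evaluate",
    "hex_positions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SOMConfig:
    grid_rows: int = 6
    grid_cols: int = 6
    topology: str = "hexagonal"
    n_iterations: int = 10_000
    lr_start: float = 0.05
    lr_end: float = 0.01
    radius_start: float | None = None  # default: 2/3 quantile of unit distances
    radius_end: float = 0.0
    neighborhood: str = "bubble"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology != "hexagonal":
            raise ContractError("only the hexagonal topology is supported")
        if self.neighborhood not in ("bubble", "gaussian"):
            raise ContractError("neighborhood must be 'bubble' or 'gaussian'")
        if not self.lr_start > self.lr_end >= 0:
            raise ContractError("need lr_start > lr_end >= 0")
        if self.radius_start is not None and self.radius_start <= 0:
            raise ContractError("radius_start must be positive")


def hex_positions(rows: int, cols: int) -> np.ndarray:
    """Planar coordinates of a hexagonal grid (odd rows offset by 1/2,
    row spacing sqrt(3)/2), unit distance between neighbors."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = c + 0.5 * (r % 2)
    y = r * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


@dataclass
class SOMModel:
    config: SOMConfig
    codebook: np.ndarray  # units x features, in standardized space
    unit_positions: np.ndarray  # units x 2 grid coordinates
    unit_labels: list[str | None]  # majority text type per unit
    feature_names: list[str]
    feature_center: np.ndarray
    feature_scale: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.feature_center) / self.feature_scale

    def bmu(self, x_std: np.ndarray) -> np.ndarray:
        """Best-matching unit index per standardized row."""
        d2 = ((x_std[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "config": {
                        k: getattr(self.config, k)
                        for k in (
                            "grid_rows", "grid_cols", "topology",
                            "n_iterations", "lr_start", "lr_end",
                            "radius_start", "radius_end", "neighborhood",
                            "seed",
                        )
                    },
                    "codebook": self.codebook.tolist(),
                    "unit_positions": self.unit_positions.tolist(),
                    "unit_labels": self.unit_labels,
                    "feature_names": self.feature_names,
                    "feature_center": self.feature_center.tolist(),
                    "feature_scale": self.feature_scale.tolist(),
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            config=SOMConfig(**d["config"]),
            codebook=np.array(d["codebook"]),
            unit_positions=np.array(d["unit_positions"]),
            unit_labels=d["unit_labels"],
            feature_names=d["feature_names"],
            feature_center=np.array(d["feature_center"]),
            feature_scale=np.array(d["feature_scale"]),
        )


def split_participant_holdout(
    rows: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign whole participants to train/test by a seeded shuffle.

    Participants are shuffled and prefixes accumulated; the prefix whose
    train-row count is closest to ``round(train_fraction * n_rows)`` wins.
    No participant straddles the split; with the balanced per-participant
    stimulus composition of the study design this stratifies the three
    text types proportionally on both sides.
    """
    if not 0 < train_fraction < 1:
        raise ContractError("train_fraction must lie in (0, 1)")
    pids = rows["participant_id"].unique()
    if len(pids) < 2:
        raise ContractError("participant holdout needs >= 2 participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(pids)
    counts = rows["participant_id"].value_counts()
    cum = np.cumsum([counts[p] for p in order])
    target = round(train_fraction * len(rows))
    # prefix of length >= 1, leaving >= 1 test participant
    best = int(np.argmin(np.abs(cum[:-1] - target)))
    achieved = int(cum[best])
    if achieved != target:
        logger.warning(
            "participant split: achieved %d train rows (target %d)",
            achieved, target,
        )
    train_ids = set(order[: best + 1])
    in_train = rows["participant_id"].isin(train_ids)
    return rows[in_train].copy(), rows[~in_train].copy()


def train_som(
    rows: pd.DataFrame,
    feature_names: list[str],
    config: SOMConfig | None = None,
    label_column: str = "text_type",
) -> SOMModel:
    """Train the SOM on standardized features; label units by majority vote.

    The codebook is initialized from a seeded sample of training rows.
    Zero-variance features are dropped with a warning.  Deterministic under
    a fixed ``config.seed``.
    """
    config = config or SOMConfig()
    x = rows[list(feature_names)].to_numpy(dtype=np.float64)
    labels = rows[label_column].to_numpy()
    n_units = config.grid_rows * config.grid_cols
    if len(x) < n_units:
        logger.warning(
            "training rows (%d) fewer than SOM units (%d)", len(x), n_units
        )

    center = x.mean(axis=0)
    scale = x.std(axis=0)
    dead = scale == 0
    if dead.all():
        # a single repeated training vector: skip standardization so the
        # codebook can still converge to it
        logger.warning("all features have zero variance; scaling disabled")
        scale = np.ones_like(scale)
        dead = np.zeros_like(dead)
    if dead.any():
        dropped = [f for f, d in zip(feature_names, dead) if d]
        logger.warning("dropping zero-variance features: %s", dropped)
        feature_names = [f for f, d in zip(feature_names, dead) if not d]
        x = x[:, ~dead]
        center, scale = center[~dead], scale[~dead]
    xs = (x - center) / scale

    positions = hex_positions(config.grid_rows, config.grid_cols)
    unit_dist = np.sqrt(
        ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    )
    if config.radius_start is None:
        radius_start = float(
            np.quantile(unit_dist[np.triu_indices(n_units, k=1)], 2 / 3)
        )
    else:
        radius_start = config.radius_start

    rng = np.random.default_rng(config.seed)
    init_idx = rng.choice(len(xs), size=n_units, replace=len(xs) < n_units)
    codebook = xs[init_idx].copy()

    n_it = config.n_iterations
    t_grid = np.arange(n_it) / max(1, n_it - 1)
    alphas = config.lr_start + (config.lr_end - config.lr_start) * t_grid
    radii = radius_start + (config.radius_end - radius_start) * t_grid
    draw = rng.integers(0, len(xs), size=n_it)
    for t in range(n_it):
        v = xs[draw[t]]
        d2 = ((codebook - v) ** 2).sum(axis=1)
        c = int(d2.argmin())
        if config.neighborhood == "bubble":
            hood = unit_dist[c] <= radii[t]
            codebook[hood] += alphas[t] * (v - codebook[hood])
        else:
            w = np.exp(-(unit_dist[c] ** 2) / (2 * max(radii[t], 1e-3) ** 2))
            codebook += (alphas[t] * w)[:, None] * (v - codebook)

    bmus = ((xs[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2).argmin(axis=1)
    unit_labels: list[str | None] = []
    for j in range(n_units):
        captured = labels[bmus == j]
        if captured.size == 0:
            unit_labels.append(None)
        else:
            uniq, cnt = np.unique(captured, return_counts=True)
            unit_labels.append(str(uniq[cnt.argmax()]))

    return SOMModel(
        config=config,
        codebook=codebook,
        unit_positions=positions,
        unit_labels=unit_labels,
        feature_names=list(feature_names),
        feature_center=center,
        feature_scale=scale,
    )


def predict(model: SOMModel, rows: pd.DataFrame) -> np.ndarray:
    """Text-type prediction: the BMU's label, or — for an unlabeled BMU —
    the label of the nearest labeled unit (grid distance, codebook-distance
    tie-break)."""
    missing = [f for f in model.feature_names if f not in rows.columns]
    if missing:
        raise ContractError(f"rows lack trained features: {missing}")
    labeled = [j for j, lab in enumerate(model.unit_labels) if lab is not None]
    if not labeled:
        raise ContractError("model has no labeled units")
    xs = model.transform(rows[model.feature_names].to_numpy(dtype=np.float64))
    bmus = model.bmu(xs)
    out = []
    for i, j in enumerate(bmus):
        lab = model.unit_labels[j]
        if lab is None:
            grid_d = np.sqrt(
                ((model.unit_positions[labeled] - model.unit_positions[j]) ** 2).sum(axis=1)
            )
            near = grid_d == grid_d.min()
            cand = [labeled[m] for m in np.nonzero(near)[0]]
            if len(cand) > 1:
                code_d = ((model.codebook[cand] - xs[i]) ** 2).sum(axis=1)
                lab = model.unit_labels[cand[int(code_d.argmin())]]
            else:
                lab = model.unit_labels[cand[0]]
        out.append(lab)
    return np.array(out)


@dataclass
class ClassificationReport:
    """3-class confusion matrix (rows true, columns predicted) + metrics."""

    labels: tuple[str, ...]
    confusion: np.ndarray
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    f1: dict[str, float] = field(default_factory=dict)
    accuracy: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion, index=list(self.labels), columns=list(self.labels)
        )


def evaluate(
    true_labels, predicted_labels, labels: tuple[str, ...] | None = None
) -> ClassificationReport:
    """Confusion counts, per-class precision/recall/F1, and accuracy.

    F1 values are rounded to 3 decimals for reporting (``f1`` dict);
    degenerate classes (no predictions or no true rows) score 0.
    """
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    if y.size == 0:
        raise ContractError("evaluate needs at least one label pair")
    if y.shape != yhat.shape:
        raise ContractError("label vectors differ in length")
    labels = tuple(sorted(TEXT_TYPES)) if labels is None else labels
    index = {lab: i for i, lab in enumerate(labels)}
    conf = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y, yhat):
        conf[index[t], index[p]] += 1

    report = ClassificationReport(labels=labels, confusion=conf)
    for i, lab in enumerate(labels):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        report.precision[lab] = float(prec)
        report.recall[lab] = float(rec)
        report.f1[lab] = round(float(f1), 3)
    report.accuracy = float(np.trace(conf) / conf.sum())
    return report
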