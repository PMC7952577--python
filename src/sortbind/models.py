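"""Binding models: WT-specific dense networks and whole-library CNNs.

Two model families predict responsiveness scores from encoded binding
sites.  WT-specific models are dense networks over one-hot sequences of a
single wild type's length, trained per (protein, prefix) sub-library with
batch size 8, Adam, MSE and dropout 0.2.  Whole-library models are
convolutional networks over the 9x50 sequence+structure encoding (batch
size 16, relu), applicable to sites of any length via the constant-flank
padding.  Hyper-parameters are selected by 3-fold cross-validation over 25
random draws from the published search spaces, maximising the mean Pearson
correlation of the validation folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .encoding import CONTEXT_LENGTH, encode, one_hot
from .nn import ConvNet, DenseNet
from .scoring import BINDER_THRESHOLD

#: hyper-parameter search space for WT-specific dense models
WT_SPACE = {
    "nodes": list(range(5, 51)),
    "layers": [1, 2, 3],
    "activation": ["identity", "tanh", "relu"],
    "epochs": list(range(20, 101, 10)),
}
#: hyper-parameter search space for whole-library convolutional models
WHOLE_LIBRARY_SPACE = {
    "nodes": list(range(5, 41)),
    "layers": [1, 2, 3],
    "kernel_len": list(range(4, 11)),
    "kernel_num": list(range(4, 36)),
    "epochs": list(range(10, 101, 10)),
}
#: the hyper-parameters selected for the published whole-library models
WHOLE_LIBRARY_FINAL = {"hidden": [45], "kernel_len": 5, "kernel_num": 24,
                       "epochs": 30}

WT_BATCH, WHOLE_BATCH, LEARNING_RATE, DROPOUT = 8, 16, 0.001, 0.2


@dataclass(frozen=True)
class HyperParams:
    """One hyper-parameter draw; ``hidden`` holds per-layer node counts."""

    hidden: tuple
    epochs: int
    activation: str = "relu"
    kernel_len: int | None = None
    kernel_num: int | None = None

    def as_dict(self) -> dict:
        return {"hidden": list(self.hidden), "epochs": self.epochs,
                "activation": self.activation, "kernel_len": self.kernel_len,
                "kernel_num": self.kernel_num}


def draw_hyperparams(space: dict, rng) -> HyperParams:
    """Uniform draw from a search space; node counts drawn per layer."""
    layers = space["layers"][rng.integers(len(space["layers"]))]
    hidden = tuple(space["nodes"][rng.integers(len(space["nodes"]))]
                   for _ in range(layers))
    kwargs = {}
    if "kernel_len" in space:
        kwargs["kernel_len"] = space["kernel_len"][rng.integers(len(space["kernel_len"]))]
        kwargs["kernel_num"] = space["kernel_num"][rng.integers(len(space["kernel_num"]))]
        kwargs["activation"] = "relu"
    else:
        acts = space["activation"]
        kwargs["activation"] = acts[rng.integers(len(acts))]
    epochs = space["epochs"][rng.integers(len(space["epochs"]))]
    return HyperParams(hidden=hidden, epochs=epochs, **kwargs)


def pearson(pred, truth) -> float:
    """Pearson correlation; zero-variance inputs give 0 with a warning."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.std(pred) == 0 or np.std(truth) == 0:
        warnings.warn("zero-variance vector; Pearson correlation set to 0")
        return 0.0
    return float(stats.pearsonr(pred, truth)[0])


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

def split_dataset(n: int, seed: int, test_frac: float = 0.2) -> tuple:
    """Random, disjoint, exhaustive train/test index split (80/20 default)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_frac))
    return np.sort(order[n_test:]), np.sort(order[:n_test])


# ---------------------------------------------------------------------------
# trained-model wrapper
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted network plus its training metadata."""

    net: object
    kind: str               # "wt" or "whole_library"
    hp: HyperParams
    seed: int
    metadata: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        return self.net.predict(np.asarray(X, dtype=float))

    def predict_site(self, site: str, dotbracket: str, prefix: str = "C") -> float:
        """Whole-library convenience: encode one site and predict."""
        if self.kind != "whole_library":
            raise ValueError("predict_site requires a whole-library model")
        enc = encode(site, prefix, dotbracket)
        return float(self.predict(enc.matrix[None])[0])

    def save(self, path):
        blob = {"kind": self.kind, "hp": self.hp.as_dict(), "seed": self.seed,
                "metadata": self.metadata, "net": self.net._config()}
        blob["net"]["weights"] = [p.tolist() for p in self.net.params]
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            blob = json.load(fh)
        netconf = blob["net"]
        weights = [np.asarray(w) for w in netconf.pop("weights")]
        netkind = netconf.pop("kind")
        net = {"dense": DenseNet, "conv": ConvNet}[netkind](**netconf)
        for p, w in zip(net.params, weights):
            p[:] = w
        hp = HyperParams(hidden=tuple(blob["hp"]["hidden"]),
                         epochs=blob["hp"]["epochs"],
                         activation=blob["hp"]["activation"],
                         kernel_len=blob["hp"]["kernel_len"],
                         kernel_num=blob["hp"]["kernel_num"])
        return cls(net, blob["kind"], hp, blob["seed"], blob["metadata"])


def train_wt_model(X, y, hp: HyperParams, seed: int = 0) -> TrainedModel:
    """Train a WT-specific dense model on fixed-length one-hot sites.

    ``X`` is (n, 4, L) — all sites must share the wild type's length —
    or pre-flattened (n, 4*L).
    """
    X = np.asarray(X, dtype=float)
    flat = X.reshape(len(X), -1)
    net = DenseNet(flat.shape[1], list(hp.hidden), activation=hp.activation,
                   dropout=DROPOUT, seed=seed)
    net.fit(flat, y, epochs=hp.epochs, batch_size=WT_BATCH,
            lr=LEARNING_RATE, seed=seed)
    return TrainedModel(net, "wt", hp, seed,
                        {"n_train": len(flat), "loss_history": net.loss_history})


def train_whole_library_model(X, y, hp: HyperParams, seed: int = 0) -> TrainedModel:
    """Train a whole-library CNN on (n, 9, 50) sequence+structure inputs."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != 9 or X.shape[2] != CONTEXT_LENGTH:
        raise ValueError(f"expected (n, 9, {CONTEXT_LENGTH}) inputs, got {X.shape}")
    net = ConvNet(9, CONTEXT_LENGTH, n_kernels=hp.kernel_num,
                  kernel_len=hp.kernel_len, hidden=list(hp.hidden), seed=seed)
    net.fit(X, y, epochs=hp.epochs, batch_size=WHOLE_BATCH,
            lr=LEARNING_RATE, seed=seed)
    return TrainedModel(net, "whole_library", hp, seed,
                        {"n_train": len(X), "loss_history": net.loss_history})


_TRAINERS = {"wt": train_wt_model, "whole_library": train_whole_library_model}


# ---------------------------------------------------------------------------
# hyper-parameter search
# ---------------------------------------------------------------------------

def hyperparam_search(X, y, space: dict, kind: str, k: int = 3,
                      n_draws: int = 25, seed: int = 0) -> tuple:
    """Random search with k-fold cross-validation.

    Draws ``n_draws`` hyper-parameter sets, evaluates each by the mean
    validation-fold Pearson correlation over ``k`` folds, and returns
    (best HyperParams, log DataFrame).  Ties break toward the earliest
    draw; degenerate folds (zero label variance) score -inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    train = _TRAINERS[kind]
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))
    log = []
    best, best_score = None, -np.inf
    for draw in range(n_draws):
        hp = draw_hyperparams(space, rng)
        fold_scores = []
        for tr, va in folds:
            if np.std(y[tr]) == 0 or np.std(y[va]) == 0:
                fold_scores.append(-np.inf)
                continue
            model = train(X[tr], y[tr], hp, seed=seed + draw)
            fold_scores.append(pearson(model.predict(X[va]), y[va]))
        mean_score = float(np.mean(fold_scores))
        log.append({"draw": draw, **hp.as_dict(), "cv_pearson": mean_score,
                    "fold_scores": fold_scores})
        if mean_score > best_score:
            best, best_score = hp, mean_score
    return best, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model: TrainedModel, X, y, threshold: float = BINDER_THRESHOLD,
             shuffle_pvalue: bool = False, n_shuffles: int = 1000,
             seed: int = 0) -> dict:
    """Held-out Pearson correlation and binder-classification AUC.

    Labels are binarised at the positive-control threshold for the AUC; an
    optional empirical p-value counts label shuffles whose AUC reaches the
    observed one.
    """
    pred = model.predict(X)
    y = np.asarray(y, dtype=float)
    out = {"pearson": pearson(pred, y)}
    binary = (y > threshold).astype(int)
    if 0 < binary.sum() < len(binary):
        out["auc"] = float(roc_auc_score(binary, pred))
        if shuffle_pvalue:
            rng = np.random.default_rng(seed)
            hits = sum(roc_auc_score(rng.permutation(binary), pred) >= out["auc"]
                       for _ in range(n_shuffles))
            out["auc_pvalue"] = (hits + 1) / (n_shuffles + 1)
    else:
        out["auc"] = np.nan
    return out


def structure_ablation_test(X, y, hp: HyperParams, n_rep: int = 100,
                            seed: int = 0, test_frac: float = 0.2) -> dict:
    """Does the structural-context block improve held-out prediction?

    For each repetition: a fresh train/test split, one CNN trained on the
    full 9-row encoding and one on the encoding with the five structure
    rows zeroed, and the pair of held-out Pearson correlations recorded.
    Significance by the paired Wilcoxon signed-rank test over repetitions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X_nostruct = X.copy()
    X_nostruct[:, 4:, :] = 0.0
    pairs = []
    for rep in range(n_rep):
        tr, te = split_dataset(len(y), seed=seed * 100003 + rep, test_frac=test_frac)
        with_s = train_whole_library_model(X[tr], y[tr], hp, seed=seed + rep)
        without = train_whole_library_model(X_nostruct[tr], y[tr], hp, seed=seed + rep)
        pairs.append((pearson(with_s.predict(X[te]), y[te]),
                      pearson(without.predict(X_nostruct[te]), y[te])))
    pairs = pd.DataFrame(pairs, columns=["with_structure", "without_structure"])
    diffs = pairs["with_structure"] - pairs["without_structure"]
    if np.allclose(diffs, 0):
        pvalue = 1.0
    else:
        pvalue = float(stats.wilcoxon(pairs["with_structure"],
                                      pairs["without_structure"],
                                      alternative="greater").pvalue)
    return {"pairs": pairs, "pvalue": pvalue,
            "n_improved": int((diffs > 0).sum()), "n_rep": n_rep}


def learning_curve(X, y, sizes, hp: HyperParams, kind: str = "whole_library",
                   n_rep: int = 10, seed: int = 0, test_size: int | None = None) -> pd.DataFrame:
    """Held-out Pearson correlation as a function of training-set size.

    For each repetition a test set is withheld, then models are trained on
    random training subsets of each size; reports mean and std over
    repetitions per size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    train = _TRAINERS[kind]
    rows = []
    for size in sizes:
        scores = []
        for rep in range(n_rep):
            rng = np.random.default_rng(seed * 99991 + rep)
            order = rng.permutation(len(y))
            n_test = test_size if test_size is not None else int(round(len(y) * 0.2))
            test, pool = order[:n_test], order[n_test:]
            if size > len(pool):
                raise ValueError(f"training size {size} exceeds the pool")
            sub = pool[:size]
            model = train(X[sub], y[sub], hp, seed=seed + rep)
            scores.append(pearson(model.predict(X[test]), y[test]))
        rows.append({"size": size, "mean_pearson": float(np.mean(scores)),
                     "std_pearson": float(np.std(scores))})
    return pd.DataFrame(rows)
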