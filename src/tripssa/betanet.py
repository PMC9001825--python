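"""Residual feed-forward network with a Beta-distribution output head.

The model maps a record's features to the two parameters of a Beta
distribution over (0, 1), so that predictions express both a location and a
confidence for a proportion-valued outcome (repair bias, local GC content,
or a conflict indicator).  The loss is the negative log-likelihood of the
observed outcome under the predicted Beta density; when both parameters are
close to 1 the density is near uniform and the model is "clueless".

Architecture: three hidden layers of 100 units, each batch-normalized and
passed through ReLU; dropout (p = 0.3) after the first two hidden layers; a
residual connection carries the first hidden layer's activations past the
last two hidden layers; the 2-unit output layer is mapped to positive Beta
parameters through a softplus.  Training uses Adam (learning rate 0.001) on
mini-batches of 256 for 100 epochs, repeated over random restarts that share
a single seeded 90/10 train/test split.

The network and its backward pass are implemented directly on numpy arrays;
gradients of the Beta likelihood use the digamma function.

Context dependence is tested by comparing learning curves: a "full" model
sees bookkeeping plus chromatin plus GC features (87 inputs), the "null"
model sees bookkeeping only (7 inputs) and can learn nothing beyond a mean
and variance per replicate group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma

from tripssa.construct import CONSTRUCT_CODES

EPS_PARAM = 1e-6
BN_EPS = 1e-5

BOOKKEEPING_COLUMNS = [
    "construct_0",
    "construct_1",
    "construct_2",
    "construct_3",
    "timepoint",
    "technology",
    "pool",
]
TRACK_COLUMNS = [f"track_{j}" for j in range(78)]
GC_COLUMNS = ["gc_10kb", "gc_1Mb"]


def feature_columns(model: str, task: str = "bias") -> list[str]:
    """Input columns: 87 for the full model, 85 for the GC task, 7 for null."""
    if model == "null":
        return list(BOOKKEEPING_COLUMNS)
    cols = BOOKKEEPING_COLUMNS + TRACK_COLUMNS + GC_COLUMNS
    if task == "gc":
        cols = [c for c in cols if c not in GC_COLUMNS]
    return cols


@dataclass
class NetConfig:
    n_hidden: int = 100
    dropout: float = 0.3
    batch_size: int = 256
    learning_rate: float = 0.001
    epochs: int = 100
    restarts: int = 10
    test_fraction: float = 0.10
    seed: int = 0


@dataclass
class LearningCurve:
    """Per-epoch test loss for each restart, with median and percentile bands."""

    losses: np.ndarray  # shape (restarts, epochs)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.losses, axis=0)

    @property
    def band(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.percentile(self.losses, 1, axis=0),
            np.percentile(self.losses, 99, axis=0),
        )

    def converged_median(self, tail: int | None = None) -> float:
        tail = tail or max(1, self.losses.shape[1] // 4)
        return float(np.median(self.median[-tail:]))


def beta_nll(alpha, beta, y):
    """Per-observation negative log Beta density, -log f(y; alpha, beta)."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("Beta parameters must be positive")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("observations must lie in the open interval (0, 1)")
    return -(
        (alpha - 1) * np.log(y) + (beta - 1) * np.log1p(-y) - betaln(alpha, beta)
    )


def _softplus(x):
    return np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))


class BetaNet:
    """The residual Beta-regression network, parameters as numpy arrays."""

    def __init__(self, n_inputs: int, config: NetConfig, rng: np.random.Generator):
        h = config.n_hidden
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        dims = [(n_inputs, h), (h, h), (h, h), (h, 2)]
        for k, (fan_in, fan_out) in enumerate(dims, start=1):
            self.params[f"W{k}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)
            )
            self.params[f"b{k}"] = np.zeros(fan_out)
        for k in (1, 2, 3):
            self.params[f"gamma{k}"] = np.ones(h)
            self.params[f"beta{k}"] = np.zeros(h)
        self.running: dict[str, np.ndarray] = {}
        for k in (1, 2, 3):
            self.running[f"mean{k}"] = np.zeros(h)
            self.running[f"var{k}"] = np.ones(h)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward ---------------------------------------------------------

    def _bn_forward(self, k: int, z, training: bool, cache: dict):
        gamma, betap = self.params[f"gamma{k}"], self.params[f"beta{k}"]
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            self.running[f"mean{k}"] = 0.9 * self.running[f"mean{k}"] + 0.1 * mu
            self.running[f"var{k}"] = 0.9 * self.running[f"var{k}"] + 0.1 * var
        else:
            mu, var = self.running[f"mean{k}"], self.running[f"var{k}"]
        inv_std = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (z - mu) * inv_std
        cache[f"bn{k}"] = (z, mu, inv_std, xhat)
        return gamma * xhat + betap

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Map inputs to (alpha, beta); dropout only when training."""
        if X.shape[1] != self.params["W1"].shape[0]:
            raise ValueError(
                f"input width {X.shape[1]} != configured {self.params['W1'].shape[0]}"
            )
        p = self.config.dropout
        cache: dict = {"X": X, "training": training}
        z1 = X @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(self._bn_forward(1, z1, training, cache), 0.0)
        cache["a1"] = a1
        if training and p > 0:
            mask1 = (rng.random(a1.shape) >= p) / (1.0 - p)
        else:
            mask1 = 1.0
        d1 = a1 * mask1
        cache["mask1"], cache["d1"] = mask1, d1

        z2 = d1 @ self.params["W2"] + self.params["b2"]
        a2 = np.maximum(self._bn_forward(2, z2, training, cache), 0.0)
        cache["a2"] = a2
        if training and p > 0:
            mask2 = (rng.random(a2.shape) >= p) / (1.0 - p)
        else:
            mask2 = 1.0
        d2 = a2 * mask2
        cache["mask2"], cache["d2"] = mask2, d2

        z3 = d2 @ self.params["W3"] + self.params["b3"]
        a3 = np.maximum(self._bn_forward(3, z3, training, cache), 0.0)
        cache["a3"] = a3

        s = a1 + a3  # residual skip bypassing hidden layers 2 and 3
        cache["s"] = s
        o = s @ self.params["W4"] + self.params["b4"]
        cache["o"] = o
        ab = _softplus(o) + EPS_PARAM
        return ab[:, 0], ab[:, 1], cache

    # -- backward --------------------------------------------------------

    def _bn_backward(self, k: int, dout, cache: dict):
        z, mu, inv_std, xhat = cache[f"bn{k}"]
        n = z.shape[0]
        grads = {
            f"gamma{k}": (dout * xhat).sum(axis=0),
            f"beta{k}": dout.sum(axis=0),
        }
        dxhat = dout * self.params[f"gamma{k}"]
        dz = (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )
        return dz, grads

    def backward(self, alpha, beta, y, cache):
        """Gradients of the mean Beta NLL w.r.t. all parameters."""
        n = len(y)
        psi_ab = digamma(alpha + beta)
        dalpha = (digamma(alpha) - psi_ab - np.log(y)) / n
        dbeta = (digamma(beta) - psi_ab - np.log1p(-y)) / n
        o = cache["o"]
        sig = 1.0 / (1.0 + np.exp(-np.clip(o, -500, 500)))
        do = np.stack([dalpha, dbeta], axis=1) * sig

        grads: dict[str, np.ndarray] = {}
        s = cache["s"]
        grads["W4"] = s.T @ do
        grads["b4"] = do.sum(axis=0)
        ds = do @ self.params["W4"].T
        da3 = ds * (cache["a3"] > 0)
        da1_skip = ds

        dz3, g = self._bn_backward(3, da3, cache)
        grads.update(g)
        grads["W3"] = cache["d2"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dd2 = dz3 @ self.params["W3"].T
        da2 = dd2 * cache["mask2"] * (cache["a2"] > 0)

        dz2, g = self._bn_backward(2, da2, cache)
        grads.update(g)
        grads["W2"] = cache["d1"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dd1 = dz2 @ self.params["W2"].T
        da1 = (dd1 * cache["mask1"] + da1_skip) * (cache["a1"] > 0)

        dz1, g = self._bn_backward(1, da1, cache)
        grads.update(g)
        grads["W1"] = cache["X"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def adam_step(self, grads: dict[str, np.ndarray], b1=0.9, b2=0.999, eps=1e-8):
        self._adam_t += 1
        lr = self.config.learning_rate
        t = self._adam_t
        for key, g in grads.items():
            m = self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * g
            v = self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    def test_loss(self, X, y) -> float:
        alpha, beta, _ = self.forward(X, training=False)
        return float(beta_nll(alpha, beta, y).mean())


def split_train_test(
    n: int, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded permutation split, shared by all restarts of one experiment."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 909)))
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return perm[n_test:], perm[:n_test]


def train(
    records: pd.DataFrame,
    model: str = "full",
    task: str = "bias",
    config: NetConfig | None = None,
) -> LearningCurve:
    """Train over random restarts and record per-epoch test losses.

    The 90/10 split is drawn once from the base seed; restart ``r`` re-seeds
    the weight initialisation, batch shuffling and dropout masks.
    """
    config = config or NetConfig()
    cols = feature_columns(model, task)
    X = records[cols].to_numpy(dtype=float)
    y = np.clip(records["outcome"].to_numpy(dtype=float), 1e-3, 1 - 1e-3)
    if len(X) < config.batch_size:
        raise ValueError("fewer records than one mini-batch")
    train_idx, test_idx = split_train_test(len(X), config.test_fraction, config.seed)
    X_train, y_train = X[train_idx], y[train_idx]
    X_test, y_test = X[test_idx], y[test_idx]

    losses = np.empty((config.restarts, config.epochs))
    for r in range(config.restarts):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101, r)))
        net = BetaNet(X.shape[1], config, rng)
        for epoch in range(config.epochs):
            order = rng.permutation(len(X_train))
            for lo in range(0, len(order), config.batch_size):
                idx = order[lo : lo + config.batch_size]
                if len(idx) < 2:
                    continue  # batch statistics are undefined on one record
                alpha, beta, cache = net.forward(X_train[idx], training=True, rng=rng)
                grads = net.backward(alpha, beta, y_train[idx], cache)
                net.adam_step(grads)
            losses[r, epoch] = net.test_loss(X_test, y_test)
    return LearningCurve(losses)


def compare_full_vs_null(
    curve_full: LearningCurve, curve_null: LearningCurve
) -> dict:
    """Converged losses and a verdict on whether chromatin context helps.

    "signal": the full model's converged median test loss falls below the
    null model's 1st-percentile band; "no_signal": it does not improve on
    the null median; anything in between is "inconclusive".
    """
    if curve_full.losses.shape[1] != curve_null.losses.shape[1]:
        raise ValueError("curves must have equal epoch counts")
    tail = max(1, curve_full.losses.shape[1] // 4)
    full_conv = curve_full.converged_median(tail)
    null_conv = curve_null.converged_median(tail)
    null_p1 = float(np.median(curve_null.band[0][-tail:]))
    if full_conv < null_p1:
        verdict = "signal"
    elif full_conv >= null_conv:
        verdict = "no_signal"
    else:
        verdict = "inconclusive"
    return {
        "full_converged_median": full_conv,
        "null_converged_median": null_conv,
        "null_band_low": null_p1,
        "full_argmin_epoch": int(np.argmin(curve_full.median)),
        "null_argmin_epoch": int(np.argmin(curve_null.median)),
        "verdict": verdict,
    }


def assemble_records(
    calls: pd.DataFrame,
    lookup: pd.DataFrame,
    features: pd.DataFrame,
    bookkeeping: pd.DataFrame,
    task: str = "bias",
    window_size: int = 200,
) -> pd.DataFrame:
    """One training record per retained, mapped barcode per replicate.

    Outcomes are treated as independent events within the same chromatin
    context.  Encodings: "bias" is the fraction of a barcode's SSA UMIs
    voting top-strand; "gc" is the 10-kb GC content at the insertion;
    "conflict" is the conflicting-UMI indicator.  All outcomes are clamped
    to [1e-3, 1 - 1e-3] so binary values are representable under a Beta
    density.  ``bookkeeping`` has one row per replicate with columns
    construct, timepoint, technology, pool.
    """
    mapped = lookup[lookup["status"] == "unique"][["barcode", "chrom", "pos"]]
    df = calls[calls["retained"] & ((calls["n_top"] + calls["n_bottom"]) > 0)].merge(
        mapped, on="barcode", how="inner"
    )
    if df.empty:
        raise ValueError("no mapped retained calls")
    df["window_start"] = (df["pos"] // window_size) * window_size
    before = len(df)
    df = df.merge(
        features, left_on=["chrom", "window_start"], right_on=["chrom", "start"]
    )
    if len(df) < before:
        raise ValueError("some loci fall outside the feature table")
    df = df.merge(bookkeeping, on="replicate")
    for k in range(4):
        # Reference-level coding: the first construct code is the baseline.
        df[f"construct_{k}"] = (
            df["construct"] == CONSTRUCT_CODES[k + 1]
        ).astype(float)
    if task == "bias":
        df["outcome"] = df["n_top"] / (df["n_top"] + df["n_bottom"])
    elif task == "gc":
        df["outcome"] = df["gc_10kb"]
    elif task == "conflict":
        df["outcome"] = df["has_conflict"].astype(float)
    else:
        raise ValueError(f"unknown task {task!r}")
    df["outcome"] = np.clip(df["outcome"], 1e-3, 1 - 1e-3)
    cols = feature_columns("full", task) + ["outcome", "barcode", "replicate"]
    return df[[c for c in cols if c in df.columns]]
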