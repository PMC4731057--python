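"""Calibrators: back-propagation neural network and PLS1 baseline.

The network is the classic chemometric regressor of the mid-90s simulator
family: one hidden layer (default 4 neurons), logistic sigmoid activations
on hidden and output neurons, inputs and target min-max scaled to
[0.1, 0.9], trained by per-pattern (online) gradient back-propagation with
momentum in a seeded shuffled order each epoch.  The output is the
contaminant cell count of the two-component mixture.

The linear benchmark is PLS1 (NIPALS) on centered data.  Both are wrapped
by a leave-one-out cross-validation driver that retrains from scratch for
every left-out spectrum and reports Eq-1 RMS, slope k and R^2 via
:mod:`maldimix.evaluate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from numba import njit

from .errors import (
    DegenerateInputError,
    DivergenceError,
    FoldError,
    ParameterError,
    ValidationError,
)
from .evaluate import CalibrationResult, rms_eq1


def _as_array(X) -> np.ndarray:
    """Accept an IntensityMatrix or a plain 2-D array."""
    values = getattr(X, "values", X)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("X must be a 2-D matrix")
    return arr


# ---------------------------------------------------------------------------
# ANN
# ---------------------------------------------------------------------------

SCALE_LO, SCALE_HI = 0.1, 0.9


@dataclass
class ANNModel:
    """Feed-forward 1-hidden-layer network state plus min-max scaling.

    ``W1`` is (n_input, n_hidden), ``w2`` (n_hidden,); biases ``b1``
    (n_hidden,) and ``b2`` (scalar).  Scaling parameters are fixed at
    training time from the training data and stored so predictions invert
    them exactly.
    """

    n_input: int
    n_hidden: int
    seed: int
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    y_min: float | None = None
    y_max: float | None = None
    hyperparameters: dict = field(default_factory=dict)

    def n_weights(self) -> int:
        return self.n_input * self.n_hidden + self.n_hidden

    def to_json(self) -> dict:
        return {
            "architecture": {
                "n_input": self.n_input,
                "n_hidden": self.n_hidden,
                "n_output": 1,
                "activation": "logistic",
            },
            "seed": self.seed,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "scaling": {
                "range": [SCALE_LO, SCALE_HI],
                "x_min": None if self.x_min is None else self.x_min.tolist(),
                "x_max": None if self.x_max is None else self.x_max.tolist(),
                "y_min": self.y_min,
                "y_max": self.y_max,
            },
            "hyperparameters": self.hyperparameters,
        }

    @classmethod
    def from_json(cls, d: dict) -> "ANNModel":
        arch, sc = d["architecture"], d["scaling"]
        return cls(
            n_input=arch["n_input"],
            n_hidden=arch["n_hidden"],
            seed=d["seed"],
            W1=np.asarray(d["W1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            x_min=None if sc["x_min"] is None else np.asarray(sc["x_min"], float),
            x_max=None if sc["x_max"] is None else np.asarray(sc["x_max"], float),
            y_min=sc["y_min"],
            y_max=sc["y_max"],
            hyperparameters=d.get("hyperparameters", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ANNModel":
        return cls.from_json(json.loads(Path(path).read_text()))


@dataclass
class TrainingTrace:
    """Per-epoch Eq-1 RMS (original cell-count units) on the training set
    and, when supplied, on a verification set."""

    epoch: np.ndarray
    rms_train: np.ndarray
    rms_verify: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"epoch": self.epoch, "rms_train": self.rms_train}
        if self.rms_verify is not None:
            d["rms_verify"] = self.rms_verify
        return pd.DataFrame(d)


def ann_init(n_input: int, n_hidden: int = 4, seed: int = 0) -> ANNModel:
    """Fresh network: weights uniform in [-0.5, 0.5] from the seeded
    generator, biases zero, scaling unset until training."""
    if n_input < 1 or n_hidden < 1:
        raise ParameterError("n_input and n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    return ANNModel(
        n_input=n_input,
        n_hidden=n_hidden,
        seed=int(seed),
        W1=rng.uniform(-0.5, 0.5, size=(n_input, n_hidden)),
        b1=np.zeros(n_hidden),
        w2=rng.uniform(-0.5, 0.5, size=n_hidden),
        b2=0.0,
    )


@njit(cache=False)
def _train_kernel(Xs, ys, W1, b1, w2, b2arr, epochs, lr, mom, shuffle_seed,
                  Xv, yv, with_val, online):  # pragma: no cover - via wrapper
    n, d = Xs.shape
    h = w2.shape[0]
    vW1 = np.zeros((d, h))
    vb1 = np.zeros(h)
    vw2 = np.zeros(h)
    vb2 = 0.0
    gW1 = np.zeros((d, h))
    gb1 = np.zeros(h)
    gw2 = np.zeros(h)
    gb2 = 0.0
    np.random.seed(shuffle_seed)
    order = np.arange(n)
    rms_train = np.empty(epochs)
    rms_val = np.empty(epochs)
    a1 = np.zeros(h)
    diverged_at = -1
    for e in range(epochs):
        if online:
            for i in range(n - 1, 0, -1):  # Fisher-Yates shuffle
                j = np.random.randint(0, i + 1)
                tmp = order[i]
                order[i] = order[j]
                order[j] = tmp
        else:
            gW1[:] = 0.0
            gb1[:] = 0.0
            gw2[:] = 0.0
            gb2 = 0.0
        sse = 0.0
        for ii in range(n):
            p = order[ii]
            for k in range(h):
                z = b1[k]
                for q in range(d):
                    z += Xs[p, q] * W1[q, k]
                a1[k] = 1.0 / (1.0 + np.exp(-z))
            z2 = b2arr[0]
            for k in range(h):
                z2 += a1[k] * w2[k]
            o = 1.0 / (1.0 + np.exp(-z2))
            err = ys[p] - o
            sse += err * err
            d2 = err * o * (1.0 - o)
            if online:
                vb2 = mom * vb2 + lr * d2
                b2arr[0] += vb2
                for k in range(h):
                    d1k = d2 * w2[k] * a1[k] * (1.0 - a1[k])
                    vw2[k] = mom * vw2[k] + lr * d2 * a1[k]
                    w2[k] += vw2[k]
                    vb1[k] = mom * vb1[k] + lr * d1k
                    b1[k] += vb1[k]
                    for q in range(d):
                        vW1[q, k] = mom * vW1[q, k] + lr * d1k * Xs[p, q]
                        W1[q, k] += vW1[q, k]
            else:
                gb2 += d2
                for k in range(h):
                    d1k = d2 * w2[k] * a1[k] * (1.0 - a1[k])
                    gw2[k] += d2 * a1[k]
                    gb1[k] += d1k
                    for q in range(d):
                        gW1[q, k] += d1k * Xs[p, q]
        if not online:
            # one momentum update per epoch on the mean gradient
            vb2 = mom * vb2 + lr * gb2 / n
            b2arr[0] += vb2
            for k in range(h):
                vw2[k] = mom * vw2[k] + lr * gw2[k] / n
                w2[k] += vw2[k]
                vb1[k] = mom * vb1[k] + lr * gb1[k] / n
                b1[k] += vb1[k]
                for q in range(d):
                    vW1[q, k] = mom * vW1[q, k] + lr * gW1[q, k] / n
                    W1[q, k] += vW1[q, k]
        rms_train[e] = np.sqrt(sse / n)
        if not np.isfinite(rms_train[e]):
            diverged_at = e
            break
        if with_val:
            sv = 0.0
            for p in range(Xv.shape[0]):
                for k in range(h):
                    z = b1[k]
                    for q in range(d):
                        z += Xv[p, q] * W1[q, k]
                    a1[k] = 1.0 / (1.0 + np.exp(-z))
                z2 = b2arr[0]
                for k in range(h):
                    z2 += a1[k] * w2[k]
                o = 1.0 / (1.0 + np.exp(-z2))
                sv += (yv[p] - o) ** 2
            rms_val[e] = np.sqrt(sv / Xv.shape[0])
        else:
            rms_val[e] = np.nan
    return rms_train, rms_val, diverged_at


def _scale_x(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    span = np.where(span > 0, span, 1.0)
    out = SCALE_LO + (SCALE_HI - SCALE_LO) * (X - lo) / span
    return np.where(hi > lo, out, (SCALE_LO + SCALE_HI) / 2)


def _scale_y(y: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi > lo:
        return SCALE_LO + (SCALE_HI - SCALE_LO) * (y - lo) / (hi - lo)
    return np.full_like(np.asarray(y, float), (SCALE_LO + SCALE_HI) / 2)


def _unscale_y(s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (np.asarray(s, float) - SCALE_LO) / (SCALE_HI - SCALE_LO) * (hi - lo)


def ann_train(
    model: ANNModel,
    X,
    y: np.ndarray,
    epochs: int,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
    X_verify=None,
    y_verify: np.ndarray | None = None,
    mode: str = "online",
) -> tuple[ANNModel, TrainingTrace]:
    """Back-propagation with momentum.

    Default is per-pattern (online) updating: patterns are visited in a
    freshly shuffled order each epoch (shuffle stream seeded from the model
    seed, so training is exactly reproducible).  ``mode='batch'`` applies
    one momentum update per epoch on the mean gradient instead.  The trace
    records Eq-1 RMS after each epoch in original cell-count units; if a
    verification set is given its RMS is traced too.
    """
    if mode not in ("online", "batch"):
        raise ParameterError(f"mode must be 'online' or 'batch', got {mode!r}")
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    if Xa.shape[0] != len(y):
        raise ValidationError("X rows and y length differ")
    if Xa.shape[1] != model.n_input:
        raise ValidationError(
            f"X has {Xa.shape[1]} columns but model expects {model.n_input}"
        )
    if epochs < 1:
        raise ParameterError("epochs must be >= 1")
    model.x_min = Xa.min(axis=0)
    model.x_max = Xa.max(axis=0)
    model.y_min = float(y.min())
    model.y_max = float(y.max())
    model.hyperparameters = {
        "epochs": int(epochs),
        "learning_rate": float(learning_rate),
        "momentum": float(momentum),
    }
    Xs = _scale_x(Xa, model.x_min, model.x_max)
    ys = _scale_y(y, model.y_min, model.y_max)
    with_val = X_verify is not None and y_verify is not None
    if with_val:
        Xv = _scale_x(_as_array(X_verify), model.x_min, model.x_max)
        yv = _scale_y(np.asarray(y_verify, float), model.y_min, model.y_max)
    else:
        Xv = np.zeros((0, model.n_input))
        yv = np.zeros(0)
    b2arr = np.array([model.b2])
    shuffle_seed = int((model.seed * 2654435761 + 1) % (2**31 - 1))
    rms_tr, rms_val, diverged_at = _train_kernel(
        np.ascontiguousarray(Xs), ys, model.W1, model.b1, model.w2, b2arr,
        int(epochs), float(learning_rate), float(momentum), shuffle_seed,
        np.ascontiguousarray(Xv), yv, with_val, mode == "online",
    )
    model.b2 = float(b2arr[0])
    if diverged_at >= 0:
        raise DivergenceError(epoch=int(diverged_at) + 1, learning_rate=learning_rate)
    # convert traced RMS from scaled space back to cell-count units
    # (constant target: scaled and original units coincide up to the
    # degenerate zero span, report the scaled RMS as-is)
    unit = ((model.y_max - model.y_min) / (SCALE_HI - SCALE_LO)
            if model.y_max > model.y_min else 1.0)
    trace = TrainingTrace(
        epoch=np.arange(1, len(rms_tr) + 1),
        rms_train=rms_tr * unit,
        rms_verify=rms_val * unit if with_val else None,
    )
    return model, trace


def ann_predict(model: ANNModel, X) -> np.ndarray:
    """Deterministic forward pass; output mapped back to cell counts."""
    Xa = _as_array(X)
    if Xa.shape[1] != model.n_input:
        raise ValidationError(
            f"X has {Xa.shape[1]} columns but model expects {model.n_input}"
        )
    if model.x_min is None or model.y_min is None:
        raise ValidationError("model has no scaling; train it first")
    Xs = _scale_x(Xa, model.x_min, model.x_max)
    a1 = 1.0 / (1.0 + np.exp(-(Xs @ model.W1 + model.b1)))
    o = 1.0 / (1.0 + np.exp(-(a1 @ model.w2 + model.b2)))
    return _unscale_y(o, model.y_min, model.y_max)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """PLS1 state: latent weights/loadings and the equivalent linear
    coefficients on centered data."""

    n_components: int
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # (n, A) X-weights
    P: np.ndarray  # (n, A) X-loadings
    q: np.ndarray  # (A,) y-loadings

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_components": self.n_components,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
        }, indent=2))


def pls_fit(X, y: np.ndarray, n_components: int) -> PLSModel:
    """NIPALS PLS1 on centered (not scaled) data.

    Extraction stops early if the residual covariance vanishes (exact
    low-rank data), so requesting more components than the data supports
    is harmless for prediction.
    """
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    m, n = Xa.shape
    if len(y) != m:
        raise ValidationError("X rows and y length differ")
    if n_components < 1 or n_components > min(m - 1, n):
        raise ParameterError(
            f"n_components={n_components} must be in [1, min(m-1, n)={min(m - 1, n)}]"
        )
    x_mean = Xa.mean(axis=0)
    y_mean = float(y.mean())
    Xc = Xa - x_mean
    if not np.any(Xc):
        raise ValidationError("X has zero variance; PLS undefined")
    yc = y - y_mean
    Ws, Ps, qs = [], [], []
    Xr, yr = Xc.copy(), yc.copy()
    scale0 = float(np.abs(Xc.T @ yc).max())
    for _ in range(n_components):
        w = Xr.T @ yr
        wn = float(np.linalg.norm(w))
        if wn <= 1e-12 * max(scale0, 1.0):
            break
        w /= wn
        t = Xr @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p = Xr.T @ t / tt
        qa = float(yr @ t / tt)
        Xr = Xr - np.outer(t, p)
        yr = yr - qa * t
        Ws.append(w)
        Ps.append(p)
        qs.append(qa)
    if not Ws:
        raise ValidationError("no PLS component could be extracted")
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.asarray(qs)
    # regression coefficients: b = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_components=len(qs), coef=coef, intercept=intercept,
        x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q,
    )


def pls_predict(model: PLSModel, X) -> np.ndarray:
    Xa = _as_array(X)
    if Xa.shape[1] != len(model.coef):
        raise ValidationError("X column count does not match the PLS model")
    return Xa @ model.coef + model.intercept


# ---------------------------------------------------------------------------
# Cross-validation drivers
# ---------------------------------------------------------------------------

Trainer = Callable[[np.ndarray, np.ndarray, int], Callable[[np.ndarray], np.ndarray]]


def make_ann_trainer(
    n_hidden: int = 4,
    epochs: int = 2000,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
) -> Trainer:
    """Factory for a trainer closure usable with :func:`loo_cross_validate`."""

    def train(Xtr: np.ndarray, ytr: np.ndarray, fold_seed: int):
        model = ann_init(Xtr.shape[1], n_hidden=n_hidden, seed=fold_seed)
        model, _ = ann_train(model, Xtr, ytr, epochs=epochs,
                             learning_rate=learning_rate, momentum=momentum)
        return lambda Xnew: ann_predict(model, Xnew)

    return train


def make_pls_trainer(n_components: int = 10) -> Trainer:
    def train(Xtr: np.ndarray, ytr: np.ndarray, fold_seed: int):
        ncomp = min(n_components, Xtr.shape[0] - 1, Xtr.shape[1])
        model = pls_fit(Xtr, ytr, ncomp)
        return lambda Xnew: pls_predict(model, Xnew)

    return train


def loo_cross_validate(
    trainer: Trainer,
    X,
    y: np.ndarray,
    row_ids: list[str] | None = None,
    seed: int = 0,
    groups: list | None = None,
    label: str = "",
) -> CalibrationResult:
    """Leave-one-out: each row (or, with ``groups``, each mixture) is
    predicted by a model retrained from scratch on all others with a fresh
    fold-derived seed.  Predictions are assembled in row order and scored
    with Eq-1 RMS, slope k and R^2."""
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    m = Xa.shape[0]
    if m < 3:
        raise ValidationError("leave-one-out needs at least 3 rows")
    if len(y) != m:
        raise ValidationError("X rows and y length differ")
    if row_ids is None:
        row_ids = getattr(X, "row_ids", None) or [str(i) for i in range(m)]
    if groups is None:
        fold_members = [[i] for i in range(m)]
    else:
        if len(groups) != m:
            raise ValidationError("groups length must match rows")
        uniq = list(dict.fromkeys(groups))
        fold_members = [[i for i in range(m) if groups[i] == g] for g in uniq]
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(len(fold_members))]
    y_pred = np.empty(m)
    for fold, members in enumerate(fold_members):
        mask = np.ones(m, dtype=bool)
        mask[members] = False
        try:
            predict = trainer(Xa[mask], y[mask], fold_seeds[fold])
            y_pred[members] = predict(Xa[members])
        except Exception as exc:
            left_out = ", ".join(str(row_ids[i]) for i in members)
            raise FoldError(f"fold leaving out [{left_out}] failed: {exc}") from exc
    return CalibrationResult.from_predictions(y, y_pred, row_ids=row_ids, label=label)


def architecture_scan(
    X,
    y: np.ndarray,
    hidden_range=(1, 2, 3, 4, 5, 6, 8),
    epochs: int = 2000,
    seed: int = 0,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
) -> pd.DataFrame:
    """LOO RMS per candidate hidden-layer size; the minimum is flagged."""
    hidden_range = list(hidden_range)
    if not hidden_range:
        raise ParameterError("hidden_range must be nonempty")
    rows = []
    for nh in hidden_range:
        trainer = make_ann_trainer(n_hidden=nh, epochs=epochs,
                                   learning_rate=learning_rate, momentum=momentum)
        res = loo_cross_validate(trainer, X, y, seed=seed, label=f"ann_h{nh}")
        rows.append({"n_hidden": nh, "loo_rms": res.rms})
    table = pd.DataFrame(rows)
    table["best"] = table["loo_rms"] == table["loo_rms"].min()
    # if ties, flag only the first
    first = table.index[table["best"]][0]
    table["best"] = table.index == first
    return table
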