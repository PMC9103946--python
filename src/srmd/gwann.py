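"""Geographically weighted artificial neural network (GWANN).

A feed-forward network with hyperbolic-tangent activations relates one
pixel's five normalized driving factors to fractional vegetation cover.
Geography enters through the output layer: there is one output neuron per
*anchor location* on the study grid, and during training the squared error
of a sample at output neuron j is weighted by a Gaussian kernel of the
distance between the sample's pixel and anchor j,

    E = 1/2 * sum_i D_i (r_i - p_i)^2,      D = exp(-d^2 / (2 b^2)).

Each output neuron therefore converges to a locally weighted fit around its
anchor, capturing spatial non-stationarity in the factor-FVC relationship.
Prediction at a pixel reads the output neuron of its (nearest) anchor, fed
that pixel's own drivers.

Training is plain gradient descent on the weighted loss (Δw = -η δ p),
either full-batch (default; one step per epoch from the mean gradient over
all pixels) or online (one step per sample). Weights update by
backpropagated error signals

    δ_j = φ'(L_j) D_j (p_j - r_j)      at an output neuron,
    δ_j = φ'(L_j) Σ_k δ_k w_jk          at a hidden neuron,

with φ = tanh, φ' = 1 - tanh².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import StudyConfig, get_logger
from .drivers import DriverStack
from .grid import Grid, require_aligned

__all__ = [
    "GWANNModel",
    "GeoWeights",
    "TrainState",
    "AccuracyReport",
    "init_model",
    "geo_weights",
    "forward",
    "weighted_error",
    "backprop_deltas",
    "gradients_from_deltas",
    "update_weights",
    "default_bandwidth_m",
    "select_anchors",
    "train_network",
    "train",
    "predict",
    "predict_values",
    "evaluate_accuracy",
    "save_model",
    "load_model",
]

logger = get_logger("srmd.gwann")

N_FACTORS = 5


@dataclass
class GWANNModel:
    """Weights, activations and anchor geometry of one trained network."""

    layer_sizes: list[int]
    weights: list[np.ndarray]          # weights[l]: (layer_sizes[l], layer_sizes[l+1])
    biases: list[np.ndarray]           # biases[l]: (layer_sizes[l+1],)
    anchors_xy: np.ndarray             # (n_outputs, 2) projected metres
    kernel: str = "gaussian"
    bandwidth_m: float = 1000.0
    seed: int = 0
    trained: bool = False

    def __post_init__(self) -> None:
        if self.layer_sizes[0] != N_FACTORS:
            raise ValueError(
                f"input layer must have {N_FACTORS} neurons (one per driving "
                f"factor), got {self.layer_sizes[0]}"
            )
        if len(self.layer_sizes) < 3:
            raise ValueError("need at least one hidden layer")
        self.anchors_xy = np.asarray(self.anchors_xy, dtype=float)
        if self.anchors_xy.ndim != 2 or self.anchors_xy.shape[1] != 2:
            raise ValueError("anchors_xy must be (n, 2)")
        if self.anchors_xy.shape[0] != self.layer_sizes[-1]:
            raise ValueError("one output neuron per anchor location required")
        for w in self.weights + self.biases:
            if not np.all(np.isfinite(w)):
                raise ValueError("non-finite weights")

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    def copy(self) -> "GWANNModel":
        return GWANNModel(
            layer_sizes=list(self.layer_sizes),
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            anchors_xy=self.anchors_xy.copy(),
            kernel=self.kernel,
            bandwidth_m=self.bandwidth_m,
            seed=self.seed,
            trained=self.trained,
        )


@dataclass
class GeoWeights:
    """Kernel weight per (training-sample location, output neuron)."""

    matrix: np.ndarray                  # (n_samples, n_outputs), values in (0, 1]
    kernel: str
    bandwidth_m: float


@dataclass
class TrainState:
    """Training trajectory: per-epoch weighted error and settings."""

    epochs_run: int
    errors: list[float]
    learning_rate: float
    converged: bool

    @property
    def final_error(self) -> float:
        return self.errors[-1]


@dataclass
class AccuracyReport:
    """Per-year RMSE / MRE of predictions against the dichotomy-model FVC."""

    table: pd.DataFrame                 # columns: year, rmse, mre, n
    mean_rmse: float
    mean_mre: float


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def init_model(
    layer_sizes: list[int],
    anchors_xy: np.ndarray,
    seed: int,
    kernel: str = "gaussian",
    bandwidth_m: float = 1000.0,
) -> GWANNModel:
    """Reproducibly initialize weights: uniform in ±1/sqrt(fan_in)."""
    anchors_xy = np.asarray(anchors_xy, dtype=float)
    if anchors_xy.size == 0:
        raise ValueError("at least one anchor location is required")
    layer_sizes = list(layer_sizes)
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        lim = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-lim, lim, size=fan_out))
    return GWANNModel(
        layer_sizes=layer_sizes,
        weights=weights,
        biases=biases,
        anchors_xy=anchors_xy,
        kernel=kernel,
        bandwidth_m=bandwidth_m,
        seed=seed,
    )


def geo_weights(
    sample_locations: np.ndarray,
    anchors_xy: np.ndarray,
    kernel: str = "gaussian",
    bandwidth_m: float = 1000.0,
) -> GeoWeights:
    """Distance-decaying kernel weights between samples and anchors.

    Gaussian kernel w = exp(-d^2 / (2 b^2)): weight 1 at zero distance,
    non-increasing in distance, symmetric in its two locations.
    """
    if not bandwidth_m > 0:
        raise ValueError(f"bandwidth_m must be > 0, got {bandwidth_m}")
    if kernel != "gaussian":
        raise ValueError(f"unknown kernel {kernel!r}")
    s = np.asarray(sample_locations, dtype=float)
    a = np.asarray(anchors_xy, dtype=float)
    d2 = ((s[:, None, :] - a[None, :, :]) ** 2).sum(axis=2)
    return GeoWeights(
        matrix=np.exp(-d2 / (2.0 * bandwidth_m**2)),
        kernel=kernel,
        bandwidth_m=bandwidth_m,
    )


def default_bandwidth_m(grid: Grid) -> float:
    """Default kernel bandwidth: a quarter of the grid diagonal."""
    h = grid.shape[0] * grid.cell_size_m
    w = grid.shape[1] * grid.cell_size_m
    return 0.25 * float(np.hypot(h, w))


def select_anchors(
    grid: Grid, valid: np.ndarray, anchor_budget: int
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor pixels: all valid pixels, or a regular stride subsample.

    Returns (anchor_rc, anchors_xy): the (row, col) indices and map
    coordinates of the anchors. Output-layer width scales with the number
    of anchors, so above ``anchor_budget`` pixels the anchors are thinned
    on a regular stride; non-anchor pixels are served by their nearest
    anchor's output neuron.
    """
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid pixels to anchor")
    stride = max(1, int(np.ceil(np.sqrt(n_valid / max(1, anchor_budget)))))
    rr, cc = np.nonzero(valid)
    if stride > 1:
        off = stride // 2
        keep = ((rr - off) % stride == 0) & ((cc - off) % stride == 0)
        if not keep.any():
            keep = (rr % stride == 0) & (cc % stride == 0)
        rr, cc = rr[keep], cc[keep]
    xs, ys = grid.cell_centers()
    anchors_xy = np.column_stack([xs[rr, cc], ys[rr, cc]])
    return np.column_stack([rr, cc]), anchors_xy


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def forward(model: GWANNModel, x: np.ndarray) -> list[np.ndarray]:
    """Forward pass; returns activations per layer (cache for backprop).

    ``x`` is (n, 5) (or a single 5-vector). Every layer, output included,
    applies tanh, so raw outputs lie in (-1, 1).
    """
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input width {a.shape[1]} != {model.layer_sizes[0]} driving factors"
        )
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite network input")
    cache = [a]
    for w, b in zip(model.weights, model.biases):
        a = np.tanh(a @ w + b)
        cache.append(a)
    return cache


def weighted_error(
    predictions: np.ndarray, targets: np.ndarray, geo_weights_row: np.ndarray
) -> float:
    """Geographically weighted squared-error loss E = 1/2 Σ D (r - p)^2."""
    p = np.asarray(predictions, dtype=float).ravel()
    r = np.asarray(targets, dtype=float).ravel()
    d = np.asarray(geo_weights_row, dtype=float).ravel()
    if not (p.size == r.size == d.size):
        raise ValueError(
            f"length mismatch: predictions {p.size}, targets {r.size}, weights {d.size}"
        )
    return float(0.5 * np.sum(d * (r - p) ** 2))


def backprop_deltas(
    model: GWANNModel,
    forward_cache: list[np.ndarray],
    targets: np.ndarray,
    geo_weights_rows: np.ndarray,
) -> list[np.ndarray]:
    """Error signals δ per neuron and sample, by backpropagation.

    ``targets`` is (n,): each sample's observed FVC, which every output
    neuron is trained towards under its own geographic weight.
    ``geo_weights_rows`` is (n, n_outputs). Output neurons get
    δ = φ'(L) D (p - r); hidden neurons δ = φ'(L) Σ_k δ_k w_jk.
    """
    if forward_cache is None or len(forward_cache) != len(model.weights) + 1:
        raise ValueError("forward cache missing or inconsistent with the model")
    r = np.atleast_1d(np.asarray(targets, dtype=float))
    d = np.atleast_2d(np.asarray(geo_weights_rows, dtype=float))
    out = forward_cache[-1]
    # phi' = 1 - tanh^2 at each neuron, using the cached activation
    delta = (1.0 - out**2) * (d * (out - r[:, None]))
    deltas = [delta]
    for l in range(len(model.weights) - 1, 0, -1):
        a = forward_cache[l]
        delta = (1.0 - a**2) * (deltas[0] @ model.weights[l].T)
        deltas.insert(0, delta)
    return deltas


def gradients_from_deltas(
    forward_cache: list[np.ndarray], deltas: list[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """∂E/∂w summed over the batch: gW[l] = a[l].T δ[l], gb[l] = Σ δ[l]."""
    g_w = [forward_cache[l].T @ deltas[l] for l in range(len(deltas))]
    g_b = [deltas[l].sum(axis=0) for l in range(len(deltas))]
    return g_w, g_b


def update_weights(
    model: GWANNModel,
    deltas: list[np.ndarray],
    forward_cache: list[np.ndarray],
    learning_rate: float,
) -> GWANNModel:
    """Gradient-descent step Δw_ij = -η δ_j p_i (bias via unit input). In place."""
    if not learning_rate >= 0:
        raise ValueError(f"learning_rate must be >= 0, got {learning_rate}")
    for dl in deltas:
        if not np.all(np.isfinite(dl)):
            raise ValueError("non-finite error signals")
    g_w, g_b = gradients_from_deltas(forward_cache, deltas)
    for l in range(len(model.weights)):
        model.weights[l] -= learning_rate * g_w[l]
        model.biases[l] -= learning_rate * g_b[l]
    return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_network(
    x: np.ndarray,
    y: np.ndarray,
    sample_xy: np.ndarray,
    model: GWANNModel,
    learning_rate: float,
    max_epochs: int,
    tolerance: float,
    update_mode: str = "batch",
    geo: GeoWeights | None = None,
) -> tuple[GWANNModel, TrainState]:
    """Fit a model to (drivers, FVC) samples at known locations.

    ``batch`` mode takes one descent step per epoch from the mean per-sample
    gradient; ``online`` mode applies Δw = -η δ p after every sample in a
    fixed pixel order. Training stops after ``max_epochs`` or when the
    epoch-over-epoch change of the mean weighted error falls below
    ``tolerance``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if n == 0:
        raise ValueError("no training samples")
    if geo is None:
        geo = geo_weights(sample_xy, model.anchors_xy, model.kernel, model.bandwidth_m)
    d = geo.matrix

    errors: list[float] = []
    converged = False
    for _epoch in range(max_epochs):
        if update_mode == "batch":
            cache = forward(model, x)
            out = cache[-1]
            err = float(0.5 * np.sum(d * (y[:, None] - out) ** 2) / n)
            deltas = backprop_deltas(model, cache, y, d)
            update_weights(model, deltas, cache, learning_rate / n)
        else:  # online: per-sample steps in pixel order
            for i in range(n):
                cache = forward(model, x[i])
                deltas = backprop_deltas(model, cache, y[i : i + 1], d[i : i + 1])
                update_weights(model, deltas, cache, learning_rate)
            out = forward(model, x)[-1]
            err = float(0.5 * np.sum(d * (y[:, None] - out) ** 2) / n)
        errors.append(err)
        if len(errors) > 1 and abs(errors[-2] - errors[-1]) < tolerance:
            converged = True
            break
    model.trained = True
    return model, TrainState(
        epochs_run=len(errors),
        errors=errors,
        learning_rate=learning_rate,
        converged=converged,
    )


def _training_arrays(
    stack: DriverStack, fvc: Grid
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, sample_xy, valid mask) for one year."""
    require_aligned(stack.grid, fvc)
    valid = stack.valid_mask() & fvc.mask
    if not valid.any():
        raise ValueError(f"year {stack.year}: no valid pixels to train on")
    x = stack.matrix(valid)
    y = fvc.values[valid]
    xs, ys = stack.grid.cell_centers()
    xy = np.column_stack([xs[valid], ys[valid]])
    return x, y, xy, valid


def train(
    stacks: dict[int, DriverStack],
    fvc: dict[int, Grid],
    config: StudyConfig,
) -> dict[int, tuple[GWANNModel, TrainState]]:
    """Train GWANN(s) on per-year (driver stack, FVC) pairs.

    ``per_year`` scope (default) fits one model per year; ``pooled`` fits a
    single model on the concatenated samples of all years. Results are keyed
    by year (the pooled model is repeated under every year's key). Fully
    deterministic under ``config.seed``.
    """
    if not stacks:
        raise ValueError("no training years supplied")
    years = sorted(stacks)
    if sorted(fvc) != years:
        raise ValueError("driver-stack years and FVC years differ")

    grid = stacks[years[0]].grid
    bw = config.bandwidth_m if config.bandwidth_m is not None else default_bandwidth_m(grid)

    results: dict[int, tuple[GWANNModel, TrainState]] = {}
    if config.training_scope == "per_year":
        for k, year in enumerate(years):
            x, y, xy, valid = _training_arrays(stacks[year], fvc[year])
            _, anchors_xy = select_anchors(stacks[year].grid, valid, config.anchor_budget)
            model = init_model(
                [N_FACTORS, *config.hidden_sizes, anchors_xy.shape[0]],
                anchors_xy,
                seed=config.seed + k,
                kernel=config.kernel,
                bandwidth_m=bw,
            )
            model, state = train_network(
                x, y, xy, model,
                learning_rate=config.learning_rate,
                max_epochs=config.max_epochs,
                tolerance=config.tolerance,
                update_mode=config.update_mode,
            )
            logger.info(
                "train year=%d epochs=%d E=%.3g", year, state.epochs_run, state.final_error
            )
            results[year] = (model, state)
    else:  # pooled
        xs, ys_, xys = [], [], []
        valid0 = None
        for year in years:
            x, y, xy, valid = _training_arrays(stacks[year], fvc[year])
            xs.append(x); ys_.append(y); xys.append(xy)
            valid0 = valid if valid0 is None else (valid0 & valid)
        _, anchors_xy = select_anchors(grid, valid0, config.anchor_budget)
        model = init_model(
            [N_FACTORS, *config.hidden_sizes, anchors_xy.shape[0]],
            anchors_xy,
            seed=config.seed,
            kernel=config.kernel,
            bandwidth_m=bw,
        )
        model, state = train_network(
            np.vstack(xs), np.concatenate(ys_), np.vstack(xys), model,
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            tolerance=config.tolerance,
            update_mode=config.update_mode,
        )
        for year in years:
            results[year] = (model, state)
    return results


# ---------------------------------------------------------------------------
# Prediction and accuracy
# ---------------------------------------------------------------------------

def _anchor_index(model: GWANNModel, sample_xy: np.ndarray) -> np.ndarray:
    """Nearest anchor (output neuron) for each sample location."""
    tree = cKDTree(model.anchors_xy)
    return tree.query(np.asarray(sample_xy, dtype=float))[1]


def predict_values(
    model: GWANNModel, x: np.ndarray, anchor_idx: np.ndarray
) -> np.ndarray:
    """Raw network prediction per sample from its own (nearest) output neuron."""
    out = forward(model, x)[-1]
    return out[np.arange(out.shape[0]), anchor_idx]


def predict(model: GWANNModel, stack: DriverStack, clip: bool = True) -> Grid:
    """Predicted FVC grid for one year's driver stack.

    Each pixel is predicted by the output neuron of its nearest anchor, fed
    the pixel's own driver vector. Values are clipped to [0, 1] for
    reporting unless ``clip=False`` (raw outputs are needed by the
    finite-difference attribution).
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    valid = stack.valid_mask()
    x = stack.matrix(valid)
    xs, ys = stack.grid.cell_centers()
    xy = np.column_stack([xs[valid], ys[valid]])
    span_x = stack.grid.shape[1] * stack.grid.cell_size_m
    span_y = stack.grid.shape[0] * stack.grid.cell_size_m
    tree_d, idx = cKDTree(model.anchors_xy).query(xy)
    if np.max(tree_d) > float(np.hypot(span_x, span_y)):
        raise ValueError("model anchors do not overlap the stack's grid geometry")
    pred = predict_values(model, x, idx)
    if clip:
        pred = np.clip(pred, 0.0, 1.0)
    out = np.full(stack.grid.shape, stack.grid.nodata, dtype=float)
    out[valid] = pred
    return stack.grid.with_values(out)


def evaluate_accuracy(
    predicted: dict[int, Grid],
    observed: dict[int, Grid],
    mre_floor: float = 0.01,
) -> AccuracyReport:
    """Per-year RMSE and MRE, and their arithmetic means across years.

    RMSE = sqrt(mean (pred - obs)^2); MRE = mean |pred - obs| / obs over
    cells with obs >= ``mre_floor`` (the relative error is unstable as the
    observed FVC approaches zero).
    """
    years = sorted(predicted)
    if sorted(observed) != years or not years:
        raise ValueError("predicted and observed year sets differ or are empty")
    rows = []
    for year in years:
        p, o = predicted[year], observed[year]
        require_aligned(p, o)
        valid = p.mask & o.mask
        if not valid.any():
            raise ValueError(f"year {year}: no valid cells to evaluate")
        dp = p.values[valid] - o.values[valid]
        rmse = float(np.sqrt(np.mean(dp**2)))
        denom_ok = valid & (observed[year].values >= mre_floor)
        if denom_ok.any():
            mre = float(
                np.mean(
                    np.abs(p.values[denom_ok] - o.values[denom_ok])
                    / o.values[denom_ok]
                )
            )
        else:
            mre = np.nan
        rows.append({"year": year, "rmse": rmse, "mre": mre, "n": int(valid.sum())})
    table = pd.DataFrame(rows)
    return AccuracyReport(
        table=table,
        mean_rmse=float(table["rmse"].mean()),
        mean_mre=float(table["mre"].mean()),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: GWANNModel, path: str | Path) -> Path:
    """Checkpoint as a flat .npz: layer sizes, weights, anchors, kernel settings."""
    path = Path(path)
    payload = {
        "layer_sizes": np.array(model.layer_sizes),
        "anchors_xy": model.anchors_xy,
        "meta": np.array(
            [model.bandwidth_m, model.seed, float(model.trained)]
        ),
        "kernel": np.array(model.kernel),
    }
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        payload[f"w{l}"] = w
        payload[f"b{l}"] = b
    np.savez(path, **payload)
    return path


def load_model(path: str | Path) -> GWANNModel:
    with np.load(path, allow_pickle=False) as z:
        layer_sizes = [int(v) for v in z["layer_sizes"]]
        n_layers = len(layer_sizes) - 1
        model = GWANNModel(
            layer_sizes=layer_sizes,
            weights=[z[f"w{l}"] for l in range(n_layers)],
            biases=[z[f"b{l}"] for l in range(n_layers)],
            anchors_xy=z["anchors_xy"],
            kernel=str(z["kernel"]),
            bandwidth_m=float(z["meta"][0]),
            seed=int(z["meta"][1]),
            trained=bool(z["meta"][2]),
        )
    return model
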