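"""Finite-difference factor attribution and the disturbance significance test.

Per-pixel contributions: each normalized driver X_i in turn is perturbed by
a small relative bias (X_i + 0.001 X_i, others untouched), the trained
network is re-run, and the partial derivative is approximated by

    C_i = (Y_{X_i} - Y) / dX_i .

The contribution *share* of the mining factor is W_mine = C_mine / sum_k C_k
over the five factors (N = 5). Because the differential scheme is noisy,
the same computation applied to a no-mining period with a *virtual* mining
factor yields the attribution noise V-W_mine; its empirical distribution
gives the one-sided critical value V_{1-alpha}, and a pixel enters the
spatial range of mining disturbance (SRMD) exactly when W_mine exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .config import StudyConfig, get_logger
from .drivers import FACTOR_IDS, DriverStack
from .grid import Grid, RegionMask, require_aligned
from .gwann import GWANNModel, predict, train

__all__ = [
    "Perturbation",
    "ContributionMaps",
    "NoiseModel",
    "perturb_factor",
    "partial_derivative",
    "contribution_shares",
    "compute_contributions",
    "virtual_contribution",
    "fit_noise",
    "significance_mask",
]

logger = get_logger("srmd.attribution")

#: absolute bias floor where a normalized factor is exactly zero
BIAS_FLOOR = 1e-6
#: |sum of partial derivatives| below this yields nodata shares
DENOM_FLOOR = 1e-9


@dataclass
class Perturbation:
    """One single-factor perturbation and the two predictions around it."""

    factor_id: str
    bias: Grid
    baseline_prediction: Grid
    perturbed_prediction: Grid


@dataclass
class ContributionMaps:
    """Per-factor partial derivatives C_i and contribution shares W_i."""

    C: dict[str, Grid]
    W: dict[str, Grid]
    convention: str = "magnitude"
    n_factors: int = len(FACTOR_IDS)


@dataclass
class NoiseModel:
    """Empirical distribution of the virtual mining contribution (the noise).

    ``critical_value`` is the empirical (1 - alpha) cumulative-frequency
    point of the pooled samples. The Gaussian curve fitted to the histogram
    is retained as a normality diagnostic only.
    """

    samples: np.ndarray
    mean: float
    sd: float
    gaussian_fit: tuple[float, float, float]   # (amplitude, centre, width)
    critical_value: float
    alpha: float

    @property
    def n(self) -> int:
        return int(self.samples.size)


# ---------------------------------------------------------------------------
# Perturbation and partial derivatives
# ---------------------------------------------------------------------------

def perturb_factor(
    stack: DriverStack, factor_id: str, bias_factor: float
) -> tuple[DriverStack, Grid]:
    """Add the relative bias dX_i = bias_factor * X_i to one factor only.

    All other factors are returned bit-identical. Where X_i = 0 the
    relative bias would vanish and the finite difference be undefined, so
    those cells receive the absolute floor ``BIAS_FLOOR`` (logged).
    """
    if factor_id not in FACTOR_IDS:
        raise ValueError(f"unknown factor {factor_id!r}")
    if not bias_factor > 0:
        raise ValueError(f"bias_factor must be > 0, got {bias_factor}")
    g = stack.factors[factor_id]
    bias_vals = bias_factor * g.values
    floored = g.mask & (bias_vals == 0.0)
    if floored.any():
        logger.debug(
            "factor %s: %d zero-valued cells received the %g bias floor",
            factor_id, int(floored.sum()), BIAS_FLOOR,
        )
        bias_vals = np.where(floored, BIAS_FLOOR, bias_vals)
    bias = g.with_values(np.where(g.mask, bias_vals, g.nodata))
    perturbed = g.with_values(np.where(g.mask, g.values + bias_vals, g.nodata))
    return stack.replace_factor(factor_id, perturbed), bias


def partial_derivative(
    model: GWANNModel,
    stack: DriverStack,
    factor_id: str,
    bias_factor: float,
) -> tuple[Grid, Perturbation]:
    """C_i = (Y_{X_i} - Y) / dX_i per pixel, from the already-trained network.

    Predictions are the raw (unclipped) network outputs; clipping would
    flatten the finite difference wherever the prediction saturates.
    """
    if not model.trained:
        raise ValueError("model has not been trained; cannot attribute")
    baseline = predict(model, stack, clip=False)
    perturbed_stack, bias = perturb_factor(stack, factor_id, bias_factor)
    perturbed = predict(model, perturbed_stack, clip=False)
    valid = baseline.mask & perturbed.mask & bias.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (perturbed.values - baseline.values) / bias.values
    out = stack.grid.with_values(np.where(valid, c, stack.grid.nodata))
    return out, Perturbation(
        factor_id=factor_id,
        bias=bias,
        baseline_prediction=baseline,
        perturbed_prediction=perturbed,
    )


def contribution_shares(
    C: dict[str, Grid], convention: str = "magnitude"
) -> ContributionMaps:
    """Normalize the five partial derivatives into per-factor shares.

    ``signed``: W_i = C_i / sum_k C_k exactly as the share formula is
    printed; the shares sum to 1 per cell but individual shares are
    unbounded near a sign-cancelling denominator, so cells where
    |sum C_k| < ``DENOM_FLOOR`` become nodata (logged).
    ``magnitude``: W_i = |C_i| / sum_k |C_k| — nonnegative shares summing
    to 1, insensitive to sign cancellation.
    """
    missing = [f for f in FACTOR_IDS if f not in C]
    if missing:
        raise ValueError(f"missing partial derivatives for factors {missing}")
    if convention not in ("signed", "magnitude"):
        raise ValueError(f"unknown share convention {convention!r}")
    require_aligned(*[C[f] for f in FACTOR_IDS])
    ref = C[FACTOR_IDS[0]]
    valid = np.logical_and.reduce([C[f].mask for f in FACTOR_IDS])
    if convention == "signed":
        denom = sum(C[f].values for f in FACTOR_IDS)
    else:
        denom = sum(np.abs(C[f].values) for f in FACTOR_IDS)
    degenerate = valid & (np.abs(denom) < DENOM_FLOOR)
    if degenerate.any():
        logger.debug(
            "%d cells with |sum C| < %g set to nodata in shares",
            int(degenerate.sum()), DENOM_FLOOR,
        )
    ok = valid & ~degenerate
    W = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for f in FACTOR_IDS:
            num = C[f].values if convention == "signed" else np.abs(C[f].values)
            W[f] = ref.with_values(np.where(ok, num / denom, ref.nodata))
    return ContributionMaps(C=dict(C), W=W, convention=convention)


def compute_contributions(
    model: GWANNModel,
    stack: DriverStack,
    bias_factor: float = 0.001,
    convention: str = "magnitude",
) -> ContributionMaps:
    """All five partial derivatives and their shares for one year."""
    C = {}
    for f in FACTOR_IDS:
        C[f], _ = partial_derivative(model, stack, f, bias_factor)
    return contribution_shares(C, convention=convention)


# ---------------------------------------------------------------------------
# Virtual contribution (the noise) and the significance test
# ---------------------------------------------------------------------------

def virtual_contribution(
    no_mining_stacks: dict[int, DriverStack],
    fvc: dict[int, Grid],
    config: StudyConfig,
) -> dict[int, Grid]:
    """Per-year virtual mining contribution V-W_mine over the no-mining period.

    Trains the network on each no-mining year's stack — whose mining factor
    is the *virtual* one, built from the mining period's production and
    boundary — then runs the differential attribution and returns the
    mining-factor share grid per year. Because these years have no true
    mining effect, the result samples the attribution noise.
    """
    for year, stack in no_mining_stacks.items():
        if not stack.mining_is_virtual:
            raise ValueError(
                f"year {year}: stack carries a real mining factor; "
                "virtual contribution requires the virtual factor"
            )
    models = train(no_mining_stacks, {y: fvc[y] for y in no_mining_stacks}, config)
    out: dict[int, Grid] = {}
    for year, stack in no_mining_stacks.items():
        model, _ = models[year]
        maps = compute_contributions(
            model, stack, bias_factor=config.bias_factor,
            convention=config.share_convention,
        )
        out[year] = maps.W["mine"]
    return out


def _gaussian(x: np.ndarray, amplitude: float, centre: float, width: float) -> np.ndarray:
    return amplitude * np.exp(-((x - centre) ** 2) / (2.0 * width**2))


def fit_noise(samples: np.ndarray, alpha: float = 0.05) -> NoiseModel:
    """Noise model from pooled virtual-contribution samples.

    Moments come straight from the samples; a Gaussian is curve-fitted to
    the histogram as a normality diagnostic; the critical value is the
    empirical (1 - alpha) cumulative-frequency point of the raw samples
    (bin-width invariant, unlike reading it off the histogram).
    """
    s = np.asarray(samples, dtype=float).ravel()
    s = s[np.isfinite(s)]
    if s.size < 100:
        raise ValueError(f"need >= 100 noise samples, got {s.size}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    mean, sd = float(s.mean()), float(s.std(ddof=1))
    counts, edges = np.histogram(s, bins=50)
    centres = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _gaussian, centres, counts,
            p0=(float(counts.max()), mean, max(sd, 1e-12)),
            maxfev=5000,
        )
        gaussian_fit = (float(popt[0]), float(popt[1]), float(abs(popt[2])))
    except RuntimeError:                      # diagnostic only; never fatal
        gaussian_fit = (float("nan"),) * 3
    critical = float(np.quantile(s, 1.0 - alpha))
    return NoiseModel(
        samples=s, mean=mean, sd=sd,
        gaussian_fit=gaussian_fit, critical_value=critical, alpha=alpha,
    )


def significance_mask(w_mine: Grid, noise: NoiseModel) -> RegionMask:
    """One-sided (right) test per pixel: flag exactly where W_mine > V_{1-alpha}.

    The null keeps a pixel undisturbed when W_mine <= critical value; the
    inequality is strict, so a pixel sitting exactly at the critical value
    is not flagged.
    """
    if noise is None or not np.isfinite(noise.critical_value):
        raise ValueError("noise model is not fitted")
    flagged = w_mine.mask & (w_mine.values > noise.critical_value)
    return RegionMask.like(w_mine, flagged)
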