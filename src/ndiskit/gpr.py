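"""Gaussian-process comparison of model structure factors to noisy experiment.

A GP with squared-exponential (RBF) kernel plus a white-noise term,

    k(q, q') = s^2 exp(-(q - q')^2 / (2 l^2)) + sigma_n^2 delta(q, q'),

is fitted to an experimental difference curve by maximising the log marginal
likelihood.  The fitted sigma_n estimates the experimental noise floor, and
model curves are scored against the GP mean and a +/- k sigma_n band.  The
fit delegates to scikit-learn's GaussianProcessRegressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = ["GPFit", "DeviationReport", "fit_gp", "score_models"]

HYPER_BOUNDS = (1e-6, 1e3)
DEFAULT_SEED = 20250627
JITTER = 1e-10


@dataclass
class GPFit:
    """Fitted hyperparameters plus the conditioned predictive model."""

    signal_variance: float
    length_scale: float  # A^-1
    noise_variance: float
    Q: np.ndarray
    y: np.ndarray
    log_marginal_likelihood: float
    model: GaussianProcessRegressor = field(repr=False, default=None)

    @property
    def sigma_noise(self) -> float:
        """Estimated white-noise standard deviation on the data."""
        return float(np.sqrt(self.noise_variance))

    def predict(self, Q, return_std: bool = False):
        Q = np.asarray(Q, dtype=float).reshape(-1, 1)
        return self.model.predict(Q, return_std=return_std)


def fit_gp(
    Q,
    y,
    init: tuple[float, float, float] | None = None,
    restarts: int = 10,
    seed: int = DEFAULT_SEED,
    noise_bounds: tuple[float, float] = HYPER_BOUNDS,
) -> GPFit:
    """Fit the RBF + white-noise GP by marginal-likelihood maximisation.

    Parameters
    ----------
    Q, y
        Training grid (A^-1) and values; at least 2 points (fewer than 10
        draws a warning since the noise estimate is then poorly constrained).
    init
        Optional (signal variance, length scale, noise variance) start point.
    restarts
        Extra random restarts of the hyperparameter optimiser.
    seed
        Seeds the restart sampler; fits are deterministic given the seed.
    noise_bounds
        Optimisation bounds on the white-noise variance; pin these low (e.g.
        ``(1e-12, 1e-10)``) to force an interpolating fit on noiseless data.
    """
    Q = np.asarray(Q, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if Q.shape != y.shape:
        raise ValueError("Q and y must match in length")
    if not (np.all(np.isfinite(Q)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in GP training data")
    if Q.size < 2:
        raise ValueError("need at least 2 points to fit a GP")
    if Q.size < 10:
        warnings.warn(
            "fewer than 10 training points; the noise estimate is weakly "
            "constrained",
            stacklevel=2,
        )

    if init is None:
        var = max(float(np.var(y)), 1e-4)
        span = max(float(np.ptp(Q)), 1.0)
        init = (var, span / 10.0, var / 10.0)
    s2, ell, sn2 = init
    sn2 = float(np.clip(sn2, *noise_bounds))

    kernel = (
        ConstantKernel(s2, constant_value_bounds=HYPER_BOUNDS)
        * RBF(ell, length_scale_bounds=HYPER_BOUNDS)
        + WhiteKernel(sn2, noise_level_bounds=noise_bounds)
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=JITTER,
        n_restarts_optimizer=restarts,
        normalize_y=False,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # bound-hitting hyperparameters are legitimate (e.g. noise -> floor)
        warnings.filterwarnings("ignore", module="sklearn")
        gp.fit(Q.reshape(-1, 1), y)

    k = gp.kernel_
    fit = GPFit(
        signal_variance=float(k.k1.k1.constant_value),
        length_scale=float(k.k1.k2.length_scale),
        noise_variance=float(k.k2.noise_level),
        Q=Q,
        y=y,
        log_marginal_likelihood=float(gp.log_marginal_likelihood_value_),
        model=gp,
    )
    if not np.isfinite(fit.log_marginal_likelihood):
        raise RuntimeError(
            "GP optimisation failed: non-finite log marginal likelihood "
            f"(hyperparameters {k})"
        )
    return fit


@dataclass
class DeviationReport:
    """Model-vs-GP deviation summary on the training Q grid."""

    Q: np.ndarray
    residuals: dict[str, np.ndarray]  # model name -> model - GP mean
    exceedance: dict[str, float]  # fraction of |residual| > band
    window_rms: dict[str, dict[str, float]]  # model -> {window label -> rms}
    band_width: float  # in sigma_noise multiples
    sigma_noise: float

    def ranking(self, window: str) -> list[str]:
        """Model names ordered by rms deviation in one Q window, best first."""
        return sorted(self.window_rms, key=lambda m: self.window_rms[m][window])


def score_models(
    fit: GPFit,
    models: dict[str, tuple[np.ndarray, np.ndarray]],
    band_sigma: float = 2.0,
    Q_split: float = 2.5,
) -> DeviationReport:
    """Score model curves against the GP mean and noise band.

    Each model is (Q, values); curves are linearly interpolated onto the
    training grid and must cover it.  The report gives per-point residuals,
    the fraction of points outside mean +/- band_sigma * sigma_noise, and rms
    deviations split at Q_split (default 2.5 A^-1, separating the long-range
    region where force-field models typically disagree most).
    """
    mean = fit.predict(fit.Q)
    band = band_sigma * fit.sigma_noise
    low = fit.Q < Q_split
    residuals, exceedance, window_rms = {}, {}, {}
    for name, (mq, mv) in models.items():
        mq = np.asarray(mq, dtype=float)
        mv = np.asarray(mv, dtype=float)
        if mq.min() > fit.Q.min() + 1e-9 or mq.max() < fit.Q.max() - 1e-9:
            raise ValueError(
                f"model {name!r} does not cover the training Q domain "
                f"[{fit.Q.min():g}, {fit.Q.max():g}]"
            )
        on_grid = np.interp(fit.Q, mq, mv)
        res = on_grid - mean
        residuals[name] = res
        exceedance[name] = float(np.mean(np.abs(res) > band))
        window_rms[name] = {
            f"Q<{Q_split:g}": _rms(res[low]),
            f"Q>={Q_split:g}": _rms(res[~low]),
            "all": _rms(res),
        }
    return DeviationReport(
        Q=fit.Q,
        residuals=residuals,
        exceedance=exceedance,
        window_rms=window_rms,
        band_width=band_sigma,
        sigma_noise=fit.sigma_noise,
    )


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2))) if x.size else float("nan")
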