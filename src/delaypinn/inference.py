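"""Posterior sampling from a trained model and pathway summaries.

The mean trace is passed through the encoder; latent samples drawn from
N(mu, diag(sigma^2)) are decoded into delay-distribution draws, from which
pointwise 95% prediction bands, rate estimates, and derived pathway
characteristics (initiation time, delay moments, response time, modality)
are computed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import dip_test
from .kernels import KernelMixture
from .model import DelayPinnModel
from .traces import TimeTraceSet

__all__ = [
    "PosteriorDraws",
    "PosteriorSummary",
    "PathwayCharacteristics",
    "posterior_sample",
    "prediction_interval",
    "summarize_pathway",
    "standardize_characteristics",
]


@dataclass
class PosteriorDraws:
    """Decoded parameter draws: n mixtures plus rate pairs on the data scale."""

    centers: np.ndarray      # (M,)
    omegas: np.ndarray       # (n, M) simplex rows
    scales: np.ndarray       # (n, M)
    lambda_b: np.ndarray     # (n,)
    lambda_d: np.ndarray     # (n,)

    @property
    def n_draws(self) -> int:
        return self.omegas.shape[0]

    def mixture(self, i: int) -> KernelMixture:
        return KernelMixture(centers=self.centers, scales=self.scales[i],
                             weights=self.omegas[i])

    def posterior_mean_mixture(self) -> KernelMixture:
        w = self.omegas.mean(axis=0)
        return KernelMixture(centers=self.centers,
                             scales=self.scales.mean(axis=0),
                             weights=w / w.sum())

    def density_draws(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate every drawn density on `grid`; shape (n, len(grid))."""
        grid = np.asarray(grid, dtype=float)
        u = np.maximum(grid[None, :, None] - self.centers[None, None, :], 0.0)
        s = self.scales[:, None, :]
        k = u / s**2 * np.exp(-(u**2) / (2 * s**2))
        return np.einsum("npm,nm->np", k, self.omegas)


@dataclass
class PosteriorSummary:
    """Pointwise posterior mean/SD/95%-PI of the delay density plus rates."""

    grid: np.ndarray
    g_mean: np.ndarray
    g_sd: np.ndarray
    pi_lower: np.ndarray
    pi_upper: np.ndarray
    lambda_b_mean: float
    lambda_b_sd: float
    lambda_d_mean: float
    lambda_d_sd: float
    n_samples: int

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "t": self.grid, "g_mean": self.g_mean, "g_sd": self.g_sd,
            "pi_lower": self.pi_lower, "pi_upper": self.pi_upper,
        }).to_csv(path, index=False)

    def scalars(self) -> dict:
        return {
            "lambda_b_mean": self.lambda_b_mean,
            "lambda_b_sd": self.lambda_b_sd,
            "lambda_d_mean": self.lambda_d_mean,
            "lambda_d_sd": self.lambda_d_sd,
            "n_samples": self.n_samples,
        }


@dataclass
class PathwayCharacteristics:
    """Derived signaling-pathway descriptors of one fitted dataset."""

    initiation_time: float   # 1 / lambda_b
    mean_delay: float        # mu_g
    var_delay: float         # sigma_g^2
    cv_delay: float          # sigma_g / mu_g
    response_time: float     # log(1/lambda_b) + log(mu_g)
    modality: str            # "unimodal" | "multimodal"
    dip: float
    dip_pvalue: float

    def to_dict(self) -> dict:
        return {
            "initiation_time": self.initiation_time,
            "mean_delay": self.mean_delay,
            "var_delay": self.var_delay,
            "cv_delay": self.cv_delay,
            "response_time": self.response_time,
            "modality": self.modality,
            "dip": self.dip,
            "dip_pvalue": self.dip_pvalue,
        }


def posterior_sample(model: DelayPinnModel,
                     traces: TimeTraceSet | np.ndarray,
                     n: int = 1000, seed: int | None = None,
                     fixed_lambda_d: float | None = None) -> PosteriorDraws:
    """Draw n decoded parameter sets from the latent posterior of the mean trace.

    ``traces`` may be the full trace set (its mean trace is used) or an
    already-averaged trace on the training grid, in raw data units.  Rates
    are returned on the data scale (lambda_b is multiplied back by the
    standardization scale).  ``fixed_lambda_d`` overrides the decoded decay
    rate with a known value.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    if model.standardizer is None:
        raise RuntimeError("model carries no standardization record")
    if n < 1:
        raise ValueError("need at least one posterior sample")
    y_bar = (traces.mean_trace() if isinstance(traces, TimeTraceSet)
             else np.asarray(traces, dtype=float))
    if y_bar.ndim != 1 or y_bar.size != model.d:
        raise ValueError(f"mean trace must have length {model.d}")
    y_std = model.standardizer.transform(y_bar[None, :])

    mu_t, sigma_t = model.encode(y_std)
    mu, sigma = mu_t.data[0], sigma_t.data[0]
    rng = np.random.default_rng(seed)
    z = mu[None, :] + sigma[None, :] * rng.standard_normal((n, model.k))
    dec = model.decode(z)
    rate_scale = model.standardizer.rate_scale
    lam_d = dec.lambda_d.data.ravel().copy()
    if fixed_lambda_d is not None:
        lam_d[:] = fixed_lambda_d
    return PosteriorDraws(
        centers=model.centers.copy(),
        omegas=dec.omega.data.copy(),
        scales=dec.s.data.copy(),
        lambda_b=dec.lambda_b.data.ravel() * rate_scale,
        lambda_d=lam_d,
    )


def prediction_interval(draws: PosteriorDraws, grid) -> PosteriorSummary:
    """Pointwise mean +- 1.96 SD band of the drawn densities (lower clipped at 0)."""
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws for a prediction interval")
    grid = np.asarray(grid, dtype=float)
    dens = draws.density_draws(grid)
    g_mean = dens.mean(axis=0)
    g_sd = dens.std(axis=0)
    return PosteriorSummary(
        grid=grid,
        g_mean=g_mean,
        g_sd=g_sd,
        pi_lower=np.maximum(g_mean - 1.96 * g_sd, 0.0),
        pi_upper=g_mean + 1.96 * g_sd,
        lambda_b_mean=float(draws.lambda_b.mean()),
        lambda_b_sd=float(draws.lambda_b.std()),
        lambda_d_mean=float(draws.lambda_d.mean()),
        lambda_d_sd=float(draws.lambda_d.std()),
        n_samples=draws.n_draws,
    )


def summarize_pathway(draws: PosteriorDraws, seed: int | None = None,
                      n_dip_samples: int = 5000, n_boot: int = 500,
                      dip_level: float = 0.05) -> PathwayCharacteristics:
    """Pathway descriptors from the posterior-mean delay distribution.

    Delay moments come from the closed-form mixture moments of the
    posterior-mean parameters; the modality call applies the dip test (with
    a uniform-null bootstrap threshold at ``dip_level``) to samples drawn
    from that mixture.
    """
    mix = draws.posterior_mean_mixture()
    mu_g, var_g, cv = mix.moments()
    lam_b = float(draws.lambda_b.mean())
    rng = np.random.default_rng(seed)
    samples = mix.sample(n_dip_samples, rng)
    dip, pval = dip_test(samples, n_boot=n_boot,
                         seed=int(rng.integers(2**31)))
    return PathwayCharacteristics(
        initiation_time=1.0 / lam_b,
        mean_delay=mu_g,
        var_delay=var_g,
        cv_delay=cv,
        response_time=float(np.log(1.0 / lam_b) + np.log(mu_g)),
        modality="multimodal" if pval < dip_level else "unimodal",
        dip=dip,
        dip_pvalue=pval,
    )


def standardize_characteristics(
        characteristics: list[PathwayCharacteristics]) -> pd.DataFrame:
    """Z-score each numeric descriptor across datasets (mean 0, variance 1)."""
    if len(characteristics) < 2:
        raise ValueError("need at least 2 entries to standardize")
    df = pd.DataFrame([c.to_dict() for c in characteristics])
    numeric = ["initiation_time", "mean_delay", "var_delay", "cv_delay",
               "response_time"]
    out = df[numeric].copy()
    for col in numeric:
        sd = out[col].std(ddof=0)
        if sd == 0:
            warnings.warn(f"zero variance in column {col!r}; set to zeros",
                          stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = (out[col] - out[col].mean()) / sd
    out["modality"] = df["modality"]
    return out
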