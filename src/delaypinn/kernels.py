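"""Shifted Rayleigh kernels and kernel mixtures.

The estimated transduction-delay density is a weighted sum of shifted
Rayleigh kernels

    K(t; c, s) = ((t - c) / s^2) * exp(-(t - c)^2 / (2 s^2))   for t >= c,
                 0 otherwise,

whose CDF is available in closed form, so reconstructions and physics
residuals never require numerical integration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RayleighKernel", "KernelMixture"]

_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


@dataclass(frozen=True)
class RayleighKernel:
    """A Rayleigh density shifted to start at ``c`` with scale ``s``."""

    c: float
    s: float

    def __post_init__(self):
        if not self.s > 0:
            raise ValueError(f"scale must be positive, got s={self.s}")
        if self.c < 0:
            raise ValueError(f"shift must be nonnegative, got c={self.c}")

    def pdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = np.maximum(t - self.c, 0.0)
        return u / self.s**2 * np.exp(-(u**2) / (2 * self.s**2))

    def cdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = np.maximum(t - self.c, 0.0)
        return 1.0 - np.exp(-(u**2) / (2 * self.s**2))

    def mean(self) -> float:
        return self.c + self.s * _SQRT_HALF_PI

    def second_moment(self) -> float:
        # E[(c + sR)^2] with R standard Rayleigh: E R = sqrt(pi/2), E R^2 = 2
        return self.c**2 + 2 * self.c * self.s * _SQRT_HALF_PI + 2 * self.s**2

    def var(self) -> float:
        return self.second_moment() - self.mean() ** 2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return self.c + self.s * np.sqrt(-2.0 * np.log1p(-u))


@dataclass
class KernelMixture:
    """Weighted mixture of shifted Rayleigh kernels.

    Parameters
    ----------
    centers
        Strictly increasing shift parameters ``c_j``.
    scales
        Positive scale parameters ``s_j``, one per center.
    weights
        Nonnegative mixture weights ``w_j``; a proper density requires
        ``sum(w) == 1`` (enforced by the network's simplex map, validated
        here only as nonnegativity).
    """

    centers: np.ndarray
    scales: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.centers.shape == self.scales.shape == self.weights.shape):
            raise ValueError(
                "centers, scales and weights must have identical shapes: "
                f"{self.centers.shape}, {self.scales.shape}, {self.weights.shape}"
            )
        if self.centers.ndim != 1 or self.centers.size == 0:
            raise ValueError("mixture parameters must be nonempty 1-D arrays")
        if np.any(np.diff(self.centers) < 0):
            raise ValueError("centers must be nondecreasing")
        if np.any(self.scales <= 0):
            raise ValueError("all scales must be positive")
        if np.any(self.weights < 0):
            raise ValueError("all weights must be nonnegative")

    @property
    def n_kernels(self) -> int:
        return self.centers.size

    # ------------------------------------------------------------------ eval
    def _uu(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.maximum(t[..., None] - self.centers, 0.0)

    def pdf(self, t) -> np.ndarray:
        u = self._uu(t)
        k = u / self.scales**2 * np.exp(-(u**2) / (2 * self.scales**2))
        return k @ self.weights

    def cdf(self, t) -> np.ndarray:
        u = self._uu(t)
        k = 1.0 - np.exp(-(u**2) / (2 * self.scales**2))
        return k @ self.weights

    def moments(self) -> tuple[float, float, float]:
        """Return (mean, variance, coefficient of variation)."""
        w = self.weights / self.weights.sum()
        m1 = self.centers + self.scales * _SQRT_HALF_PI
        m2 = (
            self.centers**2
            + 2 * self.centers * self.scales * _SQRT_HALF_PI
            + 2 * self.scales**2
        )
        mean = float(w @ m1)
        var = float(w @ m2) - mean**2
        if mean == 0.0:
            raise ZeroDivisionError("mixture mean is zero; CV undefined")
        return mean, var, float(np.sqrt(max(var, 0.0)) / mean)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF draws: pick kernel ~ weights, then c + s*sqrt(-2 ln(1-u))."""
        if n <= 0:
            raise ValueError(f"sample size must be positive, got {n}")
        w = self.weights / self.weights.sum()
        comp = rng.choice(self.n_kernels, size=n, p=w)
        u = rng.random(n)
        return self.centers[comp] + self.scales[comp] * np.sqrt(-2.0 * np.log1p(-u))

    # ------------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelMixture":
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "KernelMixture":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def export_curves(self, grid: np.ndarray, path: str | Path) -> None:
        """Write pdf and cdf on `grid` as a CSV with columns t, pdf, cdf."""
        import pandas as pd

        grid = np.asarray(grid, dtype=float)
        pd.DataFrame(
            {"t": grid, "pdf": self.pdf(grid), "cdf": self.cdf(grid)}
        ).to_csv(path, index=False)
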