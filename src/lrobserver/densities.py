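"""Class-conditional density backends for the likelihood-ratio observer.

The primary backend is the Gaussian: volumetric measures of AD patients and
normal controls are modeled as N(mu_d, sigma_d^2) and N(mu_n, sigma_n^2).
A Gaussian-kernel density estimate is provided as a nonparametric
cross-check backend (mirroring the R ``density()`` defaults).  Densities are
not truncated at zero: at brain-volume scale the sub-zero mass is < 1e-8.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateCohortError, InsufficientDataError

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GaussianDensity:
    """A fitted (or externally specified) normal density in mm^3.

    ``n`` records the number of subjects behind the fit; it is None for
    densities built directly from published summary statistics.
    """

    mu: float
    sigma: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")

    def pdf(self, x):
        x = _check_finite(x)
        return stats.norm.pdf(x, loc=self.mu, scale=self.sigma)

    def logpdf(self, x):
        x = _check_finite(x)
        return stats.norm.logpdf(x, loc=self.mu, scale=self.sigma)


@dataclass
class KernelDensity:
    """Gaussian-kernel density estimate over a fitted sample of volumes."""

    sample: np.ndarray
    bandwidth: float  # kernel standard deviation, mm^3
    _kde: stats.gaussian_kde = field(repr=False, compare=False)

    def pdf(self, x):
        x = _check_finite(x)
        out = self._kde(np.atleast_1d(np.asarray(x, dtype=float)))
        return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out

    def logpdf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(x))


def _check_finite(x):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("density evaluation point must be finite")
    return x


def _validated(values: Sequence[float], minimum: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < minimum or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        bad = arr.size < minimum
        if bad:
            raise InsufficientDataError(
                f"need at least {minimum} finite positive values, got {arr.size}"
            )
        raise ValueError("volumes must be finite and positive")
    return arr


def fit_gaussian(values: Sequence[float]) -> GaussianDensity:
    """Fit mean and sample standard deviation (n-1 denominator).

    Raises InsufficientDataError below 2 values and DegenerateCohortError on
    zero variance.
    """
    arr = _validated(values, 2)
    sigma = float(np.std(arr, ddof=1))
    if sigma == 0.0:
        raise DegenerateCohortError("all values identical: zero-variance cohort")
    return GaussianDensity(mu=float(np.mean(arr)), sigma=sigma, n=int(arr.size))


def gaussian_pdf(density: GaussianDensity, x) -> float:
    return density.pdf(x)


def fit_kde(
    values: Sequence[float],
    bandwidth_rule: str = "silverman",
    bandwidth: float | None = None,
) -> KernelDensity:
    """Gaussian-kernel density estimate; Silverman bandwidth by default."""
    arr = _validated(values, 5)
    if bandwidth_rule == "silverman":
        kde = stats.gaussian_kde(arr, bw_method="silverman")
    elif bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ValueError("fixed bandwidth_rule requires a positive bandwidth")
        kde = stats.gaussian_kde(arr, bw_method=bandwidth / np.std(arr, ddof=1))
    else:
        raise ValueError(f"unknown bandwidth_rule {bandwidth_rule!r}")
    bw = float(kde.factor * np.std(arr, ddof=1))
    return KernelDensity(sample=arr.copy(), bandwidth=bw, _kde=kde)


def backend_name(density) -> str:
    if isinstance(density, GaussianDensity):
        return "gaussian"
    if isinstance(density, KernelDensity):
        return "kde"
    raise TypeError(f"not a density: {density!r}")


def gaussian_to_dict(
    density: GaussianDensity,
    measure: str = "",
    group: str = "",
    provenance: str = "",
) -> dict:
    """Serialize with mu/sigma as decimal strings for bit-exact round trips."""
    return {
        "schema_version": SCHEMA_VERSION,
        "measure": measure,
        "group": group,
        "mu": repr(float(density.mu)),
        "sigma": repr(float(density.sigma)),
        "n": density.n,
        "backend": "gaussian",
        "provenance": provenance,
    }


def gaussian_from_dict(doc: dict) -> GaussianDensity:
    if doc.get("backend") != "gaussian":
        raise ValueError(f"unsupported backend {doc.get('backend')!r}")
    n = doc.get("n")
    return GaussianDensity(mu=float(doc["mu"]), sigma=float(doc["sigma"]),
                           n=None if n is None else int(n))


def save_gaussian(density: GaussianDensity, path: str | Path, **meta) -> None:
    Path(path).write_text(json.dumps(gaussian_to_dict(density, **meta), indent=2))


def load_gaussian(path: str | Path) -> GaussianDensity:
    return gaussian_from_dict(json.loads(Path(path).read_text()))
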