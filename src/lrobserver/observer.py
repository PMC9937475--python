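"""The likelihood-ratio ideal observer.

A measurement x (a volumetric measure in mm^3) is scored by the natural-log
likelihood ratio

    y = log f_d(x) - log f_n(x)

against the diseased (f_d) and normal (f_n) class-conditional densities, and
called diseased when y > 0.  A score of exactly zero is called normal: the
decision rule only defines y > 0 as diseased and y < 0 as normal, and ties
go to the null (non-diseased) class, the conservative clinical convention.
All Gaussian evaluation is done in the log domain, so the score is finite
for any physically plausible volume (no underflow up to |z| ~ 37 and beyond).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import MeasureSpec, NAMED_MEASURES, SubjectRecord, measure_value
from .densities import (
    GaussianDensity,
    KernelDensity,
    backend_name,
    gaussian_from_dict,
    gaussian_to_dict,
    SCHEMA_VERSION,
)
from .errors import (
    DegenerateModelError,
    UndefinedRatioError,
    UnsupportedBackendError,
)

DISEASED = "diseased"
NORMAL = "normal"


@dataclass(frozen=True)
class LRObserverModel:
    """A (normal, diseased) density pair bound to a volumetric measure."""

    normal_density: GaussianDensity | KernelDensity
    diseased_density: GaussianDensity | KernelDensity
    measure: MeasureSpec

    def __post_init__(self) -> None:
        if backend_name(self.normal_density) != backend_name(self.diseased_density):
            raise ValueError("normal and diseased densities must share a backend")

    @property
    def backend(self) -> str:
        return backend_name(self.normal_density)


@dataclass(frozen=True)
class LRScore:
    """A scored measurement: x in mm^3, y = log f_d(x) - log f_n(x)."""

    y: float
    x: float
    decision: str  # "diseased" iff y > 0

    def __post_init__(self) -> None:
        assert (self.decision == DISEASED) == (self.y > 0)


def log_likelihood_ratio(model: LRObserverModel, x: float) -> LRScore:
    """Score one measurement; natural log, y > 0 means diseased."""
    x = float(x)
    if not (math.isfinite(x) and x > 0):
        raise ValueError(f"measurement must be finite and positive, got {x!r}")
    ld = float(model.diseased_density.logpdf(x))
    ln = float(model.normal_density.logpdf(x))
    if not (math.isfinite(ld) and math.isfinite(ln)):
        raise UndefinedRatioError(
            f"likelihood ratio undefined at x={x}: zero density under KDE backend"
        )
    y = ld - ln
    return LRScore(y=y, x=x, decision=DISEASED if y > 0 else NORMAL)


def classify(model: LRObserverModel, record: SubjectRecord) -> LRScore:
    """Aggregate the record to the model's measure, then score it."""
    return log_likelihood_ratio(model, measure_value(record, model.measure))


def score_values(model: LRObserverModel, xs) -> np.ndarray:
    """Vectorized y over an array of measurements (same rule as classify)."""
    xs = np.asarray(xs, dtype=float)
    return np.asarray(model.diseased_density.logpdf(xs), dtype=float) - np.asarray(
        model.normal_density.logpdf(xs), dtype=float
    )


def _quadratic_coefficients(model: LRObserverModel) -> tuple[float, float, float]:
    """y(x) = A x^2 + B x + C for the Gaussian backend."""
    fn, fd = model.normal_density, model.diseased_density
    a = 1.0 / (2 * fn.sigma**2) - 1.0 / (2 * fd.sigma**2)
    b = fd.mu / fd.sigma**2 - fn.mu / fn.sigma**2
    c = (
        fn.mu**2 / (2 * fn.sigma**2)
        - fd.mu**2 / (2 * fd.sigma**2)
        + math.log(fn.sigma / fd.sigma)
    )
    return a, b, c


def decision_boundaries(model: LRObserverModel) -> tuple[float, ...]:
    """Real roots of y(x) = 0, ascending (Gaussian backend only).

    Equal sigmas give one root (the midpoint shifted by the variance-free
    linear term); unequal sigmas give zero, one or two roots.  Identical
    densities make y identically zero and raise DegenerateModelError.
    """
    if backend_name(model.normal_density) != "gaussian":
        raise UnsupportedBackendError("decision boundaries require the Gaussian backend")
    a, b, c = _quadratic_coefficients(model)
    if a == 0.0:
        if b == 0.0:
            raise DegenerateModelError(
                "identical normal and diseased densities: y is identically zero"
            )
        return (-c / b,)
    disc = b * b - 4 * a * c
    if disc < 0:
        return ()
    if disc == 0:
        return (-b / (2 * a),)
    # numerically stable quadratic roots
    q = -0.5 * (b + math.copysign(math.sqrt(disc), b))
    return tuple(sorted((q / a, c / q)))


def predicted_operating_point(model: LRObserverModel) -> tuple[float, float]:
    """(sensitivity, specificity) the y=0 rule attains if the test population
    truly follows the model's Gaussian densities.

    Integrates each class density over the region where the decision favors
    it, using the decision boundaries.
    """
    from scipy.stats import norm

    if model.backend != "gaussian":
        raise UnsupportedBackendError("predicted operating point requires Gaussian backend")
    roots = decision_boundaries(model)
    fn, fd = model.normal_density, model.diseased_density
    # probe midpoints of the intervals cut by the roots to find diseased regions
    edges = [-math.inf, *roots, math.inf]
    sens = 0.0
    spec = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        probe = (
            (lo + hi) / 2.0
            if math.isfinite(lo) and math.isfinite(hi)
            else (hi - 1.0 if math.isfinite(hi) else lo + 1.0)
        )
        a, b, c = _quadratic_coefficients(model)
        y_probe = a * probe * probe + b * probe + c
        p_d = norm.cdf(hi, fd.mu, fd.sigma) - norm.cdf(lo, fd.mu, fd.sigma)
        p_n = norm.cdf(hi, fn.mu, fn.sigma) - norm.cdf(lo, fn.mu, fn.sigma)
        if y_probe > 0:
            sens += p_d
        else:
            spec += p_n
    return float(sens), float(spec)


def save_model(model: LRObserverModel, path: str | Path, provenance: str = "") -> None:
    """Serialize a Gaussian-backend model to JSON (decimal-string mu/sigma)."""
    if model.backend != "gaussian":
        raise UnsupportedBackendError("only Gaussian-backend models are serializable")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "measure": model.measure.name,
        "normal": gaussian_to_dict(
            model.normal_density, measure=model.measure.name, group="NC",
            provenance=provenance,
        ),
        "diseased": gaussian_to_dict(
            model.diseased_density, measure=model.measure.name, group="AD",
            provenance=provenance,
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> LRObserverModel:
    doc = json.loads(Path(path).read_text())
    measure = NAMED_MEASURES.get(doc["measure"])
    if measure is None:
        raise ValueError(f"unknown measure name {doc['measure']!r} in model file")
    return LRObserverModel(
        normal_density=gaussian_from_dict(doc["normal"]),
        diseased_density=gaussian_from_dict(doc["diseased"]),
        measure=measure,
    )
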