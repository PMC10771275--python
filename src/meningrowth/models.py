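"""Candidate tumor growth laws as mean functions with analytic gradients.

Four growth laws are considered for serial tumor-volume data: linear growth
in volume, exponential growth, linear radial growth (the radius grows
linearly, so volume grows cubically under a spherical assumption), and
Gompertzian growth (an early exponential phase, a near-linear middle phase
and a plateau at carrying capacity K).

Each law is fitted on a declared response scale: the linear model on volume
(mL), the other three on log volume. The mean functions are

    linear        mu(t) = intercept + slope * t                 [volume]
    exponential   mu(t) = log V0 + alpha * t                    [log volume]
    radial        mu(t) = log(4*pi/3) + 3 * log(r0 + alpha*t)   [log volume]
    gompertz      mu(t) = log K + log(V0/K) * exp(-alpha * t)   [log volume]

with time t in months since the first scan, volumes in mL (== cm^3) and
radii in cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthModel",
    "GrowthModelDomainError",
    "MODELS",
    "get_model",
    "mean_response",
    "mean_gradient",
    "radius_from_volume",
    "volume_from_radius",
    "volume_radius_convert",
]

LOG_SPHERE = float(np.log(4.0 * np.pi / 3.0))


class GrowthModelDomainError(ValueError):
    """Raised when a mean function is evaluated outside its domain."""


@dataclass(frozen=True)
class GrowthModel:
    """A growth law: named parameters plus the scale the residuals live on.

    Parameters
    ----------
    name:
        One of ``linear``, ``exponential``, ``radial``, ``gompertz``.
    param_names:
        Ordered names of the mean-function parameters, natural scale.
    response_scale:
        ``"volume"`` (mL) or ``"log_volume"``.
    positive_params:
        Parameters constrained positive; optimizers work on their logs.
    """

    name: str
    param_names: tuple[str, ...]
    response_scale: str
    positive_params: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)


MODELS: dict[str, GrowthModel] = {
    "linear": GrowthModel("linear", ("intercept", "slope"), "volume"),
    "exponential": GrowthModel("exponential", ("log_v0", "alpha"), "log_volume"),
    "radial": GrowthModel(
        "radial", ("r0", "alpha"), "log_volume", positive_params=("r0",)
    ),
    "gompertz": GrowthModel(
        "gompertz",
        ("log_k", "log_v0", "alpha"),
        "log_volume",
        positive_params=("alpha",),
    ),
}


def get_model(name: str) -> GrowthModel:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown growth model {name!r}; choose from {sorted(MODELS)}"
        ) from None


def mean_response(model: GrowthModel | str, params: np.ndarray, t) -> np.ndarray:
    """Evaluate the mean function on the model's response scale.

    ``params`` is the natural-scale parameter vector in ``param_names``
    order; ``t`` is time in months (scalar or array, >= 0).
    """
    model = get_model(model) if isinstance(model, str) else model
    t = np.asarray(t, dtype=float)
    p = np.asarray(params, dtype=float)
    if p.shape != (model.n_params,):
        raise ValueError(
            f"{model.name} expects {model.n_params} parameters, got {p.shape}"
        )
    if model.name == "linear":
        intercept, slope = p
        return intercept + slope * t
    if model.name == "exponential":
        log_v0, alpha = p
        return log_v0 + alpha * t
    if model.name == "radial":
        r0, alpha = p
        radius = r0 + alpha * t
        if np.any(radius <= 0.0):
            raise GrowthModelDomainError(
                f"radial model needs r0 + alpha*t > 0; got min {np.min(radius):g}"
            )
        return LOG_SPHERE + 3.0 * np.log(radius)
    # gompertz
    log_k, log_v0, alpha = p
    return log_k + (log_v0 - log_k) * np.exp(-alpha * t)


def mean_gradient(model: GrowthModel | str, params: np.ndarray, t) -> np.ndarray:
    """Gradient of :func:`mean_response` w.r.t. the natural parameters.

    Returns an array of shape ``t.shape + (n_params,)``.
    """
    model = get_model(model) if isinstance(model, str) else model
    t = np.asarray(t, dtype=float)
    p = np.asarray(params, dtype=float)
    out = np.empty(t.shape + (model.n_params,), dtype=float)
    if model.name == "linear" or model.name == "exponential":
        out[..., 0] = 1.0
        out[..., 1] = t
        return out
    if model.name == "radial":
        r0, alpha = p
        radius = r0 + alpha * t
        if np.any(radius <= 0.0):
            raise GrowthModelDomainError(
                f"radial model needs r0 + alpha*t > 0; got min {np.min(radius):g}"
            )
        out[..., 0] = 3.0 / radius
        out[..., 1] = 3.0 * t / radius
        return out
    # gompertz: mu = log_k * (1 - E) + log_v0 * E with E = exp(-alpha t)
    log_k, log_v0, alpha = p
    decay = np.exp(-alpha * t)
    out[..., 0] = 1.0 - decay
    out[..., 1] = decay
    out[..., 2] = -t * decay * (log_v0 - log_k)
    return out


def radius_from_volume(volume_ml) -> np.ndarray:
    """Sphere-equivalent radius (cm) from volume (mL): r = (3V / 4 pi)^(1/3)."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    return np.cbrt(3.0 * v / (4.0 * np.pi))


def volume_from_radius(radius_cm) -> np.ndarray:
    """Sphere volume (mL) from radius (cm): V = (4 pi / 3) r^3."""
    r = np.asarray(radius_cm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    return (4.0 * np.pi / 3.0) * r**3


def volume_radius_convert(value, direction: str):
    """Convert between tumor volume (mL) and sphere-equivalent radius (cm).

    ``direction`` is ``"volume_to_radius"`` or ``"radius_to_volume"``.
    """
    if direction == "volume_to_radius":
        return radius_from_volume(value)
    if direction == "radius_to_volume":
        return volume_from_radius(value)
    raise ValueError(
        "direction must be 'volume_to_radius' or 'radius_to_volume'"
    )
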