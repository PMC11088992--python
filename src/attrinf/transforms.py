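"""Native <-> model space parameter transforms.

Hierarchical estimation happens in an unconstrained native space with
Gaussian group priors; parameters are mapped to their model-relevant
ranges by monotone transforms: logistic for the (0, 1) parameters
(pHI0, pSI0, eta), exponential for the positive uncertainties
(uPri, u_pi) and identity for the likelihood weights (w0, wHI, wSI).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

from .model import MODEL_VARIANTS, VARIANT_FREE_PARAMS, InvalidParameterError, ModelParams

__all__ = [
    "NATIVE_PRIOR_MEAN",
    "NATIVE_PRIOR_SD",
    "free_names",
    "to_model_space",
    "to_native_space",
    "native_vector_to_params",
    "params_to_native_vector",
]

#: broad native-space group prior used to initialize hierarchical fits
NATIVE_PRIOR_MEAN = 0.0
NATIVE_PRIOR_SD = 6.5

_LOGISTIC = {"pHI0", "pSI0", "eta"}
_LOGSCALE = {"uPri", "uPri_HI", "uPri_SI", "u_pi"}

# numerical clamps keeping exp/logit finite over the optimizer's range
_NATIVE_CLIP = 30.0
_EPS = 1e-12


def free_names(variant: str) -> tuple[str, ...]:
    if variant not in MODEL_VARIANTS:
        raise InvalidParameterError(f"unknown model variant {variant!r}")
    return VARIANT_FREE_PARAMS[variant]


def to_model_space(name: str, x: float) -> float:
    """Map one native value to model space."""
    if name in _LOGISTIC:
        return float(expit(x))
    if name in _LOGSCALE:
        return float(np.exp(np.clip(x, -_NATIVE_CLIP, _NATIVE_CLIP)))
    return float(x)


def to_native_space(name: str, v: float) -> float:
    """Inverse map, model space back to the unconstrained native space."""
    if name in _LOGISTIC:
        return float(logit(np.clip(v, _EPS, 1.0 - _EPS)))
    if name in _LOGSCALE:
        return float(np.log(max(v, _EPS)))
    return float(v)


def native_vector_to_params(vec: np.ndarray, variant: str) -> ModelParams:
    """Build model-space :class:`ModelParams` from a native vector."""
    names = free_names(variant)
    if len(vec) != len(names):
        raise InvalidParameterError(
            f"variant {variant} expects {len(names)} values, got {len(vec)}"
        )
    values = {n: to_model_space(n, float(x)) for n, x in zip(names, vec)}
    return ModelParams.from_free(variant, **values)


def params_to_native_vector(params: ModelParams) -> np.ndarray:
    """Native-space vector of a parameter set's free values."""
    return np.array(
        [to_native_space(n, v) for n, v in params.free_values().items()]
    )
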