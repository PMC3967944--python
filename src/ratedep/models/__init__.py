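"""Model registry: uniform access to the implemented myocyte models."""

from __future__ import annotations

from .base import (
    ConfiguredModel,
    ModelDefinition,
    ParameterDescriptor,
    PerturbationSet,
    neutral_vector,
)

__all__ = [
    "ConfiguredModel",
    "ModelDefinition",
    "ParameterDescriptor",
    "PerturbationSet",
    "neutral_vector",
    "available_models",
    "get_model",
    "get_parameter_registry",
    "apply_perturbation",
]

_DEFINITIONS: dict[str, ModelDefinition] = {}


def _load() -> None:
    if _DEFINITIONS:
        return
    from . import lr91, lr09, tp06

    for d in (
        lr91.DEFINITION,
        lr09.DEFINITION,
        tp06.EPI,
        tp06.MID,
        tp06.ENDO,
    ):
        _DEFINITIONS[d.model_id] = d


def available_models() -> list[str]:
    _load()
    return sorted(_DEFINITIONS)


def get_model(model_id: str) -> ModelDefinition:
    _load()
    try:
        return _DEFINITIONS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available models: {available_models()}"
        ) from None


def get_parameter_registry(model_id: str) -> list[ParameterDescriptor]:
    """Full varied-parameter registry of ``model_id`` in stable order."""
    return list(get_model(model_id).registry)


def apply_perturbation(model_id: str, perturbation=None) -> ConfiguredModel:
    """Configured instance of ``model_id`` with ``perturbation`` applied.

    ``perturbation`` maps parameter names to scale factors (G/K/p categories)
    or additive mV shifts (V category); ``None`` or ``{}`` gives the baseline.
    """
    return get_model(model_id).configure(perturbation)
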