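"""Common infrastructure for ventricular myocyte model definitions.

Every model exposes the same surface: a typed parameter registry, a roster of
membrane currents (sign convention: outward positive, units A/F), published
initial conditions, and two numba-compiled kernels:

``step(y, p, dt, istim)``
    advance the state vector ``y`` in place by ``dt`` ms.  Hodgkin-Huxley
    gates use Rush-Larsen exponential updates; voltage and concentrations use
    forward Euler.  ``p`` is the flat parameter vector (scale factors for
    G/K/p entries, additive mV shifts for V entries).

``currents(y, p, out)``
    write all roster currents (A/F, outward positive) into ``out``.

Parameter categories
--------------------
G   maximal conductance / permeability (multiplicative scale factor)
K   maximal transport rate: pumps, exchangers, SR fluxes (scale factor)
p   gating-rate scale factor; ``tau_eff = tau / p`` so *decreasing* p slows
    the gate
V   additive shift (mV) of a steady-state activation/inactivation curve;
    the time constant is evaluated at the unshifted voltage
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

CATEGORIES = ("G", "K", "p", "V")


@dataclass(frozen=True)
class ParameterDescriptor:
    """One entry of a model's varied-parameter registry."""

    name: str
    category: str  # one of G, K, p, V
    baseline: float  # native units; 0.0 (mV shift) for V-category
    units: str
    target: str  # human-readable description of what it modifies

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if self.category in ("G", "K", "p") and not self.baseline > 0:
            raise ValueError(f"{self.name}: baseline must be > 0 for category {self.category}")
        if self.category == "V" and self.baseline != 0.0:
            raise ValueError(f"{self.name}: V-category baseline is a 0 mV shift by definition")


class PerturbationSet(Mapping):
    """Map parameter name -> scale factor (G/K/p) or additive mV shift (V).

    An empty set denotes the baseline model.  Validation against a registry
    happens in :meth:`to_vector`.
    """

    def __init__(self, values: Mapping[str, float] | None = None):
        self._values = dict(values or {})

    def __getitem__(self, k):
        return self._values[k]

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def __repr__(self):
        return f"PerturbationSet({self._values!r})"

    def to_vector(self, registry: list[ParameterDescriptor]) -> np.ndarray:
        """Resolve against ``registry``, returning the flat parameter vector.

        Vector entries hold *effective* values: ``baseline * scale`` for
        G/K/p parameters and the additive mV shift for V parameters.
        """
        index = {d.name: i for i, d in enumerate(registry)}
        unknown = set(self._values) - set(index)
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {sorted(unknown)}; registry has {sorted(index)}"
            )
        vec = neutral_vector(registry)
        for name, value in self._values.items():
            d = registry[index[name]]
            if d.category in ("G", "K", "p"):
                if not value > 0:
                    raise ValueError(
                        f"{name} is category {d.category}: scale factor must be > 0, got {value}"
                    )
                vec[index[name]] = d.baseline * float(value)
            else:
                vec[index[name]] = float(value)
        return vec


def neutral_vector(registry: list[ParameterDescriptor]) -> np.ndarray:
    """Parameter vector of the unperturbed model: baselines, 0.0 mV shifts."""
    return np.array(
        [0.0 if d.category == "V" else d.baseline for d in registry], dtype=np.float64
    )


@dataclass(frozen=True)
class ModelDefinition:
    """A ventricular myocyte ODE model plus its registry and current roster."""

    model_id: str
    species: str
    layer: str | None
    citation: str
    state_names: tuple[str, ...]
    initial_state: np.ndarray
    registry: tuple[ParameterDescriptor, ...]
    current_names: tuple[str, ...]  # roster order used by the currents kernel
    stim_amplitude: float  # A/F, negative = depolarizing
    stim_duration: float  # ms
    default_sigma_log: float  # population sampling sigma used in the study
    dt_fine: float  # ms, integration step during the AP
    dt_coarse: float  # ms, integration step in diastole
    step: Callable = field(repr=False, compare=False, default=None)
    currents: Callable = field(repr=False, compare=False, default=None)
    # structural constants appended to the parameter vector (e.g. layer flags)
    const_params: tuple[float, ...] = ()

    def __post_init__(self):
        names = [d.name for d in self.registry]
        if len(names) != len(set(names)):
            raise ValueError(f"{self.model_id}: duplicate registry names")
        if len(self.initial_state) != len(self.state_names):
            raise ValueError(f"{self.model_id}: initial state/state-name length mismatch")

    @property
    def parameter_names(self) -> list[str]:
        return [d.name for d in self.registry]

    def configure(self, perturbation: PerturbationSet | Mapping[str, float] | None = None):
        """Return a :class:`ConfiguredModel` with ``perturbation`` applied.

        The definition itself is immutable; configuring never touches the
        baseline.
        """
        if not isinstance(perturbation, PerturbationSet):
            perturbation = PerturbationSet(perturbation)
        vec = perturbation.to_vector(list(self.registry))
        if self.const_params:
            vec = np.concatenate([vec, np.asarray(self.const_params, dtype=np.float64)])
        return ConfiguredModel(self, vec, perturbation)

    def baseline(self):
        return self.configure(None)


@dataclass(frozen=True)
class ConfiguredModel:
    """A model definition bound to a concrete parameter vector."""

    definition: ModelDefinition
    params: np.ndarray
    perturbation: PerturbationSet

    @property
    def model_id(self) -> str:
        return self.definition.model_id

    def evaluate_currents(self, state: np.ndarray) -> dict[str, float]:
        """All roster currents (A/F, outward positive) at ``state``."""
        state = np.asarray(state, dtype=np.float64)
        if state.shape != (len(self.definition.state_names),):
            raise ValueError(
                f"state must have shape ({len(self.definition.state_names)},), got {state.shape}"
            )
        if not np.all(np.isfinite(state)):
            raise ValueError("state contains non-finite values")
        out = np.empty(len(self.definition.current_names), dtype=np.float64)
        self.definition.currents(state, self.params, out)
        return dict(zip(self.definition.current_names, out))

    def total_ionic_current(self, state: np.ndarray) -> float:
        """Sum of roster currents; equals -dV/dt - I_stim (A/F)."""
        return float(sum(self.evaluate_currents(state).values()))
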