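"""Expanded learning rules: prediction, erasure, and passive forgetting.

All three operate on a :class:`~san.network.NetworkState` in place.
Thresholds in :class:`BehaviorConfig` are expressed in multiples of
``v_on`` (the natural unit of programmed weights) and converted to
absolute values by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkState
from .schema import Memory

__all__ = [
    "BehaviorConfig",
    "apply_predictive",
    "apply_erase",
    "apply_forgetting",
    "presynaptic_sums",
    "erase_threshold_from_similarity",
]

# Relative slack on threshold comparisons: k weights programmed at v_on
# sum to k*v_on only up to floating rounding.
_TH_RTOL = 1e-9


@dataclass
class BehaviorConfig:
    """Enable flags and thresholds (thresholds in multiples of ``v_on``)."""

    predictive_enabled: bool = False
    p_th: float = 6.0
    erase_enabled: bool = False
    r_th: float = 400.0
    forgetting_enabled: bool = False
    d_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.predictive_enabled and self.p_th <= 0:
            raise ValueError("p_th must be positive when predictive is enabled")
        if self.erase_enabled and self.r_th <= 0:
            raise ValueError("r_th must be positive when erase is enabled")
        # d_rate == 1 is a degenerate but valid setting: full decay each step.
        if not 0.0 <= self.d_rate <= 1.0:
            raise ValueError("d_rate must be in [0, 1]")

    @property
    def any_enabled(self) -> bool:
        return self.predictive_enabled or self.erase_enabled or self.forgetting_enabled

    def to_dict(self) -> dict:
        return {
            "predictive": {"enabled": self.predictive_enabled, "p_th": self.p_th},
            "erase": {"enabled": self.erase_enabled, "r_th": self.r_th},
            "forgetting": {"enabled": self.forgetting_enabled, "d_rate": self.d_rate},
        }


def apply_predictive(state: NetworkState, m: Memory, p_th: float) -> int:
    """Associate high-feedback bystander neurons with the clamped memory.

    During association of ``m`` (all of its features clamped), any neuron
    *not* receiving external input whose output reaches ``p_th``
    (absolute threshold) gains ``v_on`` links in both directions to every
    clamped feature in a different set.  Single non-cascading sweep; the
    trigger set is computed from a snapshot before any weights change.
    Returns the number of triggered neurons ("predictions made").
    """
    m.validate(state.schema)
    ids = state.memory_neurons(m)
    feedback = state.weights[ids].sum(axis=0) * state.e_mag
    mask = feedback >= p_th * (1.0 - _TH_RTOL)
    mask[ids] = False
    triggered = np.flatnonzero(mask)
    set_of = state.set_of
    for q in triggered:
        partners = ids[set_of[ids] != set_of[q]]
        state.weights[partners, q] = state.v_on
        state.weights[q, partners] = state.v_on
    return int(triggered.size)


def presynaptic_sums(state: NetworkState) -> np.ndarray:
    """Per-neuron sum of incoming (pre-synaptic) weights, shape ``(N,)``."""
    return state.weights.sum(axis=0)


def apply_erase(
    state: NetworkState, r_th: float
) -> tuple[NetworkState, np.ndarray, np.ndarray]:
    """Reset all weights of over-connected neurons.

    Every neuron whose incoming weight sum reaches ``r_th`` (absolute
    threshold, evaluated on a snapshot before any zeroing) has its full
    incoming column and outgoing row cleared.  Returns
    ``(state, erased_neuron_ids, their_pre_sums)``; a non-empty id array
    is one "erasure event".
    """
    if r_th <= 0:
        raise ValueError("r_th must be positive")
    sums = presynaptic_sums(state)
    erased = np.flatnonzero(sums >= r_th * (1.0 - _TH_RTOL))
    pre_sums = sums[erased].copy()
    if erased.size:
        state.weights[erased, :] = 0.0
        state.weights[:, erased] = 0.0
    return state, erased, pre_sums


def apply_forgetting(state: NetworkState, d_rate: float) -> NetworkState:
    """Multiply every weight by ``(1 - d_rate)``."""
    if not 0.0 <= d_rate <= 1.0:
        raise ValueError("d_rate must be in [0, 1]")
    if d_rate:
        state.weights *= 1.0 - d_rate
    return state


def erase_threshold_from_similarity(i_tot: int, f_sim: float) -> float:
    """Erase threshold sized from a known similarity frequency.

    Returns ``R_th`` in multiples of ``v_on``: ``i_tot * f_sim``, i.e. the
    number of occurrences of the common feature across the dataset.
    """
    if i_tot < 1:
        raise ValueError("i_tot must be >= 1")
    if not 0.0 < f_sim <= 1.0:
        raise ValueError("f_sim must be in (0, 1]")
    r_th = i_tot * f_sim
    if r_th < 1.0:
        raise ValueError(
            f"i_tot * f_sim = {r_th} corresponds to fewer than one occurrence"
        )
    return r_th
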