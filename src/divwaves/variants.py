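"""The published variants of the collapse-driven model.

Each variant is a bundle of three policies layered on the core step:
an optional between-collapse update, a victim-selection rule, and a
collapse/repopulation rule.

========================  =====================================================
name                      behaviour
========================  =====================================================
``basic``                 uniform victim, replace at ``gamma``, common rescale
``neutral_drift``         basic + random walk ``P -> P ± r·P(1−P)`` each step
``exp_fluct``             basic + multiplicative noise ``P -> P·(1 ± n·Ω)``
``interconnected``        alias of basic: the reseed size ``gamma`` is read as
                          the diffusive influx from neighbouring environments
``ktw``                   kill-the-winner: victim chosen ∝ ``P^sigma``
``ktl``                   kill-the-loser: victim chosen ∝ ``P^−0.2``
``fitness``               per-species growth rate Ω_i and collapse weight c_i
``resilience``            per-species Ω_i and survivor ratio γ_i; the victim
                          shrinks (``P -> γ_i·P``) instead of being replaced,
                          so species identities persist for the whole run
========================  =====================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import model as _model

__all__ = [
    "VariantConfig",
    "StepPolicy",
    "validate_variant_params",
    "variant_needs_species_params",
    "sample_species_params",
    "neutral_drift_update",
    "exp_fluct_update",
    "make_variant",
]

#: variant_params keys each variant accepts
_ALLOWED_KEYS = {
    "basic": set(),
    "interconnected": set(),
    "neutral_drift": {"r", "drift_law"},
    "exp_fluct": {"n"},
    "ktw": {"sigma"},
    "ktl": {"ktl_exponent"},
    "fitness": {"omega_range", "c_range", "resample_newcomer_params"},
    "resilience": {"omega_range", "gamma_i_range"},
}

_DRIFT_LAWS = ("linear", "sqrt")

#: smallest representable population in the resilience variant; far below any
#: observable scale, it only prevents multiplicative underflow to exactly 0
POPULATION_FLOOR = 1e-280


def validate_variant_params(variant: str, params: dict) -> None:
    """Reject unknown keys and out-of-range values for the given variant."""
    allowed = _ALLOWED_KEYS.get(variant)
    if allowed is None:
        raise ValueError(f"unknown variant {variant!r}")
    for key in params:
        if key not in allowed:
            raise ValueError(
                f"variant_params key {key!r} does not apply to variant "
                f"{variant!r} (allowed: {sorted(allowed) or 'none'})"
            )
    if "sigma" in params and params["sigma"] < 0:
        raise ValueError("ktw requires sigma >= 0 (use ktl for negative exponents)")
    if "r" in params and params["r"] < 0:
        raise ValueError("drift rate r must be >= 0")
    if "drift_law" in params and params["drift_law"] not in _DRIFT_LAWS:
        raise ValueError(f"drift_law must be one of {_DRIFT_LAWS}")
    if "n" in params and not (0.0 <= params["n"] < 1.0):
        raise ValueError(
            "fluctuation amplitude n must lie in [0, 1): n >= 1 would allow "
            "non-positive populations"
        )
    for key in ("omega_range", "c_range", "gamma_i_range"):
        if key in params:
            lo, hi = params[key]
            if not (0.0 < lo < hi):
                raise ValueError(f"{key} must satisfy 0 < low < high, got {params[key]}")
            if key == "gamma_i_range" and hi >= 1.0:
                raise ValueError("gamma_i_range must stay below 1")


def variant_needs_species_params(variant: str) -> bool:
    return variant in ("fitness", "resilience")


@dataclass
class VariantConfig:
    """Resolved variant parameters (defaults follow the published runs)."""

    name: str = "basic"
    sigma: float = 1.0
    ktl_exponent: float = -0.2
    r: float = 1e-7
    n: float = 0.1
    drift_law: str = "linear"
    omega_range: tuple = (0.1, 1.0)
    c_range: tuple = (0.1, 1.0)
    gamma_i_range: tuple = (1e-9, 1e-2)
    resample_newcomer_params: bool = True

    def __post_init__(self) -> None:
        overrides = {
            k: v for k, v in self.__dict__.items() if k != "name"
        }
        validate_variant_params(
            self.name,
            {k: overrides[k] for k in _ALLOWED_KEYS[self.name] if k in overrides},
        )

    @classmethod
    def from_model_params(cls, params: "_model.ModelParams") -> "VariantConfig":
        return cls(name=params.variant, **params.variant_params)


def sample_species_params(
    config: VariantConfig, rng: np.random.Generator, count: int
) -> "_model.SpeciesParams":
    """Draw per-species traits, log-uniform on the configured ranges.

    Consumption order from ``rng`` is fixed: omega first, then c
    (fitness) or gamma_i (resilience), one ``rng.random(count)`` call
    each.
    """

    def log_uniform(bounds: tuple) -> np.ndarray:
        lo, hi = bounds
        return lo * np.exp(rng.random(count) * math.log(hi / lo))

    if config.name == "fitness":
        return _model.SpeciesParams(
            omega=log_uniform(config.omega_range),
            c=log_uniform(config.c_range),
        )
    if config.name == "resilience":
        return _model.SpeciesParams(
            omega=log_uniform(config.omega_range),
            gamma_i=log_uniform(config.gamma_i_range),
        )
    raise ValueError(f"variant {config.name!r} has no per-species parameters")


# ---------------------------------------------------------------------------
# between-collapse updates


def neutral_drift_update(
    state: "_model.CommunityState",
    r: float,
    rng: np.random.Generator,
    drift_law: str = "linear",
) -> "_model.CommunityState":
    """Community-drift kick between collapses: ``P -> P ± r·P(1−P)``.

    Signs are independent and equiprobable per species (one
    ``rng.random(N)`` draw; u < 0.5 means +).  ``drift_law='sqrt'``
    replaces the magnitude with ``r·sqrt(P(1−P))``, the classical
    sampling-noise scaling.  Negatives are floored at zero, then the
    community is renormalised to sum 1.
    """
    if r < 0:
        raise ValueError("drift rate r must be >= 0")
    if r == 0.0:
        return state
    p = state.populations
    signs = np.where(rng.random(p.size) < 0.5, 1.0, -1.0)
    pq = p * (1.0 - p)
    magnitude = r * pq if drift_law == "linear" else r * np.sqrt(pq)
    p += signs * magnitude
    np.clip(p, 0.0, None, out=p)
    p /= p.sum()
    return state


def exp_fluct_update(
    state: "_model.CommunityState",
    n: float,
    rng: np.random.Generator,
    omega: Optional[np.ndarray] = None,
) -> "_model.CommunityState":
    """Multiplicative fluctuation between collapses: ``P -> P·(1 ± n·Ω)``.

    Ω defaults to 1 for every species when the variant carries no
    per-species growth rates.  The community is renormalised afterwards
    so the carrying capacity stays saturated.
    """
    if not (0.0 <= n < 1.0):
        raise ValueError("amplitude n must lie in [0, 1)")
    if n == 0.0:
        return state
    p = state.populations
    signs = np.where(rng.random(p.size) < 0.5, 1.0, -1.0)
    w = 1.0 if omega is None else omega
    p *= 1.0 + signs * (n * w)
    p /= p.sum()
    return state


# ---------------------------------------------------------------------------
# policy bundles


@dataclass
class StepPolicy:
    """The three pluggable pieces of one collapse step."""

    name: str
    select_victim: Callable  # (state, rng) -> int
    collapse: Callable  # (state, victim, rng, n_substantial, step) -> None
    saturate: Callable  # (state) -> rescale factor
    between_update: Optional[Callable] = None  # (state, rng) -> None


def make_variant(params: "_model.ModelParams") -> StepPolicy:
    """Compose the step policy for ``params.variant``."""
    config = VariantConfig.from_model_params(params)
    gamma = params.gamma

    def uniform_victim(state, rng):
        return _model.select_victim(state.populations, "uniform", rng)

    def replace_collapse(state, victim, rng, n_substantial, t):
        _model.apply_collapse(
            state,
            victim,
            "replace_with_newcomer",
            gamma=gamma,
            n_substantial=n_substantial,
            birth_step=t,
        )

    def common_saturate(state):
        return _model.saturate(state)

    name = config.name
    if name in ("basic", "interconnected"):
        return StepPolicy(name, uniform_victim, replace_collapse, common_saturate)

    if name == "neutral_drift":
        def drift(state, rng):
            neutral_drift_update(state, config.r, rng, config.drift_law)

        return StepPolicy(
            name, uniform_victim, replace_collapse, common_saturate, drift
        )

    if name == "exp_fluct":
        def fluct(state, rng):
            exp_fluct_update(state, config.n, rng)

        return StepPolicy(
            name, uniform_victim, replace_collapse, common_saturate, fluct
        )

    if name in ("ktw", "ktl"):
        sigma = config.sigma if name == "ktw" else config.ktl_exponent

        def weighted_victim(state, rng):
            return _model.select_victim(
                state.populations, "power_weighted", rng, sigma=sigma
            )

        return StepPolicy(name, weighted_victim, replace_collapse, common_saturate)

    if name == "fitness":
        log_omega_lo = math.log(config.omega_range[0])
        log_omega_span = math.log(config.omega_range[1] / config.omega_range[0])
        log_c_lo = math.log(config.c_range[0])
        log_c_span = math.log(config.c_range[1] / config.c_range[0])

        def c_victim(state, rng):
            return _model.select_victim(
                state.populations, "fitness_c", rng, c=state.params_ref.c
            )

        def fitness_collapse(state, victim, rng, n_substantial, t):
            replace_collapse(state, victim, rng, n_substantial, t)
            if config.resample_newcomer_params:
                # fresh traits for the newcomer: omega draw, then c draw
                state.params_ref.omega[victim] = math.exp(
                    log_omega_lo + rng.random() * log_omega_span
                )
                state.params_ref.c[victim] = math.exp(
                    log_c_lo + rng.random() * log_c_span
                )

        def species_saturate(state):
            return _model.saturate(state, state.params_ref.omega)

        return StepPolicy(name, c_victim, fitness_collapse, species_saturate)

    if name == "resilience":
        # repeated multiplicative shrinks can underflow double precision to
        # an absorbing zero; the floor keeps every species recoverable
        floor = POPULATION_FLOOR

        def shrink_collapse(state, victim, rng, n_substantial, t):
            _model.apply_collapse(state, victim, "shrink_by_gamma_i")
            if state.populations[victim] < floor:
                state.populations[victim] = floor

        def species_saturate(state):
            return _model.saturate(state, state.params_ref.omega)

        return StepPolicy(name, uniform_victim, shrink_collapse, species_saturate)

    raise ValueError(f"unknown variant {name!r}")
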