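"""Fixed-N collapse-driven community dynamics.

A community of ``N`` species shares a single environment whose carrying
capacity is normalised to 1.  Between collapses the community sits in the
saturated state (population fractions summing to 1).  Time advances in
discrete steps, one collapse per step:

1. optionally apply a between-collapse update (neutral drift or
   multiplicative fluctuations, see :mod:`divwaves.variants`);
2. pick a victim species according to the variant's selection policy;
3. remove the victim — either replace it by a brand-new species seeded at
   fraction ``gamma`` (the default scheme that keeps ``N`` constant), or
   multiply it by a per-species survivor ratio ``gamma_i``;
4. instantly repopulate the freed capacity: every population grows
   exponentially until the total reaches 1 again ("saturation").

Saturation with a common growth rate reduces to multiplying all
populations by the same factor ``1 / sum(P)``; with per-species growth
rates ``Omega_i`` the endpoint of the logistic competition is
``P_i * exp(Omega_i * A)`` where the scalar ``A`` solves
``sum(P_i * exp(Omega_i * A)) = 1``.

Randomness is consumed from a single :class:`numpy.random.Generator` in a
fixed, documented order per step (between-collapse update draws, then the
victim draw, then any newcomer parameter draws), so runs are exactly
reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "VARIANT_NAMES",
    "ModelParams",
    "SpeciesParams",
    "CommunityState",
    "CollapseEvent",
    "RunSummary",
    "init_community",
    "select_victim",
    "apply_collapse",
    "saturate",
    "equalize_populations",
    "step",
    "simulate",
]

VARIANT_NAMES = (
    "basic",
    "neutral_drift",
    "exp_fluct",
    "interconnected",
    "ktw",
    "ktl",
    "fitness",
    "resilience",
)

#: tolerance on |sum(P) - 1| for a state to count as saturated
SATURATION_TOL = 1e-9


@dataclass
class ModelParams:
    """Configuration of one simulation.

    Parameters
    ----------
    N : int
        Number of species slots; constant over the whole run.
    gamma : float
        Population fraction at which every newcomer species is seeded,
        in units of the carrying capacity; ``0 < gamma < 1``.
    variant : str
        One of :data:`VARIANT_NAMES`.
    variant_params : dict
        Variant-specific scalars (``sigma`` for kill-the-winner, drift
        rate ``r``, fluctuation amplitude ``n``, sampling ranges for the
        fitness/resilience variants).  Keys are validated against the
        declared variant.
    equalize_at_wave_start : bool
        If True, run the simplified model: whenever a dominant species
        (pre-collapse size above ``wave_threshold``) collapses, all
        populations are reset to ``1/N`` instead of being rescaled.
    seed : int, optional
        Seed for the run's random generator.
    wave_threshold : float, optional
        Pre-collapse size above which a collapse counts as a wave
        boundary; defaults to ``1 - 1/N``.
    substantial_threshold : float
        Population cut used when counting "substantial" populations at
        the moment a newcomer is seeded (the cross-wave memory label).
    """

    N: int
    gamma: float
    variant: str = "basic"
    variant_params: dict = field(default_factory=dict)
    equalize_at_wave_start: bool = False
    seed: Optional[int] = None
    carrying_capacity: float = 1.0
    wave_threshold: Optional[float] = None
    substantial_threshold: float = 1e-10

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        self.N = int(self.N)
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma!r}")
        if self.carrying_capacity != 1.0:
            raise ValueError("carrying_capacity is fixed at 1")
        if self.variant not in VARIANT_NAMES:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANT_NAMES}"
            )
        if self.wave_threshold is None:
            self.wave_threshold = 1.0 - 1.0 / self.N
        if not (0.0 < self.wave_threshold < 1.0):
            raise ValueError("wave_threshold must lie in (0, 1)")
        from . import variants  # deferred: variants imports this module

        variants.validate_variant_params(self.variant, self.variant_params)


@dataclass
class SpeciesParams:
    """Per-species traits for the heterogeneous variants (struct of arrays).

    ``omega`` — exponential growth rate used during repopulation;
    ``c`` — relative collapse propensity (victim-selection weight);
    ``gamma_i`` — survivor ratio applied on collapse (``P -> gamma_i * P``).
    Fields not used by the active variant are ``None``.
    """

    omega: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None
    gamma_i: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.omega is not None and np.any(self.omega <= 0):
            raise ValueError("all omega must be > 0")
        if self.c is not None and np.any(self.c < 0):
            raise ValueError("all c must be >= 0")
        if self.gamma_i is not None and not np.all(
            (self.gamma_i > 0) & (self.gamma_i < 1)
        ):
            raise ValueError("all gamma_i must lie in (0, 1)")

    def copy(self) -> "SpeciesParams":
        return SpeciesParams(
            omega=None if self.omega is None else self.omega.copy(),
            c=None if self.c is None else self.c.copy(),
            gamma_i=None if self.gamma_i is None else self.gamma_i.copy(),
        )


@dataclass
class CommunityState:
    """Snapshot of the community at a given collapse step.

    ``populations[i]`` is the fraction of the carrying capacity held by
    the species in slot ``i``; ``species_id`` labels are unique over the
    whole run; ``birth_step`` records when the slot's current occupant was
    seeded; ``n_substantial_at_birth`` is the number of populations above
    the substantial threshold at that moment.
    """

    populations: np.ndarray
    species_id: np.ndarray
    birth_step: np.ndarray
    n_substantial_at_birth: np.ndarray
    step: int = 0
    params_ref: Optional[SpeciesParams] = None
    next_species_id: int = 0

    @property
    def N(self) -> int:
        return self.populations.size

    def copy(self) -> "CommunityState":
        return CommunityState(
            populations=self.populations.copy(),
            species_id=self.species_id.copy(),
            birth_step=self.birth_step.copy(),
            n_substantial_at_birth=self.n_substantial_at_birth.copy(),
            step=self.step,
            params_ref=None if self.params_ref is None else self.params_ref.copy(),
            next_species_id=self.next_species_id,
        )

    def is_saturated(self, tol: float = SATURATION_TOL) -> bool:
        return abs(float(self.populations.sum()) - 1.0) <= tol


@dataclass(slots=True)
class CollapseEvent:
    """Record of one collapse step.

    ``rescale_factor`` is the total-mass ratio ``1 / sum(P)`` measured
    just before saturation; with a common growth rate it is exactly the
    multiplicative factor applied to every survivor.
    """

    step: int
    victim_index: int
    victim_species_id: int
    victim_birth_step: int
    victim_n_substantial_at_birth: int
    pre_collapse_size: float
    is_wave_boundary: bool
    rescale_factor: float
    n_substantial: int  # populations above threshold just before the collapse


@dataclass
class RunSummary:
    """What :func:`simulate` returns: bookkeeping, not statistics."""

    params: ModelParams
    n_steps: int
    n_wave_boundaries: int
    final_state: CommunityState


# ---------------------------------------------------------------------------
# elementary operations


def init_community(
    params: ModelParams, rng: Optional[np.random.Generator] = None
) -> CommunityState:
    """Uniform initial condition: N species, each at 1/N.

    For heterogeneous variants the per-species traits are drawn here
    (first use of the run's random stream).
    """
    from . import variants

    N = params.N
    state = CommunityState(
        populations=np.full(N, 1.0 / N),
        species_id=np.arange(N, dtype=np.int64),
        birth_step=np.zeros(N, dtype=np.int64),
        n_substantial_at_birth=np.zeros(N, dtype=np.int64),
        step=0,
        next_species_id=N,
    )
    if variants.variant_needs_species_params(params.variant):
        if rng is None:
            rng = np.random.default_rng(params.seed)
        state.params_ref = variants.sample_species_params(
            variants.VariantConfig.from_model_params(params), rng, N
        )
    return state


def select_victim(
    populations: np.ndarray,
    policy: str,
    rng: np.random.Generator,
    *,
    sigma: Optional[float] = None,
    c: Optional[np.ndarray] = None,
) -> int:
    """Draw the index of the species that collapses this step.

    ``uniform`` picks every slot with equal probability; ``power_weighted``
    with probability proportional to ``P_i ** sigma`` (sigma > 0 is
    kill-the-winner, sigma < 0 kill-the-loser); ``fitness_c`` proportional
    to the per-species propensity ``c_i``.

    Every policy consumes exactly one uniform double from ``rng`` per
    call, so switching policies does not shift the random stream of the
    rest of the run.
    """
    n = populations.size
    if policy == "uniform":
        return min(int(rng.random() * n), n - 1)
    if policy == "power_weighted":
        if sigma is None:
            raise ValueError("power_weighted selection requires sigma")
        if sigma == 0.0:
            return min(int(rng.random() * n), n - 1)
        if sigma < 0 and np.any(populations <= 0.0):
            raise ValueError(
                "power_weighted selection with sigma < 0 is undefined for "
                "zero populations"
            )
        weights = populations if sigma == 1.0 else populations**sigma
    elif policy == "fitness_c":
        if c is None:
            raise ValueError("fitness_c selection requires the c array")
        weights = c
    else:
        raise ValueError(f"unknown victim-selection policy {policy!r}")
    cum = np.cumsum(weights)
    u = rng.random() * cum[-1]
    return int(np.searchsorted(cum, u, side="right"))


def apply_collapse(
    state: CommunityState,
    victim_index: int,
    mode: str = "replace_with_newcomer",
    *,
    gamma: Optional[float] = None,
    n_substantial: Optional[int] = None,
    birth_step: Optional[int] = None,
) -> CommunityState:
    """Remove the victim, leaving the state unsaturated (sum < 1).

    ``replace_with_newcomer`` puts a brand-new species (fresh id) in the
    victim's slot at population ``gamma``; ``shrink_by_gamma_i`` keeps the
    species and multiplies its population by its survivor ratio.
    The state is modified in place and returned.
    """
    if mode == "replace_with_newcomer":
        if gamma is None:
            raise ValueError("replace_with_newcomer requires gamma")
        if n_substantial is None:
            n_substantial = int(
                np.count_nonzero(state.populations > 1e-10)
            )
        state.populations[victim_index] = gamma
        state.species_id[victim_index] = state.next_species_id
        state.next_species_id += 1
        state.birth_step[victim_index] = (
            state.step + 1 if birth_step is None else birth_step
        )
        state.n_substantial_at_birth[victim_index] = n_substantial
    elif mode == "shrink_by_gamma_i":
        if state.params_ref is None or state.params_ref.gamma_i is None:
            raise ValueError("shrink_by_gamma_i requires per-species gamma_i")
        state.populations[victim_index] *= state.params_ref.gamma_i[victim_index]
    else:
        raise ValueError(f"unknown collapse mode {mode!r}")
    return state


def saturate(
    state: CommunityState, omega: Optional[np.ndarray] = None
) -> float:
    """Return the community to the carrying capacity; return 1/sum(P).

    With a common growth rate (``omega is None``) every population is
    multiplied by ``1 / sum(P)``.  With per-species rates the logistic
    endpoint is ``P_i * exp(omega_i * A)`` with ``A`` the unique root of
    ``sum(P_i * exp(omega_i * A)) = 1``; the root is bracketed by
    ``[0, ln(1/sum P) / min(omega)]`` and solved to relative tolerance
    1e-12, then the result is renormalised exactly.

    Small overshoot (``sum(P)`` slightly above 1, which between-collapse
    fluctuations can cause when a newcomer replaces a victim that had
    drifted below ``gamma``) is handled symmetrically by shrinking
    (``A < 0``).  A total more than 10% above capacity indicates a caller
    bug and raises.
    """
    p = state.populations
    s = float(p.sum())
    if s <= 0.0:
        raise ValueError("total population is zero: community extinct")
    if s > 1.1:
        raise ValueError(f"total population {s} exceeds the carrying capacity")
    factor = 1.0 / s
    if abs(s - 1.0) < 1e-15:
        return 1.0  # already saturated: identity (A = 0)
    if omega is None:
        p *= factor
        return factor
    omega = np.asarray(omega, dtype=float)
    log_deficit = math.log(factor)  # negative when shrinking
    a_far = log_deficit / float(omega.min())

    def mass_excess(a: float) -> float:
        return float(np.sum(p * np.exp(omega * a))) - 1.0

    # the analytic far bracket can round to the wrong side when rates are equal
    if s < 1.0:
        while mass_excess(a_far) < 0.0:
            a_far *= 1.0 + 1e-6
        lo, hi = 0.0, a_far
    else:
        while mass_excess(a_far) > 0.0:
            a_far *= 1.0 + 1e-6
        lo, hi = a_far, 0.0
    a = brentq(mass_excess, lo, hi, xtol=1e-15 * max(abs(a_far), 1.0), rtol=1e-14)
    p *= np.exp(omega * a)
    p /= p.sum()  # kill the residual of the root solve
    return factor


def equalize_populations(state: CommunityState) -> CommunityState:
    """Reset every population to 1/N, keeping identities (simplified model)."""
    state.populations[:] = 1.0 / state.N
    return state


# ---------------------------------------------------------------------------
# the step and the run loop


def step(
    state: CommunityState,
    params: ModelParams,
    rng: np.random.Generator,
    policy=None,
    on_pre_saturation: Optional[Callable[[np.ndarray, "CollapseEvent"], None]] = None,
) -> tuple[CommunityState, CollapseEvent]:
    """Advance the community by one collapse event.

    Order of operations: between-collapse update (variant hook), victim
    selection, event record, collapse, optional pre-saturation snapshot
    callback at wave boundaries, then saturation (or equalisation at wave
    starts in the simplified model).  The state is modified in place.
    """
    if policy is None:
        from . import variants

        policy = variants.make_variant(params)

    if policy.between_update is not None:
        policy.between_update(state, rng)

    p = state.populations
    victim = policy.select_victim(state, rng)
    pre_size = float(p[victim])
    is_boundary = pre_size > params.wave_threshold
    n_sub = int(np.count_nonzero(p > params.substantial_threshold))
    t = state.step + 1

    event = CollapseEvent(
        step=t,
        victim_index=victim,
        victim_species_id=int(state.species_id[victim]),
        victim_birth_step=int(state.birth_step[victim]),
        victim_n_substantial_at_birth=int(state.n_substantial_at_birth[victim]),
        pre_collapse_size=pre_size,
        is_wave_boundary=is_boundary,
        rescale_factor=1.0,
        n_substantial=n_sub,
    )

    policy.collapse(state, victim, rng, n_sub, t)

    if is_boundary and on_pre_saturation is not None:
        on_pre_saturation(p.copy(), event)

    if params.equalize_at_wave_start and is_boundary:
        event.rescale_factor = 1.0 / float(p.sum())
        equalize_populations(state)
    else:
        event.rescale_factor = policy.saturate(state)

    state.step = t
    return state, event


def simulate(
    params: ModelParams,
    n_steps: int,
    recorders: Sequence = (),
    rng: Optional[np.random.Generator] = None,
) -> RunSummary:
    """Run ``n_steps`` collapse events from the uniform initial condition.

    Every recorder's ``on_step(state, event)`` is called after each full
    step; recorders that override ``on_pre_saturation`` additionally see
    the unsaturated populations at wave boundaries.  Deterministic given
    ``params.seed`` (or the supplied generator).
    """
    from . import variants
    from .recorders import Recorder

    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    policy = variants.make_variant(params)
    state = init_community(params, rng)

    for rec in recorders:
        rec.start(state, params)

    pre_hooks = [
        rec
        for rec in recorders
        if type(rec).on_pre_saturation is not Recorder.on_pre_saturation
    ]
    if pre_hooks:

        def _pre_cb(populations: np.ndarray, event: CollapseEvent) -> None:
            for rec in pre_hooks:
                rec.on_pre_saturation(populations, event)

    else:
        _pre_cb = None

    n_boundaries = 0
    for _ in range(n_steps):
        state, event = step(state, params, rng, policy, on_pre_saturation=_pre_cb)
        if event.is_wave_boundary:
            n_boundaries += 1
        for rec in recorders:
            rec.on_step(state, event)

    for rec in recorders:
        rec.finish(state)

    return RunSummary(
        params=params,
        n_steps=n_steps,
        n_wave_boundaries=n_boundaries,
        final_state=state,
    )
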