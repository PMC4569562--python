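"""Observables and estimators for collapse-driven runs.

Covers the emergent quantities of the model: the inverse-Simpson
diversity trace, wave segmentation and per-wave statistics (durations,
diversity decay constants, survivor curves), time-aggregated and
snapshot species abundance distributions (SADs), power-law tail
exponents, survivor-jump series, and the trait-vs-abundance maps of the
heterogeneous variants.

Conventions
-----------
* Abundances are fractions of the carrying capacity, so SAD support is
  a sub-interval of (0, 1].
* The log-binned density is ``pi(P) = dProb(P_i > P)/dlog10 P``; a tail
  ``dProb/dP ∝ P^-tau`` therefore appears as a log-binned slope of
  ``-(tau - 1)``.
* Step indices are 1-based: the diversity trace entry at array index
  ``t - 1`` is the state after step ``t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "diversity",
    "SADHistogram",
    "accumulate_sad",
    "WaveStats",
    "detect_waves",
    "TailFit",
    "fit_powerlaw_tail",
    "sample_truncated_powerlaw",
    "InterpeakFit",
    "interpeak_slope",
    "WaveSummary",
    "wave_statistics",
    "survivor_decay_rates",
    "jump_series",
    "jump_growth_rate",
    "fitness_population_map",
    "trait_marginal",
]


def diversity(populations: np.ndarray) -> float:
    """Inverse Simpson index ``D = 1 / sum(P_i^2)``.

    Ranges from 1 (one species holds everything) to N (perfectly even
    community).
    """
    p = np.asarray(populations, dtype=float)
    ss = float(np.dot(p, p))
    if ss == 0.0:
        raise ValueError("all populations are zero; diversity undefined")
    return 1.0 / ss


# ---------------------------------------------------------------------------
# species abundance distribution


class SADHistogram:
    """Streaming log10-binned abundance histogram.

    Bins have constant width ``1 / bins_per_decade`` in log10 P, with the
    top edge pinned at P = 1.  Each call to :meth:`add` increments one
    bin per species; the support is extended downwards on demand (the
    resilience variant can push populations below any preset floor).
    """

    def __init__(self, low: float, high: float = 1.0, bins_per_decade: int = 5):
        if not (0.0 < low < high <= 1.0):
            raise ValueError("need 0 < low < high <= 1")
        if bins_per_decade < 1:
            raise ValueError("bins_per_decade must be >= 1")
        self.bins_per_decade = int(bins_per_decade)
        n_bins = math.ceil(-math.log10(low) * self.bins_per_decade - 1e-9)
        self._lo_log = -n_bins / self.bins_per_decade  # top edge exactly 0
        self.counts = np.zeros(n_bins, dtype=np.int64)
        self.n_snapshots = 0
        self.n_species: Optional[int] = None

    # -- geometry ----------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def log10_bin_edges(self) -> np.ndarray:
        return self._lo_log + np.arange(self.n_bins + 1) / self.bins_per_decade

    @property
    def bin_width(self) -> float:
        """Bin width in log10 units."""
        return 1.0 / self.bins_per_decade

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers, in abundance units."""
        e = self.log10_bin_edges
        return 10.0 ** ((e[:-1] + e[1:]) / 2.0)

    # -- accumulation ------------------------------------------------------

    def _extend_low(self, extra_bins: int) -> None:
        extra = math.ceil(extra_bins / self.bins_per_decade) * self.bins_per_decade
        self.counts = np.concatenate([np.zeros(extra, dtype=np.int64), self.counts])
        self._lo_log -= extra / self.bins_per_decade

    def add(self, populations: np.ndarray) -> "SADHistogram":
        """Bin every population of one saturated snapshot."""
        p = np.asarray(populations, dtype=float)
        if p.size == 0:
            raise ValueError("empty population vector")
        if self.n_species is None:
            self.n_species = p.size
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.log10(p)  # NaN for negatives, -inf for zeros: caught below
        t -= self._lo_log
        t *= self.bins_per_decade
        lo = t.min()
        if not lo >= 0.0:
            if np.isnan(lo) or np.isinf(lo):
                raise ValueError("non-positive population cannot be log-binned")
            self._extend_low(int(math.ceil(-lo)))
            t = (np.log10(p) - self._lo_log) * self.bins_per_decade
        idx = t.astype(np.intp)  # trunc == floor for non-negative values
        n = self.n_bins
        if idx.max() >= n:  # P == 1 (or fp overshoot) lands in the top bin
            idx[idx >= n] = n - 1
        self.counts += np.bincount(idx, minlength=n)
        self.n_snapshots += 1
        return self

    def merge(self, other: "SADHistogram") -> "SADHistogram":
        """Pool another histogram (same binning) into this one."""
        if other.bins_per_decade != self.bins_per_decade:
            raise ValueError("cannot merge histograms with different binning")
        if other.n_species is not None:
            if self.n_species is None:
                self.n_species = other.n_species
            elif self.n_species != other.n_species:
                raise ValueError("cannot merge histograms with different N")
        shift = round((other._lo_log - self._lo_log) * self.bins_per_decade)
        if shift < 0:
            self._extend_low(-shift)
            shift = round((other._lo_log - self._lo_log) * self.bins_per_decade)
        if shift + other.n_bins > self.n_bins:
            raise ValueError("histogram supports are incompatible at the top edge")
        self.counts[shift : shift + other.n_bins] += other.counts
        self.n_snapshots += other.n_snapshots
        return self

    def __iadd__(self, other: "SADHistogram") -> "SADHistogram":
        return self.merge(other)

    # -- read-out ----------------------------------------------------------

    def density(self) -> np.ndarray:
        """Normalised density: integrates to 1 over log10 P."""
        if self.n_snapshots == 0 or not self.n_species:
            raise ValueError("empty histogram has no density")
        norm = self.n_snapshots * self.n_species * self.bin_width
        return self.counts / norm

    def to_frame(self) -> pd.DataFrame:
        e = self.log10_bin_edges
        return pd.DataFrame(
            {
                "bin_low": 10.0 ** e[:-1],
                "bin_high": 10.0 ** e[1:],
                "count": self.counts,
                "density": self.density()
                if self.n_snapshots
                else np.zeros(self.n_bins),
            }
        )


def accumulate_sad(histogram: SADHistogram, state) -> SADHistogram:
    """Add one community snapshot to a time-aggregated histogram."""
    return histogram.add(state.populations)


# ---------------------------------------------------------------------------
# wave segmentation


@dataclass
class WaveStats:
    """Wave boundaries (step indices) and the durations between them."""

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("wave boundaries must be strictly increasing")

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def n_complete_waves(self) -> int:
        return max(self.boundaries.size - 1, 0)


def _events_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events
    from .recorders import EVENT_COLUMNS

    return pd.DataFrame(
        {col: [getattr(e, col) for e in events] for col in EVENT_COLUMNS}
    )


def detect_waves(
    events, N: Optional[int] = None, threshold: Optional[float] = None
) -> WaveStats:
    """Segment a run into diversity waves.

    A wave boundary is any collapse whose pre-collapse size exceeds
    ``threshold`` (default ``1 - 1/N``): the elimination of a dominant
    species frees almost the whole carrying capacity and restarts the
    diversity cycle.
    """
    df = _events_frame(events)
    if df.empty:
        return WaveStats(boundaries=np.empty(0, dtype=np.int64))
    if threshold is None:
        if N is None:
            mask = df["is_wave_boundary"].to_numpy(dtype=bool)
        else:
            mask = df["pre_collapse_size"].to_numpy() > 1.0 - 1.0 / N
    else:
        mask = df["pre_collapse_size"].to_numpy() > threshold
    return WaveStats(boundaries=df.loc[mask, "step"].to_numpy(dtype=np.int64))


# ---------------------------------------------------------------------------
# power-law tail


@dataclass
class TailFit:
    """Fitted abundance-distribution tail ``dProb(P_i > P)/dP ∝ P^-tau``."""

    tau: float
    slope: float  # log-binned density slope, -(tau - 1) for logbin_ls
    stderr: float
    fit_range: tuple
    method: str
    n_points: int


def fit_powerlaw_tail(
    data: Union[SADHistogram, np.ndarray],
    fit_range: tuple,
    method: str = "logbin_ls",
) -> TailFit:
    """Estimate the tail exponent tau over ``fit_range = (P_low, P_high)``.

    ``logbin_ls`` (on a histogram): least-squares slope of log10 density
    vs log10 P over the nonempty bins whose centers fall in the range;
    ``tau = 1 - slope``.

    ``mle`` (on raw abundance samples): maximum-likelihood exponent of a
    power-law density truncated to the range — a Hill-type estimator that
    serves as a binning-free cross-check.
    """
    p_low, p_high = fit_range
    if not (0.0 < p_low < p_high):
        raise ValueError("fit_range must satisfy 0 < P_low < P_high")
    if method == "logbin_ls":
        if not isinstance(data, SADHistogram):
            raise TypeError("logbin_ls requires a SADHistogram")
        centers = data.centers
        dens = data.density()
        mask = (centers >= p_low) & (centers <= p_high) & (data.counts > 0)
        if mask.sum() < 4:
            raise ValueError(
                f"need >= 4 nonempty bins in [{p_low:g}, {p_high:g}], "
                f"found {int(mask.sum())}"
            )
        fit = stats.linregress(np.log10(centers[mask]), np.log10(dens[mask]))
        return TailFit(
            tau=1.0 - fit.slope,
            slope=float(fit.slope),
            stderr=float(fit.stderr),
            fit_range=(p_low, p_high),
            method="logbin_ls",
            n_points=int(mask.sum()),
        )
    if method == "mle":
        samples = np.asarray(data, dtype=float)
        x = samples[(samples >= p_low) & (samples <= p_high)]
        if x.size < 10:
            raise ValueError(
                f"need >= 10 samples in [{p_low:g}, {p_high:g}], found {x.size}"
            )
        tau, se = _truncated_powerlaw_mle(x, p_low, p_high)
        return TailFit(
            tau=tau,
            slope=-(tau - 1.0),
            stderr=se,
            fit_range=(p_low, p_high),
            method="mle",
            n_points=int(x.size),
        )
    raise ValueError(f"unknown method {method!r}")


def _truncated_powerlaw_mle(
    x: np.ndarray, a: float, b: float
) -> tuple[float, float]:
    """MLE of tau for density ∝ P^-tau on [a, b]; returns (tau, stderr)."""
    mean_log = float(np.mean(np.log(x)))
    log_a, log_b = math.log(a), math.log(b)

    def expected_log(tau: float) -> float:
        # E[ln P] under the truncated power law with exponent tau
        beta = 1.0 - tau
        if abs(beta) < 1e-9:
            return (log_a + log_b) / 2.0  # log-uniform limit
        ea, eb = a**beta, b**beta
        return (eb * log_b - ea * log_a) / (eb - ea) - 1.0 / beta

    def score(tau: float) -> float:
        return expected_log(tau) - mean_log  # decreasing in tau

    lo, hi = 1e-3, 50.0
    if score(lo) < 0 or score(hi) > 0:
        raise ValueError("sample mean log outside the representable range")
    tau = brentq(score, lo, hi, xtol=1e-10)
    # observed information from the slope of the score
    h = 1e-5
    info = -(score(tau + h) - score(tau - h)) / (2.0 * h)  # Var[ln P] at tau
    se = 1.0 / math.sqrt(x.size * info) if info > 0 else float("nan")
    return tau, se


def sample_truncated_powerlaw(
    tau: float, low: float, high: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. samples from density ∝ P^-tau on [low, high] (inverse CDF)."""
    u = rng.random(size)
    beta = 1.0 - tau
    if abs(beta) < 1e-12:
        return low * np.exp(u * math.log(high / low))
    ea, eb = low**beta, high**beta
    return (ea + u * (eb - ea)) ** (1.0 / beta)


# ---------------------------------------------------------------------------
# intermediate region between the two SAD peaks


@dataclass
class InterpeakFit:
    """Fitted slope of the region connecting the bimodal SAD's peaks."""

    slope: float
    stderr: float
    fit_range: tuple
    lower_peak: float
    upper_peak: float
    n_points: int


def interpeak_slope(
    histogram: SADHistogram,
    N: int,
    gamma: float,
    split: Optional[float] = None,
    margin_decades: float = 0.5,
    min_bins: int = 4,
) -> InterpeakFit:
    """Slope of the log-binned density between the two SAD peaks.

    The lower peak (recently collapsed / newly seeded species, around
    ``gamma`` to ``gamma*N``) and the upper peak (current-wave survivors,
    around ``1/N``) are located as density maxima on either side of
    ``split`` (default ``sqrt(gamma)``, the geometric midpoint of
    ``gamma*N`` and ``1/N``).  The connecting region is the rising flank
    from the density minimum (the dip of the valley between the peaks) up
    to the upper peak; the fit excludes ``margin_decades`` next to the
    dip and the peak to avoid their curvature.
    """
    if split is None:
        split = math.sqrt(gamma)
    centers = histogram.centers
    dens = histogram.density()
    lower_mask = centers < split
    upper_mask = centers >= split
    if not lower_mask.any() or not upper_mask.any():
        raise ValueError("split point leaves no bins on one side")
    lower_peak = centers[lower_mask][np.argmax(dens[lower_mask])]
    upper_peak = centers[upper_mask][np.argmax(dens[upper_mask])]
    between = (centers > lower_peak) & (centers < upper_peak)
    if not between.any():
        raise ValueError("no bins between the detected peaks")
    dip = centers[between][np.argmin(dens[between])]
    p_lo = dip * 10.0**margin_decades
    p_hi = upper_peak / 10.0**margin_decades
    mask = (centers > p_lo) & (centers < p_hi) & (histogram.counts > 0)
    if mask.sum() < min_bins:
        raise ValueError(
            f"only {int(mask.sum())} nonempty bins between the peaks "
            f"({p_lo:g}, {p_hi:g}); peaks too close for a slope fit"
        )
    fit = stats.linregress(np.log10(centers[mask]), np.log10(dens[mask]))
    return InterpeakFit(
        slope=float(fit.slope),
        stderr=float(fit.stderr),
        fit_range=(p_lo, p_hi),
        lower_peak=float(lower_peak),
        upper_peak=float(upper_peak),
        n_points=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# wave statistics


@dataclass
class WaveSummary:
    """Aggregate wave statistics of one run."""

    n_waves: int
    mean_duration: float
    median_duration: float
    decay_constants: np.ndarray = field(repr=False)
    median_decay_constant: float = float("nan")
    mean_decay_constant: float = float("nan")


def _decay_phase_constants(
    t: np.ndarray,
    d: np.ndarray,
    jump_ratio: float = 1.5,
    floor: float = 2.0,
    min_points: int = 20,
    min_efolds: float = 0.5,
) -> list:
    """Decay constants of the decaying phases of one diversity stretch.

    Big redistributions (a sizeable victim's capacity handed to the
    survivors) make D jump upwards mid-wave; the exponential-decay law
    applies between such jumps.  The stretch is split wherever D rises by
    more than ``jump_ratio`` in one step, and each resulting phase is fit
    by least squares on ``ln D`` over its points above ``floor``
    (excluding the monodominant D ~ 1 plateau).  Phases spanning less
    than ``min_efolds`` e-folds are skipped as uninformative.
    """
    rises = np.flatnonzero(d[1:] > jump_ratio * d[:-1]) + 1
    bounds = np.concatenate([[0], rises, [d.size]])
    constants = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        tt, yy = t[a:b], d[a:b]
        keep = yy > floor
        if keep.sum() < min_points:
            continue
        log_y = np.log(yy[keep])
        if np.ptp(log_y) < min_efolds:
            continue
        fit = stats.linregress(tt[keep], log_y)
        if fit.slope < 0:
            constants.append(-1.0 / fit.slope)
    return constants


def wave_statistics(
    waves: WaveStats,
    diversity_trace: np.ndarray,
    trim: float = 0.05,
    min_points: int = 5,
    min_waves: int = 5,
    jump_ratio: float = 1.5,
    floor: float = 2.0,
) -> WaveSummary:
    """Durations and per-wave exponential decay constants of D(t).

    Within each wave the diversity decays as ``exp(-t/N)`` between
    redistribution events; each wave's decay constant is the median over
    its decaying phases (see :func:`_decay_phase_constants`), after
    discarding a fraction ``trim`` of steps at each wave end to avoid
    boundary transients.
    """
    if waves.n_complete_waves < min_waves:
        raise ValueError(
            f"only {waves.n_complete_waves} complete waves; simulate longer "
            f"(need >= {min_waves})"
        )
    d = np.asarray(diversity_trace, dtype=float)
    constants = np.full(waves.n_complete_waves, np.nan)  # aligned per wave
    for w, (b0, b1) in enumerate(zip(waves.boundaries[:-1], waves.boundaries[1:])):
        dur = b1 - b0
        t_lo = b0 + trim * dur
        t_hi = b1 - trim * dur
        t = np.arange(math.ceil(t_lo), math.floor(t_hi) + 1)
        t = t[(t >= 1) & (t <= d.size)]
        if t.size < min_points:
            continue
        phase_constants = _decay_phase_constants(
            t, d[t - 1], jump_ratio=jump_ratio, floor=floor,
            min_points=max(min_points, min(20, t.size // 4)),
        )
        if phase_constants:
            constants[w] = float(np.median(phase_constants))
    durations = waves.durations
    fitted = constants[np.isfinite(constants)]
    return WaveSummary(
        n_waves=waves.n_complete_waves,
        mean_duration=float(durations.mean()),
        median_duration=float(np.median(durations)),
        decay_constants=constants,
        median_decay_constant=float(np.median(fitted)) if fitted.size else float("nan"),
        mean_decay_constant=float(fitted.mean()) if fitted.size else float("nan"),
    )


def survivor_decay_rates(
    events, waves: WaveStats, N: int, min_points: int = 5
) -> np.ndarray:
    """Per-wave fitted decay rate of the survivor count.

    ``N_surv(t)`` counts the species present at the wave start that have
    not yet collapsed ``t`` steps into the wave; with uniform victim
    choice it follows ``N exp(-t/N)``, so the fitted rates should cluster
    at ``1/N``.  The least-squares fit on ``ln N_surv`` uses the points
    with at least 3 survivors.
    """
    df = _events_frame(events)
    steps = df["step"].to_numpy()
    births = df["victim_birth_step"].to_numpy()
    rates = []
    for b0, b1 in zip(waves.boundaries[:-1], waves.boundaries[1:]):
        in_wave = (steps > b0) & (steps <= b1)
        t = steps[in_wave] - b0
        died = births[in_wave] <= b0
        n_surv = N - np.cumsum(died)
        keep = n_surv >= 3
        if keep.sum() < min_points:
            continue
        fit = stats.linregress(t[keep], np.log(n_surv[keep]))
        rates.append(-fit.slope)
    return np.asarray(rates)


# ---------------------------------------------------------------------------
# survivor jumps and cross-wave memory


def jump_value(pre_collapse_size: float, rescale_factor: float = None) -> float:
    """Survivor jump ``-ln(1 - P_collapsed)`` for one collapse.

    When the victim held so much of the capacity that ``1 - P`` underflows
    (possible at extremely small ``gamma``), the jump falls back to the
    log of the rescale factor that was actually applied, which the
    newcomer's seeding keeps finite.
    """
    remainder = 1.0 - pre_collapse_size
    if remainder > 0.0:
        return -math.log1p(-pre_collapse_size)
    if rescale_factor is not None and rescale_factor > 0.0:
        return math.log(rescale_factor)
    raise ValueError("collapse of the entire capacity with no rescale factor")


def jump_series(
    events, substantial_threshold: float = 1e-10
) -> pd.DataFrame:
    """Survivor jumps ``-ln(1 - P_collapsed)`` for substantial collapses.

    Each collapse of a population above the threshold multiplies every
    survivor by ``1/(1 - P_collapsed)``; the jump is that factor's log.
    Points carry the time since the current wave start and the victim's
    substantial-population count at birth (the memory label that colours
    the hierarchical sub-peak structure).  Events before the first wave
    boundary are dropped.
    """
    df = _events_frame(events)
    rows = {"t_in_wave": [], "jump": [], "n_substantial_at_birth": []}
    wave_start = None
    for step_t, pre, boundary, n_sub, factor in zip(
        df["step"], df["pre_collapse_size"], df["is_wave_boundary"],
        df["victim_n_substantial_at_birth"], df["rescale_factor"],
    ):
        if wave_start is not None and pre > substantial_threshold:
            rows["t_in_wave"].append(int(step_t) - wave_start)
            rows["jump"].append(jump_value(pre, factor))
            rows["n_substantial_at_birth"].append(int(n_sub))
        if boundary:
            wave_start = int(step_t)
    return pd.DataFrame(rows)


def jump_growth_rate(
    jumps: pd.DataFrame,
    N: int,
    t_max: Optional[float] = None,
    n_bins: int = 12,
    min_per_bin: int = 5,
) -> float:
    """Exponential growth rate of the mean jump with time in the wave.

    The mean substantial jump grows as ``exp(t/N)/N``, so regressing
    ``ln(mean jump)`` on binned ``t`` should give a slope near ``1/N``.
    The default window covers the first 60% of the typical wave
    (``0.6 N ln N``): beyond that the surviving pool is small and the
    statistic is dominated by rare near-total collapses.
    """
    if t_max is None:
        t_max = 0.6 * N * math.log(N)
    t = jumps["t_in_wave"].to_numpy(dtype=float)
    j = jumps["jump"].to_numpy(dtype=float)
    keep = t <= t_max
    t, j = t[keep], j[keep]
    edges = np.linspace(0.0, t_max, n_bins + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for k in range(n_bins):
        sel = idx == k
        if sel.sum() >= min_per_bin:
            centers.append((edges[k] + edges[k + 1]) / 2.0)
            means.append(j[sel].mean())
    if len(centers) < 4:
        raise ValueError("too few populated time bins for a growth-rate fit")
    fit = stats.linregress(np.asarray(centers), np.log(np.asarray(means)))
    return float(fit.slope)


# ---------------------------------------------------------------------------
# trait maps (heterogeneous variants)


def fitness_population_map(
    mean_populations: np.ndarray,
    x_values: np.ndarray,
    y_values: np.ndarray,
    n_bins: int = 8,
) -> pd.DataFrame:
    """2-D map of mean time-averaged population by two species traits.

    Species are partitioned into a log-spaced ``n_bins x n_bins`` grid on
    ``(x, y)`` (e.g. growth rate Omega vs survivor ratio gamma_i); each
    cell holds the mean of ``<P_i>_t`` over the species falling in it,
    NaN where the cell is empty.  Rows are y bins, columns x bins.
    """
    mp = np.asarray(mean_populations, dtype=float)
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if not (mp.size == x.size == y.size):
        raise ValueError("mean_populations, x_values, y_values must align")

    def edges(v: np.ndarray) -> np.ndarray:
        return np.logspace(
            np.log10(v.min()), np.log10(v.max()), n_bins + 1
        )

    xe, ye = edges(x), edges(y)
    xi = np.clip(np.digitize(x, xe) - 1, 0, n_bins - 1)
    yi = np.clip(np.digitize(y, ye) - 1, 0, n_bins - 1)
    grid = np.full((n_bins, n_bins), np.nan)
    for r in range(n_bins):
        for c in range(n_bins):
            sel = (yi == r) & (xi == c)
            if sel.any():
                grid[r, c] = mp[sel].mean()
    x_centers = np.sqrt(xe[:-1] * xe[1:])
    y_centers = np.sqrt(ye[:-1] * ye[1:])
    return pd.DataFrame(grid, index=y_centers, columns=x_centers)


def trait_marginal(
    mean_populations: np.ndarray, trait_values: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """1-D marginal: mean time-averaged population binned by one trait."""
    mp = np.asarray(mean_populations, dtype=float)
    v = np.asarray(trait_values, dtype=float)
    edges = np.logspace(np.log10(v.min()), np.log10(v.max()), n_bins + 1)
    idx = np.clip(np.digitize(v, edges) - 1, 0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = idx == k
        if sel.any():
            rows.append((math.sqrt(edges[k] * edges[k + 1]), mp[sel].mean(), int(sel.sum())))
    return pd.DataFrame(rows, columns=["trait", "mean_population", "n_species"])
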