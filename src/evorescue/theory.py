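"""Rescue time window and closed-form rescue-probability approximation.

The deterministic flow fixes two first-passage times: ``t_decline``, the
time for the ancestral population to fall from its initial density to the
critical size ``N_c``, and ``t_grow``, the time a single mutant (starting
at the extinction threshold, at stress onset) needs to climb to ``N_c``
against the declining background.  Their difference is the *rescue time
window*: a mutant arising after the window closes cannot reach the
critical size before the ancestors fall below it, so rescue is impossible
no matter the mutation rate.

The rescue probability is the chance that at least one mutant arises while
arising still helps.  Under the Poisson arrival model (rate ``mu * A(t)``)
this is ``P = 1 - exp(-mu * int A(t) dt)`` over the viable arrival span.
Two variants of the span are implemented:

- ``method="arrival"`` (default): the span is computed exactly from the
  deterministic flow by bisecting for the earliest and latest arrival
  times from which a threshold-sized mutant still reaches ``N_c``.  This
  accounts for the saturated phase right after stress onset, when the
  logistic term makes a fresh mutant's net growth negative.
- ``method="window"``: the literal span ``[0, window]``, a cruder but
  fully closed-form-style approximation.

For mutualists the probabilities of the two (rare, independent) arrival
events multiply; the second species' span is evaluated on a background in
which the first species has already adapted, which captures the
competition-accelerated decline of the partner.  The cheater model has no
analytic treatment.

All first-passage times come from dense-output integration plus event
root-finding; the exponential/logistic closed forms serve as cross-checks
in the test-suite only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core_model import ModelParams, derivatives, initial_state
from .engine import _rescue_threshold, _species_slices

__all__ = [
    "TheoryError",
    "RescueWindow",
    "ancestor_decline_time",
    "mutant_growth_time",
    "rescue_window",
    "rescue_probability_theory",
    "viable_arrival_interval",
]

_RTOL = 1e-9
_ATOL = 1e-10
_MAX_HORIZON = 65536.0


class TheoryError(ValueError):
    """A theory computation was requested outside its regime."""


@dataclass(frozen=True)
class RescueWindow:
    """Analytic rescue time window.

    ``window = max(0, t_decline - t_grow)``; for the baseline (no Allee
    effect) the window is the full ancestor extinction time, since a mutant
    arising at any moment before the ancestors die can spread.
    """

    t_decline: float
    t_grow: float
    window: float


def _theory_params_check(params: ModelParams) -> None:
    if params.model_variant == "cheater":
        raise TheoryError(
            "no closed-form rescue approximation exists for the cheater model"
        )


def _mutant_free(params: ModelParams) -> np.ndarray:
    y = initial_state(params).abundances.copy()
    for _, _, mut in _species_slices(params.model_variant):
        y[mut] = 0.0
    return y


def _rhs(params: ModelParams):
    def rhs(t, y):
        return derivatives(y, params)

    return rhs


def _species_total_fn(params: ModelParams, species: int):
    _, anc, mut = _species_slices(params.model_variant)[species]

    def total(y):
        return y[..., anc] + y[..., mut]

    return total


# ---------------------------------------------------------------------------
# First-passage times on the deterministic flow
# ---------------------------------------------------------------------------


def ancestor_decline_time(
    params: ModelParams,
    N_start: float | None = None,
    N_target: float | None = None,
    species: int = 0,
) -> float:
    """First-passage time of the mutant-free flow to a target density.

    Measures the total of ``species`` (species are symmetric in the default
    mutualism setup).  ``N_start`` rescales all ancestors so the measured
    species starts there; ``N_target`` defaults to ``N_c``.  Raises
    :class:`TheoryError` if the flow never reaches the target ("no finite
    decline time").
    """
    _theory_params_check(params)
    if N_target is None:
        N_target = params.N_c
    y0 = _mutant_free(params)
    total = _species_total_fn(params, species)
    start = float(total(y0))
    if N_start is not None:
        if start <= 0:
            raise TheoryError("cannot rescale a zero initial density")
        y0 = y0 * (N_start / start)
        start = N_start
    if N_target >= start:
        if N_target == start:
            return 0.0
        raise TheoryError("N_target must be below the starting density")

    def hit(t, y):
        return total(y) - N_target

    hit.terminal = True
    hit.direction = -1

    horizon = 32.0
    while horizon <= _MAX_HORIZON:
        sol = solve_ivp(
            _rhs(params), (0.0, horizon), y0, method="RK45",
            rtol=_RTOL, atol=_ATOL, events=hit,
        )
        if not sol.success:
            raise TheoryError(f"decline integration failed: {sol.message}")
        if sol.t_events[0].size:
            return float(sol.t_events[0][0])
        horizon *= 4.0
    raise TheoryError("no finite decline time for these parameters")


def mutant_growth_time(
    params: ModelParams,
    N_start: float | None = None,
    N_target: float | None = None,
    species: int = 0,
) -> float:
    """Time for a mutant arising at stress onset to climb to ``N_c``.

    The mutant starts at the extinction threshold on top of the full
    (declining) ancestral background; the logistic term therefore includes
    the background.  Returns ``math.inf`` when the mutant's growth is cut
    off by the background collapse before it reaches the target, and raises
    :class:`TheoryError` when the mutant cannot grow at all
    (``r_M <= delta``).
    """
    _theory_params_check(params)
    _, rM, _ = params.species_rates()
    if rM[species] <= params.delta:
        raise TheoryError("mutant cannot grow: r_M <= delta")
    thr = params.extinction_threshold
    if N_start is None:
        N_start = thr if thr > 0 else 1.0
    if N_target is None:
        N_target = params.N_c
    if N_target <= N_start:
        return 0.0
    y0 = _mutant_free(params)
    mut = _species_slices(params.model_variant)[species][2]
    y0[mut] = N_start

    def hit(t, y):
        return y[mut] - N_target

    hit.terminal = True
    hit.direction = 1

    cap = _growth_cap(params, species)
    sol = solve_ivp(
        _rhs(params), (0.0, cap), y0, method="RK45",
        rtol=_RTOL, atol=_ATOL, events=hit,
    )
    if not sol.success:
        raise TheoryError(f"growth integration failed: {sol.message}")
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return math.inf


def _growth_cap(params: ModelParams, species: int) -> float:
    """Generous horizon for mutant-growth integrations."""
    _, rM, _ = params.species_rates()
    net = float(rM[species]) - params.delta
    R = _rescue_threshold(params)
    base = math.log(max(R, 2.0)) / max(net, 1e-3)
    try:
        t_ext = ancestor_decline_time(
            params, N_target=max(params.extinction_threshold, 1e-6)
        )
    except TheoryError:
        t_ext = 100.0
    return t_ext + 10.0 * base + 20.0


def rescue_window(params: ModelParams) -> RescueWindow:
    """The analytic rescue time window of a parameter set."""
    _theory_params_check(params)
    thr = max(params.extinction_threshold, 1e-6)
    if params.model_variant == "baseline":
        t_dec = ancestor_decline_time(params, N_target=thr)
        return RescueWindow(t_decline=t_dec, t_grow=0.0, window=t_dec)
    t_dec = ancestor_decline_time(params)
    t_grow = mutant_growth_time(params)
    return RescueWindow(
        t_decline=t_dec, t_grow=t_grow, window=max(0.0, t_dec - t_grow)
    )


# ---------------------------------------------------------------------------
# Deterministic background with arrival-exposure quadrature
# ---------------------------------------------------------------------------


class _Background:
    """Dense mutant-free trajectory with cumulative ancestor exposure.

    The augmented states ``z_s(t) = int_0^t A_s dt`` turn every arrival
    integral into two evaluations of the dense solution.
    """

    def __init__(self, params: ModelParams, y0: np.ndarray, t_span):
        self.params = params
        self.slices = _species_slices(params.model_variant)
        self.C = len(params.labels)
        S = len(self.slices)

        def rhs(t, yz):
            dy = derivatives(yz[: self.C], params)
            dz = [yz[anc] for _, anc, _ in self.slices]
            return np.concatenate([dy, dz])

        yz0 = np.concatenate([y0, np.zeros(S)])
        sol = solve_ivp(
            rhs, t_span, yz0, method="RK45", rtol=_RTOL, atol=_ATOL,
            dense_output=True,
        )
        if not sol.success:
            raise TheoryError(f"background integration failed: {sol.message}")
        self.sol = sol
        self.t0 = t_span[0]
        self.t_end = float(sol.t[-1])

    def state(self, t: float) -> np.ndarray:
        return np.maximum(self.sol.sol(t)[: self.C], 0.0)

    def exposure(self, species: int, t: float) -> float:
        return float(self.sol.sol(t)[self.C + species])

    def species_total(self, species: int, t: float) -> float:
        _, anc, mut = self.slices[species]
        y = self.state(t)
        return float(y[anc] + y[mut])


def _stress_background(params: ModelParams) -> _Background:
    thr = max(params.extinction_threshold, 1e-6)
    t_ext = ancestor_decline_time(params, N_target=thr)
    return _Background(params, _mutant_free(params), (0.0, t_ext))


# ---------------------------------------------------------------------------
# Viable arrival span and rescue probability
# ---------------------------------------------------------------------------


def _mutant_can_grow_below(params: ModelParams, species: int) -> bool:
    _, rM, _ = params.species_rates()
    return float(rM[species]) * (1.0 - params.rho) > params.delta


def _survives(
    params: ModelParams,
    bg,
    tau: float,
    species: int,
    cap: float,
    inject_partner: tuple[float, int] | None = None,
) -> bool:
    """Does a threshold-sized mutant arising at ``tau`` reach the critical
    size, deterministically?  ``inject_partner=(t1, sp1)`` adds a partner
    mutant at a later time ``t1`` mid-integration (mutualism conditioning).
    """
    slices = _species_slices(params.model_variant)
    mut = slices[species][2]
    R = _rescue_threshold(params)
    thr = params.extinction_threshold if params.extinction_threshold > 0 else 1.0

    y = np.asarray(bg.state(tau), dtype=float).copy()
    y[mut] += thr

    def success(t, yv):
        return yv[mut] - R

    success.terminal = True
    success.direction = 1

    events = [success]
    # once the Allee reference of the mutant drops below N_c its net growth
    # is negative (rescue-relevant regime), so that crossing is absorbing
    if params.rho > 0 and not _mutant_can_grow_below(params, species):
        if params.model_variant == "cooperation":
            ref_anc, ref_mut = slices[0][1], slices[0][2]
        elif params.model_variant in ("mutualism", "mutualism_no_competition"):
            partner = 1 - species
            ref_anc, ref_mut = slices[partner][1], slices[partner][2]
        else:
            ref_anc = ref_mut = None
        if ref_anc is not None:
            # the partner-reference failure only applies while no partner
            # mutant is being injected below
            def failure(t, yv):
                return yv[ref_anc] + yv[ref_mut] - params.N_c

            failure.terminal = True
            failure.direction = -1
            if inject_partner is None or ref_mut != slices[inject_partner[1]][2]:
                events.append(failure)

    t = tau
    while True:
        t_stop = cap
        if inject_partner is not None and t < inject_partner[0]:
            t_stop = inject_partner[0]
        sol = solve_ivp(
            _rhs(params), (t, t_stop), y, method="RK45",
            rtol=_RTOL, atol=_ATOL, events=events,
        )
        if not sol.success:
            raise TheoryError(f"arrival integration failed: {sol.message}")
        if sol.t_events[0].size:
            return True
        if len(sol.t_events) > 1 and sol.t_events[1].size:
            return False
        if inject_partner is not None and t < inject_partner[0]:
            y = np.maximum(sol.y[:, -1], 0.0)
            y[slices[inject_partner[1]][2]] += thr
            t = float(sol.t[-1])
            inject_partner = None
            continue
        return False


def viable_arrival_interval(
    params: ModelParams,
    species: int = 0,
    bg: "_Background | None" = None,
    inject_partner: tuple[float, int] | None = None,
    n_scan: int = 48,
) -> tuple[float, float] | None:
    """Earliest and latest arrival times of a rescuing mutant.

    Scans the stress phase, then bisects both edges of the viable set to
    about 1e-3 of the scan span.  Returns ``None`` when no arrival time is
    viable (zero rescue probability for every mutation rate).
    """
    _theory_params_check(params)
    _, rM, _ = params.species_rates()
    if rM[species] <= params.delta:
        return None
    if bg is None:
        bg = _stress_background(params)
    t_hi = bg.t_end
    cap = _growth_cap(params, species)

    taus = np.linspace(0.0, t_hi * (1.0 - 1e-9), n_scan)
    flags = [
        _survives(params, bg, float(tau), species, cap, inject_partner)
        for tau in taus
    ]
    if not any(flags):
        return None

    first = flags.index(True)
    last = len(flags) - 1 - flags[::-1].index(True)
    tol = max(t_hi * 1e-3, 1e-6)

    def edge(lo, hi, lo_flag):
        # invariant: survives(lo) == lo_flag != survives(hi)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _survives(params, bg, mid, species, cap, inject_partner) == lo_flag:
                lo = mid
            else:
                hi = mid
        return lo, hi

    if first == 0:
        tau_lo = 0.0
    else:
        lo, hi = edge(taus[first - 1], taus[first], lo_flag=False)
        tau_lo = hi
    if last == len(taus) - 1:
        tau_hi = taus[-1]
    else:
        lo, hi = edge(taus[last], taus[last + 1], lo_flag=True)
        tau_hi = lo
    return float(tau_lo), float(tau_hi)


def _arrival_probability(mu: float, exposure: float) -> float:
    return float(-math.expm1(-mu * max(exposure, 0.0)))


def rescue_probability_theory(params: ModelParams, method: str = "arrival") -> float:
    """Closed-form approximation of the rescue probability.

    See the module docstring for the two methods.  Supported variants:
    baseline, cooperation, and both mutualism forms; the cheater model
    raises :class:`TheoryError`.
    """
    _theory_params_check(params)
    if method not in ("arrival", "window"):
        raise ValueError("method must be 'arrival' or 'window'")
    _, rM, mu = params.species_rates()
    if np.all(mu == 0):
        return 0.0
    if np.any(rM <= params.delta):
        return 0.0

    v = params.model_variant
    if v in ("baseline", "cooperation"):
        return _single_species_probability(params, method)
    if v == "mutualism_no_competition":
        # independent cooperating populations: the joint probability is the
        # product of two single-population probabilities
        p = 1.0
        rA, rM, mu = params.species_rates()
        fracs = (params.initial_fraction, 1.0 - params.initial_fraction)
        K = params.K
        for s in range(2):
            single = params.replace(
                model_variant="cooperation",
                r_A=float(rA[s]),
                r_M=float(rM[s]),
                mu=float(mu[s]),
                r_A2=None,
                r_M2=None,
                mu2=None,
                initial_density=2.0 * fracs[s] * (K if math.isfinite(K) else 1e12),
            )
            p *= _single_species_probability(single, method)
        return p
    return _mutualism_probability(params, method)


def _single_species_probability(params: ModelParams, method: str) -> float:
    bg = _stress_background(params)
    if method == "window":
        w = rescue_window(params).window
        if w <= 0:
            return 0.0
        return _arrival_probability(params.mu, bg.exposure(0, min(w, bg.t_end)))
    iv = viable_arrival_interval(params, 0, bg)
    if iv is None:
        return 0.0
    lo, hi = iv
    return _arrival_probability(params.mu, bg.exposure(0, hi) - bg.exposure(0, lo))


def _mutualism_probability(params: ModelParams, method: str) -> float:
    bg = _stress_background(params)
    _, _, mu = params.species_rates()

    if method == "window":
        p = 1.0
        for s in range(2):
            try:
                t_dec = ancestor_decline_time(params, species=1 - s)
                t_grow = mutant_growth_time(params, species=s)
            except TheoryError:
                return 0.0
            w = max(0.0, t_dec - t_grow)
            if w <= 0:
                return 0.0
            p *= _arrival_probability(
                float(mu[s]), bg.exposure(s, min(w, bg.t_end))
            )
        return p

    # species 1 (index 0): unconditioned viable span
    iv1 = viable_arrival_interval(params, 0, bg)
    if iv1 is None:
        return 0.0
    lo1, hi1 = iv1
    p1 = _arrival_probability(
        float(mu[0]), bg.exposure(0, hi1) - bg.exposure(0, lo1)
    )

    # species 2 (index 1): conditioned on the first adaptation happening at
    # the exposure-weighted mean arrival time within the first span
    tbar = _mean_arrival_time(bg, 0, lo1, hi1)
    iv2 = viable_arrival_interval(
        params, 1, bg, inject_partner=(tbar, 0)
    )
    if iv2 is None:
        return 0.0
    lo2, hi2 = iv2
    exposure2 = _conditioned_exposure(params, bg, tbar, lo2, hi2)
    p2 = _arrival_probability(float(mu[1]), exposure2)
    return p1 * p2


def _mean_arrival_time(bg: _Background, species: int, lo: float, hi: float) -> float:
    """Mean of the arrival density mu*A(t) restricted to [lo, hi]."""
    ts = np.linspace(lo, hi, 101)
    anc = np.array([bg.state(t)[bg.slices[species][1]] for t in ts])
    w = np.trapezoid(anc, ts)
    if w <= 0:
        return 0.5 * (lo + hi)
    return float(np.trapezoid(ts * anc, ts) / w)


def _conditioned_exposure(
    params: ModelParams, bg: _Background, tbar: float, lo: float, hi: float
) -> float:
    """Ancestor-2 exposure over [lo, hi] on the background in which the
    first species' mutant arrived at ``tbar``."""
    anc2 = bg.slices[1][1]
    mut1 = bg.slices[0][2]
    thr = params.extinction_threshold if params.extinction_threshold > 0 else 1.0
    exposure = 0.0
    if lo < tbar:
        t_mid = min(hi, tbar)
        exposure += bg.exposure(1, t_mid) - bg.exposure(1, lo)
    if hi > tbar:
        y0 = bg.state(tbar).copy()
        y0[mut1] += thr
        cond = _Background(params, y0, (tbar, max(hi, tbar + 1e-6)))
        t_lo = max(lo, tbar)
        exposure += cond.exposure(1, hi) - cond.exposure(1, t_lo)
    return exposure
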