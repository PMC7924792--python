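"""Hybrid deterministic-stochastic simulation engine.

Dynamics advance deterministically (an adaptive Runge-Kutta solve of the
variant's ODE) over discrete reporting intervals of length ``dt``; at each
interval boundary, new mutants arrive as a Poisson draw with mean
``mu * A * dt`` per species (``A`` the species' ancestor abundance at the
interval start), and extinction clamping is applied.  No other demographic
stochasticity is modeled.

Clamping zeroes a whole species when its total (ancestor + mutant) falls
below ``extinction_threshold`` (default: one individual).  Clamping by
species rather than by compartment lets a newly arisen mutant lineage dip
transiently below one individual while its ancestral background is still
large — without this, mutants appearing right after stress onset, when the
saturated logistic term makes their net growth momentarily negative, could
never rescue the population (``clamp_mode="compartment"`` restores the
stricter rule).

A replicate ends with one of three verdicts:

- ``rescued``: the variant's rescue criterion held (mutants at or above the
  critical size; both species for mutualism; for the cheater model the
  cooperator mutant must be above ``N_c`` with the cheaters purged, or
  still above ``N_c`` at ``t_max``);
- ``extinct``: every compartment clamped to zero;
- ``undecided_at_t_max``: neither by ``t_max`` (counted as non-rescue).
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core_model import (
    ModelParams,
    PopulationState,
    compartment_labels,
    derivatives,
    initial_state,
    species_names,
)

__all__ = [
    "EngineError",
    "SimulationOutcome",
    "sample_mutants",
    "step",
    "run_simulation",
    "run_replicates",
    "replicate_rng",
    "deterministic_extinction_time",
    "resolve_t_max",
    "burn_in_state",
]

_RTOL = 1e-7
_ATOL = 1e-12
# fallback horizon when the decline time has no finite deterministic bound
_FALLBACK_T_MAX = 200.0
_T_MAX_FACTOR = 10.0


class EngineError(RuntimeError):
    """Raised when the ODE integrator fails; never a silent NaN."""


@dataclass
class SimulationOutcome:
    """Result of one replicate.

    ``mutation_events`` is a list of ``(time, species, count)`` tuples;
    ``trajectory``, when recorded, is a tidy frame with columns
    ``t, species, genotype, abundance`` thinned by the recording stride.
    """

    verdict: str
    verdict_time: float
    final_state: PopulationState
    mutation_events: list[tuple[float, str, int]] = field(default_factory=list)
    trajectory: pd.DataFrame | None = None

    @property
    def rescued(self) -> bool:
        return self.verdict == "rescued"

    def to_json(self) -> str:
        payload = {
            "verdict": self.verdict,
            "verdict_time": self.verdict_time,
            "final_state": {
                "t": self.final_state.t,
                "abundances": {
                    f"{sp}/{gt}": a for (sp, gt), a in self.final_state.as_dict().items()
                },
                "model_variant": self.final_state.model_variant,
            },
            "mutation_events": [
                {"t": t, "species": sp, "count": c}
                for t, sp, c in self.mutation_events
            ],
        }
        return json.dumps(payload, sort_keys=True)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def sample_mutants(
    ancestor_abundance: float, mu: float, dt: float, rng: np.random.Generator
) -> int:
    """Poisson number of new mutants over one interval, mean ``mu * A * dt``.

    Mutants are added to the mutant compartment without decrementing the
    ancestor; for the mutation rates of interest (mu <= 1e-3 per individual
    per unit time) the non-conservation bias is negligible.
    """
    if ancestor_abundance < 0 or mu < 0 or dt < 0:
        raise ValueError("sample_mutants arguments must be non-negative")
    if mu == 0 or ancestor_abundance == 0:
        # zero mean: no draw is consumed from the stream
        return 0
    return int(rng.poisson(mu * ancestor_abundance * dt))


# Dormand-Prince RK5(4) tableau
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = [
    np.array([]),
    np.array([1 / 5]),
    np.array([3 / 40, 9 / 40]),
    np.array([44 / 45, -56 / 15, 32 / 9]),
    np.array([19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729]),
    np.array([9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656]),
    np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84]),
]
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)
_ADV_RTOL = 1e-7
_ADV_ATOL = 1e-10


def _advance(y: np.ndarray, params: ModelParams, t0: float) -> np.ndarray:
    """Advance a batch of states (R, C) by one interval of length dt.

    Embedded Dormand-Prince 5(4) pair with standard step-size control,
    vectorized over all replicates of the batch (the stacked systems are
    independent, so a shared accepted step just has to satisfy the error
    tolerance for every component).  One accepted step usually covers the
    whole reporting interval.
    """
    y = np.asarray(y, dtype=float)
    t_end = params.dt
    t = 0.0
    h = t_end
    while t < t_end - 1e-14:
        h = min(h, t_end - t)
        k = [derivatives(y, params)]
        for stage in range(1, 7):
            ys = y + h * sum(
                a * kk for a, kk in zip(_DP_A[stage], k)
            )
            k.append(derivatives(ys, params))
        y5 = y + h * sum(b * kk for b, kk in zip(_DP_B5, k) if b != 0.0)
        y4 = y + h * sum(b * kk for b, kk in zip(_DP_B4, k) if b != 0.0)
        scale = _ADV_ATOL + _ADV_RTOL * np.maximum(np.abs(y), np.abs(y5))
        err = float(np.sqrt(np.mean(((y5 - y4) / scale) ** 2)))
        if err <= 1.0:
            t += h
            y = y5
            h *= min(5.0, max(0.2, 0.9 * (max(err, 1e-10)) ** -0.2))
        else:
            h *= max(0.2, 0.9 * err**-0.2)
            if h < 1e-12:
                raise EngineError(
                    f"ODE step size underflow at t={t0 + t:.6g} "
                    f"({params.model_variant})"
                )
    if not np.all(np.isfinite(y)):
        raise EngineError(f"non-finite state after integration at t={t0:.6g}")
    # the solve can leave tolerance-level negative residues
    return np.maximum(y, 0.0)


def _species_slices(variant: str) -> list[tuple[str, int, int]]:
    """(name, ancestor column, mutant column) per species, layout order."""
    labels = compartment_labels(variant)
    out = []
    for sp in species_names(variant):
        anc = labels.index((sp, "ancestor"))
        mut = labels.index((sp, "mutant"))
        out.append((sp, anc, mut))
    return out


def _clamp(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Apply extinction clamping to a batch (R, C), in place."""
    thr = params.extinction_threshold
    if params.clamp_mode == "compartment":
        y[y < thr] = 0.0
        return y
    for _, anc, mut in _species_slices(params.model_variant):
        dead = (y[:, anc] + y[:, mut]) < thr
        if dead.any():
            y[dead, anc] = 0.0
            y[dead, mut] = 0.0
    return y


def step(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """One discrete interval: ODE advance, mutant injection, clamping.

    The deterministic advance is independent of ``rng``; with ``mu = 0``
    the whole step is deterministic.
    """
    if state.model_variant != params.model_variant:
        raise ValueError(
            f"state variant {state.model_variant!r} does not match params "
            f"variant {params.model_variant!r}"
        )
    new_state, _ = _step_with_events(state, params, rng)
    return new_state


def _step_with_events(state, params, rng):
    y = _advance(state.abundances[None, :], params, state.t)
    _, _, mu = params.species_rates()
    events = []
    t1 = state.t + params.dt
    for k, (sp, anc, mut) in enumerate(_species_slices(params.model_variant)):
        count = sample_mutants(float(y[0, anc]), float(mu[k]), params.dt, rng)
        if count:
            y[0, mut] += count
            events.append((t1, sp, count))
    _clamp(y, params)
    return (
        PopulationState(t=t1, abundances=y[0], model_variant=params.model_variant),
        events,
    )


# ---------------------------------------------------------------------------
# Time horizon and burn-in
# ---------------------------------------------------------------------------


def deterministic_extinction_time(params: ModelParams) -> float:
    """Time for the mutant-free system to decline below the extinction
    threshold (every species), under the stressed death rate.

    Returns ``math.inf`` when the ancestor persists deterministically.
    The cheater variant is measured from its post-burn-in state.
    """
    y0 = (
        burn_in_state(params).abundances
        if params.model_variant == "cheater"
        else initial_state(params).abundances
    )
    thr = params.extinction_threshold
    slices = _species_slices(params.model_variant)

    def rhs(t, y):
        return derivatives(y, params)

    def all_below(t, y):
        return max(y[anc] + y[mut] for _, anc, mut in slices) - thr

    all_below.terminal = True
    all_below.direction = -1

    horizon = 64.0
    while horizon <= 65536.0:
        sol = solve_ivp(
            rhs, (0.0, horizon), y0, method="RK45", rtol=1e-8, atol=1e-10,
            events=all_below,
        )
        if not sol.success:
            raise EngineError(f"extinction-time integration failed: {sol.message}")
        if sol.t_events[0].size:
            return float(sol.t_events[0][0])
        horizon *= 4.0
    return math.inf


def resolve_t_max(params: ModelParams) -> float:
    """Explicit ``t_max`` if set, else 10x the deterministic extinction time
    (with a fixed fallback horizon when that time is unbounded)."""
    if params.t_max is not None:
        return params.t_max
    t_ext = _cached_extinction_time(params)
    if math.isinf(t_ext):
        return _FALLBACK_T_MAX
    return _T_MAX_FACTOR * t_ext


@functools.lru_cache(maxsize=512)
def _cached_extinction_time(params: ModelParams) -> float:
    return deterministic_extinction_time(params)


@functools.lru_cache(maxsize=512)
def burn_in_state(params: ModelParams) -> PopulationState:
    """Deterministic pre-stress cooperator-cheater state at stress onset.

    Runs the cheater system for ``burn_in_time`` at the pre-stress dilution
    rate ``burn_in_delta`` (no mutation: pre-stress mutants confer no
    advantage relevant to the coming stress), starting from cooperators at
    ``N_c`` and cheaters at ``N_c / 10``.  Shared by all replicates.
    """
    if params.model_variant != "cheater":
        raise ValueError("burn-in only applies to the cheater variant")
    y, _ = _burn_in_path(params, record=False)
    return PopulationState(t=0.0, abundances=y, model_variant="cheater")


def _burn_in_path(params: ModelParams, record: bool):
    # The burn-in is deterministic, so instead of stepping through dt
    # intervals it is integrated in one sweep, restarted whenever a species
    # total crosses the extinction threshold (the clamping events).
    pre = params.replace(delta=params.burn_in_delta, t_max=None)
    y = initial_state(params).abundances.copy()
    slices = _species_slices(params.model_variant)
    thr = params.extinction_threshold

    def rhs(t, yv):
        return derivatives(yv, pre)

    def make_event(anc, mut):
        def ev(t, yv):
            return yv[anc] + yv[mut] - thr

        ev.terminal = True
        ev.direction = -1
        return ev

    t = -params.burn_in_time
    rows: list[tuple[float, np.ndarray]] = []
    while t < -1e-9:
        events = [
            make_event(anc, mut)
            for _, anc, mut in slices
            if y[anc] + y[mut] >= thr
        ]
        sol = solve_ivp(
            rhs, (t, 0.0), y, method="RK45", rtol=_RTOL, atol=_ATOL,
            events=events or None, dense_output=record,
        )
        if not sol.success:
            raise EngineError(f"burn-in integration failed: {sol.message}")
        if record:
            ts = np.arange(t + params.dt, sol.t[-1] + 1e-12, params.dt)
            for tk in ts:
                rows.append((float(tk), np.maximum(sol.sol(tk), 0.0)))
        y = np.maximum(sol.y[:, -1], 0.0)
        t = float(sol.t[-1])
        for _, anc, mut in slices:
            if 0.0 < y[anc] + y[mut] < thr:
                y[anc] = 0.0
                y[mut] = 0.0
    return y, rows


# ---------------------------------------------------------------------------
# Full replicates
# ---------------------------------------------------------------------------


def replicate_rng(master_seed: int, replicate: int, point: int = 0) -> np.random.Generator:
    """Named per-replicate stream: ``SeedSequence([master_seed, point,
    replicate])``.  This is the documented spawning scheme used by the sweep
    machinery; replicate streams never overlap."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, point, replicate]))


def _rescue_threshold(params: ModelParams) -> float:
    # N_c is the spreading criterion; for near-zero N_c fall back to the
    # extinction threshold so "rescued" still means an established lineage.
    return max(params.N_c, params.extinction_threshold)


def run_simulation(
    params: ModelParams,
    rng: np.random.Generator,
    record: bool = False,
    record_stride: int = 1,
) -> SimulationOutcome:
    """Simulate one replicate from stress onset to a verdict.

    The cheater variant first runs its deterministic burn-in (recorded at
    negative times when ``record`` is set), then the stressed phase.
    """
    outcomes = run_replicates(
        params, [rng], record=record, record_stride=record_stride
    )
    return outcomes[0]


def run_replicates(
    params: ModelParams,
    rngs: list[np.random.Generator],
    record: bool = False,
    record_stride: int = 1,
) -> list[SimulationOutcome]:
    """Advance a batch of replicates in lockstep.

    All replicates share each deterministic interval solve (they are
    independent components of one stacked ODE system); mutation draws come
    from each replicate's own generator, in replicate order, so results are
    identical whether replicates run together or one at a time up to
    solver round-off.
    """
    variant = params.model_variant
    slices = _species_slices(variant)
    _, _, mu = params.species_rates()
    t_max = resolve_t_max(params)
    thr = _rescue_threshold(params)

    R = len(rngs)
    burn_rows: list[tuple[float, np.ndarray]] = []
    if variant == "cheater":
        if record:
            y0, burn_rows = _burn_in_path(params, record=True)
        else:
            y0 = burn_in_state(params).abundances
    else:
        y0 = initial_state(params).abundances
    y = np.tile(np.asarray(y0, dtype=float), (R, 1))

    verdict = np.array(["undecided_at_t_max"] * R, dtype=object)
    vtime = np.full(R, math.nan)
    events: list[list[tuple[float, str, int]]] = [[] for _ in range(R)]
    traj_rows: list[list[tuple[float, np.ndarray]]] | None = None
    if record:
        traj_rows = [[(0.0, y0.copy())] for _ in range(R)]

    alive = np.ones(R, dtype=bool)
    k = 0
    n_max = int(math.ceil(t_max / params.dt - 1e-9))
    while alive.any() and k < n_max:
        t0 = k * params.dt
        t1 = t0 + params.dt
        idx = np.nonzero(alive)[0]
        ya = _advance(y[alive], params, t0)
        for s, (sp, anc, mut) in enumerate(slices):
            mus = float(mu[s])
            if mus == 0.0:
                continue
            for row, i in enumerate(idx):
                A = ya[row, anc]
                if A > 0.0:
                    c = int(rngs[i].poisson(mus * A * params.dt))
                    if c:
                        ya[row, mut] += c
                        events[i].append((t1, sp, c))
        _clamp(ya, params)
        y[alive] = ya

        extinct = ~ya.any(axis=1)
        rescued = _rescued_mask(ya, params, slices, thr)
        done_r = rescued & ~extinct
        done_e = extinct
        if done_r.any() or done_e.any():
            gi_r = idx[done_r]
            gi_e = idx[done_e]
            verdict[gi_r] = "rescued"
            verdict[gi_e] = "extinct"
            vtime[gi_r] = t1
            vtime[gi_e] = t1
            alive[gi_r] = False
            alive[gi_e] = False
        if record and (k + 1) % record_stride == 0:
            for row, i in enumerate(idx):
                traj_rows[i].append((t1, ya[row].copy()))
        k += 1

    # replicates still alive at the horizon: an adapted cheater lineage may
    # still be mid-crash, so only the absorbing configuration (cooperator
    # mutant established, cheaters purged) counts as rescued here too
    if alive.any():
        t_end = k * params.dt
        done = _rescued_mask(y[alive], params, slices, thr)
        for j, i in enumerate(np.nonzero(alive)[0]):
            if done[j]:
                verdict[i] = "rescued"
            vtime[i] = t_end

    out = []
    labels = compartment_labels(variant)
    for i in range(R):
        final = PopulationState(
            t=float(vtime[i]), abundances=y[i], model_variant=variant
        )
        traj = None
        if record:
            rows = burn_rows + traj_rows[i]
            traj = pd.DataFrame(
                [
                    (t, sp, gt, yv[j])
                    for t, yv in rows
                    for j, (sp, gt) in enumerate(labels)
                ],
                columns=["t", "species", "genotype", "abundance"],
            )
        out.append(
            SimulationOutcome(
                verdict=str(verdict[i]),
                verdict_time=float(vtime[i]),
                final_state=final,
                mutation_events=events[i],
                trajectory=traj,
            )
        )
    return out


def _rescued_mask(ya, params, slices, thr):
    """Per-variant rescue criterion on a batch (R, C)."""
    v = params.model_variant
    if v in ("baseline", "cooperation"):
        return ya[:, slices[0][2]] >= thr
    if v in ("mutualism", "mutualism_no_competition"):
        return (ya[:, slices[0][2]] >= thr) & (ya[:, slices[1][2]] >= thr)
    # cheater: the rise of the cooperator mutant is absorbing only once the
    # cheater species is gone (an adapted cheater can still crash it);
    # otherwise the verdict waits until t_max.
    coop_mut = ya[:, slices[0][2]]
    cheat_gone = (ya[:, slices[1][1]] == 0.0) & (ya[:, slices[1][2]] == 0.0)
    return (coop_mut >= thr) & cheat_gone
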