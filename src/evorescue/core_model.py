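"""Deterministic skeleton of the rescue models.

Four ecological settings share one state layout and one right-hand-side
dispatcher:

``baseline``
    logistic growth with an external death rate and no Allee effect
    (the non-interacting reference population).
``cooperation``
    intraspecies cooperation: the per-capita growth rate of ancestors and
    mutants drops by a factor ``1 - rho`` when the *total* population is
    below the critical size ``N_c`` (strong Allee effect).
``mutualism`` / ``mutualism_no_competition``
    two obligate mutualists; each species' growth rate is reduced when its
    *partner's* total is below ``N_c``.  In the default form both species
    share one logistic term (competition for a common resource); the
    ``_no_competition`` form gives each species its own logistic term.
``cheater``
    cooperators plus non-producing cheaters.  Both genotypes reference the
    cooperator total: cheaters grow faster by ``1 + b`` above ``N_c`` and
    slower by ``(1 - rho) * (1 - a)`` below it.

Only the mutation process (handled in :mod:`evorescue.engine`) is
stochastic; everything here is an ordinary differential equation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "VARIANTS",
    "ModelParams",
    "PopulationState",
    "growth_rate_step",
    "growth_rate_smooth",
    "cooperation_derivatives",
    "mutualism_derivatives",
    "cheater_derivatives",
    "derivatives",
    "initial_state",
    "classify_regime",
    "compartment_labels",
]

VARIANTS = (
    "baseline",
    "cooperation",
    "mutualism",
    "mutualism_no_competition",
    "cheater",
)

# Fixed compartment layout per variant: (species, genotype) pairs, in the
# order used by every array in the package.
_LAYOUTS: dict[str, tuple[tuple[str, str], ...]] = {
    "baseline": (("pop", "ancestor"), ("pop", "mutant")),
    "cooperation": (("pop", "ancestor"), ("pop", "mutant")),
    "mutualism": (
        ("sp1", "ancestor"),
        ("sp1", "mutant"),
        ("sp2", "ancestor"),
        ("sp2", "mutant"),
    ),
    "mutualism_no_competition": (
        ("sp1", "ancestor"),
        ("sp1", "mutant"),
        ("sp2", "ancestor"),
        ("sp2", "mutant"),
    ),
    "cheater": (
        ("coop", "ancestor"),
        ("coop", "mutant"),
        ("cheat", "ancestor"),
        ("cheat", "mutant"),
    ),
}


def compartment_labels(model_variant: str) -> tuple[tuple[str, str], ...]:
    """Return the ordered (species, genotype) labels of a variant."""
    try:
        return _LAYOUTS[model_variant]
    except KeyError:
        raise ValueError(
            f"unknown model variant {model_variant!r}; expected one of {VARIANTS}"
        ) from None


def species_names(model_variant: str) -> tuple[str, ...]:
    seen: list[str] = []
    for sp, _ in compartment_labels(model_variant):
        if sp not in seen:
            seen.append(sp)
    return tuple(seen)


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one model variant.

    Rates are per unit time, abundances in individuals.  ``r_A2``, ``r_M2``
    and ``mu2`` apply to the second mutualistic species and default to the
    species-1 values when left ``None``.

    The stress scenario is: growth at ``delta = 0`` before time zero (the
    ancestor sits at its pre-stress equilibrium), then an abrupt jump to the
    stressed death rate.  Simulations therefore start at stress onset; the
    cheater variant is the exception and runs a pre-stress burn-in at a
    small dilution rate ``burn_in_delta`` so the stress hits the oscillating
    cooperator-cheater quasi-attractor.
    """

    model_variant: str = "cooperation"
    r_A: float = 0.5
    r_M: float = 3.0
    K: float = 1000.0
    N_c: float = 50.0
    rho: float = 0.7
    delta: float = 1.0
    mu: float = 3e-4
    r_A2: float | None = None
    r_M2: float | None = None
    mu2: float | None = None
    a: float = 0.3
    b: float = 0.5
    allee_form: str = "step"
    smooth_steepness: float = 4.0
    dt: float = 0.01
    extinction_threshold: float = 1.0
    t_max: float | None = None
    initial_fraction: float = 0.5
    initial_density: float | None = None
    burn_in_time: float = 300.0
    burn_in_delta: float = 0.1
    burn_in_coop0: float | None = None
    burn_in_cheat0: float | None = None
    clamp_mode: str = "species"

    def __post_init__(self) -> None:
        if self.model_variant not in VARIANTS:
            raise ValueError(
                f"unknown model variant {self.model_variant!r}; "
                f"expected one of {VARIANTS}"
            )
        if self.allee_form not in ("step", "smooth"):
            raise ValueError("allee_form must be 'step' or 'smooth'")
        if self.clamp_mode not in ("species", "compartment"):
            raise ValueError("clamp_mode must be 'species' or 'compartment'")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.initial_fraction <= 1.0:
            raise ValueError("initial_fraction must lie in [0, 1]")
        for name in ("r_A", "r_M", "delta", "mu", "a", "b", "burn_in_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("r_A2", "r_M2", "mu2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.K > 0:
            raise ValueError("K must be positive (math.inf is allowed)")
        if self.N_c < 0:
            raise ValueError("N_c must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.smooth_steepness > 0:
            raise ValueError("smooth_steepness must be positive")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be non-negative")
        if self.t_max is not None and not self.t_max > 0:
            raise ValueError("t_max must be positive when given")
        if self.model_variant == "baseline" and self.rho != 0.0:
            raise ValueError("the baseline variant requires rho = 0")
        two_species = self.model_variant in (
            "mutualism",
            "mutualism_no_competition",
        )
        if not two_species:
            for name in ("r_A2", "r_M2", "mu2"):
                if getattr(self, name) is not None:
                    raise ValueError(f"{name} only applies to mutualism variants")

    # -- convenience views -------------------------------------------------

    @property
    def labels(self) -> tuple[tuple[str, str], ...]:
        return compartment_labels(self.model_variant)

    @property
    def species(self) -> tuple[str, ...]:
        return species_names(self.model_variant)

    def species_rates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-species (r_A, r_M, mu) arrays, in layout species order."""
        if self.model_variant in ("mutualism", "mutualism_no_competition"):
            rA = np.array([self.r_A, self.r_A if self.r_A2 is None else self.r_A2])
            rM = np.array([self.r_M, self.r_M if self.r_M2 is None else self.r_M2])
            mu = np.array([self.mu, self.mu if self.mu2 is None else self.mu2])
        else:
            n = len(self.species)
            rA = np.full(n, self.r_A)
            rM = np.full(n, self.r_M)
            mu = np.full(n, self.mu)
        return rA, rM, mu

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
        return cls(**dict(mapping))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))


@dataclass
class PopulationState:
    """Abundances of every (species, genotype) compartment at one time.

    ``abundances`` follows the fixed layout of ``model_variant`` (see
    :func:`compartment_labels`).  Totals are always recomputed from the
    compartments, never stored.
    """

    t: float
    abundances: np.ndarray
    model_variant: str = "cooperation"

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        labels = compartment_labels(self.model_variant)
        if self.abundances.shape != (len(labels),):
            raise ValueError(
                f"state for {self.model_variant!r} needs "
                f"{len(labels)} compartments, got shape {self.abundances.shape}"
            )
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")

    @classmethod
    def from_mapping(
        cls, t: float, mapping: Mapping[tuple[str, str], float], model_variant: str
    ) -> "PopulationState":
        labels = compartment_labels(model_variant)
        extra = set(mapping) - set(labels)
        if extra:
            raise ValueError(f"unknown compartments: {sorted(extra)}")
        y = np.array([float(mapping.get(lab, 0.0)) for lab in labels])
        return cls(t=t, abundances=y, model_variant=model_variant)

    @property
    def labels(self) -> tuple[tuple[str, str], ...]:
        return compartment_labels(self.model_variant)

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(zip(self.labels, self.abundances.tolist()))

    @property
    def total(self) -> float:
        """Grand total N_T over all compartments."""
        return float(self.abundances.sum())

    def species_total(self, species: str) -> float:
        return float(
            sum(a for (sp, _), a in zip(self.labels, self.abundances) if sp == species)
        )

    def species_totals(self) -> dict[str, float]:
        return {sp: self.species_total(sp) for sp in species_names(self.model_variant)}

    def __getitem__(self, label: tuple[str, str]) -> float:
        return float(self.abundances[self.labels.index(label)])


# ---------------------------------------------------------------------------
# Allee response functions
# ---------------------------------------------------------------------------


def growth_rate_step(r, N_ref, N_c, rho):
    """Step Allee response: ``r`` above ``N_c``, ``r * (1 - rho)`` at or below.

    The boundary ``N_ref == N_c`` takes the reduced branch (the inequality
    ``N_ref > N_c`` is strict).
    """
    r = np.asarray(r, dtype=float)
    N_ref = np.asarray(N_ref, dtype=float)
    if np.any(r < 0) or np.any(N_ref < 0) or N_c < 0:
        raise ValueError("rates and abundances must be non-negative")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    out = np.where(N_ref > N_c, r, r * (1.0 - rho))
    return out if out.ndim else float(out)


def growth_rate_smooth(r, N_ref, N_c, rho, h):
    """Smooth (Hill-type) Allee response.

    ``r * (1 - rho * N_c**h / (N_c**h + N_ref**h))``: continuous and
    sigmoidal around ``N_c``, with limits ``r * (1 - rho)`` at zero density
    and ``r`` at high density, and the midpoint value ``r * (1 - rho / 2)``
    exactly at ``N_ref == N_c``.  Converges pointwise to the step response
    as the steepness ``h`` grows.
    """
    if not h > 0:
        raise ValueError("steepness h must be positive")
    r = np.asarray(r, dtype=float)
    N_ref = np.asarray(N_ref, dtype=float)
    if np.any(r < 0) or np.any(N_ref < 0) or N_c < 0:
        raise ValueError("rates and abundances must be non-negative")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    out = r * (1.0 - rho * _hill_weight(N_ref, N_c, h))
    return out if out.ndim else float(out)


def _hill_weight(N_ref, N_c, h):
    """Weight of the low-density branch: 1 at N=0, 1/2 at N_c, 0 as N -> inf."""
    N_ref = np.asarray(N_ref, dtype=float)
    if N_c == 0:
        w = np.zeros_like(N_ref)
        return w if w.ndim else 0.0
    with np.errstate(over="ignore"):
        ratio = np.power(N_ref / N_c, h)
    return 1.0 / (1.0 + ratio)


def _branch_mix(hi, lo, N_ref, params: ModelParams):
    """Blend a high-density and a low-density branch value.

    Step form: strict threshold at ``N_c`` (equality -> low branch).
    Smooth form: Hill-weight interpolation with steepness ``smooth_steepness``.
    Works elementwise for array ``N_ref``.
    """
    if params.allee_form == "step":
        return np.where(N_ref > params.N_c, hi, lo)
    w = _hill_weight(N_ref, params.N_c, params.smooth_steepness)
    return hi * (1.0 - w) + lo * w


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------


def _logistic(N, K):
    # K = inf is allowed: the logistic term is then exactly 1.
    if math.isinf(K):
        return np.ones_like(np.asarray(N, dtype=float))
    return 1.0 - np.asarray(N, dtype=float) / K


def _deriv_single(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Baseline / cooperation: compartments (A, M), Allee reference N_T."""
    A = y[..., 0]
    M = y[..., 1]
    NT = A + M
    mult = _branch_mix(1.0, 1.0 - params.rho, NT, params)
    logi = _logistic(NT, params.K)
    dA = params.r_A * mult * A * logi - params.delta * A
    dM = params.r_M * mult * M * logi - params.delta * M
    return np.stack([dA, dM], axis=-1)


def _deriv_mutualism(y: np.ndarray, params: ModelParams) -> np.ndarray:
    A1, M1, A2, M2 = (y[..., i] for i in range(4))
    N1 = A1 + M1
    N2 = A2 + M2
    rA, rM, _ = params.species_rates()
    # species i references its partner's total
    mult1 = _branch_mix(1.0, 1.0 - params.rho, N2, params)
    mult2 = _branch_mix(1.0, 1.0 - params.rho, N1, params)
    if params.model_variant == "mutualism":
        logi1 = logi2 = _logistic(N1 + N2, params.K)
    else:  # no interspecies competition: per-species logistic term
        logi1 = _logistic(N1, params.K)
        logi2 = _logistic(N2, params.K)
    d = params.delta
    dA1 = rA[0] * mult1 * A1 * logi1 - d * A1
    dM1 = rM[0] * mult1 * M1 * logi1 - d * M1
    dA2 = rA[1] * mult2 * A2 * logi2 - d * A2
    dM2 = rM[1] * mult2 * M2 * logi2 - d * M2
    return np.stack([dA1, dM1, dA2, dM2], axis=-1)


def _deriv_cheater(y: np.ndarray, params: ModelParams) -> np.ndarray:
    Ac, Mc, Ah, Mh = (y[..., i] for i in range(4))
    N_coop = Ac + Mc
    NT = N_coop + Ah + Mh
    logi = _logistic(NT, params.K)
    mult_coop = _branch_mix(1.0, 1.0 - params.rho, N_coop, params)
    mult_cheat = _branch_mix(
        1.0 + params.b, (1.0 - params.rho) * (1.0 - params.a), N_coop, params
    )
    d = params.delta
    dAc = params.r_A * mult_coop * Ac * logi - d * Ac
    dMc = params.r_M * mult_coop * Mc * logi - d * Mc
    dAh = params.r_A * mult_cheat * Ah * logi - d * Ah
    dMh = params.r_M * mult_cheat * Mh * logi - d * Mh
    return np.stack([dAc, dMc, dAh, dMh], axis=-1)


def derivatives(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-compartment rates of change, vectorized over leading axes.

    ``y`` has shape ``(..., C)`` in the variant's compartment layout.  Any
    compartment at exactly zero has derivative zero (all terms are
    proportional to the compartment's own abundance).
    """
    y = np.asarray(y, dtype=float)
    v = params.model_variant
    if v in ("baseline", "cooperation"):
        return _deriv_single(y, params)
    if v in ("mutualism", "mutualism_no_competition"):
        return _deriv_mutualism(y, params)
    return _deriv_cheater(y, params)


def _state_derivatives(
    state: PopulationState, params: ModelParams, expected: tuple[str, ...]
) -> np.ndarray:
    if params.model_variant not in expected:
        raise ValueError(
            f"params are for variant {params.model_variant!r}, expected {expected}"
        )
    if state.model_variant != params.model_variant:
        raise ValueError(
            f"state variant {state.model_variant!r} does not match params "
            f"variant {params.model_variant!r}"
        )
    return derivatives(state.abundances, params)


def cooperation_derivatives(state: PopulationState, params: ModelParams) -> np.ndarray:
    """d/dt of (A, M) for the single-species (baseline/cooperation) model."""
    return _state_derivatives(state, params, ("baseline", "cooperation"))


def mutualism_derivatives(state: PopulationState, params: ModelParams) -> np.ndarray:
    """d/dt of (A1, M1, A2, M2) for the obligate-mutualism model."""
    return _state_derivatives(
        state, params, ("mutualism", "mutualism_no_competition")
    )


def cheater_derivatives(state: PopulationState, params: ModelParams) -> np.ndarray:
    """d/dt of (A_coop, M_coop, A_cheat, M_cheat) for the cheater model."""
    return _state_derivatives(state, params, ("cheater",))


# ---------------------------------------------------------------------------
# Initial conditions and regime classification
# ---------------------------------------------------------------------------


def initial_state(params: ModelParams) -> PopulationState:
    """State at stress onset (or at burn-in start for the cheater variant).

    Single-species variants start with the ancestor at its pre-stress
    equilibrium (the carrying capacity, unless ``initial_density``
    overrides it).  Mutualists split the initial density between the two
    species by ``initial_fraction``; without interspecies competition each
    species has its own equilibrium, so the per-species densities are
    ``2 * fraction * K`` (both at ``K`` for the default even split).
    The cheater variant starts at the burn-in condition: cooperators at
    ``N_c`` and cheaters at ``N_c / 10`` by default.
    """
    v = params.model_variant
    K = params.K if math.isfinite(params.K) else 1e12
    if v in ("baseline", "cooperation"):
        A0 = params.initial_density if params.initial_density is not None else K
        y = np.array([A0, 0.0])
    elif v == "mutualism":
        total = params.initial_density if params.initial_density is not None else K
        f = params.initial_fraction
        y = np.array([f * total, 0.0, (1.0 - f) * total, 0.0])
    elif v == "mutualism_no_competition":
        total = params.initial_density if params.initial_density is not None else K
        f = params.initial_fraction
        y = np.array([2.0 * f * total, 0.0, 2.0 * (1.0 - f) * total, 0.0])
    else:  # cheater
        coop0 = params.burn_in_coop0 if params.burn_in_coop0 is not None else params.N_c
        cheat0 = (
            params.burn_in_cheat0
            if params.burn_in_cheat0 is not None
            else params.N_c / 10.0
        )
        y = np.array([coop0, 0.0, cheat0, 0.0])
    return PopulationState(t=0.0, abundances=y, model_variant=v)


def classify_regime(params: ModelParams) -> str:
    """Report which dynamical regime a parameter set is in.

    Returns one of:

    - ``"no_stress"``: delta = 0, the population never declines.
    - ``"trivially_safe"``: the ancestor persists deterministically (either
      ``delta < r_A * (1 - rho)``, or ``delta < r_A`` with the stressed
      logistic equilibrium above ``N_c``), so no rescue is needed.
    - ``"deterministic_extinction"``: mutants cannot outgrow the stress
      (``r_M <= delta``), so extinction is certain.
    - ``"rescue_relevant"``: the ancestor declines but an established
      mutant can grow above the critical size
      (``r_A < delta < r_M``, the paper's scenario).
    """
    rA, rM, _ = params.species_rates()
    d = params.delta
    if d == 0:
        return "no_stress"
    lo = rA * (1.0 - params.rho)
    if np.all(d < lo):
        return "trivially_safe"
    if np.all(d < rA):
        if math.isinf(params.K):
            return "trivially_safe"
        if params.K * (1.0 - d / np.min(rA)) > params.N_c:
            return "trivially_safe"
    if np.any(rM <= d):
        return "deterministic_extinction"
    return "rescue_relevant"
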