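"""Monte Carlo estimation of rescue probabilities and parameter sweeps.

Every estimate is the fraction of replicate simulations that ended with
the ``rescued`` verdict, with a 95% Wilson score interval (well behaved at
the probabilities near 0 and 1 where most of these estimates live).
Replicate streams derive from ``(master_seed, grid point index, replicate
index)``, so sweeps are reproducible row by row and independent of
evaluation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core_model import ModelParams
from .engine import replicate_rng, run_replicates

__all__ = [
    "SweepResult",
    "NoMatchingRatioError",
    "estimate_rescue_probability",
    "sweep",
    "compare_model_families",
    "matched_growth_ratio",
    "family_params",
]

logger = logging.getLogger(__name__)

_META_COLUMNS = [
    "point",
    "n_replicates",
    "n_rescued",
    "n_undecided",
    "p_hat",
    "ci_low",
    "ci_high",
    "seed",
]


@dataclass
class SweepResult:
    """Table of rescue-probability estimates over a parameter grid.

    One row per grid point: the point's full parameter values, the
    replicate counts, ``p_hat = n_rescued / n_replicates`` and its 95%
    Wilson interval, and the master seed.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.table)


def wilson_interval(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _params_columns(params: ModelParams) -> dict:
    d = params.to_dict()
    return {k: (math.nan if v is None else v) for k, v in d.items()}


def estimate_rescue_probability(
    params: ModelParams,
    n_replicates: int = 1000,
    master_seed: int = 0,
    point: int = 0,
) -> dict:
    """Estimate the rescue probability of one parameter set.

    Returns a flat row (see :class:`SweepResult`).  Replicates that were
    still undecided at ``t_max`` count as non-rescues and are reported in
    ``n_undecided``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    rngs = [replicate_rng(master_seed, i, point) for i in range(n_replicates)]
    outcomes = run_replicates(params, rngs)
    n_rescued = sum(o.rescued for o in outcomes)
    n_undecided = sum(o.verdict == "undecided_at_t_max" for o in outcomes)
    p_hat = n_rescued / n_replicates
    ci_low, ci_high = wilson_interval(n_rescued, n_replicates)
    row = _params_columns(params)
    row.update(
        point=point,
        n_replicates=n_replicates,
        n_rescued=n_rescued,
        n_undecided=n_undecided,
        p_hat=p_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        seed=master_seed,
    )
    return row


def sweep(
    grid: Sequence[ModelParams],
    n_replicates: int = 1000,
    master_seed: int = 0,
    on_row: Callable[[dict], None] | None = None,
    skip_points: Iterable[int] = (),
) -> SweepResult:
    """Estimate rescue probabilities over a grid of parameter sets.

    Rows are independent given ``(grid, n_replicates, master_seed)``; the
    optional ``on_row`` callback receives each finished row (checkpointing),
    and ``skip_points`` restarts a partially completed sweep.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    for idx, p in enumerate(grid):
        if not isinstance(p, ModelParams):
            raise ValueError(f"grid point {idx} is not a ModelParams")
    skip = set(skip_points)
    rows = []
    for idx, p in enumerate(grid):
        if idx in skip:
            continue
        try:
            row = estimate_rescue_probability(p, n_replicates, master_seed, point=idx)
        except Exception as exc:
            raise RuntimeError(f"grid point {idx} failed: {exc}") from exc
        logger.info(
            "point %d/%d: p_hat=%.4f [%d/%d]",
            idx + 1, len(grid), row["p_hat"], row["n_rescued"], n_replicates,
        )
        rows.append(row)
        if on_row is not None:
            on_row(row)
    table = pd.DataFrame(rows)
    ordered = [c for c in table.columns if c not in _META_COLUMNS] + _META_COLUMNS
    return SweepResult(table[ordered])


# ---------------------------------------------------------------------------
# Model-family comparison
# ---------------------------------------------------------------------------

FAMILIES = (
    "baseline",
    "cooperation",
    "mutualism_no_competition",
    "mutualism",
    "cheater",
)


def family_params(base: ModelParams, variant: str) -> ModelParams:
    """Re-target a shared parameter set at another interaction type.

    ``base`` carries the ecological parameters (rates, K, N_c, rho, mu,
    cheater advantages, burn-in settings); only the variant label changes,
    except for the baseline where the Allee effect is switched off.
    """
    if variant == "baseline":
        return base.replace(model_variant="baseline", rho=0.0)
    return base.replace(model_variant=variant)


def compare_model_families(
    grid: Sequence[ModelParams],
    n_replicates: int = 1000,
    master_seed: int = 0,
    families: Sequence[str] = FAMILIES,
) -> pd.DataFrame:
    """Rescue probability of every interaction type on a shared grid.

    One row per grid point with a ``p_<family>`` (and Wilson CI) column
    group per family, plus ``p_cooperation_squared``: the rescue
    probability of two *independent* cooperating populations, the analytic
    reference for mutualists that do not compete.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for idx, base in enumerate(grid):
        row: dict = {"point": idx}
        row.update({f"base_{k}": v for k, v in _params_columns(base).items()})
        for f_idx, fam in enumerate(families):
            p = family_params(base, fam)
            est = estimate_rescue_probability(
                p, n_replicates, master_seed, point=idx * 101 + f_idx
            )
            row[f"p_{fam}"] = est["p_hat"]
            row[f"ci_low_{fam}"] = est["ci_low"]
            row[f"ci_high_{fam}"] = est["ci_high"]
        if "cooperation" in families:
            row["p_cooperation_squared"] = row["p_cooperation"] ** 2
        rows.append(row)
        logger.info("compare point %d/%d done", idx + 1, len(grid))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Growth-rate-ratio matching
# ---------------------------------------------------------------------------


class NoMatchingRatioError(RuntimeError):
    """No growth-rate multiplier in the bracket equalizes the two rescue
    probabilities (typically because the reference probability is zero)."""


def matched_growth_ratio(
    base_params: ModelParams,
    family_pair: tuple[str, str] = ("cooperation", "baseline"),
    n_replicates: int = 1000,
    tol: float = 0.05,
    master_seed: int = 0,
    bracket: tuple[float, float] = (1.0, 4.0),
) -> float:
    """Growth-rate multiplier at which two interaction types rescue equally.

    Scales both ``r_A`` and ``r_M`` of the handicapped family (the first of
    ``family_pair``) by a factor ``c`` and bisects on ``c`` until the
    handicapped family's rescue probability matches the reference family's
    (monotonicity of the rescue probability in the growth rates makes the
    bisection valid).  Matching is declared when the two estimates differ
    by at most ``tol`` or their 95% CIs overlap, or the bracket has shrunk
    below 1e-2.
    """
    handicapped, reference = family_pair
    ref = estimate_rescue_probability(
        family_params(base_params, reference), n_replicates, master_seed, point=0
    )
    p_ref, ref_lo, ref_hi = ref["p_hat"], ref["ci_low"], ref["ci_high"]
    if p_ref == 0.0:
        raise NoMatchingRatioError(
            "reference rescue probability is zero: probabilities match only "
            "when neither population can be rescued"
        )

    def scaled(c: float) -> ModelParams:
        p = family_params(base_params, handicapped)
        changes = {"r_A": c * p.r_A, "r_M": c * p.r_M}
        if p.r_A2 is not None:
            changes["r_A2"] = c * p.r_A2
        if p.r_M2 is not None:
            changes["r_M2"] = c * p.r_M2
        return p.replace(**changes)

    evals = 0

    def estimate(c: float) -> dict:
        nonlocal evals
        evals += 1
        return estimate_rescue_probability(
            scaled(c), n_replicates, master_seed, point=evals
        )

    def matched(est: dict) -> bool:
        if abs(est["p_hat"] - p_ref) <= tol:
            return True
        return est["ci_low"] <= ref_hi and ref_lo <= est["ci_high"]

    lo, hi = bracket
    est_lo = estimate(lo)
    if est_lo["p_hat"] >= p_ref:
        if matched(est_lo):
            return lo
        raise NoMatchingRatioError(
            f"handicapped family already rescues more at c={lo}"
        )
    est_hi = estimate(hi)
    if est_hi["p_hat"] < p_ref and not matched(est_hi):
        raise NoMatchingRatioError(
            f"no crossing inside the bracket {bracket}: "
            f"p({hi})={est_hi['p_hat']:.3f} < p_ref={p_ref:.3f}"
        )
    while hi - lo > 1e-2:
        mid = 0.5 * (lo + hi)
        est = estimate(mid)
        logger.info("ratio bisection: c=%.4f p=%.4f (ref %.4f)", mid, est["p_hat"], p_ref)
        if matched(est):
            return mid
        if est["p_hat"] < p_ref:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
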