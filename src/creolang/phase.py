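"""Demographic phase diagram: dominance sweeps and the transition stripe.

The demographic plane has coordinates x = N_M/(N_M+N_B) (fraction of
Mulattos in the Black population) and y = (N_M+N_B)/N (fraction of Blacks
in the overall population).  For each point we run replicate simulations,
call the creole dominant when its tail-averaged fraction exceeds the
dominance threshold, and locate the creole/no-creole transition curve
y*(x) where the creole-dominance probability crosses 1/2.  Running the
curve at epsilon = 0.05, 0.06 and 0.07 yields the uncertainty stripe used
to classify census demographies.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidPointError
from .model import FractionSummary, ModelParams, init_population, run

logger = logging.getLogger(__name__)

STRIPE_EPSILONS = (0.05, 0.06, 0.07)  # lower, mid, upper transition curves


@dataclass(frozen=True)
class DemographicPoint:
    """A territory's position in the (x, y) demographic plane."""

    x: float  # N_M / (N_M + N_B)
    y: float  # (N_M + N_B) / (N_M + N_B + N_Eu)

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise InvalidPointError(f"x must be in [0, 1], got {self.x}")
        if not 0.0 < self.y <= 1.0:
            raise InvalidPointError(
                f"y must be in (0, 1], got {self.y} (no Black population)"
            )


@dataclass(frozen=True)
class DominanceEstimate:
    """Replicate-based dominance probabilities at one demographic point."""

    point: DemographicPoint
    p_creole: float
    p_european: float
    f_E: float
    f_A: float
    f_C: float
    n_replicates: int


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def point_to_counts(
    point: DemographicPoint, n_total: int
) -> tuple[int, int, int]:
    """Realize (x, y) as integer counts (n_eu, n_m, n_b) summing to n_total.

    n_black = round(y * n_total), n_m = round(x * n_black) (round half up);
    when y < 1 at least one European is kept by rounding n_black down.
    """
    if n_total < 2:
        raise InvalidPointError("n_total must be at least 2")
    n_black = _round_half_up(point.y * n_total)
    if point.y < 1.0 and n_black >= n_total:
        n_black = n_total - 1  # keep at least one European
    n_m = _round_half_up(point.x * n_black)
    n_b = n_black - n_m
    n_eu = n_total - n_black
    if n_m + n_b < 1:
        raise InvalidPointError(
            f"point (x={point.x}, y={point.y}) at N={n_total} yields no "
            "Mulattos or Bozals"
        )
    return n_eu, n_m, n_b


def estimate_dominance(
    point: DemographicPoint,
    params: ModelParams,
    n_total: int,
    n_replicates: int,
    seed: int | None = None,
) -> DominanceEstimate:
    """Replicate simulations at one demographic point.

    p_creole (p_european) is the fraction of replicates whose tail-averaged
    creole (European) fraction exceeds the dominance threshold; replicate r
    uses seed + r.
    """
    if seed is None:
        seed = params.seed
    n_eu, n_m, n_b = point_to_counts(point, n_total)
    wins_c = wins_e = 0
    mean = np.zeros(3)
    for r in range(n_replicates):
        state = init_population(n_eu, n_m, n_b)
        _, summary, _ = run(state, params, seed=seed + r)
        wins_c += summary.f_C > params.dominance_threshold
        wins_e += summary.f_E > params.dominance_threshold
        mean += (summary.f_E, summary.f_A, summary.f_C)
    mean /= n_replicates
    return DominanceEstimate(
        point=point,
        p_creole=wins_c / n_replicates,
        p_european=wins_e / n_replicates,
        f_E=mean[0],
        f_A=mean[1],
        f_C=mean[2],
        n_replicates=n_replicates,
    )


def sweep_grid(
    xs: list[float],
    ys: list[float],
    params: ModelParams,
    n_total: int,
    n_replicates: int,
    seed: int | None = None,
) -> list[DominanceEstimate]:
    """Dominance estimates over the cartesian grid xs × ys.

    Invalid points (no Mulatto/Bozal population at this N) are skipped with
    a logged warning.  Reproducible under a fixed seed: each grid cell gets
    an independent seed block.
    """
    if not xs or not ys:
        raise ValueError("grids must be non-empty")
    if seed is None:
        seed = params.seed
    out: list[DominanceEstimate] = []
    for k, x in enumerate(xs):
        for l, y in enumerate(ys):
            cell_seed = seed + 10_000 * (k * len(ys) + l)
            try:
                point = DemographicPoint(x=x, y=y)
                out.append(
                    estimate_dominance(
                        point, params, n_total, n_replicates, seed=cell_seed
                    )
                )
            except InvalidPointError as exc:
                logger.warning("skipping grid point (%g, %g): %s", x, y, exc)
    return out


def grid_to_frame(grid: list[DominanceEstimate]) -> pd.DataFrame:
    """Tabular form of a sweep (columns x, y, p_creole, ..., n_replicates)."""
    return pd.DataFrame(
        {
            "x": [g.point.x for g in grid],
            "y": [g.point.y for g in grid],
            "p_creole": [g.p_creole for g in grid],
            "p_european": [g.p_european for g in grid],
            "f_E": [g.f_E for g in grid],
            "f_A": [g.f_A for g in grid],
            "f_C": [g.f_C for g in grid],
            "n_replicates": [g.n_replicates for g in grid],
        }
    )


def transition_curve(
    params: ModelParams,
    xs: list[float],
    n_total: int,
    n_replicates: int,
    y_tolerance: float = 0.02,
    seed: int | None = None,
    y_bounds: tuple[float, float] = (0.05, 0.995),
) -> dict[float, float]:
    """Locate y*(x) where p_creole crosses 1/2, by bisection in y.

    For each x the crossing must be bracketed by the y endpoints
    (p_creole < 1/2 at the bottom, >= 1/2 at the top); otherwise the curve
    is undefined there and the returned mapping holds NaN.  The same seed
    block is reused across calls with different epsilon so that curves for
    nearby parameters share their random numbers (common-random-number
    variance reduction).
    """
    if seed is None:
        seed = params.seed
    curve: dict[float, float] = {}
    y_lo_0, y_hi_0 = y_bounds
    for k, x in enumerate(xs):
        base = seed + 1_000_000 * k

        def p_creole(y: float, block: int) -> float:
            est = estimate_dominance(
                DemographicPoint(x=x, y=y),
                params,
                n_total,
                n_replicates,
                seed=base + 1000 * block,
            )
            return est.p_creole

        lo, hi = y_lo_0, y_hi_0
        p_lo, p_hi = p_creole(lo, 0), p_creole(hi, 1)
        if not (p_lo < 0.5 <= p_hi):
            logger.warning(
                "transition undefined at x=%g (p_creole %g at y=%g, %g at y=%g)",
                x, p_lo, lo, p_hi, hi,
            )
            curve[x] = float("nan")
            continue
        block = 2
        while hi - lo > y_tolerance:
            mid = 0.5 * (lo + hi)
            if p_creole(mid, block) >= 0.5:
                hi = mid
            else:
                lo = mid
            block += 1
        curve[x] = 0.5 * (lo + hi)
    return curve


@dataclass
class TransitionStripe:
    """The creole/no-creole uncertainty stripe.

    Three transition curves tabulated on a common x grid: lower
    (epsilon = 0.05), mid (0.06) and upper (0.07).  Undefined entries are
    NaN.  Lookups interpolate linearly between tabulated x values and clamp
    to the nearest defined endpoint outside the range (with a warning).
    """

    xs: np.ndarray
    y_lower: np.ndarray
    y_mid: np.ndarray
    y_upper: np.ndarray
    meta: dict = field(default_factory=dict)

    def _interp(self, x: float, ys: np.ndarray) -> float:
        ok = ~np.isnan(ys)
        if not ok.any():
            raise InvalidPointError("stripe has no defined points")
        xs, ys = self.xs[ok], ys[ok]
        if x < xs[0] or x > xs[-1]:
            warnings.warn(
                f"x={x:g} outside the stripe's tabulated range "
                f"[{xs[0]:g}, {xs[-1]:g}]; clamping to the nearest endpoint",
                stacklevel=3,
            )
        return float(np.interp(x, xs, ys))

    def lower_at(self, x: float) -> float:
        return self._interp(x, self.y_lower)

    def mid_at(self, x: float) -> float:
        return self._interp(x, self.y_mid)

    def upper_at(self, x: float) -> float:
        return self._interp(x, self.y_upper)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.xs,
                "y_lower": self.y_lower,
                "y_mid": self.y_mid,
                "y_upper": self.y_upper,
            }
        )

    def to_csv(self, path) -> None:
        """Write the stripe table with a provenance comment header."""
        with open(path, "w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}: {val}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransitionStripe":
        with open(path) as fh:
            lines = fh.readlines()
        meta = {}
        body = []
        for line in lines:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                body.append(line)
        df = pd.read_csv(io.StringIO("".join(body)))
        return cls(
            xs=df["x"].to_numpy(),
            y_lower=df["y_lower"].to_numpy(),
            y_mid=df["y_mid"].to_numpy(),
            y_upper=df["y_upper"].to_numpy(),
            meta=meta,
        )


def build_stripe(
    params: ModelParams,
    xs: list[float],
    n_total: int,
    n_replicates: int,
    y_tolerance: float = 0.02,
    seed: int | None = None,
) -> TransitionStripe:
    """Transition curves at epsilon = 0.05, 0.06, 0.07, other params shared."""
    if seed is None:
        seed = params.seed
    curves = []
    for eps in STRIPE_EPSILONS:
        p = replace(params, epsilon=eps)
        curves.append(
            transition_curve(
                p, xs, n_total, n_replicates, y_tolerance=y_tolerance, seed=seed
            )
        )
    lower, mid, upper = curves
    return TransitionStripe(
        xs=np.asarray(xs, dtype=float),
        y_lower=np.array([lower[x] for x in xs]),
        y_mid=np.array([mid[x] for x in xs]),
        y_upper=np.array([upper[x] for x in xs]),
        meta={
            "gamma": params.gamma,
            "delta": params.delta,
            "epsilons": "0.05,0.06,0.07",
            "n_total": n_total,
            "n_replicates": n_replicates,
            "y_tolerance": y_tolerance,
            "seed": seed,
        },
    )
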