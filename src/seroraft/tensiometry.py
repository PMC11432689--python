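"""Langmuir tensiometry analytics.

* **CMC estimation.** Surface tension falls roughly linearly with surfactant
  concentration up to the critical micellar concentration (CMC) and is
  nearly constant above it; the CMC is the abscissa of the break between the
  two regimes.  We fit a continuous two-segment linear model
  γ(c) = β₀ + β₁·c + β₂·(c − b)₊ by least squares, scanning candidate break
  points b over the interior of the data and refining the best interval with
  bounded scalar minimization of the SSR.  The fit is forced continuous at
  the knot.  A log-concentration axis mode is available.

* **Adsorption kinetics.** Solute binding to a monolayer raises the surface
  pressure following π(t) = π₀ + Δπ∞·(1 − e^(−kt)); we fit (π₀, Δπ∞, k) by
  nonlinear least squares and report Δπ at any requested time (typically the
  60-min endpoint of an experiment).

* **Group statistics.** One-way ANOVA from textbook sums of squares plus
  Tukey's honest-significant-difference pairwise comparisons with p-values
  from the studentized-range distribution (Tukey–Kramer for unequal n).

* **Monolayer arithmetic.** At equal trough area and surface pressure, the
  molecule-count ratio of two film-forming species equals the inverse ratio
  of their molecular areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitFailure, ValidationError


@dataclass
class TensiometryCurve:
    """Concentration (mM) vs surface tension (mN/m) table."""

    concentration: np.ndarray
    tension: np.ndarray
    axis_mode: str = "linear"

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.tension = np.asarray(self.tension, dtype=float)
        if self.concentration.shape != self.tension.shape:
            raise ValidationError("concentration and tension lengths differ")
        if np.any(self.concentration <= 0):
            raise ValidationError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentration) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if self.axis_mode not in ("linear", "log"):
            raise ValidationError("axis_mode must be 'linear' or 'log'")

    @classmethod
    def from_csv(cls, path: str | Path, axis_mode: str = "linear"
                 ) -> "TensiometryCurve":
        df = pd.read_csv(path)
        try:
            return cls(df["concentration_mM"].to_numpy(),
                       df["tension_mN_per_m"].to_numpy(), axis_mode)
        except KeyError as exc:
            raise ValidationError(
                f"{path}: expected columns concentration_mM,tension_mN_per_m"
            ) from exc

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "concentration_mM": self.concentration,
            "tension_mN_per_m": self.tension,
        }).to_csv(path, index=False)


@dataclass
class CMCEstimate:
    cmc: float                      # mM
    slope_below: float              # per mM (or per log10 mM in log mode)
    slope_above: float
    intercept: float                # mN/m
    ssr: float
    degenerate: bool
    ci: tuple[float, float] | None = None
    n_boot: int = 0


@dataclass
class KineticsCurve:
    """Time (min) vs surface pressure (mN/m) table."""

    time: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.time.shape != self.pressure.shape:
            raise ValidationError("time and pressure lengths differ")
        if np.any(self.time < 0) or np.any(np.diff(self.time) <= 0):
            raise ValidationError("times must be non-negative and increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "KineticsCurve":
        df = pd.read_csv(path)
        try:
            return cls(df["time_min"].to_numpy(),
                       df["pressure_mN_per_m"].to_numpy())
        except KeyError as exc:
            raise ValidationError(
                f"{path}: expected columns time_min,pressure_mN_per_m"
            ) from exc

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "time_min": self.time,
            "pressure_mN_per_m": self.pressure,
        }).to_csv(path, index=False)


@dataclass
class KineticsFit:
    pi0: float              # mN/m
    delta_pi_inf: float     # mN/m
    rate_k: float           # min⁻¹
    ssr: float

    def delta_pi_at(self, t: float) -> float:
        """Pressure increase over π₀ at time t (min)."""
        return float(self.delta_pi_inf * (1.0 - np.exp(-self.rate_k * t)))

    def pressure_at(self, t: float) -> float:
        return float(self.pi0 + self.delta_pi_at(t))


@dataclass
class GroupComparison:
    labels: list[str]
    f_stat: float
    p_value: float
    table: pd.DataFrame = field(repr=False)  # pair, diff, q, p_adj


# ---------------------------------------------------------------------------
# CMC break-point estimation


def _segment_ssr(x: np.ndarray, y: np.ndarray, b: float):
    """Least-squares fit of the continuous two-segment model at fixed break b."""
    a = np.column_stack([np.ones_like(x), x, np.maximum(x - b, 0.0)])
    beta, _, _, _ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ beta
    return float(resid @ resid), beta


def _fit_breakpoint(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    n = x.size
    if n < 6:
        raise ValidationError("need ≥ 6 points to estimate a break-point")
    # candidate knots: midpoints between consecutive interior points, keeping
    # ≥ 3 points strictly on each side of the knot
    lo_i, hi_i = 2, n - 3
    candidates = 0.5 * (x[lo_i:hi_i] + x[lo_i + 1:hi_i + 1])
    ssrs = np.array([_segment_ssr(x, y, b)[0] for b in candidates])
    k = int(np.argmin(ssrs))
    # refine within the bracketing data interval
    lo = x[lo_i + max(k - 1, 0)]
    hi = x[lo_i + min(k + 2, hi_i - lo_i)]
    res = optimize.minimize_scalar(
        lambda b: _segment_ssr(x, y, b)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-9 * (x[-1] - x[0])},
    )
    b_best = float(res.x)
    ssr, beta = _segment_ssr(x, y, b_best)
    # the coarse grid may beat a refinement trapped at an interval edge
    if ssrs[k] < ssr:
        b_best = float(candidates[k])
        ssr, beta = _segment_ssr(x, y, b_best)
    return b_best, beta, ssr


def estimate_cmc(curve: TensiometryCurve, n_boot: int = 0,
                 seed: int | None = None,
                 degenerate_slope_tol: float = 0.01) -> CMCEstimate:
    """Break-point (CMC) of a surface-tension vs concentration curve.

    Continuous two-segment least squares; SSR grid search over candidate
    breaks between interior points followed by bounded refinement.  The
    ``degenerate`` flag is set when the fitted slope change is below
    ``degenerate_slope_tol`` (per mM, or per log10 mM in log mode), i.e. the
    data are effectively one straight line and the break abscissa is not
    meaningful.  Optional case-resampling bootstrap (seeded) gives a
    percentile 95% CI.
    """
    c = curve.concentration
    y = curve.tension
    x = np.log10(c) if curve.axis_mode == "log" else c
    b, beta, ssr = _fit_breakpoint(x, y)
    cmc = float(10.0 ** b) if curve.axis_mode == "log" else float(b)
    est = CMCEstimate(
        cmc=cmc,
        slope_below=float(beta[1]),
        slope_above=float(beta[1] + beta[2]),
        intercept=float(beta[0]),
        ssr=ssr,
        degenerate=abs(float(beta[2])) < degenerate_slope_tol,
        n_boot=n_boot,
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = x.size
        attempts = 0
        while len(boots) < n_boot and attempts < 10 * n_boot:
            attempts += 1
            idx = np.sort(rng.integers(0, n, size=n))
            xb, yb = x[idx], y[idx]
            xu, inv = np.unique(xb, return_index=True)
            if xu.size < 7:
                continue
            try:
                bb, _, _ = _fit_breakpoint(xu, yb[inv])
            except ValidationError:
                continue
            boots.append(10.0 ** bb if curve.axis_mode == "log" else bb)
        if boots:
            est.ci = (float(np.percentile(boots, 2.5)),
                      float(np.percentile(boots, 97.5)))
    return est


# ---------------------------------------------------------------------------
# adsorption kinetics


def _kinetics_model(t, pi0, dpi, k):
    return pi0 + dpi * (1.0 - np.exp(-k * t))


def fit_binding_kinetics(curve: KineticsCurve) -> KineticsFit:
    """Nonlinear least squares for π(t) = π₀ + Δπ∞(1 − e^(−kt))."""
    t, y = curve.time, curve.pressure
    if t.size < 5:
        raise ValidationError("need ≥ 5 time points to fit kinetics")
    pi0_0 = float(y[0])
    dpi_0 = max(float(y[-1] - y[0]), 1e-9)
    # crude rate guess: time to reach 63% of the apparent rise
    target = pi0_0 + 0.632 * dpi_0
    above = np.nonzero(y >= target)[0]
    t63 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(
        max(t[-1] / 3.0, 1e-6))
    k_0 = 1.0 / t63
    try:
        popt, _ = optimize.curve_fit(
            _kinetics_model, t, y, p0=[pi0_0, dpi_0, k_0],
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailure(
            f"kinetics fit failed to converge: {exc}; initial guess "
            f"(pi0={pi0_0:.3g}, dpi={dpi_0:.3g}, k={k_0:.3g})"
        ) from exc
    resid = y - _kinetics_model(t, *popt)
    return KineticsFit(float(popt[0]), float(popt[1]), float(popt[2]),
                       float(resid @ resid))


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD


def anova_tukey(groups: dict[str, "np.typing.ArrayLike"],
                include_tukey: bool = True) -> GroupComparison:
    """One-way ANOVA F/p plus Tukey HSD adjusted pairwise comparisons.

    ``groups`` maps a label to its replicate values (each n ≥ 2).  Pairwise
    q statistics use the Tukey–Kramer standard error
    sqrt((MSW/2)(1/nᵢ + 1/nⱼ)) — equal to sqrt(MSW/n) for equal group sizes —
    with p-values from the studentized-range distribution.  If all
    observations are identical, F = 0 and p = 1 by convention.
    ``include_tukey=False`` skips the pairwise table (the studentized-range
    integral dominates the cost in large simulation loops).
    """
    if len(groups) < 2:
        raise ValidationError("need ≥ 2 groups")
    labels = list(groups)
    data = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ValidationError(f"group {k!r} has n={v.size}, need n ≥ 2")
    all_vals = np.concatenate(list(data.values()))
    n_total = all_vals.size
    k_groups = len(labels)
    grand = all_vals.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k_groups - 1, n_total - k_groups
    if ssw == 0.0 and ssb == 0.0:
        f_stat, p = 0.0, 1.0
    elif ssw == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    msw = ssw / df_w if df_w > 0 else 0.0

    rows = []
    for a, b in combinations(labels, 2) if include_tukey else ():
        va, vb = data[a], data[b]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(msw / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k_groups, df_w))
        rows.append({"group_a": a, "group_b": b, "diff": diff,
                     "q": float(q), "p_adj": min(max(p_adj, 0.0), 1.0)})
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "q",
                                        "p_adj"])
    return GroupComparison(labels, float(f_stat), float(p), table)


def monolayer_mole_ratio(area_a: float, area_b: float) -> float:
    """Molecule-count ratio N_a/N_b filling equal trough area.

    At equal surface pressure, a species with molecular area ``area_a``
    (Å²/molecule) packs A_total/area_a molecules into a trough of area
    A_total, so the count ratio is area_b/area_a.
    """
    if area_a <= 0 or area_b <= 0:
        raise ValidationError("molecular areas must be positive")
    return float(area_b) / float(area_a)
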