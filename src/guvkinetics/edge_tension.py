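"""Pore-edge tension inference from rate constants at multiple tensions.

Taking the log of the Arrhenius rupture rate linearizes it in the inverse
total tension:

    ln k_r = ln A - (pi * Gamma**2 / k_B T) * 1 / (sigma_e + B)

So a straight-line fit of ln k_r against 1/(sigma_e + B), over a set of
conditions differing only in applied tension, yields the pore-edge tension
from the slope,

    Gamma = sqrt(-slope * k_B * T / pi),

and the frequency factor from the intercept, A = exp(intercept).  A valid
fit has a strictly negative slope (rates must fall as the inverse tension
grows); a non-negative slope is rejected as non-physical rather than
propagated.  The standard error of Gamma follows from the slope's standard
error by the delta method, se(Gamma) = k_B T / (2 pi Gamma) * se(slope);
a vesicle-level bootstrap is available as a cross-check.

Across peptide content, the fitted Gamma values are summarized by the
quadratic (biphasic) model Gamma(phi) = Gamma0 + a*phi - b*phi**2 on the
mole-fraction scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .electromechanics import MembraneConstants
from .energetics import DEFAULT_B_N_PER_M, BiphasicParams
from .survival import VesicleRecord, aggregate_rate

__all__ = [
    "TensionRatePoint",
    "EdgeTensionFit",
    "BiphasicFit",
    "fit_edge_tension",
    "gamma_confidence_interval",
    "bootstrap_gamma",
    "fit_biphasic",
    "predict_rate_curve",
]


@dataclass(frozen=True)
class TensionRatePoint:
    """One (applied tension, measured rate) pair for a single peptide content."""

    sigma_e: float
    k_r: float
    k_r_se: Optional[float] = None
    gra_mole_percent: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_e > 0:
            raise ValueError(f"sigma_e must be strictly positive, got {self.sigma_e!r}")
        if not self.k_r > 0:
            raise ValueError(
                f"k_r must be strictly positive (its log is taken), got {self.k_r!r}"
            )


@dataclass(frozen=True)
class EdgeTensionFit:
    """Result of the ln k_r vs 1/(sigma_e + B) straight-line fit.

    ``slope`` carries units of N/m (tension), ``intercept`` is ln A
    (dimensionless), ``Gamma`` and ``Gamma_se`` are in N, ``A`` in 1/s.
    """

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    Gamma: float
    Gamma_se: float
    A: float
    r_squared: float
    n_points: int
    B: float
    T: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("EdgeTensionFit requires a negative slope")


@dataclass(frozen=True)
class BiphasicFit:
    """Quadratic fit of edge tension against peptide mole fraction.

    Coefficients follow the convention Gamma(phi) = Gamma0 + a*phi - b*phi**2,
    i.e. ``b`` is the negated phi^2 regression coefficient.
    """

    Gamma0: float
    a: float
    b: float
    Gamma0_se: float
    a_se: float
    b_se: float
    residual_sum_of_squares: float
    n_points: int

    def predict(self, phi: np.ndarray | float) -> np.ndarray | float:
        phi = np.asarray(phi, dtype=float)
        out = self.Gamma0 + self.a * phi - self.b * phi**2
        return float(out) if out.ndim == 0 else out


def fit_edge_tension(
    points: Sequence[TensionRatePoint],
    B: float = DEFAULT_B_N_PER_M,
    constants: MembraneConstants | None = None,
    weighting: str = "none",
) -> EdgeTensionFit:
    """Fit ln k_r = intercept + slope / (sigma_e + B) and derive Gamma and A.

    Parameters
    ----------
    points
        At least 3 points at distinct tensions, all for the same peptide
        content.
    B
        Electrostatic tension component in N/m, added to each sigma_e.
    weighting
        "none" for ordinary least squares (default; mirrors the conventional
        analysis) or "inverse-variance" to weight each point by
        (k_r / k_r_se)^2, the inverse variance of ln k_r.
    """
    if constants is None:
        constants = MembraneConstants()
    points = list(points)
    sigmas = np.array([p.sigma_e for p in points], dtype=float)
    if len(set(np.round(sigmas, 12))) < 3:
        raise ValueError("need at least 3 distinct tensions to fit the linearized rate law")
    gras = {p.gra_mole_percent for p in points}
    if len(gras) > 1:
        raise ValueError(
            f"points mix peptide contents {sorted(gras)}; fit each content separately"
        )

    x = 1.0 / (sigmas + B)
    y = np.log(np.array([p.k_r for p in points], dtype=float))
    X = sm.add_constant(x)
    if weighting == "none":
        model = sm.OLS(y, X)
    elif weighting == "inverse-variance":
        ses = [p.k_r_se for p in points]
        if any(s is None or not s > 0 for s in ses):
            raise ValueError("inverse-variance weighting requires positive k_r_se on every point")
        # var(ln k) ~ (se_k / k)^2 by the delta method
        w = np.array([(p.k_r / p.k_r_se) ** 2 for p in points], dtype=float)
        model = sm.WLS(y, X, weights=w)
    else:
        raise ValueError(f"weighting must be 'none' or 'inverse-variance', got {weighting!r}")
    res = model.fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse
    if slope >= 0:
        raise ValueError(
            "non-physical fit: rate must decrease with 1/(sigma_e + B) "
            f"(fitted slope {slope:.4g} >= 0)"
        )
    kBT = constants.kBT
    gamma = math.sqrt(-slope * kBT / math.pi)
    gamma_se = abs(kBT / (2.0 * math.pi * gamma)) * slope_se
    return EdgeTensionFit(
        slope=float(slope),
        slope_se=float(slope_se),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        Gamma=gamma,
        Gamma_se=float(gamma_se),
        A=math.exp(float(intercept)),
        r_squared=float(res.rsquared),
        n_points=len(points),
        B=B,
        T=constants.T,
    )


def gamma_confidence_interval(fit: EdgeTensionFit, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for Gamma, in N.

    Built by transforming the exact Student-t interval for the slope through
    the monotone map Gamma = sqrt(-slope * k_B T / pi) (t quantile with
    n_points - 2 residual degrees of freedom).  Because the map is monotone,
    the transformed interval inherits the slope interval's coverage without
    the symmetric delta-method approximation, which matters at the small
    point counts typical of these designs.  If the slope's upper limit
    reaches zero the lower Gamma limit is clamped at 0.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level!r}")
    df = fit.n_points - 2
    if df < 1:
        raise ValueError("confidence interval needs at least 3 points")
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    # recover k_B T from the fit's own slope/Gamma relation
    kBT = fit.Gamma**2 * math.pi / (-fit.slope)
    slope_lo = fit.slope - tq * fit.slope_se  # more negative -> larger Gamma
    slope_hi = fit.slope + tq * fit.slope_se
    gamma_hi = math.sqrt(-slope_lo * kBT / math.pi)
    gamma_lo = math.sqrt(max(-slope_hi, 0.0) * kBT / math.pi)
    return (gamma_lo, gamma_hi)


def bootstrap_gamma(
    records: Sequence[VesicleRecord],
    B: float = DEFAULT_B_N_PER_M,
    constants: MembraneConstants | None = None,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
    estimator: str = "ls",
) -> np.ndarray:
    """Vesicle-level bootstrap distribution of Gamma (N) from raw records.

    Vesicles are the independent replicates, so resampling is with
    replacement within each tension group; each resample is refit end to end
    (rate per tension, then the linearized regression).  Resamples whose
    refit degenerates (all censored in a group, or a non-negative slope)
    are skipped, which slightly understates the spread in pathological
    designs but keeps the distribution interpretable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = list(records)
    groups: dict[float, list[VesicleRecord]] = {}
    for r in records:
        groups.setdefault(r.sigma_e, []).append(r)
    if len(groups) < 3:
        raise ValueError("bootstrap needs records at >= 3 distinct tensions")
    gammas = []
    for _ in range(n_boot):
        try:
            pts = []
            for sigma, grp in groups.items():
                idx = rng.integers(0, len(grp), size=len(grp))
                resampled = [grp[i] for i in idx]
                fit = aggregate_rate(resampled, method=estimator, pooled=True)
                pts.append(
                    TensionRatePoint(
                        sigma_e=sigma,
                        k_r=fit.k_r,
                        k_r_se=fit.k_r_se,
                        gra_mole_percent=grp[0].gra_mole_percent,
                    )
                )
            gammas.append(fit_edge_tension(pts, B=B, constants=constants).Gamma)
        except ValueError:
            continue
    if not gammas:
        raise ValueError("every bootstrap resample degenerated; design too sparse")
    return np.asarray(gammas)


def fit_biphasic(
    phi: Sequence[float],
    Gamma: Sequence[float],
    Gamma_se: Optional[Sequence[float]] = None,
) -> BiphasicFit:
    """Least-squares quadratic Gamma(phi) = Gamma0 + a*phi - b*phi**2.

    ``phi`` are peptide mole fractions in [0, 1] (at least 3 distinct values),
    ``Gamma`` edge tensions in N.  With ``Gamma_se`` given, points are
    weighted by inverse variance.  The phi^2 regression coefficient is
    negated on output so that ``b`` follows the -b*phi**2 sign convention.
    """
    phi = np.asarray(phi, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    if phi.shape != Gamma.shape:
        raise ValueError("phi and Gamma must have the same length")
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("phi values must lie in [0, 1]")
    if len(np.unique(phi)) < 3:
        raise ValueError("need at least 3 distinct mole fractions for a quadratic fit")
    X = np.column_stack([np.ones_like(phi), phi, phi**2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design is collinear; mole fractions do not span a quadratic")
    if Gamma_se is None:
        model = sm.OLS(Gamma, X)
    else:
        se = np.asarray(Gamma_se, dtype=float)
        if np.any(se <= 0):
            raise ValueError("Gamma_se must be strictly positive")
        model = sm.WLS(Gamma, X, weights=1.0 / se**2)
    # three points determine the quadratic exactly (zero residual dof);
    # coefficient SEs are then undefined and come out nan
    with np.errstate(divide="ignore", invalid="ignore"):
        res = model.fit()
        c0, c1, c2 = res.params
        se0, se1, se2 = res.bse
    resid = Gamma - X @ res.params
    return BiphasicFit(
        Gamma0=float(c0),
        a=float(c1),
        b=float(-c2),
        Gamma0_se=float(se0),
        a_se=float(se1),
        b_se=float(se2),
        residual_sum_of_squares=float(resid @ resid),
        n_points=len(phi),
    )


def predict_rate_curve(
    fit: EdgeTensionFit,
    sigma_grid: Sequence[float] | np.ndarray,
    B: Optional[float] = None,
    constants: MembraneConstants | None = None,
) -> np.ndarray:
    """Rupture rates (1/s) predicted by a fitted rate law on a tension grid.

    Evaluates the Arrhenius law with the fitted Gamma and A, which in
    ln-space is exactly the fitted straight line; rates increase strictly
    with tension.
    """
    if B is None:
        B = fit.B
    sigma = np.asarray(sigma_grid, dtype=float)
    if np.any(sigma + B <= 0):
        raise ValueError("sigma_grid + B must be strictly positive")
    return np.exp(fit.intercept + fit.slope / (sigma + B))
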