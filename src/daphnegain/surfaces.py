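"""Two-regime photosynthetic response surfaces and light-response traits.

Net photosynthesis Pn of a leaf responds jointly to temperature and light.
Measured over a factorial grid of chamber temperatures and PAR levels, the
response of understory shrub leaves splits into two qualitatively different
regimes, fitted independently:

* **low light** (PAR below a split point, default 75 µmol m⁻² s⁻¹): a
  paraboloid, linear in its coefficients::

      Pn = k − a·Temp + b·PAR + c·Temp² − d·PAR²

  which captures the near-linear light response below saturation and the
  temperature dependence of dark respiration (Pn at PAR = 0 is −Rd(Temp));

* **high light** (at and above the split): a two-dimensional Lorentzian
  peak::

      Pn = a / [(1 + ((Temp − k)/b)²) · (1 + ((PAR − l)/c)²)]

  with maximum ``a`` at temperature optimum ``k`` and PAR optimum ``l`` and
  half-widths ``b`` (°C) and ``c`` (µmol m⁻² s⁻¹).

The two fits are joined into a :class:`HybridResponseSurface` used to predict
Pn from microclimate records.  No continuity is enforced at the split; the
step there is reported as a diagnostic, not repaired.

Single-temperature light-response curves are reduced to the classical traits
A_max (light-saturated net rate), Rd (dark respiration) and LCP (light
compensation point) by fitting a non-rectangular hyperbola.

Estimators follow scikit-learn conventions (``fit``/``predict``, fitted
attributes with trailing underscores) so they compose with sklearn tooling;
the module-level ``fit_*`` functions are thin wrappers over them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_PAR_SPLIT = 75.0


class ConvergenceError(RuntimeError):
    """Nonlinear surface fitting failed to converge from every start."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ParaboloidParams:
    """Low-light regime coefficients of Pn = k − a·Temp + b·PAR + c·Temp² − d·PAR²."""

    k: float
    a: float
    b: float
    c: float
    d: float

    def predict(self, temp, par):
        temp = np.asarray(temp, dtype=float)
        par = np.asarray(par, dtype=float)
        return (self.k - self.a * temp + self.b * par
                + self.c * temp**2 - self.d * par**2)


@dataclass(frozen=True)
class LorentzianParams:
    """High-light regime: 2-D Lorentzian peak.

    ``a`` peak Pn (µmol m⁻² s⁻¹), ``k`` peak temperature (°C), ``b``
    temperature half-width (°C), ``l`` peak PAR (µmol m⁻² s⁻¹), ``c`` PAR
    half-width (µmol m⁻² s⁻¹).
    """

    a: float
    k: float
    b: float
    l: float
    c: float

    def __post_init__(self):
        if self.b == 0 or self.c == 0:
            raise ValueError("Lorentzian half-widths b and c must be nonzero")

    def predict(self, temp, par):
        temp = np.asarray(temp, dtype=float)
        par = np.asarray(par, dtype=float)
        return self.a / ((1.0 + ((temp - self.k) / self.b) ** 2)
                         * (1.0 + ((par - self.l) / self.c) ** 2))


@dataclass
class HybridResponseSurface:
    """Paraboloid below ``par_split``, Lorentzian at and above it.

    The split is half-open: the low regime owns [0, par_split), the high
    regime [par_split, ∞).
    """

    low: ParaboloidParams
    high: LorentzianParams
    par_split: float = DEFAULT_PAR_SPLIT
    fit_r2_low: float | None = None
    fit_r2_high: float | None = None

    def __post_init__(self):
        if self.par_split <= 0:
            raise ValueError("par_split must be positive")

    def predict(self, temp, par):
        temp, par = np.broadcast_arrays(np.asarray(temp, dtype=float),
                                        np.asarray(par, dtype=float))
        return np.where(par < self.par_split,
                        self.low.predict(temp, par),
                        self.high.predict(temp, par))

    def dark_respiration(self, temp):
        """Rd(Temp) implied by the low-light regime: −Pn at PAR = 0."""
        return -self.low.predict(temp, 0.0)

    def split_step(self, temp):
        """Prediction discontinuity at the split point (diagnostic only)."""
        return float(self.high.predict(temp, self.par_split)
                     - self.low.predict(temp, self.par_split))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"low": asdict(self.low), "high": asdict(self.high),
                   "par_split": self.par_split,
                   "fit_r2_low": self.fit_r2_low, "fit_r2_high": self.fit_r2_high}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "HybridResponseSurface":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        return cls(low=ParaboloidParams(**payload["low"]),
                   high=LorentzianParams(**payload["high"]),
                   par_split=payload.get("par_split", DEFAULT_PAR_SPLIT),
                   fit_r2_low=payload.get("fit_r2_low"),
                   fit_r2_high=payload.get("fit_r2_high"))


def predict_pn(surface: HybridResponseSurface, temp, par):
    """Raw hybrid-surface prediction (no sanitization)."""
    return surface.predict(temp, par)


# ---------------------------------------------------------------------------
# estimators


def _as_temp_par(X):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be of shape (n_samples, 2): columns (temp, par)")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    return X[:, 0], X[:, 1]


def _r2_corrected(y, yhat):
    """R² = 1 − SSE/SST with SST corrected for the mean of the observations."""
    y = np.asarray(y, dtype=float)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst if sst > 0 else np.nan, sse, sst


class ParaboloidSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares for the low-light paraboloid regime.

    Linear in its parameters, so the fit is exact least squares via the
    normal equations.  Fitted attributes: ``params_`` (:class:`ParaboloidParams`),
    ``r2_`` (corrected for the observation mean), ``f_statistic_`` and
    ``f_pvalue_`` (regression ANOVA with 4 model degrees of freedom),
    ``sse_``, ``n_``.
    """

    def fit(self, X, y):
        temp, par = _as_temp_par(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != temp.shape[0]:
            raise ValueError("X and y length mismatch")
        if temp.size < 5:
            raise ValueError("need at least 5 records to fit the paraboloid")
        if np.unique(temp).size < 2 or np.unique(par).size < 2:
            raise ValueError("design must span at least 2 temperatures and 2 PAR levels")
        design = np.column_stack([np.ones_like(temp), temp, par, temp**2, par**2])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient design (collinear temperature/PAR levels)")
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.params_ = ParaboloidParams(k=float(beta[0]), a=float(-beta[1]),
                                        b=float(beta[2]), c=float(beta[3]),
                                        d=float(-beta[4]))
        yhat = design @ beta
        self.r2_, self.sse_, sst = _r2_corrected(y, yhat)
        self.n_ = int(temp.size)
        df_model, df_resid = 4, self.n_ - 5
        if df_resid > 0 and self.sse_ > 0:
            self.f_statistic_ = ((sst - self.sse_) / df_model) / (self.sse_ / df_resid)
            self.f_pvalue_ = float(stats.f.sf(self.f_statistic_, df_model, df_resid))
        else:
            self.f_statistic_ = np.inf
            self.f_pvalue_ = 0.0
        return self

    def predict(self, X):
        temp, par = _as_temp_par(X)
        return self.params_.predict(temp, par)


def _lorentzian_model(tp, a, k, b, l, c):
    temp, par = tp
    return LorentzianParams(a, k, b, l, c).predict(temp, par)


class LorentzianSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least squares for the high-light Lorentzian regime.

    Initialization is data driven (peak height/location from the argmax
    record, half-widths from half the data ranges) with ``n_restarts``
    jittered restarts; the best converged start by SSE wins.  Fitted
    attributes: ``params_``, ``r2_``, ``sse_``, ``converged_``, ``n_``.

    Parameters
    ----------
    n_restarts : int
        Number of jittered restarts beyond the data-driven start.
    random_state : int
        Seed for the restart jitter.
    """

    def __init__(self, n_restarts: int = 10, random_state: int = 0,
                 maxfev: int = 20000):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.maxfev = maxfev

    def fit(self, X, y):
        temp, par = _as_temp_par(X)
        y = np.asarray(y, dtype=float)
        if temp.size < 6:
            raise ValueError("need at least 6 records to fit the Lorentzian")
        if np.unique(temp).size < 3 or np.unique(par).size < 3:
            raise ValueError("design must span at least 3 temperatures and 3 PAR levels")
        if np.ptp(y) == 0:
            raise ValueError("degenerate data: all Pn values identical")

        lower = np.array([1e-3, -20.0, 0.5, 10.0, 5.0])
        upper = np.array([50.0, 70.0, 300.0, 10000.0, 10000.0])
        imax = int(np.argmax(y))
        base = np.array([
            np.clip(y.max(), lower[0], upper[0]),
            np.clip(temp[imax], lower[1], upper[1]),
            np.clip(max(np.ptp(temp) / 2.0, 5.0), lower[2], upper[2]),
            np.clip(par[imax] if par[imax] > 0 else np.median(par), lower[3], upper[3]),
            np.clip(max(np.ptp(par) / 2.0, 50.0), lower[4], upper[4]),
        ])
        rng = np.random.default_rng(self.random_state)
        starts = [base]
        for _ in range(self.n_restarts):
            jitter = base * rng.lognormal(0.0, 0.3, size=5)
            jitter[1] = base[1] + rng.normal(0.0, max(np.ptp(temp) / 4.0, 2.0))
            jitter[3] = base[3] + rng.normal(0.0, max(np.ptp(par) / 4.0, 50.0))
            starts.append(np.clip(jitter, lower, upper))

        best = None
        for p0 in starts:
            try:
                popt, _ = optimize.curve_fit(
                    _lorentzian_model, (temp, par), y, p0=p0,
                    bounds=(lower, upper), maxfev=self.maxfev)
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((y - _lorentzian_model((temp, par), *popt)) ** 2))
            if best is None or sse < best[1]:
                best = (popt, sse)
        if best is None:
            raise ConvergenceError(
                f"Lorentzian fit failed to converge from {len(starts)} starts")
        popt, sse = best
        self.params_ = LorentzianParams(*[float(v) for v in popt])
        self.r2_, self.sse_, _ = _r2_corrected(y, _lorentzian_model((temp, par), *popt))
        self.converged_ = True
        self.n_ = int(temp.size)
        return self

    def predict(self, X):
        temp, par = _as_temp_par(X)
        return self.params_.predict(temp, par)


class HybridSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Fit both regimes on a partition of one factorial dataset.

    Records with PAR < ``par_split`` train the paraboloid, the rest the
    Lorentzian.  ``surface_`` holds the joined :class:`HybridResponseSurface`.
    """

    def __init__(self, par_split: float = DEFAULT_PAR_SPLIT,
                 n_restarts: int = 10, random_state: int = 0):
        self.par_split = par_split
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y):
        temp, par = _as_temp_par(X)
        y = np.asarray(y, dtype=float)
        low_mask = par < self.par_split
        if low_mask.sum() < 5:
            raise ValueError("too few low-light records below the PAR split")
        if (~low_mask).sum() < 6:
            raise ValueError("too few high-light records at/above the PAR split")
        lo = ParaboloidSurfaceRegressor().fit(
            np.column_stack([temp[low_mask], par[low_mask]]), y[low_mask])
        hi = LorentzianSurfaceRegressor(
            n_restarts=self.n_restarts, random_state=self.random_state).fit(
            np.column_stack([temp[~low_mask], par[~low_mask]]), y[~low_mask])
        self.low_ = lo
        self.high_ = hi
        self.surface_ = HybridResponseSurface(
            low=lo.params_, high=hi.params_, par_split=self.par_split,
            fit_r2_low=lo.r2_, fit_r2_high=hi.r2_)
        return self

    def predict(self, X):
        temp, par = _as_temp_par(X)
        return self.surface_.predict(temp, par)


# ---------------------------------------------------------------------------
# functional wrappers (CSV-frame interface)


def fit_paraboloid(data: pd.DataFrame, par_split: float = DEFAULT_PAR_SPLIT):
    """Fit the low-light paraboloid to records with PAR < ``par_split``.

    ``data`` needs columns ``temp``, ``par``, ``pn``.  Returns
    ``(ParaboloidParams, diagnostics dict)``.
    """
    sub = data[data["par"] < par_split]
    est = ParaboloidSurfaceRegressor().fit(
        sub[["temp", "par"]].to_numpy(), sub["pn"].to_numpy())
    diag = {"r2": est.r2_, "sse": est.sse_, "n": est.n_,
            "f_statistic": est.f_statistic_, "f_pvalue": est.f_pvalue_}
    return est.params_, diag


def fit_lorentzian(data: pd.DataFrame, par_split: float = DEFAULT_PAR_SPLIT,
                   n_restarts: int = 10, random_state: int = 0):
    """Fit the high-light Lorentzian to records with PAR ≥ ``par_split``."""
    sub = data[data["par"] >= par_split]
    est = LorentzianSurfaceRegressor(
        n_restarts=n_restarts, random_state=random_state).fit(
        sub[["temp", "par"]].to_numpy(), sub["pn"].to_numpy())
    diag = {"r2": est.r2_, "sse": est.sse_, "n": est.n_, "converged": est.converged_}
    return est.params_, diag


def fit_hybrid_surface(data: pd.DataFrame, par_split: float = DEFAULT_PAR_SPLIT,
                       n_restarts: int = 10, random_state: int = 0) -> HybridResponseSurface:
    """Fit both regimes of one plant's factorial dataset and join them."""
    est = HybridSurfaceRegressor(par_split=par_split, n_restarts=n_restarts,
                                 random_state=random_state).fit(
        data[["temp", "par"]].to_numpy(), data["pn"].to_numpy())
    return est.surface_


# ---------------------------------------------------------------------------
# prediction sanitization


def sanitize_predictions(temp, par, pn, floor: float = -10.0,
                         par_tol: float = 10.0, temp_tol: float = 2.0):
    """Repair physically inconsistent surface predictions.

    A prediction is flagged when it is positive in darkness (PAR = 0) or
    falls below a physical floor.  Each flagged value is replaced by the mean
    of the nearest non-flagged predictions (searching outward in time) whose
    temperature and PAR lie within ``temp_tol`` / ``par_tol`` of the flagged
    record's inputs.  If no similar neighbour exists anywhere in the series
    the nearest non-flagged values are used regardless of similarity.

    Returns ``(pn_clean, n_replaced)``.  Raises ``ValueError`` when every
    value is flagged.
    """
    temp = np.asarray(temp, dtype=float)
    par = np.asarray(par, dtype=float)
    pn = np.asarray(pn, dtype=float)
    flagged = ((par <= 0) & (pn > 0)) | (pn < floor)
    if flagged.all():
        raise ValueError("all predictions flagged as inconsistent; "
                         "check the fitted surface and input units")
    clean = pn.copy()
    n = pn.size
    idx_flagged = np.flatnonzero(flagged)
    for i in idx_flagged:
        replacement = None
        fallback = None
        for r in range(1, n):
            cands = [j for j in (i - r, i + r) if 0 <= j < n and not flagged[j]]
            if not cands:
                if i - r < 0 and i + r >= n:
                    break
                continue
            if fallback is None:
                fallback = float(np.mean([pn[j] for j in cands]))
            similar = [j for j in cands
                       if abs(temp[j] - temp[i]) <= temp_tol
                       and abs(par[j] - par[i]) <= par_tol]
            if similar:
                replacement = float(np.mean([pn[j] for j in similar]))
                break
        clean[i] = replacement if replacement is not None else fallback
    return clean, int(idx_flagged.size)


# ---------------------------------------------------------------------------
# single-curve light-response traits


@dataclass
class LightResponseTraits:
    """Traits of one light-response curve.

    ``amax``: light-saturated net rate Pmax − Rd; ``rd``: dark respiration
    (positive magnitude); ``lcp``: light compensation point, ``None`` when
    the fitted curve never crosses zero within the measured PAR range.
    """

    amax: float
    rd: float
    lcp: float | None
    phi: float
    theta: float
    pmax: float
    r2: float
    lcp_defined: bool


def nonrectangular_hyperbola(par, phi, theta, pmax, rd):
    """Non-rectangular hyperbola light response.

    Pn(PAR) = [φ·PAR + Pmax − √((φ·PAR + Pmax)² − 4·θ·φ·PAR·Pmax)] / (2θ) − Rd
    with quantum yield φ, curvature θ ∈ (0, 1], gross capacity Pmax and dark
    respiration Rd.
    """
    par = np.asarray(par, dtype=float)
    s = phi * par + pmax
    disc = np.clip(s**2 - 4.0 * theta * phi * par * pmax, 0.0, None)
    return (s - np.sqrt(disc)) / (2.0 * theta) - rd


def fit_light_response(par, pn, theta_bounds=(0.5, 0.99)) -> LightResponseTraits:
    """Fit a non-rectangular hyperbola to one PAR → Pn curve.

    Requires at least 4 distinct PAR levels including one at or near zero
    (≤ 5 µmol m⁻² s⁻¹).  The LCP is located by a bracketed root search on
    the fitted curve.
    """
    par = np.asarray(par, dtype=float)
    pn = np.asarray(pn, dtype=float)
    if np.unique(par).size < 4:
        raise ValueError("need at least 4 distinct PAR levels")
    if par.min() > 5.0:
        raise ValueError("curve must include a dark (PAR ≈ 0) point")
    if np.ptp(pn) == 0:
        raise ValueError("degenerate curve: all Pn values identical")

    i_dark = int(np.argmin(par))
    rd0 = max(-pn[i_dark], 0.05)
    pmax0 = max(pn.max() + rd0, 0.5)
    bright = par > par.min()
    slope0 = np.median((pn[bright] - pn[i_dark]) / (par[bright] - par[i_dark]))
    phi0 = float(np.clip(slope0, 1e-3, 0.4))
    lo = [1e-4, theta_bounds[0], 1e-3, 1e-6]
    hi = [0.5, theta_bounds[1], 500.0, 50.0]
    p0 = np.clip([phi0, 0.8, pmax0, rd0], lo, hi)
    try:
        popt, _ = optimize.curve_fit(nonrectangular_hyperbola, par, pn, p0=p0,
                                     bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:
        raise ConvergenceError(f"light-response fit did not converge: {err}") from err
    phi, theta, pmax, rd = (float(v) for v in popt)
    r2, _, _ = _r2_corrected(pn, nonrectangular_hyperbola(par, *popt))

    f = lambda q: nonrectangular_hyperbola(q, phi, theta, pmax, rd)
    lcp = None
    hi_par = float(par.max())
    if f(0.0) < 0.0 and f(hi_par) > 0.0:
        lcp = float(optimize.brentq(f, 0.0, hi_par, xtol=1e-10))
    return LightResponseTraits(amax=pmax - rd, rd=rd, lcp=lcp, phi=phi,
                               theta=theta, pmax=pmax, r2=r2,
                               lcp_defined=lcp is not None)
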