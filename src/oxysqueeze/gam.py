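"""Gaussian additive model for daily habitat-volume trends.

The daily suitable-habitat series is strongly persistent, so trends are
modelled with a penalized additive model

    volume_t = b0 + f(volume_{t-1}) + f(doy_t) + f(date_t) + f(level_t) + e_t

with Gaussian errors and identity link.  The day-of-year smooth uses a
cyclic cubic regression spline (continuous across the year boundary); the
lagged-volume, long-term date and water-level smooths use penalized
B-splines.  Smoothing parameters are selected by restricted maximum
likelihood (REML), term complexity is summarised by effective degrees of
freedom (edf), and per-term significance uses a Wald-type F test on the
fitted smooth at rank ~ edf (Wood-style), which is well calibrated for
penalized terms.

The fit is fully deterministic given the design table and basis
dimensions; no stochastic initialisation is involved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.gam.smooth_basis import BSplines, CyclicCubicSplines

from .errors import InsufficientDataError
from .habitat import Scenario
from .indicators import day_of_year

logger = logging.getLogger(__name__)

_MIN_ROWS = 30


def prepare_gam_table(
    volumes: pd.DataFrame,
    levels: pd.DataFrame,
    range_name: str,
    scenario: Scenario | str = Scenario.BOTH,
) -> pd.DataFrame:
    """Design table: volume, one-day-lagged volume, doy, fractional year, level.

    A row is kept only when the previous calendar day's volume and the
    day's water level are both observed.  Fractional year is
    ``year + doy/365.25`` (so Jan 1 1995 is 1995.003).
    """
    df = volumes[
        (volumes["range_name"] == range_name)
        & (volumes["scenario"] == Scenario(scenario).value)
    ][["date", "volume_m3"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    lag = df.rename(columns={"volume_m3": "volume_lag1_m3"}).copy()
    lag["date"] = lag["date"] + pd.Timedelta(days=1)
    out = df.merge(lag, on="date", how="inner")
    lev = levels[["date", "level_m"]].copy()
    lev["date"] = pd.to_datetime(lev["date"])
    out = out.merge(lev, on="date", how="inner").sort_values("date")
    doy = day_of_year(out["date"])
    out["day_of_year"] = doy
    out["date_frac"] = pd.DatetimeIndex(out["date"]).year + doy / 365.25
    out = out.reset_index(drop=True)
    if len(out) < _MIN_ROWS:
        raise InsufficientDataError(
            f"only {len(out)} usable rows (need >= {_MIN_ROWS})"
        )
    return out


@dataclass
class TermFit:
    """Summary of one smooth term."""

    name: str
    k: int
    edf: float
    f_stat: float
    p_value: float
    degenerate: bool = False


@dataclass
class GamFit:
    """Fitted additive model with diagnostics and partial effects."""

    terms: list[TermFit]
    r_squared: float
    r_squared_adj: float
    sigma2: float
    edf_total: float
    n: int
    fitted: np.ndarray
    residuals: np.ndarray
    lambdas: dict[str, float]
    partial_effects: pd.DataFrame
    resid_lag1_acf: float
    intercept: float
    _predict: object = field(default=None, repr=False)

    def term(self, name: str) -> TermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "k": t.k,
                    "edf": t.edf,
                    "F": t.f_stat,
                    "p": t.p_value,
                    "degenerate": t.degenerate,
                }
                for t in self.terms
            ]
        )


class _SmoothTerm:
    """Centred spline basis + penalty for one predictor."""

    def __init__(self, name: str, x: np.ndarray, k: int, cyclic: bool):
        if k < 3:
            raise ValueError("basis dimension must be >= 3")
        self.name, self.k, self.cyclic = name, k, cyclic
        x = np.asarray(x, dtype=float)
        self.degenerate = np.ptp(x) == 0
        if self.degenerate:
            warnings.warn(
                f"term {name!r}: constant predictor, effect fixed at zero",
                stacklevel=2,
            )
            self._smoother = None
            self.X = np.zeros((len(x), 1))
            self.S = np.eye(1)
            self.rank = 1
            self.Z = np.eye(1)
            return
        if cyclic:
            self._smoother = CyclicCubicSplines(x[:, None], df=[k])
        else:
            # equally spaced knots: quantile placement degenerates when the
            # predictor has a point mass (e.g. many zero-volume days)
            self._smoother = BSplines(
                x[:, None],
                df=[k],
                degree=[3],
                include_intercept=True,
                knot_kwds=[{"spacing": "equal"}],
            )
        B = self._smoother.basis
        S = self._smoother.penalty_matrices[0]
        # centring constraint sum_i f(x_i) = 0 via the null space of the
        # column-mean vector; removes the constant direction from the span
        c = B.mean(axis=0)
        q, _ = np.linalg.qr(
            np.column_stack([c, np.eye(len(c))]), mode="reduced"
        )
        Z = q[:, 1:]
        self.Z = Z
        self.X = B @ Z
        self.S = Z.T @ S @ Z
        eig = np.linalg.eigvalsh(self.S)
        self.rank = int((eig > eig.max() * 1e-9).sum()) if eig.max() > 0 else 0

    def basis_at(self, x_new: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.zeros((len(x_new), 1))
        return self._smoother.transform(np.asarray(x_new, float)[:, None]) @ self.Z


def _reml_score(rho, XtX, Xty, yty, blocks, n, mp, want_grad=False):
    """Negative restricted log-likelihood (profiled scale), up to constants.

    With ``want_grad`` also returns the exact gradient in rho = log(lambda):
    the envelope theorem gives dD/drho_j = lambda_j beta'S_j beta, and
    d logdet(H)/drho_j = lambda_j tr(H^-1 S_j).
    """
    p = XtX.shape[0]
    S = np.zeros((p, p))
    for (sl, Sj, rj), r in zip(blocks, rho):
        S[sl, sl] += np.exp(r) * Sj
    H = XtX + S
    try:
        cf = linalg.cho_factor(H, lower=True)
    except linalg.LinAlgError:
        # numerically semidefinite design (tied predictor values); a tiny
        # ridge restores positive definiteness without noticeable bias
        H = H + (1e-10 * np.trace(H) / p) * np.eye(p)
        try:
            cf = linalg.cho_factor(H, lower=True)
        except linalg.LinAlgError:
            if want_grad:
                return np.inf, None, np.zeros(len(rho))
            return np.inf, None
    beta = linalg.cho_solve(cf, Xty)
    rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
    pen = beta @ S @ beta
    d = max(rss + pen, 1e-300)
    logdet_h = 2.0 * np.sum(np.log(np.diag(cf[0])))
    logdet_s = sum(rj * r for (_, _, rj), r in zip(blocks, rho))
    score = (n - mp) * np.log(d) + logdet_h - logdet_s
    if not want_grad:
        return score, beta
    Hinv = linalg.cho_solve(cf, np.eye(p))
    grad = np.zeros(len(rho))
    for i, ((sl, Sj, rj), r) in enumerate(zip(blocks, rho)):
        lam = np.exp(r)
        d_pen = lam * (beta[sl] @ Sj @ beta[sl])
        d_logdet = lam * np.trace(Hinv[sl, sl] @ Sj)
        grad[i] = (n - mp) * d_pen / d + d_logdet - rj
    return score, beta, grad


def fit_squeeze_gam(
    table: pd.DataFrame,
    k_lag: int = 10,
    k_doy: int = 20,
    k_date: int = 10,
    k_level: int = 10,
    seed: int | None = None,
) -> GamFit:
    """Fit the four-smooth additive model to a prepared design table.

    ``seed`` is accepted for interface symmetry with the stochastic stages;
    the fit itself is deterministic.  Basis dimensions must be >= 3 with at
    least 30 rows.  A constant predictor yields a degenerate term (edf ~ 0,
    warning) rather than an exception.
    """
    del seed  # deterministic fit
    if len(table) < _MIN_ROWS:
        raise InsufficientDataError(f"need >= {_MIN_ROWS} rows, got {len(table)}")
    y = table["volume_m3"].to_numpy(dtype=float)
    n = len(y)
    if np.ptp(y) == 0:
        warnings.warn("constant response: all smooth effects degenerate", stacklevel=2)
        return _degenerate_fit(table, y, k_lag, k_doy, k_date, k_level)
    specs = [
        ("volume_lag1_m3", k_lag, False),
        ("day_of_year", k_doy, True),
        ("date_frac", k_date, False),
        ("level_m", k_level, False),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        terms = [
            _SmoothTerm(name, table[name].to_numpy(dtype=float), k, cyc)
            for name, k, cyc in specs
        ]

    X_parts = [np.ones((n, 1))] + [t.X for t in terms]
    X = np.column_stack(X_parts)
    slices, start = [], 1
    for t in terms:
        stop = start + t.X.shape[1]
        slices.append(slice(start, stop))
        start = stop
    p = X.shape[1]

    y_mean = y.mean()
    yc = y - y_mean  # centre response; intercept refit after
    XtX = X.T @ X
    Xty = X.T @ yc
    yty = yc @ yc
    blocks = [(sl, t.S, t.rank) for sl, t in zip(slices, terms)]
    mp = p - sum(t.rank for t in terms)

    def objective(rho):
        score, _, grad = _reml_score(rho, XtX, Xty, yty, blocks, n, mp, want_grad=True)
        return score, grad

    # balanced start: lambda_j ~ tr(X_j'X_j)/tr(S_j), the classic smoothing
    # initialisation; REML surfaces can be multimodal when a time smooth is
    # flexible enough to alias the seasonal cycle, and this start keeps the
    # local optimum in the intended basin (as mgcv's does)
    x0 = np.zeros(len(terms))
    for i, (a, Sj, _) in enumerate(blocks):
        tr_x, tr_s = np.trace(XtX[a, a]), np.trace(Sj)
        if tr_x > 0 and tr_s > 0:
            x0[i] = np.log(tr_x / tr_s)
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        jac=True,
        bounds=[(-18.0, 22.0)] * len(terms),
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
    )
    rho = res.x
    _, beta = _reml_score(rho, XtX, Xty, yty, blocks, n, mp)

    S = np.zeros((p, p))
    for (sl, Sj, rj), r in zip(blocks, rho):
        S[sl, sl] += np.exp(r) * Sj
    H = XtX + S
    try:
        Hinv = linalg.cho_solve(linalg.cho_factor(H, lower=True), np.eye(p))
    except linalg.LinAlgError:
        Hinv = linalg.pinvh(H)
    F = Hinv @ XtX
    FF = F @ F
    edf_total = float(np.trace(F))
    fitted = X @ beta + y_mean
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(yc @ yc)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    denom = max(n - edf_total, 1.0)
    r2_adj = 1.0 - (rss / denom) / (tss / (n - 1)) if tss > 0 else 0.0
    sigma2 = rss / denom
    Vb = sigma2 * Hinv

    term_fits, lambdas = [], {}
    pe_frames = []
    for (name, k, cyc), t, sl, r in zip(specs, terms, slices, rho):
        edf_j = float(np.trace(F[sl, sl]))
        # "alternative" edf tr(2F - F^2), the better testing rank
        edf1_j = float(2.0 * np.trace(F[sl, sl]) - np.trace(FF[sl, sl]))
        lambdas[name] = float(np.exp(r))
        if t.degenerate or edf_j < 1e-3:
            term_fits.append(TermFit(name, k, max(edf_j, 0.0), 0.0, 1.0, True))
        else:
            beta_j = beta[sl]
            V_j = Vb[sl, sl]
            Rj = np.linalg.qr(t.X, mode="r")
            fj = Rj @ beta_j
            M = Rj @ V_j @ Rj.T
            w, U = np.linalg.eigh(M)
            # integer testing rank from the alternative edf: floor, bumped
            # when the fractional part exceeds 0.05
            rank_f = min(len(w), max(edf1_j, 1.0))
            rank = int(np.floor(rank_f))
            if rank_f - rank > 0.05:
                rank += 1
            rank = int(np.clip(rank, 1, len(w)))
            idx = np.argsort(w)[::-1][:rank]
            w_sel, U_sel = w[idx], U[:, idx]
            w_sel = np.maximum(w_sel, w_sel.max() * 1e-12)
            tstat = float((U_sel.T @ fj) ** 2 @ (1.0 / w_sel))
            f_stat = tstat / rank
            p_val = float(stats.f.sf(f_stat, rank, denom))
            term_fits.append(TermFit(name, k, edf_j, f_stat, p_val, False))
        # centred partial-effect curve on an even grid
        xobs = table[name].to_numpy(dtype=float)
        grid = np.linspace(xobs.min(), xobs.max(), 200)
        G = t.basis_at(grid)
        eff = G @ beta[sl]
        se = np.sqrt(np.maximum(np.sum((G @ Vb[sl, sl]) * G, axis=1), 0.0))
        pe_frames.append(
            pd.DataFrame({"term": name, "grid_value": grid, "effect": eff, "se": se})
        )

    resid_acf = float("nan")
    if np.std(resid) > 0 and n > 3:
        resid_acf = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])

    def _predict(new: pd.DataFrame) -> np.ndarray:
        parts = [np.ones((len(new), 1))]
        for (name, _, _), t in zip(specs, terms):
            parts.append(t.basis_at(new[name].to_numpy(dtype=float)))
        return np.column_stack(parts) @ beta + y_mean

    return GamFit(
        terms=term_fits,
        r_squared=r2,
        r_squared_adj=r2_adj,
        sigma2=sigma2,
        edf_total=edf_total,
        n=n,
        fitted=fitted,
        residuals=resid,
        lambdas=lambdas,
        partial_effects=pd.concat(pe_frames, ignore_index=True),
        resid_lag1_acf=resid_acf,
        intercept=float(beta[0] + y_mean),
        _predict=_predict,
    )


def _degenerate_fit(table, y, k_lag, k_doy, k_date, k_level) -> GamFit:
    """Zero-variance response: every smooth effect is identically zero."""
    n = len(y)
    specs = [
        ("volume_lag1_m3", k_lag),
        ("day_of_year", k_doy),
        ("date_frac", k_date),
        ("level_m", k_level),
    ]
    pe = []
    for name, _ in specs:
        x = table[name].to_numpy(dtype=float)
        grid = np.linspace(x.min(), x.max(), 200)
        pe.append(
            pd.DataFrame(
                {"term": name, "grid_value": grid, "effect": 0.0, "se": 0.0}
            )
        )
    return GamFit(
        terms=[TermFit(name, k, 0.0, 0.0, 1.0, True) for name, k in specs],
        r_squared=0.0,
        r_squared_adj=0.0,
        sigma2=0.0,
        edf_total=0.0,
        n=n,
        fitted=np.full(n, y.mean()),
        residuals=np.zeros(n),
        lambdas={name: np.inf for name, _ in specs},
        partial_effects=pd.concat(pe, ignore_index=True),
        resid_lag1_acf=float("nan"),
        intercept=float(y.mean()),
        _predict=lambda new: np.full(len(new), y.mean()),
    )


def long_term_trend_test(fit: GamFit, alpha: float = 0.05) -> dict:
    """Classify the long-term date smooth: linear vs nonlinear, significant or not.

    A date-term edf <= 1.1 is reported as effectively linear (one degree of
    freedom beyond the intercept), matching the usual edf reading of
    penalized smooths.
    """
    t = fit.term("date_frac")
    return {
        "edf": t.edf,
        "p_value": t.p_value,
        "shape": "linear" if t.edf <= 1.1 else "nonlinear",
        "significant": bool(t.p_value < alpha),
    }
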