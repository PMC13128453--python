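"""Covalent-ligand and enzyme kinetics fits.

Three regression-shaped estimators, each seeded from a deterministic
linearization and solved by nonlinear least squares:

* :class:`FirstOrderDecay` — pseudo-first-order loss of unreacted species,
  ``v(t) = v0 * exp(-k_obs t)``; with the inhibitor concentration declared,
  the second-order efficiency ``k_obs/[I]`` (M^-1 s^-1) is derived.
* :class:`LogisticIC50` — four-parameter logistic dose-response with the
  top and bottom constrained to 100% and 0%:
  ``response = 100 / (1 + (IC50/x)^h)``.
* :class:`MichaelisMenten` — ``v = Vmax S / (Km + S)`` over pooled
  replicates; with the enzyme concentration declared, ``k_cat`` and
  ``k_cat/Km`` follow, the latter with a symmetric (Wald) confidence
  interval propagated from the parameter covariance.

All confidence intervals are symmetric Wald intervals (estimate +/- 1.96 SE);
lower bounds are reported even when negative.  Inputs are SI: seconds and
molar.  The module-level functions are thin wrappers returning a
:class:`KineticFit` record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

Z95 = 1.959963984540054

_OPT = dict(xtol=1e-10, ftol=1e-10, gtol=1e-10, maxfev=10_000)

_TIME_UNITS = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0}
_CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


def to_seconds(value, unit: str):
    """Convert a declared time unit to seconds (unit declaration required)."""
    if unit not in _TIME_UNITS:
        raise ValueError(f"unknown time unit {unit!r}; declare one of {sorted(_TIME_UNITS)}")
    return np.asarray(value, dtype=float) * _TIME_UNITS[unit]


def to_molar(value, unit: str):
    """Convert a declared concentration unit to molar."""
    if unit not in _CONC_UNITS:
        raise ValueError(
            f"unknown concentration unit {unit!r}; declare one of {sorted(_CONC_UNITS)}"
        )
    return np.asarray(value, dtype=float) * _CONC_UNITS[unit]


@dataclass(frozen=True)
class TimeCourse:
    """Fraction of unreacted species (GSH or protein complex) over time."""

    times: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # fraction remaining
    inhibitor_conc: float | None = None  # molar
    species: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape or len(t) == 0:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")


@dataclass
class KineticFit:
    """Fitted kinetic parameters with symmetric uncertainties."""

    model: str
    params: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    rss: float = np.nan
    n: int = 0
    flags: tuple[str, ...] = ()

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def _wald(params: dict, se: dict) -> dict:
    return {
        k: (params[k] - Z95 * se[k], params[k] + Z95 * se[k])
        for k in se
        if np.isfinite(se[k])
    }


# ---------------------------------------------------------------------------
# first-order decay
# ---------------------------------------------------------------------------


class FirstOrderDecay(BaseEstimator, RegressorMixin):
    """Pseudo-first-order decay ``v = v0 exp(-k_obs t)``.

    Parameters
    ----------
    fix_v0 : bool
        Fix the initial fraction at 1 instead of fitting it (single-parameter
        fit; appropriate when traces are normalized to the t=0 measurement).

    Fitted attributes: ``k_obs_`` (s^-1), ``v0_``, ``kobs_per_I_``
    (M^-1 s^-1, when the inhibitor concentration was given), ``se_``,
    ``ci95_``, ``flags_``, ``result_``.
    """

    def __init__(self, fix_v0: bool = False):
        self.fix_v0 = fix_v0

    def fit(self, t, v, inhibitor_conc: float | None = None):
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if len(t) < 2:
            raise ValueError("need at least 2 time points")
        flags: list[str] = []

        pos = v > 0
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(v[pos]), 1)[0]
            k0 = max(-slope, 0.0)
            v0_0 = float(np.exp(np.polyfit(t[pos], np.log(v[pos]), 1)[1]))
        else:
            k0, v0_0 = 1.0 / max(t[-1], 1.0), 1.0
            flags.append("seed_fallback")

        if self.fix_v0:
            fun = lambda tt, k: np.exp(-k * tt)
            p0, bounds = [k0], (0.0, np.inf)
        else:
            fun = lambda tt, k, v0: v0 * np.exp(-k * tt)
            p0, bounds = [k0, max(v0_0, 1e-12)], ([0.0, 0.0], [np.inf, np.inf])

        try:
            popt, pcov = curve_fit(
                fun, t, v, p0=p0, bounds=bounds, **_OPT
            )
            perr = np.sqrt(np.diag(pcov))
        except RuntimeError:
            popt, perr = np.asarray(p0), np.full(len(p0), np.nan)
            flags.append("non_converged")

        self.k_obs_ = float(popt[0])
        self.v0_ = 1.0 if self.fix_v0 else float(popt[1])
        # no decay signal: nothing falls below the initial observation
        v_ref = 1.0 if self.fix_v0 else v[0]
        if np.all(v >= v_ref * (1.0 - 1e-9)) or self.k_obs_ <= 1e-15:
            self.k_obs_ = 0.0
            flags.append("no_decay")
        resid = v - fun(t, *popt)
        params = {"k_obs": self.k_obs_, "v0": self.v0_}
        se = {"k_obs": float(perr[0])}
        if not self.fix_v0:
            se["v0"] = float(perr[1])
        self.kobs_per_I_ = np.nan
        if inhibitor_conc is not None:
            if inhibitor_conc <= 0:
                raise ValueError("inhibitor concentration must be positive (molar)")
            self.kobs_per_I_ = self.k_obs_ / inhibitor_conc
            params["kobs_per_I"] = self.kobs_per_I_
            se["kobs_per_I"] = se["k_obs"] / inhibitor_conc
        self.se_ = se
        self.ci95_ = _wald(params, se)
        self.flags_ = tuple(flags)
        self.result_ = KineticFit(
            model="first_order",
            params=params,
            se=se,
            ci95=self.ci95_,
            rss=float(np.sum(resid**2)),
            n=len(t),
            flags=self.flags_,
        )
        return self

    def predict(self, t):
        return self.v0_ * np.exp(-self.k_obs_ * np.asarray(t, dtype=float))


def fit_first_order(tc: TimeCourse, fix_v0: bool = False) -> KineticFit:
    """Fit a pseudo-first-order decay to a time course."""
    est = FirstOrderDecay(fix_v0=fix_v0).fit(
        tc.times, tc.values, inhibitor_conc=tc.inhibitor_conc
    )
    return est.result_


def kobs_from_endpoint(v_remaining: float, t: float, inhibitor_conc: float) -> KineticFit:
    """Single-endpoint pseudo-first-order rate: ``-ln(v) / (t [I])``.

    ``v_remaining`` is the fraction of unreacted species at time ``t``
    (seconds) under inhibitor concentration ``inhibitor_conc`` (molar).
    Complete consumption (v <= 0) yields an undefined rate with an explicit
    status flag; v >= 1 yields zero with a no-decay flag.
    """
    if t <= 0 or inhibitor_conc <= 0:
        raise ValueError("time and inhibitor concentration must be positive")
    flags: tuple[str, ...] = ()
    if v_remaining <= 0:
        k = np.nan
        flags = ("undefined_complete_consumption",)
    elif v_remaining >= 1:
        k = 0.0
        if v_remaining > 1:
            flags = ("no_decay",)
    else:
        k = -np.log(v_remaining) / t
    return KineticFit(
        model="first_order_endpoint",
        params={"k_obs": k, "kobs_per_I": k / inhibitor_conc},
        n=1,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# constrained 4PL IC50
# ---------------------------------------------------------------------------


class LogisticIC50(BaseEstimator, RegressorMixin):
    """Four-parameter logistic dose-response with top=100 and bottom=0 fixed.

    ``response = 100 / (1 + (IC50/x)^h)`` fitted as (log10 IC50, Hill slope)
    for numerical stability.  Fitted attributes: ``ic50_``, ``hill_``,
    ``se_``, ``ci95_``, ``status_`` ("ok", "no_transition" or
    "non_converged"), ``flags_``, ``result_``.
    """

    def __init__(self, hill_sign: float = 1.0):
        self.hill_sign = hill_sign

    @staticmethod
    def _model(x, log_ic50, h):
        return 100.0 / (1.0 + (10.0**log_ic50 / x) ** h)

    def fit(self, dose, response):
        x = np.asarray(dose, dtype=float)
        y = np.asarray(response, dtype=float)
        if len(x) < 4:
            raise ValueError("need at least 4 dose points")
        if np.any(x <= 0):
            raise ValueError("doses must be positive")
        order = np.argsort(x)
        x, y = x[order], y[order]
        flags: list[str] = []

        # monotonicity heuristic: the constrained response rises with dose
        if len(y) > 2 and np.std(y) > 0 and np.corrcoef(np.log10(x), y)[0, 1] < -0.3:
            flags.append("non_monotonic")

        if y.min() > 75.0 or y.max() < 25.0:
            self.ic50_, self.hill_ = np.nan, np.nan
            self.se_, self.ci95_ = {}, {}
            self.status_ = "no_transition"
            self.flags_ = tuple(flags) + ("no_transition",)
            self.result_ = KineticFit(
                model="four_pl", params={"ic50": np.nan, "hill": np.nan},
                n=len(x), flags=self.flags_,
            )
            return self

        mid = np.argmin(np.abs(y - 50.0))
        p0 = [np.log10(x[mid]), 1.0]
        try:
            popt, pcov = curve_fit(
                self._model, x, y, p0=p0,
                bounds=([-np.inf, 1e-3], [np.inf, 20.0]), **_OPT,
            )
            perr = np.sqrt(np.diag(pcov))
            self.status_ = "ok"
        except RuntimeError:
            popt, perr = np.asarray(p0), np.full(2, np.nan)
            self.status_ = "non_converged"
            flags.append("non_converged")

        log_ic50, h = popt
        self.ic50_ = float(10.0**log_ic50)
        self.hill_ = float(h)
        se_ic50 = float(self.ic50_ * np.log(10.0) * perr[0])
        params = {"ic50": self.ic50_, "hill": self.hill_}
        se = {"ic50": se_ic50, "hill": float(perr[1])}
        resid = y - self._model(x, *popt)
        self.se_ = se
        self.ci95_ = _wald(params, se)
        self.flags_ = tuple(flags)
        self.result_ = KineticFit(
            model="four_pl", params=params, se=se, ci95=self.ci95_,
            rss=float(np.sum(resid**2)), n=len(x), flags=self.flags_,
        )
        return self

    def predict(self, dose):
        return self._model(np.asarray(dose, dtype=float), np.log10(self.ic50_), self.hill_)


def fit_ic50(dose, response) -> KineticFit:
    """Constrained 4PL fit of percent-of-control responses vs dose."""
    return LogisticIC50().fit(dose, response).result_


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------


class MichaelisMenten(BaseEstimator, RegressorMixin):
    """``v = Vmax S / (Km + S)`` over pooled replicates.

    With ``enzyme_conc`` (molar) declared, ``k_cat = Vmax / [E]`` and
    ``k_cat / Km`` are derived; the ratio's symmetric 95% CI comes from
    first-order (Wald) propagation of the joint (Vmax, Km) covariance.
    An optional additive basal rate absorbs cofactor-independent background
    activity (off by default).

    Fitted attributes: ``vmax_``, ``km_``, ``kcat_``, ``kcat_over_km_``,
    ``basal_``, ``se_``, ``ci95_``, ``flags_``, ``result_``.
    """

    def __init__(self, enzyme_conc: float | None = None, fit_basal: bool = False):
        self.enzyme_conc = enzyme_conc
        self.fit_basal = fit_basal

    def fit(self, substrate, rate):
        S = np.asarray(substrate, dtype=float)
        v = np.asarray(rate, dtype=float)
        if len(np.unique(S)) < 4:
            raise ValueError("need at least 4 distinct substrate concentrations")
        if np.any(S < 0) or np.any(~np.isfinite(v)):
            raise ValueError("substrate concentrations must be >= 0 and rates finite")
        flags: list[str] = []

        # Lineweaver-Burk seed on the positive observations
        pos = (S > 0) & (v > 0)
        if pos.sum() >= 2:
            b, a = np.polyfit(1.0 / S[pos], 1.0 / v[pos], 1)  # 1/v = a + b/S
            vmax0 = 1.0 / a if a > 0 else float(np.max(v))
            km0 = b * vmax0 if b * vmax0 > 0 else float(np.median(S[S > 0]))
        else:
            vmax0, km0 = float(np.max(v)), float(np.median(S[S > 0]))
            flags.append("seed_fallback")

        if self.fit_basal:
            fun = lambda s, vmax, km, b0: vmax * s / (km + s) + b0
            p0 = [vmax0, km0, 0.0]
            bounds = ([0.0, 0.0, 0.0], np.inf)
        else:
            fun = lambda s, vmax, km: vmax * s / (km + s)
            p0 = [vmax0, km0]
            bounds = (0.0, np.inf)

        try:
            popt, pcov = curve_fit(fun, S, v, p0=p0, bounds=bounds, **_OPT)
            perr = np.sqrt(np.diag(pcov))
        except RuntimeError:
            popt, pcov = np.asarray(p0), np.full((len(p0), len(p0)), np.nan)
            perr = np.full(len(p0), np.nan)
            flags.append("non_converged")

        self.vmax_, self.km_ = float(popt[0]), float(popt[1])
        self.basal_ = float(popt[2]) if self.fit_basal else 0.0
        if self.km_ > 10.0 * S.max():
            flags.append("km_extrapolated")

        params = {"vmax": self.vmax_, "km": self.km_}
        se = {"vmax": float(perr[0]), "km": float(perr[1])}
        if self.fit_basal:
            params["basal"] = self.basal_
            se["basal"] = float(perr[2])

        self.kcat_ = np.nan
        self.kcat_over_km_ = np.nan
        if self.enzyme_conc is not None:
            if self.enzyme_conc <= 0:
                raise ValueError("enzyme concentration must be positive (molar)")
            E = self.enzyme_conc
            self.kcat_ = self.vmax_ / E
            self.kcat_over_km_ = self.kcat_ / self.km_
            params["kcat"] = self.kcat_
            params["kcat_over_km"] = self.kcat_over_km_
            se["kcat"] = se["vmax"] / E
            # Wald propagation on g = Vmax / (Km * E)
            grad = np.array([1.0 / (self.km_ * E), -self.vmax_ / (self.km_**2 * E)])
            cov2 = np.asarray(pcov)[:2, :2]
            var = float(grad @ cov2 @ grad)
            se["kcat_over_km"] = float(np.sqrt(var)) if var >= 0 else np.nan

        resid = v - fun(S, *popt)
        self.se_ = se
        self.ci95_ = _wald(params, se)
        self.flags_ = tuple(flags)
        self.result_ = KineticFit(
            model="michaelis_menten", params=params, se=se, ci95=self.ci95_,
            rss=float(np.sum(resid**2)), n=len(S), flags=self.flags_,
        )
        return self

    def predict(self, substrate):
        s = np.asarray(substrate, dtype=float)
        return self.vmax_ * s / (self.km_ + s) + self.basal_


def fit_mm(substrate, rate, enzyme_conc: float | None = None, fit_basal: bool = False) -> KineticFit:
    """Michaelis-Menten fit over pooled replicates."""
    return MichaelisMenten(enzyme_conc=enzyme_conc, fit_basal=fit_basal).fit(
        substrate, rate
    ).result_
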