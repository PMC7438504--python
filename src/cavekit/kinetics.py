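"""nth-order thermal-degradation kinetics with Arrhenius temperature coupling.

The decay law is ``dN/dt = -k(T) * N**n`` with

    ``k(T) = k_ref * exp(-(Ea/R) * (1/T - 1/T_ref))``

whose integral is ``N(t) = (N0**(1-n) + (n-1)*k*t)**(1/(1-n))`` for ``n != 1``
and the plain exponential at ``n = 1``.  Half-life and its sensitivity to the
initial titer follow in closed form; fitting is bounded nonlinear least
squares on log-transformed titers, jointly over all temperature groups.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateDesignError, DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

GAS_CONSTANT = 8.314
"""Molar gas constant, J mol^-1 K^-1 (fixed)."""

T_REF_DEFAULT_K = 335.15
"""Default reference temperature (62 degC) used in all regressions."""

TITER_UNIT_PFU_ML = 1.0e8
"""Canonical internal titer unit (PFU/mL per model unit).

For ``n != 1`` the numeric value of the rate constant depends on the titer
unit, so fits normalise titers to this scale before regression and record the
unit on the result.
"""

#: switch to the exponential branch this close to n = 1
_N_ONE_TOL = 1e-9


def celsius_to_kelvin(temp_c: float) -> float:
    return float(temp_c) + 273.15


def kelvin_to_celsius(temp_k: float) -> float:
    return float(temp_k) - 273.15


@dataclass(frozen=True)
class DegradationModel:
    """Kinetic/thermodynamic parameter set governing titer decay.

    Parameters
    ----------
    order_n : dimensionless reaction order (> 0; ``n = 1`` handled).
    k_ref : rate constant at ``t_ref``, min^-1 (titer unit)^(1-n).
    activation_energy : Ea, J/mol (>= 0).
    t_ref : reference temperature, K.
    """

    order_n: float
    k_ref: float
    activation_energy: float
    t_ref: float = T_REF_DEFAULT_K
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        if not self.order_n > 0:
            raise DomainError(f"order_n must be > 0, got {self.order_n}")
        if not self.k_ref > 0:
            raise DomainError(f"k_ref must be > 0, got {self.k_ref}")
        if self.activation_energy < 0:
            raise DomainError("activation_energy must be >= 0")
        if not self.t_ref > 0:
            raise DomainError("t_ref must be > 0 K")

    def with_log_rate_shift(self, delta_ln_k: float) -> "DegradationModel":
        """Return a copy whose rate constant is multiplied by exp(delta_ln_k)."""
        return replace(self, k_ref=self.k_ref * math.exp(delta_ln_k))

    def to_dict(self) -> dict:
        return {
            "order_n": self.order_n,
            "k_ref": self.k_ref,
            "activation_energy": self.activation_energy,
            "t_ref": self.t_ref,
            "gas_constant": self.gas_constant,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DegradationModel":
        return cls(
            order_n=float(d["order_n"]),
            k_ref=float(d["k_ref"]),
            activation_energy=float(d["activation_energy"]),
            t_ref=float(d.get("t_ref", T_REF_DEFAULT_K)),
        )


def arrhenius_rate(model: DegradationModel, temperature_k: float):
    """Rate constant at ``temperature_k``: ``k_ref * exp(-(Ea/R)(1/T - 1/T_ref))``."""
    temperature_k = np.asarray(temperature_k, dtype=float)
    if np.any(temperature_k <= 0):
        raise DomainError("temperature must be > 0 K")
    expo = -(model.activation_energy / model.gas_constant) * (
        1.0 / temperature_k - 1.0 / model.t_ref
    )
    return model.k_ref * np.exp(expo)


def predict_titer(model: DegradationModel, n0: float, temperature_k: float, t):
    """Titer at time ``t`` (minutes) for initial titer ``n0`` at ``temperature_k``.

    Vectorised over ``t``.  For ``n < 1`` the bracket reaches zero in finite
    time and the prediction is clamped at 0 (complete decay).
    """
    if not n0 > 0:
        raise DomainError("n0 must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    k = arrhenius_rate(model, temperature_k)
    n = model.order_n
    if abs(n - 1.0) < _N_ONE_TOL:
        out = n0 * np.exp(-k * t)
    else:
        bracket = n0 ** (1.0 - n) + (n - 1.0) * k * t
        bracket = np.maximum(bracket, 0.0)
        with np.errstate(divide="ignore"):
            out = np.where(bracket > 0.0, bracket ** (1.0 / (1.0 - n)), 0.0)
    return out if out.ndim else float(out)


def survival_fraction(model: DegradationModel, n0: float, temperature_k: float, t):
    """``predict_titer(...) / n0``, clipped to [0, 1] against round-off."""
    frac = predict_titer(model, n0, temperature_k, t) / n0
    return np.clip(frac, 0.0, 1.0) if np.ndim(frac) else min(max(frac, 0.0), 1.0)


def half_life(model: DegradationModel, n0: float, temperature_k: float) -> float:
    """Time at which the titer reaches ``n0 / 2``.

    Closed form ``t_half = n0**(1-n) * (2**(n-1) - 1) / ((n-1) * k(T))`` for
    ``n != 1`` and ``ln 2 / k(T)`` at ``n = 1``.
    """
    if not n0 > 0:
        raise DomainError("n0 must be > 0")
    k = float(arrhenius_rate(model, temperature_k))
    n = model.order_n
    if abs(n - 1.0) < _N_ONE_TOL:
        return math.log(2.0) / k
    return n0 ** (1.0 - n) * (2.0 ** (n - 1.0) - 1.0) / ((n - 1.0) * k)


def half_life_dn0(model: DegradationModel, n0: float, temperature_k: float) -> float:
    """Partial derivative of the half-life with respect to the initial titer:

    ``(1 - 2**(n-1)) * exp((Ea/R)(1/T - 1/T_ref)) / (k_ref * n0**n)``

    (identically 0 at ``n = 1``: first-order half-life is independent of n0).
    """
    if not n0 > 0:
        raise DomainError("n0 must be > 0")
    if temperature_k <= 0:
        raise DomainError("temperature must be > 0 K")
    n = model.order_n
    if abs(n - 1.0) < _N_ONE_TOL:
        return 0.0
    expo = (model.activation_energy / model.gas_constant) * (
        1.0 / temperature_k - 1.0 / model.t_ref
    )
    return (1.0 - 2.0 ** (n - 1.0)) * math.exp(expo) / (model.k_ref * n0**n)


def half_life_sd(
    model: DegradationModel,
    n0: float,
    sigma_n0: float,
    temperature_k: float,
    parameter_cov: np.ndarray | None = None,
) -> float:
    """Standard deviation of the half-life propagated from ``sigma_n0``.

    By default only the initial-titer uncertainty is propagated:
    ``sigma = |d t_half / d n0| * sigma_n0``.  If ``parameter_cov`` (a 3x3
    covariance over ``(n, k_ref, Ea)``) is supplied, a delta-method term over
    the fitted parameters is added in quadrature.  This extension is off by
    default and clearly optional.
    """
    if sigma_n0 < 0:
        raise DomainError("sigma_n0 must be >= 0")
    var = (half_life_dn0(model, n0, temperature_k) * sigma_n0) ** 2
    if parameter_cov is not None:
        grad = _half_life_param_grad(model, n0, temperature_k)
        var += float(grad @ np.asarray(parameter_cov, dtype=float) @ grad)
    return math.sqrt(var)


def _half_life_param_grad(
    model: DegradationModel, n0: float, temperature_k: float
) -> np.ndarray:
    """Numeric gradient of half_life w.r.t. (n, k_ref, Ea), central differences."""
    base = (model.order_n, model.k_ref, model.activation_energy)
    steps = (1e-7 * max(1.0, abs(base[0])), 1e-7 * base[1], 1e-7 * max(1.0, base[2]))
    grad = np.empty(3)
    for i in range(3):
        lo, hi = list(base), list(base)
        hi[i] += steps[i]
        lo[i] -= steps[i]
        m_hi = DegradationModel(hi[0], hi[1], hi[2], model.t_ref)
        m_lo = DegradationModel(lo[0], lo[1], lo[2], model.t_ref)
        grad[i] = (
            half_life(m_hi, n0, temperature_k) - half_life(m_lo, n0, temperature_k)
        ) / (2.0 * steps[i])
    return grad


# ---------------------------------------------------------------------------
# time-course container and fitting
# ---------------------------------------------------------------------------


@dataclass
class TimeCourseSet:
    """Replicated titer measurements indexed by temperature and time.

    ``temperature_k``/``time_min``/``titer``/``replicate`` are parallel
    arrays; ``initial_titer`` maps temperature (K) to the group's N0 in the
    same unit as ``titer``.  Records with non-positive titer are excluded on
    construction with a logged warning (they cannot enter a log-space fit).
    """

    temperature_k: np.ndarray
    time_min: np.ndarray
    titer: np.ndarray
    replicate: np.ndarray
    initial_titer: dict[float, float] = field(default_factory=dict)
    n_excluded: int = 0

    @classmethod
    def from_records(
        cls,
        temperature_k,
        time_min,
        titer,
        replicate=None,
        initial_titer: Mapping[float, float] | None = None,
    ) -> "TimeCourseSet":
        temperature_k = np.asarray(temperature_k, dtype=float)
        time_min = np.asarray(time_min, dtype=float)
        titer = np.asarray(titer, dtype=float)
        if replicate is None:
            replicate = np.zeros(len(titer), dtype=int)
        replicate = np.asarray(replicate)
        if not (len(temperature_k) == len(time_min) == len(titer) == len(replicate)):
            raise ValueError("record arrays must have equal length")
        keep = titer > 0
        n_excluded = int((~keep).sum())
        if n_excluded:
            logger.warning(
                "excluded %d record(s) with non-positive titer from log-space data",
                n_excluded,
            )
        obj = cls(
            temperature_k=temperature_k[keep],
            time_min=time_min[keep],
            titer=titer[keep],
            replicate=replicate[keep],
            initial_titer=dict(initial_titer or {}),
            n_excluded=n_excluded,
        )
        obj._validate()
        return obj

    def _validate(self):
        for temp in np.unique(self.temperature_k):
            times = np.unique(self.time_min[self.temperature_k == temp])
            if len(times) < 2:
                raise DegenerateDesignError(
                    f"temperature group {temp:.2f} K has fewer than 2 distinct times"
                )

    @classmethod
    def from_tsv(cls, path) -> "TimeCourseSet":
        """Read a TSV with columns temperature_c, time_min, titer_pfu_ml, replicate."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"temperature_c", "time_min", "titer_pfu_ml"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"time-course TSV missing columns: {sorted(missing)}")
        rep = df["replicate"] if "replicate" in df.columns else np.zeros(len(df), int)
        return cls.from_records(
            temperature_k=df["temperature_c"].to_numpy(float) + 273.15,
            time_min=df["time_min"].to_numpy(float),
            titer=df["titer_pfu_ml"].to_numpy(float),
            replicate=np.asarray(rep),
        )

    def to_tsv(self, path):
        pd.DataFrame(
            {
                "temperature_c": self.temperature_k - 273.15,
                "time_min": self.time_min,
                "titer_pfu_ml": self.titer,
                "replicate": self.replicate,
            }
        ).to_csv(path, sep="\t", index=False)

    def group_n0(self, temp_k: float) -> float:
        """N0 for a temperature group; defaults to the geometric mean titer at
        the group's earliest time point when not supplied explicitly."""
        for key, val in self.initial_titer.items():
            if abs(key - temp_k) < 1e-9:
                return val
        mask = self.temperature_k == temp_k
        t0 = self.time_min[mask].min()
        at_t0 = self.titer[mask & (self.time_min == t0)]
        return float(np.exp(np.mean(np.log(at_t0))))

    def __len__(self) -> int:
        return len(self.titer)


@dataclass
class FitResult:
    """Outcome of a degradation fit.

    ``covariance`` is 3x3 over ``(n, k_ref, Ea)``; ``rss`` is the residual sum
    of squares in natural-log titer space.  ``titer_unit`` records the PFU/mL
    value of one internal titer unit (k_ref is expressed in those units).
    """

    model: DegradationModel
    covariance: np.ndarray
    rss: float
    converged: bool
    n_obs: int
    titer_unit: float = TITER_UNIT_PFU_ML

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def to_dict(self) -> dict:
        se = self.standard_errors
        return {
            "model": self.model.to_dict(),
            "covariance": np.asarray(self.covariance).tolist(),
            "standard_errors": {
                "order_n": se[0],
                "k_ref": se[1],
                "activation_energy": se[2],
            },
            "rss_log_space": self.rss,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "titer_unit_pfu_ml": self.titer_unit,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model=DegradationModel.from_dict(d["model"]),
            covariance=np.asarray(d["covariance"], dtype=float),
            rss=float(d["rss_log_space"]),
            converged=bool(d["converged"]),
            n_obs=int(d["n_obs"]),
            titer_unit=float(d.get("titer_unit_pfu_ml", TITER_UNIT_PFU_ML)),
        )


_N_BOUNDS = (0.2, 5.0)
_LNK_BOUNDS = (-30.0, 10.0)
_EA_BOUNDS = (0.0, 2.0e6)
_DEFAULT_STARTS = (0.8, 1.2, 2.0)


def fit_degradation(
    courses: TimeCourseSet,
    initial_guess: DegradationModel | None = None,
    *,
    t_ref: float = T_REF_DEFAULT_K,
    fix_ea: float | None = None,
    average_replicates: bool = False,
    multistart_n: Sequence[float] = _DEFAULT_STARTS,
    titer_unit: float = TITER_UNIT_PFU_ML,
) -> FitResult:
    """Globally fit ``(n, k_ref, Ea)`` to multi-temperature time-courses.

    Minimises ``sum((ln N_obs - ln N_model)**2)`` jointly over all
    temperature groups with shared parameters, using bounded trust-region
    least squares (``scipy.optimize.least_squares`` method ``trf``).
    Replicates enter as separate residuals unless ``average_replicates``.
    Single-temperature designs require ``fix_ea`` (Ea is unidentifiable).
    """
    temps = np.unique(courses.temperature_k)
    if len(courses) < 4:
        raise InsufficientDataError(
            f"need at least 4 usable observations, have {len(courses)}"
        )
    if len(np.unique(courses.time_min)) < 2:
        raise DegenerateDesignError("all observations share a single time point")
    if len(temps) < 2 and fix_ea is None:
        raise DegenerateDesignError(
            "a single temperature group cannot identify Ea; pass fix_ea"
        )

    # normalise to internal titer units
    temp_arr = courses.temperature_k
    time_arr = courses.time_min
    y = courses.titer / titer_unit
    n0_by_temp = {t: courses.group_n0(t) / titer_unit for t in temps}

    if average_replicates:
        df = pd.DataFrame({"T": temp_arr, "t": time_arr, "ln_y": np.log(y)})
        grouped = df.groupby(["T", "t"], as_index=False)["ln_y"].mean()
        temp_arr = grouped["T"].to_numpy()
        time_arr = grouped["t"].to_numpy()
        y = np.exp(grouped["ln_y"].to_numpy())

    ln_y = np.log(y)
    n0_arr = np.array([n0_by_temp[t] for t in temp_arr])

    fit_ea = fix_ea is None

    def model_ln(params):
        n = params[0]
        k_ref = math.exp(params[1])
        ea = params[2] if fit_ea else fix_ea
        k = k_ref * np.exp(
            -(ea / GAS_CONSTANT) * (1.0 / temp_arr - 1.0 / t_ref)
        )
        if abs(n - 1.0) < _N_ONE_TOL:
            ln_model = np.log(n0_arr) - k * time_arr
        else:
            bracket = n0_arr ** (1.0 - n) + (n - 1.0) * k * time_arr
            bracket = np.maximum(bracket, 1e-300)
            ln_model = np.log(bracket) / (1.0 - n)
        return ln_model

    def residuals(params):
        return model_ln(params) - ln_y

    # crude per-group first-order rates for k/Ea starting values
    rates, inv_t = [], []
    for t_k in temps:
        m = temp_arr == t_k
        slope = np.polyfit(time_arr[m], ln_y[m], 1)[0]
        if slope < -1e-12:
            rates.append(math.log(-slope))
            inv_t.append(1.0 / t_k)
    if len(rates) >= 2:
        ea0 = -GAS_CONSTANT * np.polyfit(inv_t, rates, 1)[0]
        ea0 = float(np.clip(ea0, *_EA_BOUNDS))
        lnk0 = float(np.interp(1.0 / t_ref, sorted(inv_t), [r for _, r in sorted(zip(inv_t, rates))]))
    else:
        ea0 = 1.0e5
        lnk0 = rates[0] if rates else math.log(0.01)
    lnk0 = float(np.clip(lnk0, *_LNK_BOUNDS))

    starts = []
    if initial_guess is not None:
        starts.append(
            (
                float(np.clip(initial_guess.order_n, *_N_BOUNDS)),
                float(np.clip(math.log(initial_guess.k_ref), *_LNK_BOUNDS)),
                float(np.clip(initial_guess.activation_energy, *_EA_BOUNDS)),
            )
        )
    for n_start in multistart_n:
        starts.append((n_start, lnk0, ea0 if fit_ea else 0.0))

    lower = [_N_BOUNDS[0], _LNK_BOUNDS[0]] + ([_EA_BOUNDS[0]] if fit_ea else [])
    upper = [_N_BOUNDS[1], _LNK_BOUNDS[1]] + ([_EA_BOUNDS[1]] if fit_ea else [])

    best = None
    for start in starts:
        x0 = list(start[:2]) + ([start[2]] if fit_ea else [])
        res = least_squares(
            lambda p: residuals(_expand(p, fit_ea, fix_ea)),
            x0,
            bounds=(lower, upper),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res

    params = _expand(best.x, fit_ea, fix_ea)
    n_hat, k_ref_hat, ea_hat = params[0], math.exp(params[1]), params[2]
    rss = float(2.0 * best.cost)
    n_obs = len(ln_y)
    n_par = len(best.x)

    # covariance of internal params from the Jacobian, then transform
    # (n, ln k, Ea) -> (n, k_ref, Ea) via dk = k d(ln k)
    cov = np.zeros((3, 3))
    dof = n_obs - n_par
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov_int = (rss / dof) * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov_int = (rss / dof) * np.linalg.pinv(jtj)
        scale = np.array([1.0, k_ref_hat] + ([1.0] if fit_ea else []))
        cov_int = cov_int * np.outer(scale, scale)
        if fit_ea:
            cov = cov_int
        else:
            cov[:2, :2] = cov_int
    cov = 0.5 * (cov + cov.T)

    model = DegradationModel(
        order_n=float(n_hat),
        k_ref=float(k_ref_hat),
        activation_energy=float(ea_hat),
        t_ref=t_ref,
    )
    return FitResult(
        model=model,
        covariance=cov,
        rss=rss,
        converged=bool(best.status > 0),
        n_obs=n_obs,
        titer_unit=titer_unit,
    )


def _expand(p, fit_ea: bool, fix_ea):
    if fit_ea:
        return (p[0], p[1], p[2])
    return (p[0], p[1], float(fix_ea))
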