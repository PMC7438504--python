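"""Spot-test titer estimation and survival ratios.

Stock titer is the slope of a zero-intercept regression of plaque counts on
dilution fraction (``slope = sum(x*y) / sum(x*x)``), divided by the plated
volume.  Survival is the treated/control titer ratio expressed in percent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedRatioError

logger = logging.getLogger(__name__)

SURVIVAL_FLAG_PERCENT = 120.0


def serial_dilution_fractions(
    transfer_volume_ul: float, diluent_volume_ul: float, n_steps: int
) -> list[float]:
    """Dilution-from-stock fractions after each of ``n_steps`` serial transfers.

    Per-step factor is ``transfer / (transfer + diluent)``; step i carries
    fraction ``factor**i``.
    """
    if transfer_volume_ul <= 0 or diluent_volume_ul <= 0:
        raise DomainError("transfer and diluent volumes must be > 0")
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    factor = transfer_volume_ul / (transfer_volume_ul + diluent_volume_ul)
    return [factor ** i for i in range(1, n_steps + 1)]


@dataclass
class SpotTestSeries:
    """Plaque counts over known dilution fractions.

    Fractions must lie in (0, 1].  Counts of zero are retained: they are
    informative under through-origin least squares.
    """

    dilution_fraction: np.ndarray
    count: np.ndarray
    replicate: np.ndarray
    plated_volume_ml: float = 1.0

    @classmethod
    def from_records(
        cls, dilution_fraction, count, replicate=None, plated_volume_ml: float = 1.0
    ) -> "SpotTestSeries":
        x = np.asarray(dilution_fraction, dtype=float)
        y = np.asarray(count, dtype=float)
        if replicate is None:
            replicate = np.zeros(len(x), dtype=int)
        replicate = np.asarray(replicate)
        if len(x) != len(y) or len(x) != len(replicate):
            raise ValueError("record arrays must have equal length")
        if np.any(x <= 0) or np.any(x > 1):
            raise DomainError("dilution fractions must lie in (0, 1]")
        if np.any(y < 0):
            raise DomainError("plaque counts must be non-negative")
        if plated_volume_ml <= 0:
            raise DomainError("plated_volume_ml must be > 0")
        if len(np.unique(x)) < 2:
            logger.warning(
                "spot-test series has fewer than 2 distinct dilution fractions; "
                "slope standard error will be unavailable"
            )
        return cls(x, y, replicate, plated_volume_ml)

    @classmethod
    def from_tsv(
        cls, path, plated_volume_ml: float = 1.0, drop_tntc: bool = True
    ) -> "SpotTestSeries":
        """Read a spot-test TSV; rows whose count is "TNTC" (too numerous to
        count / saturated) are dropped when ``drop_tntc`` with a logged count,
        otherwise they are an error."""
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = {"dilution_fraction", "count"} - set(df.columns)
        if missing:
            raise ValueError(f"spot-test TSV missing columns: {sorted(missing)}")
        tntc = df["count"].astype(str).str.strip().str.upper() == "TNTC"
        if tntc.any():
            if not drop_tntc:
                raise ValueError(f"{int(tntc.sum())} TNTC spot(s) present")
            logger.warning("dropping %d TNTC spot(s)", int(tntc.sum()))
            df = df[~tntc]
        rep = df["replicate"] if "replicate" in df.columns else None
        return cls.from_records(
            df["dilution_fraction"].to_numpy(float),
            df["count"].to_numpy(float),
            None if rep is None else np.asarray(rep),
            plated_volume_ml=plated_volume_ml,
        )

    def __len__(self) -> int:
        return len(self.count)


@dataclass
class TiterEstimate:
    """Stock titer (PFU/mL) from a through-origin regression.

    ``r_squared`` is the uncentered, through-origin definition
    ``1 - sum(e**2) / sum(y**2)`` — not comparable with centered R^2.
    """

    titer: float
    standard_error: float
    r_squared: float
    n_points: int
    flags: tuple[str, ...] = field(default_factory=tuple)


def estimate_titer(series: SpotTestSeries) -> TiterEstimate:
    """Through-origin least squares of counts on dilution fraction.

    slope = sum(x*y)/sum(x*x); titer = slope / plated volume.  The slope
    standard error uses residual variance with N - 1 degrees of freedom.
    """
    x = series.dilution_fraction
    y = series.count
    flags: list[str] = []
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    sse = float(np.sum(resid**2))
    syy = float(np.sum(y**2))
    n = len(x)

    if np.all(y == 0):
        flags.append("all_counts_zero")
        logger.warning("all plaque counts are zero; titer reported as 0")
    if len(np.unique(x)) < 2 or n < 2:
        se_slope = math.nan
        flags.append("se_unavailable")
    else:
        se_slope = math.sqrt(sse / (n - 1) / sxx)
    r2 = 1.0 - sse / syy if syy > 0 else 0.0

    return TiterEstimate(
        titer=slope / series.plated_volume_ml,
        standard_error=se_slope / series.plated_volume_ml if not math.isnan(se_slope) else math.nan,
        r_squared=r2,
        n_points=n,
        flags=tuple(flags),
    )


@dataclass
class SurvivalResult:
    percent: float
    standard_error: float
    flagged_above_100: bool


def percent_survival(treated: TiterEstimate, control: TiterEstimate) -> SurvivalResult:
    """``100 * treated / control`` with delta-method SE.

    Values above 100% are possible under measurement noise and are not
    clamped; results above 120% carry a flag.
    """
    if control.titer <= 0:
        raise UndefinedRatioError("control titer must be > 0 for a survival ratio")
    pct = 100.0 * treated.titer / control.titer
    se = math.nan
    if (
        treated.titer > 0
        and not math.isnan(treated.standard_error)
        and not math.isnan(control.standard_error)
    ):
        rel = math.sqrt(
            (treated.standard_error / treated.titer) ** 2
            + (control.standard_error / control.titer) ** 2
        )
        se = pct * rel
    elif treated.titer == 0:
        se = math.nan
    flagged = pct > SURVIVAL_FLAG_PERCENT
    if flagged:
        logger.warning("percent survival %.1f exceeds %.0f%%", pct, SURVIVAL_FLAG_PERCENT)
    return SurvivalResult(percent=pct, standard_error=se, flagged_above_100=flagged)
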