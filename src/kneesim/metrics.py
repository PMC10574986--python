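"""Validation statistics: RMSE, Pearson correlation with categorical bands.

Correlations are banded as weak (rho <= 0.35), moderate (0.35 < rho <=
0.67), strong (0.67 < rho <= 0.9) and excellent (rho > 0.9); negative
correlations fall in the lowest band.  Load errors are additionally
reported as a percentage of the mean experimentally obtained force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ValidationError

RHO_BANDS = ((0.35, "weak"), (0.67, "moderate"), (0.90, "strong"))


def _pair(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError(f"series length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValidationError("empty series")
    return a, b


def rmse(a, b) -> float:
    """Root-mean-square error between two equal-length series."""
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson(a, b) -> float:
    """Pearson product-moment correlation; constant series are undefined."""
    a, b = _pair(a, b)
    if a.size < 2:
        raise ValidationError("correlation needs at least 2 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation undefined for a constant series")
    return float(_stats.pearsonr(a, b).statistic)


def categorize_rho(rho: float) -> str:
    """Band a correlation coefficient; boundaries belong to the lower band."""
    if not (-1.0 - 1e-12 <= rho <= 1.0 + 1e-12):
        raise ValidationError(f"correlation {rho} outside [-1, 1]")
    for upper, name in RHO_BANDS:
        if rho <= upper:
            return name
    return "excellent"


def load_error_percent(rmse_load: float, mean_experimental_load: float) -> float:
    """Load RMSE as a percentage of the mean experimentally obtained force."""
    if mean_experimental_load <= 0:
        raise ValidationError("mean experimental load must be positive")
    if rmse_load < 0:
        raise ValidationError("RMSE must be non-negative")
    return 100.0 * rmse_load / mean_experimental_load


@dataclass(frozen=True)
class ChannelComparison:
    """Agreement of one simulated channel with its reference."""

    channel: str
    rmse: float
    rho: float
    rho_category: str
    load_error_pct: float | None = None  # loads only

    def as_dict(self) -> dict:
        return {
            "channel": self.channel,
            "rmse": self.rmse,
            "rho": self.rho,
            "rho_category": self.rho_category,
            "load_error_pct": self.load_error_pct,
        }


LOAD_CHANNELS = ("F_ankle", "F_quad")


def compare_channels(simulated: pd.DataFrame, reference: pd.DataFrame, channels) -> list:
    """Per-channel RMSE / Pearson table between two sampled traces."""
    out = []
    for c in channels:
        if c not in simulated.columns or c not in reference.columns:
            raise ValidationError(f"channel {c!r} missing from a trace")
        e = rmse(simulated[c], reference[c])
        try:
            rho = pearson(simulated[c], reference[c])
            category = categorize_rho(rho)
        except ValidationError:
            rho, category = float("nan"), "undefined"
        pct = None
        if c in LOAD_CHANNELS:
            mean_ref = float(np.mean(reference[c]))
            pct = load_error_percent(e, mean_ref) if mean_ref > 0 else None
        out.append(ChannelComparison(c, e, rho, category, pct))
    return out


def comparison_table(comparisons) -> pd.DataFrame:
    return pd.DataFrame([c.as_dict() for c in comparisons])
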