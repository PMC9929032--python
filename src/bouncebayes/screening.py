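"""Post-fit screening and tidy summaries of parameter estimates.

Outliers (|z| > 3, z-scores from the mean and sample SD of the input,
computed once) are Winsorized to a value 1% beyond the next most
extreme non-outlying score on the same tail. Summaries provide the
per-group x cell means, SDs and t-based 95% CIs that downstream group
statistics consume, plus the absolute prior-strength |pB - 0.5| and
SP/pB ratio transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    """Fewer than three values were supplied for screening."""


@dataclass(frozen=True)
class ScreeningReport:
    n_values: int
    n_outliers: int
    replacements: list[tuple[int, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_values": self.n_values,
            "n_outliers": self.n_outliers,
            "replacements": [
                {"index": int(i), "original": float(o), "replacement": float(r)}
                for i, o, r in self.replacements
            ],
        }


def winsorize(values: Sequence[float], z_threshold: float = 3.0) -> tuple[np.ndarray, ScreeningReport]:
    """Replace |z| > z_threshold values with 1% beyond the nearest
    non-outlying score on the same tail.

    z-scores are computed once from the mean and sample SD of the input
    (non-iterative). "1% beyond" means 1% larger in magnitude away from
    the center: next * 1.01 on the upper tail and next * 0.99 on the
    lower tail for positive values, symmetric for negative ones.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise InsufficientDataError("need a 1-d vector of at least 3 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return x.copy(), ScreeningReport(n_values=len(x), n_outliers=0)

    z = (x - mean) / sd
    upper = z > z_threshold
    lower = z < -z_threshold
    keep = ~(upper | lower)
    out = x.copy()
    replacements: list[tuple[int, float, float]] = []

    if upper.any():
        next_upper = float(np.max(x[keep]))
        repl = next_upper + 0.01 * abs(next_upper)
        for i in np.flatnonzero(upper):
            replacements.append((int(i), float(x[i]), repl))
            out[i] = repl
    if lower.any():
        next_lower = float(np.min(x[keep]))
        repl = next_lower - 0.01 * abs(next_lower)
        for i in np.flatnonzero(lower):
            replacements.append((int(i), float(x[i]), repl))
            out[i] = repl

    replacements.sort(key=lambda t: t[0])
    return out, ScreeningReport(n_values=len(x), n_outliers=len(replacements), replacements=replacements)


def winsorize_table(
    fits: pd.DataFrame,
    columns: Sequence[str] = ("SP_hat", "pB_hat"),
    group_by: Sequence[str] = ("cell",),
    z_threshold: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Winsorize each parameter column within each cell across participants."""
    out = fits.copy()
    report: dict = {}
    for key, idx in out.groupby(list(group_by)).groups.items():
        key_label = key if isinstance(key, str) else ":".join(map(str, np.atleast_1d(key)))
        for col in columns:
            vals = out.loc[idx, col].to_numpy(dtype=float)
            if len(vals) < 3:
                continue
            screened, rep = winsorize(vals, z_threshold)
            out.loc[idx, col] = screened
            report[f"{key_label}/{col}"] = rep.to_dict()
    return out, report


def _ci_half_width(sd: float, n: int, level: float = 0.95) -> float:
    if n < 2 or not np.isfinite(sd):
        return float("nan")
    return float(stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n))


def summarize_parameters(
    fits: pd.DataFrame,
    grouping: Sequence[str] = ("group", "cell"),
) -> pd.DataFrame:
    """Per-group summary of the fitted parameters and their transforms.

    Returns one row per grouping combination and variable (SP_hat,
    pB_hat, prior strength |pB - 0.5|, and the SP/pB ratio) with n,
    mean, SD and a t-based 95% CI; single-observation groups are kept
    but flagged with ci_defined = False.
    """
    if fits.empty:
        raise ValueError("fits table is empty")
    work = fits.copy()
    work["pB_prior_strength"] = (work["pB_hat"] - 0.5).abs()
    work["SP_pB_ratio"] = work["SP_hat"] / work["pB_hat"]
    variables = ["SP_hat", "pB_hat", "pB_prior_strength", "SP_pB_ratio"]

    rows = []
    for key, grp in work.groupby(list(grouping), dropna=False):
        if grp.empty:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"empty group {key} omitted from summary")
            continue
        key = np.atleast_1d(key)
        for var in variables:
            vals = grp[var].to_numpy(dtype=float)
            n = len(vals)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
            half = _ci_half_width(sd, n)
            rows.append(
                dict(zip(grouping, key))
                | {
                    "variable": var,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "ci_low": mean - half,
                    "ci_high": mean + half,
                    "ci_defined": bool(np.isfinite(half)),
                }
            )
    return pd.DataFrame(rows)
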