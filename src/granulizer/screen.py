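"""High-content screen scoring and dose-response fitting.

Each plate carries DMSO control wells; every feature of every well is
z-scored against that plate's control mean and SD, and the per-well z
vector is collapsed into a Mahalanobis distance from the control cloud —
a covariance-aware effect size that rewards coordinated multiparameter
shifts and discounts correlated features.  With few controls relative to
features the sample covariance is ill-conditioned, so Ledoit-Wolf shrinkage
is applied by default.

Dose-response curves (granules per cell or nuclear partition against
compound concentration) are fitted with the four-parameter logistic
(Rodbard) model on a log-concentration axis; in vitro plate measurements
that drift with time are corrected against start/end-of-row controls
assuming a linear change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.covariance import LedoitWolf

__all__ = [
    "control_zscores",
    "mahalanobis_score",
    "time_drift_normalize",
    "monotone_dose_check",
    "four_param_logistic",
    "PlateScreenModel",
    "ScreenResults",
    "DoseResponseModel",
    "DoseResponseResults",
]


def control_zscores(
    features: pd.DataFrame, roles: pd.Series, control_role: str = "control"
) -> pd.DataFrame:
    """z = (x - mu)/sigma per feature, with mu, sigma from this plate's controls.

    Features whose control SD is zero carry no information on this plate and
    are dropped with a warning.
    """
    is_ctrl = roles == control_role
    if is_ctrl.sum() < 2:
        raise ValueError("need at least 2 control wells per plate")
    ctrl = features.loc[is_ctrl]
    mu, sd = ctrl.mean(), ctrl.std(ddof=1)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(f"dropping constant control features: {list(dead)}", stacklevel=2)
    keep = sd[sd > 0].index
    return (features[keep] - mu[keep]) / sd[keep]


def _control_covariance(control_z: np.ndarray, shrinkage: str | None) -> np.ndarray:
    if shrinkage == "lw":
        return np.atleast_2d(LedoitWolf(assume_centered=False).fit(control_z).covariance_)
    if shrinkage is None:
        n, p = control_z.shape
        if n < p + 1:
            raise ValueError(
                f"{n} control wells cannot estimate a full-rank {p}x{p} covariance; "
                "use shrinkage='lw'"
            )
        return np.atleast_2d(np.cov(control_z, rowvar=False))
    raise ValueError(f"unknown shrinkage {shrinkage!r}")


def mahalanobis_score(
    z_vector: np.ndarray, control_z: np.ndarray, shrinkage: str | None = "lw"
) -> float:
    """D = sqrt(z' S^-1 z) with S the covariance of the control-well z vectors."""
    z = np.atleast_1d(np.asarray(z_vector, dtype=float))
    cz = np.atleast_2d(np.asarray(control_z, dtype=float))
    S = _control_covariance(cz, shrinkage)
    try:
        sol = np.linalg.solve(S, z)
    except np.linalg.LinAlgError:
        raise ValueError("singular control covariance; use shrinkage='lw'") from None
    return float(np.sqrt(z @ sol))


def time_drift_normalize(
    values: np.ndarray,
    timestamps: np.ndarray,
    t_start: float,
    t_end: float,
    control_start: float,
    control_end: float,
    mode: str = "divide",
) -> np.ndarray:
    """Correct a slow linear drift using controls at the start and end of a row.

    The reference at each well's timestamp is the linear interpolant between
    the start- and end-of-row control values; wells are divided by (default)
    or have subtracted (``mode="subtract"``) the reference, scaled so that
    equal start/end controls leave the data untouched.
    """
    values = np.asarray(values, dtype=float)
    ts = np.asarray(timestamps, dtype=float)
    if t_end == t_start:
        frac = np.zeros_like(ts)
    else:
        frac = (ts - t_start) / (t_end - t_start)
    ref = control_start + frac * (control_end - control_start)
    mid = 0.5 * (control_start + control_end)
    if mode == "divide":
        if np.any(ref == 0):
            raise ValueError("zero reference value in divide mode")
        return values * mid / ref
    if mode == "subtract":
        return values - (ref - mid)
    raise ValueError(f"unknown mode {mode!r}")


def monotone_dose_check(
    concentrations: np.ndarray,
    responses: np.ndarray,
    rho_threshold: float = 0.8,
    direction: str | None = None,
) -> bool:
    """True when the response is convincingly monotone in dose.

    Spearman rank correlation between concentration and response must exceed
    ``rho_threshold`` in magnitude (and have the stated sign if ``direction``
    is ``"increasing"`` or ``"decreasing"``).  Constant responses fail.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 concentrations")
    if np.all(r == r[0]):
        return False
    rho = stats.spearmanr(c, r).statistic
    if np.isnan(rho):
        return False
    if direction == "increasing":
        return rho >= rho_threshold
    if direction == "decreasing":
        return rho <= -rho_threshold
    return abs(rho) >= rho_threshold


@dataclass
class PlateScreenModel:
    """Mahalanobis hit scoring of a multi-plate screen.

    ``wells`` needs columns plate_id, well_id, role (control/treatment) and
    one column per feature (``feature_columns``; default: every remaining
    numeric column).  Control statistics and covariance are per plate.
    """

    wells: pd.DataFrame
    feature_columns: list | None = None
    control_role: str = "control"
    shrinkage: str | None = "lw"

    def fit(self) -> "ScreenResults":
        df = self.wells
        feats = self.feature_columns or [
            c for c in df.columns
            if c not in ("plate_id", "well_id", "compound_id", "role", "concentration")
        ]
        records = []
        for plate_id, plate in df.groupby("plate_id", sort=False):
            z = control_zscores(plate[feats], plate["role"], self.control_role)
            ctrl_z = z[plate["role"] == self.control_role].to_numpy()
            S = _control_covariance(ctrl_z, self.shrinkage)
            Sinv = np.linalg.inv(S)
            for idx, row in z.iterrows():
                v = row.to_numpy()
                d = float(np.sqrt(v @ Sinv @ v))
                records.append(
                    {
                        "plate_id": plate_id,
                        "well_id": df.at[idx, "well_id"],
                        "compound_id": df.at[idx, "compound_id"] if "compound_id" in df else None,
                        "role": df.at[idx, "role"],
                        "mahalanobis": d,
                    }
                )
        table = pd.DataFrame(records).sort_values("mahalanobis", ascending=False)
        table["rank"] = np.arange(1, len(table) + 1)
        return ScreenResults(model=self, table=table.reset_index(drop=True))


@dataclass
class ScreenResults:
    """Ranked well table of a screen; hits are the top of the ranking."""

    model: PlateScreenModel
    table: pd.DataFrame

    def top_hits(self, n: int = 47, exclude_controls: bool = True) -> pd.DataFrame:
        t = self.table
        if exclude_controls:
            t = t[t["role"] != self.model.control_role]
        return t.head(n)

    def summary(self) -> str:
        t = self.table
        treat = t[t["role"] != self.model.control_role]["mahalanobis"]
        ctrl = t[t["role"] == self.model.control_role]["mahalanobis"]
        return "\n".join(
            [
                "Plate screen Mahalanobis scoring",
                "=" * 41,
                f"wells:               {len(t)} ({len(ctrl)} controls)",
                f"plates:              {t['plate_id'].nunique()}",
                f"covariance:          {self.model.shrinkage or 'sample'} (per plate)",
                f"median D (controls): {ctrl.median():.2f}",
                f"median D (treated):  {treat.median():.2f}",
                f"max D:               {t['mahalanobis'].max():.2f}",
            ]
        )


def four_param_logistic(x, bottom, top, ec50, slope):
    """4PL response: bottom + (top - bottom) / (1 + (x/ec50)^slope)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** slope)


@dataclass
class DoseResponseModel:
    """Four-parameter logistic (Rodbard) dose-response fit.

    concentrations : strictly increasing positive molar values (>= 5 distinct)
    responses : matching readout (granule count per cell, nuclear partition p)

    The fit runs on the log-concentration axis with multistart
    initialization over a grid of candidate EC50s and slope signs; an EC50
    outside [min(conc)/10, max(conc)*10] or a flat fitted curve flags the
    result unreliable rather than silently clamping.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    fit_scale: str = "auto"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(np.unique(self.concentrations)) < 5:
            raise ValueError("need at least 5 distinct concentrations")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(np.unique(self.concentrations)) <= 0):
            raise ValueError("concentrations must be sortable strictly increasing")

    def fit(self) -> "DoseResponseResults":
        x, y = self.concentrations, self.responses
        lx = np.log(x)
        # assay readouts carry multiplicative error, so the data are fitted
        # log-transformed whenever they admit it ("auto"); residuals are then
        # on the log scale
        use_log = self.fit_scale == "log" or (self.fit_scale == "auto" and np.all(y > 0))
        target = np.log(y) if use_log else y

        def model_l(lxv, bottom, top, lec50, slope):
            pred = bottom + (top - bottom) / (1.0 + np.exp(slope * (lxv - lec50)))
            return np.log(np.maximum(pred, 1e-300)) if use_log else pred

        lo, hi = float(y.min()), float(y.max())
        starts = []
        for lec0 in np.quantile(lx, [0.25, 0.5, 0.75]):
            for slope0 in (1.0, -1.0, 2.0, -2.0):
                starts.append((lo, hi, lec0, slope0))
        best = None
        for p0 in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(model_l, lx, target, p0=p0, maxfev=5000)
            except (RuntimeError, optimize.OptimizeWarning):
                continue
            resid = float(np.sum((model_l(lx, *popt) - target) ** 2))
            if best is None or resid < best[1]:
                best = (popt, resid)
        if best is None:
            return DoseResponseResults(self, np.nan, np.nan, np.nan, np.nan, np.inf,
                                       converged=False, reliable=False,
                                       flags=("no-convergence",))
        (bottom, top, lec50, slope), resid = best
        ec50 = float(np.exp(lec50))
        flags = []
        if not (x.min() / 10.0 <= ec50 <= x.max() * 10.0):
            flags.append("ec50-outside-range")
        # a fitted amplitude small next to the response magnitude is noise
        scale = max(float(np.max(np.abs(y))), 1e-12)
        if abs(top - bottom) < 0.05 * scale:
            flags.append("flat-response")
        return DoseResponseResults(
            self, float(bottom), float(top), ec50, float(slope), resid,
            converged=True, reliable=not flags, flags=tuple(flags),
        )


@dataclass
class DoseResponseResults:
    model: DoseResponseModel
    bottom: float
    top: float
    ec50: float
    slope: float
    residual_ss: float
    converged: bool = True
    reliable: bool = True
    flags: tuple = field(default_factory=tuple)

    def predict(self, concentrations) -> np.ndarray:
        return four_param_logistic(concentrations, self.bottom, self.top, self.ec50, self.slope)

    def summary(self) -> str:
        lines = [
            "Dose-response fit (4-parameter logistic)",
            "=" * 41,
            f"n points:    {len(self.model.concentrations)}",
            f"bottom:      {self.bottom:.4g}",
            f"top:         {self.top:.4g}",
            f"EC50:        {self.ec50:.4g} M",
            f"slope:       {self.slope:.4g}",
            f"residual SS: {self.residual_ss:.4g}",
            f"reliable:    {self.reliable}" + (f" {self.flags}" if self.flags else ""),
        ]
        return "\n".join(lines)
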