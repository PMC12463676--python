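"""Thermal proteome profiling (TPP) stability scoring.

A TPP experiment heats aliquots of treated and control cells across a
temperature gradient and quantifies the protein left in solution at each
temperature by multiplexed mass spectrometry.  A compound that engages a
protein typically shifts its apparent melting behaviour; a compound that
changes expression or solubility shifts the whole curve up or down.  The
two effects are separated without any sigmoid fitting:

* the **abundance score** of a protein is the mean log2 fold change
  (treatment over control) at the two lowest temperatures, where essentially
  no protein has melted, so it reads out abundance/solubility changes only;
* the **thermal stability score** subtracts the abundance score from the
  log2 fold change at every temperature and sums the residuals, so a pure
  abundance change cancels and only a melting shift accumulates.

Both scores are z-transformed across proteins, assigned moderated two-sided
p-values against a robust empirical null, corrected for multiple testing,
and thresholded (|z| > 1.5 and FDR < 0.05 by default) into
stabilized / destabilized / unaffected calls.

The model-fitting surface follows the statsmodels convention:
``StabilityModel(matrix, treatment=...).fit()`` returns a
:class:`StabilityResults` carrying the per-protein table and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MeltCurveMatrix",
    "compute_fold_changes",
    "abundance_score",
    "stability_score",
    "z_transform",
    "moderated_significance",
    "classify",
    "StabilityModel",
    "StabilityResults",
]

CLASS_STABILIZED = "stabilized"
CLASS_DESTABILIZED = "destabilized"
CLASS_UNAFFECTED = "unaffected"


@dataclass
class MeltCurveMatrix:
    """Soluble-protein intensities on a (protein x temperature x condition) grid.

    Parameters
    ----------
    protein_ids : list of str
    temperatures : 1-D array of float, strictly increasing, in deg C
    conditions : list of str, containing ``control``
    intensity : float array, shape (n_proteins, n_temperatures, n_conditions),
        non-negative, NaN where a protein was not quantified
    control : str
        Name of the vehicle-control condition.
    """

    protein_ids: list
    temperatures: np.ndarray
    conditions: list
    intensity: np.ndarray
    control: str = "DMSO"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.temperatures.ndim != 1 or len(self.temperatures) < 2:
            raise ValueError("need a 1-D grid of at least two temperatures")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.control not in self.conditions:
            raise ValueError(f"control condition {self.control!r} not present")
        expected = (len(self.protein_ids), len(self.temperatures), len(self.conditions))
        if self.intensity.shape != expected:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != {expected} "
                "(protein x temperature x condition)"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.intensity < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def condition_index(self, name: str) -> int:
        try:
            return self.conditions.index(name)
        except ValueError:
            raise KeyError(f"unknown condition {name!r}; have {self.conditions}") from None

    @classmethod
    def from_long(cls, df: pd.DataFrame, control: str = "DMSO") -> "MeltCurveMatrix":
        """Build from a long table with columns protein_id, condition, temperature, intensity."""
        required = {"protein_id", "condition", "temperature", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long table missing columns: {sorted(missing)}")
        wide = df.pivot_table(
            index="protein_id", columns=["temperature", "condition"],
            values="intensity", aggfunc="mean",
        )
        temperatures = sorted(df["temperature"].unique())
        conditions = sorted(df["condition"].unique())
        full = pd.MultiIndex.from_product([temperatures, conditions])
        wide = wide.reindex(columns=full)
        arr = wide.to_numpy().reshape(len(wide), len(temperatures), len(conditions))
        return cls(list(wide.index), np.array(temperatures), conditions, arr, control=control)

    def to_long(self) -> pd.DataFrame:
        recs = []
        for i, pid in enumerate(self.protein_ids):
            for j, t in enumerate(self.temperatures):
                for k, cond in enumerate(self.conditions):
                    recs.append((pid, cond, t, self.intensity[i, j, k]))
        return pd.DataFrame(recs, columns=["protein_id", "condition", "temperature", "intensity"])


def compute_fold_changes(
    matrix: MeltCurveMatrix, treatment: str, control: str | None = None
) -> pd.DataFrame:
    """Per-temperature log2 fold changes of treatment over control intensity.

    Zero or missing intensity on either side makes the entry NaN (the log
    ratio is undefined); the number of such rows is reported via a warning.

    Returns a DataFrame indexed by protein_id with one column per temperature
    plus an ``n_points`` column counting non-missing entries.
    """
    control = control or matrix.control
    if treatment == control:
        raise ValueError("treatment and control conditions must differ")
    it = matrix.intensity[:, :, matrix.condition_index(treatment)]
    ic = matrix.intensity[:, :, matrix.condition_index(control)]
    with np.errstate(divide="ignore", invalid="ignore"):
        valid = np.isfinite(it) & np.isfinite(ic) & (it > 0) & (ic > 0)
        log2fc = np.where(valid, np.log2(np.where(valid, it, 1.0) / np.where(valid, ic, 1.0)), np.nan)
    n_zero = int(np.sum((np.isfinite(it) & (it == 0)) | (np.isfinite(ic) & (ic == 0))))
    if n_zero:
        warnings.warn(f"{n_zero} zero intensities treated as missing in fold changes", stacklevel=2)
    out = pd.DataFrame(log2fc, index=pd.Index(matrix.protein_ids, name="protein_id"),
                       columns=matrix.temperatures)
    out["n_points"] = valid.sum(axis=1)
    return out


def abundance_score(fold_changes: pd.DataFrame) -> pd.Series:
    """Mean log2 fold change at the two lowest temperatures.

    Undefined (NaN) if either of the two lowest-temperature entries is missing.
    """
    temps = [c for c in fold_changes.columns if c != "n_points"]
    low2 = sorted(temps)[:2]
    return fold_changes[low2].mean(axis=1, skipna=False).rename("abundance_score")


def stability_score(
    fold_changes: pd.DataFrame, abundance: pd.Series, min_points: int = 10
) -> pd.Series:
    """Sum of abundance-corrected log2 fold changes over all temperatures.

    NaN where fewer than ``min_points`` temperatures were quantified or the
    abundance score itself is undefined.
    """
    temps = [c for c in fold_changes.columns if c != "n_points"]
    resid = fold_changes[temps].sub(abundance, axis=0)
    score = resid.sum(axis=1, skipna=True)
    bad = (fold_changes["n_points"] < min_points) | abundance.isna()
    score[bad] = np.nan
    return score.rename("stability_score")


def z_transform(scores: pd.Series | np.ndarray) -> pd.Series:
    """Standardize to zero mean, unit sample standard deviation (ddof=1).

    NaN entries are ignored for the moments and propagate through.
    """
    s = pd.Series(scores, dtype=float)
    vals = s.dropna()
    if len(vals) < 2:
        raise ValueError("need at least two non-missing scores to standardize")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero standard deviation")
    return (s - vals.mean()) / sd


def moderated_significance(
    z: pd.Series | np.ndarray,
    weights: pd.Series | np.ndarray | None = None,
    fdr_method: str = "bh",
    shrink: float = 0.5,
) -> pd.DataFrame:
    """Two-sided p-values and FDR for z scores against a robust empirical null.

    The null centre and scale are estimated by median and MAD, so that a
    minority of genuinely shifted proteins does not inflate the null width.
    Per-protein precision weights (the number of quantified temperatures)
    scale the null variance as ``scale^2 * mean(w)/w_i``; the per-protein
    variance is then shrunk toward the pooled (robust) variance with weight
    ``shrink`` — an empirical-Bayes compromise between fully per-protein and
    fully pooled error.

    fdr_method : ``"bh"`` (Benjamini-Hochberg tail-area FDR, default) or
        ``"local"`` (local FDR from a half-normal empirical-null density fit).
    """
    zs = pd.Series(z, dtype=float)
    obs = zs.dropna()
    if len(obs) < 10:
        raise ValueError("need at least 10 proteins to estimate the empirical null")
    center = float(np.median(obs))
    mad = float(stats.median_abs_deviation(obs, scale="normal"))
    if mad == 0:
        raise ValueError("degenerate z distribution: zero MAD")
    if weights is None:
        w = pd.Series(1.0, index=zs.index)
    else:
        w = pd.Series(weights, dtype=float).reindex(zs.index)
        if (w.dropna() < 1).any():
            raise ValueError("weights must be >= 1")
    wbar = float(w[zs.notna()].mean())
    var_i = mad**2 * (wbar / w)
    var_mod = shrink * mad**2 + (1.0 - shrink) * var_i
    t = (zs - center) / np.sqrt(var_mod)
    p = pd.Series(2.0 * stats.norm.sf(np.abs(t)), index=zs.index, name="p_value")
    p[zs.isna()] = np.nan

    fdr = pd.Series(np.nan, index=zs.index, name="fdr")
    ok = p.notna()
    if fdr_method == "bh":
        fdr[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    elif fdr_method == "local":
        fdr[ok] = _local_fdr(zs[ok].to_numpy(), center, mad)
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    return pd.DataFrame({"p_value": p, "fdr": fdr})


def _local_fdr(z: np.ndarray, center: float, scale: float, pi0: float | None = None) -> np.ndarray:
    """Local FDR from a half-normal null fit on |z - center|.

    fdr(z) = pi0 * f0(z) / f(z), with f0 the fitted null density and f a
    Gaussian kernel estimate of the mixture; clipped to [0, 1].
    """
    a = np.abs(z - center)
    f0 = stats.halfnorm.pdf(a, scale=scale)
    kde = stats.gaussian_kde(a)
    f = np.maximum(kde(a), 1e-300)
    if pi0 is None:
        # fraction of mass consistent with the null beyond its own median
        med = stats.halfnorm.ppf(0.5, scale=scale)
        pi0 = min(1.0, 2.0 * np.mean(a <= med))
    return np.clip(pi0 * f0 / f, 0.0, 1.0)


def classify(
    z: pd.Series, fdr: pd.Series, z_cut: float = 1.5, fdr_cut: float = 0.05
) -> pd.Series:
    """Three-way stabilized / destabilized / unaffected call.

    A protein changes class only when both arms pass: |z| above ``z_cut``
    AND FDR below ``fdr_cut``; anything else (including missing) is unaffected.
    """
    out = pd.Series(CLASS_UNAFFECTED, index=z.index, name="class")
    sig = (z.abs() > z_cut) & (fdr < fdr_cut)
    out[sig & (z > 0)] = CLASS_STABILIZED
    out[sig & (z < 0)] = CLASS_DESTABILIZED
    return out


@dataclass
class StabilityModel:
    """Abundance/stability scoring of one treatment-vs-control contrast.

    Parameters
    ----------
    matrix : MeltCurveMatrix
    treatment : str
        Treatment condition of the contrast; the headline contrast in the
        lipoamide study is the combined treatment against vehicle.
    control : str, optional
        Defaults to the matrix's control condition.
    min_points : int
        Minimum quantified temperatures for a defined stability score
        (default 10 — complete rows on the canonical 10-point grid).
    """

    matrix: MeltCurveMatrix
    treatment: str
    control: str | None = None
    min_points: int = 10
    z_cut: float = 1.5
    fdr_cut: float = 0.05
    fdr_method: str = "bh"

    def fit(self) -> "StabilityResults":
        fc = compute_fold_changes(self.matrix, self.treatment, self.control)
        ab = abundance_score(fc)
        st = stability_score(fc, ab, min_points=self.min_points)
        ab_z = z_transform(ab)
        st_z = z_transform(st)
        w = fc["n_points"].clip(lower=1)
        sig_ab = moderated_significance(ab_z, w, fdr_method=self.fdr_method)
        sig_st = moderated_significance(st_z, w, fdr_method=self.fdr_method)
        cls = classify(st_z, sig_st["fdr"], self.z_cut, self.fdr_cut)
        table = pd.DataFrame(
            {
                "abundance_score": ab,
                "stability_score": st,
                "abundance_z": ab_z,
                "stability_z": st_z,
                "abundance_p": sig_ab["p_value"],
                "abundance_fdr": sig_ab["fdr"],
                "p_value": sig_st["p_value"],
                "fdr": sig_st["fdr"],
                "n_points": fc["n_points"],
                "class": cls,
            }
        )
        return StabilityResults(model=self, table=table, fold_changes=fc)


@dataclass
class StabilityResults:
    """Per-protein stability table for one contrast, with a text summary."""

    model: StabilityModel
    table: pd.DataFrame
    fold_changes: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_stabilized(self) -> int:
        return int((self.table["class"] == CLASS_STABILIZED).sum())

    @property
    def n_destabilized(self) -> int:
        return int((self.table["class"] == CLASS_DESTABILIZED).sum())

    def summary(self) -> str:
        m = self.model
        n = len(self.table)
        lines = [
            "Thermal stability scoring",
            "=" * 41,
            f"contrast:        {m.treatment} vs {m.control or m.matrix.control}",
            f"proteins:        {n}",
            f"min points:      {m.min_points}",
            f"cutoffs:         |z| > {m.z_cut}, FDR < {m.fdr_cut} ({m.fdr_method})",
            f"stabilized:      {self.n_stabilized}",
            f"destabilized:    {self.n_destabilized}",
            f"unaffected:      {n - self.n_stabilized - self.n_destabilized}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="protein_id")
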