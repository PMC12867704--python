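"""Enzyme-activity analysis: cAMP quantification, turnover numbers, and
rank-based statistics.

Assay readings (fluorescent cAMP immunoassay, arbitrary units) are converted
to cAMP amounts through a 4-parameter-logistic standard curve, then to
activities (pmol cAMP per minute) and turnover numbers
(mol cAMP per mol enzyme per second).  Group comparisons use the
nonparametric recipe of the study: Mann-Whitney U (exact permutation for
small samples, tie-corrected normal approximation otherwise),
Kruskal-Wallis with Dunn's post hoc z tests, and Benjamini-Hochberg
step-up FDR adjustment.

The rank tests are implemented here rather than delegated so that the exact
small-sample permutation distributions are available; scipy/statsmodels
serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class InputError(ValueError):
    pass


class FitError(RuntimeError):
    pass


EXACT_TEST_MAX_N = 12  # combined sample size up to which exact p is used


# ---------------------------------------------------------------------------
# Standard curve (4-parameter logistic)
# ---------------------------------------------------------------------------

def _four_pl(x, a, b, c, d):
    # a: response at zero concentration, d: response at saturation,
    # c: inflection concentration, b: slope factor.
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass
class StandardCurve:
    """Fitted 4PL calibration curve reading = f(concentration)."""

    concentrations: np.ndarray  # nM, strictly positive, increasing
    readings: np.ndarray        # a.u.
    coefficients: tuple[float, float, float, float]  # (a, b, c, d)
    residuals: np.ndarray
    monotone: bool

    def predict(self, conc):
        return _four_pl(np.asarray(conc, dtype=float), *self.coefficients)

    def inverse(self, reading: float) -> float | None:
        """Concentration (nM) for a reading; None outside the monotone range."""
        a, b, c, d = self.coefficients
        lo, hi = sorted((a, d))
        if not lo < reading < hi:
            return None
        ratio = (a - d) / (reading - d) - 1.0
        if ratio <= 0:
            return None
        return c * ratio ** (1.0 / b)


def fit_standard_curve(concentrations, readings) -> StandardCurve:
    """Least-squares 4PL fit of readings against calibrator concentrations.

    Requires at least 5 calibrators spanning two decades.  Initialisation
    from the data range and the geometric-mean concentration; refinement by
    Levenberg-Marquardt.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(readings, dtype=float)
    if x.size < 5:
        raise InputError("need at least 5 calibrator points")
    if np.any(x <= 0) or np.any(np.diff(x) <= 0):
        raise InputError("concentrations must be positive and increasing")
    if x[-1] / x[0] < 100:
        raise InputError("calibrators must span at least two decades")
    monotone = bool(np.all(np.diff(y) > 0) or np.all(np.diff(y) < 0))
    if not monotone:
        warnings.warn("calibrator readings are not monotone", stacklevel=2)
    a0, d0 = float(y[0]), float(y[-1])
    c0 = float(np.exp(np.mean(np.log(x))))
    try:
        popt, _ = optimize.curve_fit(
            _four_pl, x, y, p0=[a0, 1.0, c0, d0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"4PL fit failed: {exc}") from exc
    residuals = y - _four_pl(x, *popt)
    return StandardCurve(
        concentrations=x, readings=y,
        coefficients=tuple(float(v) for v in popt),
        residuals=residuals, monotone=monotone,
    )


def reading_to_camp(
    curve: StandardCurve, reading: float,
    well_volume_ul: float | None = None,
) -> dict:
    """Invert the standard curve; optionally propagate to pmol per well."""
    conc = curve.inverse(reading)
    out = {"camp_nM": conc, "in_range": conc is not None}
    if well_volume_ul is not None and conc is not None:
        out["camp_pmol"] = conc * well_volume_ul * 1e-3  # nM * uL -> pmol
    return out


# ---------------------------------------------------------------------------
# Activity / turnover arithmetic
# ---------------------------------------------------------------------------

def activity(camp_pmol, time_min) -> float:
    """cAMP synthesis rate in pmol per minute."""
    if np.any(np.asarray(time_min) <= 0):
        raise InputError("reaction time must be positive")
    return np.asarray(camp_pmol, dtype=float) / time_min


def turnover(camp_pmol, time_s, enzyme_pmol) -> float:
    """Turnover number k: mol cAMP per mol enzyme per second."""
    if np.any(np.asarray(time_s) <= 0):
        raise InputError("reaction time must be positive")
    if np.any(np.asarray(enzyme_pmol) <= 0):
        raise InputError("enzyme amount must be positive")
    return np.asarray(camp_pmol, dtype=float) / time_s / enzyme_pmol


@dataclass
class PlateAssay:
    """Per-well assay readings with condition metadata.

    ``wells`` columns: any of {ph, metal, hco3_mM, ca_nM, construct},
    plus ``replicate`` and either ``camp_pmol`` or ``reading``.
    """

    wells: pd.DataFrame
    reaction_time_min: float = 10.0
    enzyme_pmol: float | None = None  # None for lysate assays

    def __post_init__(self):
        if self.reaction_time_min <= 0:
            raise InputError("reaction time must be positive")
        if "ph" in self.wells.columns:
            ph = self.wells["ph"].dropna()
            if len(ph) and not ((ph >= 5) & (ph <= 10)).all():
                raise InputError("pH outside [5, 10]")


def turnover_table(
    plate: PlateAssay, by=("ph", "metal", "construct"),
) -> pd.DataFrame:
    """Per-condition turnover number mean, SD and n from a purified-enzyme
    plate (requires ``enzyme_pmol``)."""
    if plate.enzyme_pmol is None:
        raise InputError("turnover requires a purified-enzyme plate")
    df = plate.wells.copy()
    keys = [k for k in by if k in df.columns]
    df["k"] = turnover(
        df["camp_pmol"].to_numpy(),
        plate.reaction_time_min * 60.0, plate.enzyme_pmol)
    grouped = df.groupby(keys, dropna=False)["k"]
    out = grouped.agg(k_mean="mean", k_sd="std", n="count").reset_index()
    return out


def fold_change(group_a, group_b, estimator: str = "ratio_of_means") -> float:
    """Fold change of condition b over condition a.

    Default: ratio of group means (bar-chart convention); alternative
    ``median_of_ratios`` pairs sorted replicates.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    if estimator == "ratio_of_means":
        ma = a.mean()
        if ma <= 0:
            raise InputError("denominator group mean must be positive")
        return float(b.mean() / ma)
    if estimator == "median_of_ratios":
        if np.any(a <= 0):
            raise InputError("denominator values must be positive")
        n = min(a.size, b.size)
        return float(np.median(np.sort(b)[:n] / np.sort(a)[:n]))
    raise InputError(f"unknown estimator {estimator!r}")


def ph_profile(ph_values, k_values) -> dict:
    """Shape descriptor of a pH-activity relation.

    Returns the ordered (pH, k) table plus interior local peak/trough
    positions and the max/min activity ratio — enough to flag the biphasic
    profile (first peak near pH 7.0, trough at 7.2, surge above 7.8).
    """
    df = pd.DataFrame({"ph": np.asarray(ph_values, dtype=float),
                       "k": np.asarray(k_values, dtype=float)})
    if df["ph"].duplicated().any():
        warnings.warn("duplicate pH values averaged", stacklevel=2)
        df = df.groupby("ph", as_index=False)["k"].mean()
    df = df.sort_values("ph").reset_index(drop=True)
    if len(df) < 3:
        raise InputError("need at least 3 pH points")
    k = df["k"].to_numpy()
    peaks, troughs = [], []
    for i in range(1, len(k) - 1):
        if k[i] > k[i - 1] and k[i] > k[i + 1]:
            peaks.append(float(df["ph"][i]))
        if k[i] < k[i - 1] and k[i] < k[i + 1]:
            troughs.append(float(df["ph"][i]))
    kmin = k.min()
    ratio = float(k.max() / kmin) if kmin > 0 else math.inf
    return {"table": df, "peaks": peaks, "troughs": troughs,
            "max_min_ratio": ratio}


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def _rank_u(x_ranks_sum: float, n1: int) -> float:
    return x_ranks_sum - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x, y, alternative: str = "two-sided") -> dict:
    """Mann-Whitney U test.

    Exact permutation p (enumeration of all label assignments) when the
    combined sample size is at most 12, else tie-corrected normal
    approximation with continuity correction.  All-tied data yields p = 1
    with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = _rank_u(ranks[:n1].sum(), n1)
    mean_u = n1 * n2 / 2.0

    if np.all(combined == combined[0]):
        return {"U": float(u1), "p": 1.0, "method": "degenerate",
                "degenerate": True}

    if n1 + n2 <= EXACT_TEST_MAX_N:
        dev = abs(u1 - mean_u)
        count = total = 0
        idx = range(n1 + n2)
        for subset in itertools.combinations(idx, n1):
            u = _rank_u(ranks[list(subset)].sum(), n1)
            total += 1
            if alternative == "two-sided":
                hit = abs(u - mean_u) >= dev - 1e-12
            elif alternative == "greater":
                hit = u >= u1 - 1e-12
            elif alternative == "less":
                hit = u <= u1 + 1e-12
            else:
                raise InputError(f"unknown alternative {alternative!r}")
            count += hit
        return {"U": float(u1), "p": count / total, "method": "exact",
                "degenerate": False}

    # tie-corrected normal approximation with continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return {"U": float(u1), "p": 1.0, "method": "degenerate",
                "degenerate": True}
    sd = math.sqrt(var_u)
    if alternative == "two-sided":
        z = (abs(u1 - mean_u) - 0.5) / sd
        p = 2.0 * stats.norm.sf(z)
    elif alternative == "greater":
        z = (u1 - mean_u - 0.5) / sd
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (u1 - mean_u + 0.5) / sd
        p = stats.norm.cdf(z)
    else:
        raise InputError(f"unknown alternative {alternative!r}")
    return {"U": float(u1), "p": float(min(p, 1.0)),
            "method": "normal-approx", "degenerate": False}


def _kw_h(ranks, sizes, correction: float) -> float:
    h = 0.0
    start = 0
    n = ranks.size
    for size in sizes:
        h += ranks[start:start + size].sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / correction


def kruskal_wallis(groups, p_method: str = "auto") -> dict:
    """Tie-corrected Kruskal-Wallis H.

    The p value is an exact permutation tail probability (over all label
    permutations of the joint sample) when the combined size is at most 8
    under ``p_method="auto"`` or always under ``"exact"``; otherwise the
    usual chi-square approximation.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise InputError("need at least 3 groups")
    if any(g.size == 0 for g in groups):
        raise InputError("groups must be non-empty")
    combined = np.concatenate(groups)
    n = combined.size
    sizes = [g.size for g in groups]
    ranks = stats.rankdata(combined)
    _, tie_counts = np.unique(combined, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    df = len(groups) - 1
    if correction == 0:
        return {"H": 0.0, "p": 1.0, "df": df, "degenerate": True,
                "method": "degenerate"}
    h = _kw_h(ranks, sizes, correction)
    exact = p_method == "exact" or (p_method == "auto" and n <= 8)
    if exact:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if _kw_h(ranks[list(perm)], sizes, correction) >= h - 1e-12:
                count += 1
        return {"H": float(h), "p": count / total, "df": df,
                "degenerate": False, "method": "exact"}
    return {"H": float(h), "p": float(stats.chi2.sf(h, df)), "df": df,
            "degenerate": False, "method": "chi-square"}


def dunn_posthoc(groups, labels=None, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's pairwise z tests on joint ranks, BH-adjusted by default."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    combined = np.concatenate(groups)
    n = combined.size
    ranks = stats.rankdata(combined)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1 / sizes[i] + 1 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var) if var > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"a": labels[i], "b": labels[j], "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if adjust == "bh":
        df["p_adj"] = benjamini_hochberg(df["p_raw"].to_numpy())
    elif adjust == "none":
        df["p_adj"] = df["p_raw"]
    else:
        raise InputError(f"unknown adjustment {adjust!r}")
    return df


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up FDR adjustment; monotone in rank order, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        val = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


# ---------------------------------------------------------------------------
# Mutant panel comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    table: pd.DataFrame
    skipped_strata: list = field(default_factory=list)


def compare_mutant_panel(
    plate: PlateAssay, wild_type: str = "WT",
    value_column: str = "camp_pmol",
) -> ComparisonResult:
    """Per (mutant, pH, metal): fold change vs wild type, Mann-Whitney p,
    BH-adjusted across the whole panel.

    A stratum without wild-type wells is skipped with a warning.
    """
    df = plate.wells
    if df.empty:
        return ComparisonResult(table=pd.DataFrame(
            columns=["construct", "ph", "metal", "fold", "U",
                     "p_raw", "p_adj"]))
    strata_keys = [k for k in ("ph", "metal") if k in df.columns]
    rows, skipped = [], []
    for stratum, sub in df.groupby(strata_keys, dropna=False):
        if not isinstance(stratum, tuple):
            stratum = (stratum,)
        wt = sub[sub["construct"] == wild_type][value_column].to_numpy()
        if wt.size == 0:
            skipped.append(stratum)
            warnings.warn(f"stratum {stratum} lacks wild-type wells; skipped",
                          stacklevel=2)
            continue
        for construct, msub in sub.groupby("construct"):
            if construct == wild_type:
                continue
            mut = msub[value_column].to_numpy()
            test = mann_whitney_u(wt, mut)
            rows.append({
                **dict(zip(strata_keys, stratum)),
                "construct": construct,
                "fold": fold_change(wt, mut),
                "U": test["U"], "p_raw": test["p"],
            })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
    else:
        table = pd.DataFrame(columns=[*strata_keys, "construct", "fold",
                                      "U", "p_raw", "p_adj"])
    return ComparisonResult(table=table, skipped_strata=skipped)
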