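"""Comparison statistics for multi-occasion sampler studies.

A study table is long-format: one row per measurement with a 4-level
``location``, a 3-level ``time``, their crossing as the measurement
``occasion``, and a replicate ``value``.  The intraclass correlation is the
between-occasion share of total variance after removing additive location
and time effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

STUDY_COLUMNS = ["location", "time", "value"]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")
    table = table.copy()
    if "occasion" not in table.columns:
        table["occasion"] = (
            table["location"].astype(str) + ":" + table["time"].astype(str)
        )
    return table


@dataclass
class IccResult:
    icc: float
    var_within: float
    var_between: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0
    n_bootstrap_failed: int = 0
    singular: bool = False


def _icc_anova(table: pd.DataFrame) -> tuple[float, float, bool]:
    """Variance components by expected mean squares for a balanced
    location x time layout; identical to REML in the balanced case."""
    matrix = _balanced_matrix(table)
    if matrix is None:
        raise ValueError("ANOVA variance components require a balanced table")
    var_between, var_within = _anova_components_batch(matrix)
    var_between, var_within = float(var_between), float(var_within)
    return var_between, var_within, var_between == 0.0


def _balanced_matrix(table: pd.DataFrame) -> np.ndarray | None:
    """Values as an (L, T, n) array for a balanced table, else None."""
    counts = table.groupby(["location", "time"])["value"].count()
    if counts.nunique() != 1:
        return None
    locs = sorted(table["location"].unique())
    times = sorted(table["time"].unique())
    if len(counts) != len(locs) * len(times):
        return None
    n = int(counts.iloc[0])
    matrix = np.empty((len(locs), len(times), n))
    grouped = table.groupby(["location", "time"])["value"]
    for (loc, t), values in grouped:
        matrix[locs.index(loc), times.index(t), :] = values.to_numpy()
    return matrix


def _anova_components_batch(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized expected-mean-squares components for (..., L, T, n) data."""
    L, T, n = matrix.shape[-3:]
    cell = matrix.mean(axis=-1)
    resid = matrix - cell[..., None]
    df_res = L * T * (n - 1)
    if df_res <= 0:
        raise ValueError("need replicates within occasions to estimate variance")
    ms_res = (resid**2).sum(axis=(-3, -2, -1)) / df_res
    row = cell.mean(axis=-1, keepdims=True)
    col = cell.mean(axis=-2, keepdims=True)
    grand = cell.mean(axis=(-2, -1))[..., None, None]
    interaction = cell - row - col + grand
    ms_int = n * (interaction**2).sum(axis=(-2, -1)) / ((L - 1) * (T - 1))
    var_between = np.maximum(0.0, (ms_int - ms_res) / n)
    return var_between, ms_res


def _icc_reml(table: pd.DataFrame) -> tuple[float, float, bool]:
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(
            "value ~ C(location) + C(time)", data=table, groups=table["occasion"]
        )
        fit = model.fit(reml=True)
    var_between = float(np.asarray(fit.cov_re)[0, 0])
    var_within = float(fit.scale)
    singular = var_between <= 1e-10 * max(var_within, 1e-300)
    if singular:
        var_between = 0.0
    return var_between, var_within, singular


def icc_mixed(table: pd.DataFrame, method: str = "reml") -> IccResult:
    """ICC from a mixed model: value ~ location + time + (1 | occasion).

    ``method='reml'`` fits via statsmodels MixedLM; ``method='anova'`` uses
    the balanced-design expected-mean-squares estimator (equal to REML for
    balanced tables and much faster, used by the bootstrap machinery).
    A singular fit (zero between-occasion variance) yields icc = 0 with the
    ``singular`` flag set.
    """
    table = _check_table(table)
    if table["occasion"].nunique() < 2:
        raise ValueError("need at least two occasions")
    if (table.groupby("occasion")["value"].count() < 2).all():
        raise ValueError("need at least one occasion with >= 2 replicates")
    if method == "anova":
        var_b, var_w, singular = _icc_anova(table)
    elif method == "reml":
        var_b, var_w, singular = _icc_reml(table)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = var_b + var_w
    icc = var_b / total if total > 0 else 0.0
    return IccResult(icc=icc, var_within=var_w, var_between=var_b, singular=singular)


def icc_bootstrap_ci(
    table: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    method: str = "reml",
    resample: str = "replicate",
    alpha: float = 0.05,
) -> IccResult:
    """Basic bootstrap CI for the ICC: (2*theta - q_hi, 2*theta - q_lo),
    clipped to [0, 1].

    ``resample='replicate'`` draws replicates with replacement within each
    occasion (preserves the fixed-effect design); ``resample='occasion'``
    resamples whole occasions within each location x time cell label;
    ``resample='parametric'`` redraws occasion effects and replicate noise
    from the fitted variance components (balanced tables only).
    Failed refits are skipped and counted.  Deterministic under ``seed``.

    Calibration note, measured by simulation at a 4x3-occasion design with
    10 replicates: replicate-level resampling cannot see the handful of
    between-occasion degrees of freedom and its nominal 95% interval covers
    the true ICC only ~55% of the time; the parametric variant covers ~80%.
    """
    table = _check_table(table)
    point = icc_mixed(table, method=method)
    rng = np.random.default_rng(seed)
    matrix = _balanced_matrix(table) if method == "anova" else None
    if matrix is not None:
        # vectorized path: all B resamples at once
        L, T, n = matrix.shape
        if resample == "replicate":
            idx = rng.integers(0, n, size=(B, L, T, n))
            boot = np.take_along_axis(
                np.broadcast_to(matrix, (B, L, T, n)), idx, axis=-1
            )
        elif resample == "occasion":
            cells = matrix.reshape(L * T, n)
            donor = rng.integers(0, L * T, size=(B, L * T))
            boot = cells[donor].reshape(B, L, T, n)
        elif resample == "parametric":
            cell_means = matrix.mean(axis=-1)
            row = cell_means.mean(axis=1, keepdims=True)
            col = cell_means.mean(axis=0, keepdims=True)
            additive = row + col - cell_means.mean()
            occ = rng.normal(0.0, np.sqrt(point.var_between), size=(B, L, T))
            noise = rng.normal(0.0, np.sqrt(point.var_within), size=(B, L, T, n))
            boot = additive[None, :, :, None] + occ[..., None] + noise
        else:
            raise ValueError(f"unknown resampling unit {resample!r}")
        var_b, var_w = _anova_components_batch(boot)
        total = var_b + var_w
        estimates = list(np.where(total > 0, var_b / np.where(total > 0, total, 1.0), 0.0))
        failed = 0
        return _basic_interval(point, estimates, failed, alpha)
    if resample == "parametric":
        raise ValueError(
            "parametric resampling requires a balanced table with method='anova'"
        )
    groups = {occ: sub.index.to_numpy() for occ, sub in table.groupby("occasion")}
    estimates = []
    failed = 0
    for _ in range(B):
        if resample == "replicate":
            idx = np.concatenate(
                [rng.choice(members, size=members.size, replace=True)
                 for members in groups.values()]
            )
            boot = table.loc[idx]
        elif resample == "occasion":
            # keep each occasion label but swap in the data of a random occasion
            labels = list(groups)
            chosen = rng.choice(len(labels), size=len(labels), replace=True)
            parts = []
            for lab, pick in zip(labels, chosen):
                donor = table.loc[groups[labels[pick]]].copy()
                target = table.loc[groups[lab]].iloc[0]
                donor["location"] = target["location"]
                donor["time"] = target["time"]
                donor["occasion"] = lab
                parts.append(donor)
            boot = pd.concat(parts, ignore_index=True)
        else:
            raise ValueError(f"unknown resampling unit {resample!r}")
        try:
            estimates.append(icc_mixed(boot, method=method).icc)
        except Exception:
            failed += 1
    return _basic_interval(point, estimates, failed, alpha)


def _basic_interval(
    point: IccResult, estimates: list, failed: int, alpha: float
) -> IccResult:
    if not estimates:
        raise RuntimeError("every bootstrap refit failed")
    q_lo, q_hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
    low = float(np.clip(2 * point.icc - q_hi, 0.0, 1.0))
    high = float(np.clip(2 * point.icc - q_lo, 0.0, 1.0))
    return IccResult(
        icc=point.icc,
        var_within=point.var_within,
        var_between=point.var_between,
        ci_low=low,
        ci_high=high,
        n_bootstrap=len(estimates),
        n_bootstrap_failed=failed,
        singular=point.singular,
    )


@dataclass
class DeviationTestResult:
    """Per-model mean +/- SD of squared deviation from the reference, with
    paired t-test p-values between models."""

    mean: dict[str, float]
    sd: dict[str, float]
    p_values: dict[tuple[str, str], float]
    n: int


def model_deviation_test(
    values: pd.DataFrame, reference_means: dict
) -> DeviationTestResult:
    """Squared-deviation comparison of analysis models against a reference.

    ``values`` has columns (model, sampler_id, occasion, value); every model
    must cover the identical set of (sampler_id, occasion) pairs, since the
    models are deterministic transforms of the same raw samplers and the
    test is paired.  For each measurement, d = (value - ref_mean(occasion))^2;
    models are compared by paired t-tests on d.
    """
    required = {"model", "sampler_id", "occasion", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"values table needs columns {sorted(required)}")
    values = values.copy()
    missing_ref = set(values["occasion"]) - set(reference_means)
    if missing_ref:
        raise ValueError(f"no reference mean for occasions: {sorted(missing_ref)}")
    values["deviation"] = (
        values["value"] - values["occasion"].map(reference_means)
    ) ** 2
    pivot = values.pivot_table(
        index=["sampler_id", "occasion"], columns="model", values="deviation"
    )
    if pivot.isna().any().any():
        raise ValueError("models are not paired on identical (sampler, occasion) sets")
    if len(pivot) < 2:
        raise ValueError("paired t-test needs at least two pairs")
    means = {m: float(pivot[m].mean()) for m in pivot.columns}
    sds = {m: float(pivot[m].std(ddof=1)) for m in pivot.columns}
    p_values: dict[tuple[str, str], float] = {}
    for a, b in combinations(pivot.columns, 2):
        diff = pivot[a] - pivot[b]
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            p = float(sps.ttest_rel(pivot[a], pivot[b]).pvalue)
        p_values[(a, b)] = p
    return DeviationTestResult(mean=means, sd=sds, p_values=p_values, n=len(pivot))


def origin_regression(x, y) -> tuple[float, float]:
    """Least-squares line through the origin.

    slope = sum(xy) / sum(x^2); R^2 is computed on the through-origin
    (uncentered) model, R^2 = 1 - SSE / sum(y^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all x are zero: slope undefined")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    if syy == 0.0:
        return slope, float("nan")
    sse = float(np.sum((y - slope * x) ** 2))
    return slope, 1.0 - sse / syy


@dataclass
class Descriptives:
    mean: float
    sd: float
    cv: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n: int
    cv_defined: bool = True


def descriptives(values) -> Descriptives:
    """Summary statistics; quartiles by linear interpolation (type 7),
    SD with ddof=1 (0 for a single value), CV = SD/mean (flagged undefined
    when the mean is zero)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75]))
    if mean == 0.0:
        cv, defined = float("nan"), False
    else:
        cv, defined = sd / mean, True
    return Descriptives(
        mean=mean, sd=sd, cv=cv, median=med, q1=q1, q3=q3,
        min=float(v.min()), max=float(v.max()), n=int(v.size), cv_defined=defined,
    )
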