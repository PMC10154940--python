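"""Body-size and development-time morphometrics across species and sexes.

Works on tidy per-individual tables (one row per fly) with the schema

    species, sex, larval_h, pupal_h, total_h, pupal_width_mm,
    pupal_length_mm, scutum_mm, [trait areas / complexities ...]

and reduces them to sex-specific species means, male − female differences
(and percent differences relative to the female mean — the female is the
baseline sex throughout), one-sample t-tests of those differences across
species, and Pearson correlations of trait sizes with development times.

Species means are the unit of replication in every cross-species test
(n = number of species, unweighted by per-species sample size).  Pupal
volume uses the perfect-ellipsoid proxy (pi/6) * width^2 * length; growth
rate is adult scutum width divided by total (larval + pupal) development
time, mm per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pupal_volume",
    "growth_rate",
    "one_sample_t",
    "pearson_r",
    "summarize_panel",
    "OneSampleT",
    "PanelSummary",
]

SEXES = ("male", "female")

#: per-individual quantities that get per-sex means and sex differences
DEFAULT_QUANTITIES = (
    "larval_h", "pupal_h", "total_h", "scutum_mm", "pupal_volume_mm3",
    "growth_rate_mm_per_h",
)


def pupal_volume(width_mm, length_mm):
    """Ellipsoid pupal volume (pi/6) * width^2 * length, mm^3."""
    width_mm = np.asarray(width_mm, dtype=float)
    length_mm = np.asarray(length_mm, dtype=float)
    if np.any(width_mm < 0) or np.any(length_mm < 0):
        raise ValueError("pupal width and length must be >= 0")
    out = (np.pi / 6.0) * width_mm**2 * length_mm
    return float(out) if out.ndim == 0 else out


def growth_rate(scutum_mm, total_h):
    """Adult scutum width per hour of total development, mm h^-1."""
    scutum_mm = np.asarray(scutum_mm, dtype=float)
    total_h = np.asarray(total_h, dtype=float)
    if np.any(total_h <= 0):
        raise ValueError("total development time must be > 0")
    out = scutum_mm / total_h
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OneSampleT:
    """Two-sided one-sample t-test with its 95% confidence interval."""

    t: float
    p: float
    mean: float
    ci_low: float
    ci_high: float
    n: int


def one_sample_t(values, mu0: float = 0.0) -> OneSampleT:
    """Two-sided one-sample t-test of the mean against ``mu0``.

    The 95% CI half-width is ``t_{0.975, n-1} * sd / sqrt(n)``.  Degenerate
    samples (n < 2 or zero variance) are rejected rather than returning
    infinite statistics.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError(f"need n >= 2 non-missing values, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample variance: t statistic undefined")
    res = stats.ttest_1samp(x, popmean=mu0)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    mean = float(x.mean())
    return OneSampleT(t=float(res.statistic), p=float(res.pvalue), mean=mean,
                      ci_low=mean - half, ci_high=mean + half, n=n)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value.

    The p-value comes from the t transform ``r * sqrt((n-2)/(1-r^2))`` on
    n − 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need n >= 3 complete pairs, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PanelSummary:
    """Sex-specific species means plus male − female differences.

    ``means`` — one row per species × sex (mean of each quantity and n);
    ``differences`` — one row per species with ``<q>_diff`` (male − female)
    and ``<q>_pct_diff`` (100 · diff / female mean) columns;
    ``incomplete_species`` — species lacking one sex, excluded from
    differences but retained in ``means``.
    """

    means: pd.DataFrame
    differences: pd.DataFrame
    incomplete_species: tuple[str, ...]


def _derive_columns(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    if {"pupal_width_mm", "pupal_length_mm"} <= set(records.columns):
        records["pupal_volume_mm3"] = pupal_volume(
            records["pupal_width_mm"], records["pupal_length_mm"])
    if "total_h" not in records.columns and \
            {"larval_h", "pupal_h"} <= set(records.columns):
        records["total_h"] = records["larval_h"] + records["pupal_h"]
    if "total_h" in records.columns and "scutum_mm" in records.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            records["growth_rate_mm_per_h"] = np.where(
                records["total_h"] > 0,
                records["scutum_mm"] / records["total_h"], np.nan)
    return records


def summarize_panel(records: pd.DataFrame,
                    quantities: tuple[str, ...] | None = None) -> PanelSummary:
    """Reduce per-individual records to species × sex means and differences.

    Derived quantities (pupal volume, total time, growth rate) are appended
    first when their inputs are present.  ``quantities`` defaults to every
    numeric column available among the standard set plus any trait area /
    complexity columns found in the table.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    required = {"species", "sex"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    bad_sex = set(records["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    records = _derive_columns(records)

    if quantities is None:
        numeric = [c for c in records.columns
                   if c not in ("species", "sex")
                   and pd.api.types.is_numeric_dtype(records[c])]
        quantities = tuple(numeric)
    missing = [q for q in quantities if q not in records.columns]
    if missing:
        raise ValueError(f"quantities not in records: {missing}")

    grouped = records.groupby(["species", "sex"], sort=True)
    means = grouped[list(quantities)].mean()
    means["n"] = grouped.size()
    means = means.reset_index()

    wide = means.pivot(index="species", columns="sex")
    diffs = {}
    for q in quantities:
        male = wide.get((q, "male"))
        female = wide.get((q, "female"))
        if male is None or female is None:
            continue
        diffs[f"{q}_diff"] = male - female
        with np.errstate(divide="ignore", invalid="ignore"):
            diffs[f"{q}_pct_diff"] = 100.0 * (male - female) / female
    differences = pd.DataFrame(diffs)
    complete = differences.dropna(how="all")
    has_both = means.groupby("species")["sex"].nunique() == 2
    incomplete = tuple(sorted(has_both.index[~has_both]))
    complete = complete.loc[[s for s in complete.index if s not in incomplete]]
    return PanelSummary(means=means, differences=complete,
                        incomplete_species=incomplete)


def sex_difference_tests(summary: PanelSummary,
                         quantities: tuple[str, ...] | None = None) -> pd.DataFrame:
    """One-sample t-tests of per-species male − female differences against 0.

    One row per quantity: mean difference, 95% CI, t, p, n (species).
    """
    diffs = summary.differences
    cols = [c for c in diffs.columns if c.endswith("_diff")
            and not c.endswith("_pct_diff")]
    if quantities is not None:
        cols = [f"{q}_diff" for q in quantities]
    rows = []
    for col in cols:
        vals = diffs[col].dropna()
        try:
            res = one_sample_t(vals)
        except ValueError:
            continue
        rows.append({"quantity": col[:-5], "mean_diff": res.mean,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "t": res.t, "p": res.p, "n_species": res.n})
    return pd.DataFrame(rows)


def size_time_correlations(summary: PanelSummary, size_cols: list[str],
                           time_cols: list[str],
                           sex: str = "male") -> pd.DataFrame:
    """Pearson correlations of trait sizes with development times.

    Computed across species means of one sex (default male, following the
    size-effects analysis design).
    """
    means = summary.means
    sub = means[means["sex"] == sex].set_index("species")
    rows = []
    for s in size_cols:
        for t in time_cols:
            if s not in sub.columns or t not in sub.columns:
                continue
            pair = sub[[s, t]].dropna()
            if len(pair) < 3:
                continue
            r, p = pearson_r(pair[s], pair[t])
            rows.append({"size": s, "time": t, "r": r, "p": p,
                         "n_species": len(pair)})
    return pd.DataFrame(rows)


def load_species_means(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load a deposited species-means table (one row per species).

    ``column_map`` renames the file's columns onto the canonical
    ``<quantity>_<sex>`` / ``<quantity>_diff`` names so differently headed
    deposits can be mapped in without editing the file.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "species" not in df.columns:
        raise ValueError("species-means table needs a 'species' column")
    return df
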