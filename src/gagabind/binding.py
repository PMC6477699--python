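"""(q)DPI-ELISA binding statistics.

Replicate summarization, background subtraction against a non-binding
probe, fold differences relative to a single-motif reference probe,
Welch t-test significance calls, and the minimal-motif inference
statistics: Pearson correlation between motif counts and fold
differences, a chi-square goodness-of-fit of folds against
count-proportional expectations, and classical one-way ANOVA across
probes.

Measurement tables are pandas DataFrames with columns
``probe, extract, plate, tech_rep, signal``.  Technical replicates are
averaged within a plate before cross-plate statistics, so that the
effective replication unit is the (extract, plate) combination rather
than the technical well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ContractError,
    InsufficientReplicationError,
    NormalizationError,
    UndefinedCorrelationError,
)

MEASUREMENT_COLUMNS = ("probe", "extract", "plate", "tech_rep", "signal")


@dataclass(frozen=True)
class BindingTest:
    p_value: float
    significant: bool
    degenerate: bool = False  # zero variance on both sides


@dataclass(frozen=True)
class InterdependenceReport:
    """Chi-square goodness-of-fit of fold differences vs motif-count ratios.

    ``statistic`` is sum((obs - exp)^2 / exp) over included probes with
    expected fold count(p)/count(reference); ``p_value`` is the upper tail
    of the chi-square distribution with (included - 1) degrees of freedom.
    A p near 1 means the folds are fully explained by the motif counts.
    """

    motif_class: str
    n_probes: int
    statistic: float
    p_value: float
    df: int
    excluded: tuple[str, ...]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


def _validate_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ContractError(f"measurement table is missing columns: {sorted(missing)}")
    if measurements.empty:
        raise InsufficientReplicationError("measurement table is empty")
    dup = measurements.duplicated(subset=["probe", "extract", "plate", "tech_rep"])
    if dup.any():
        raise ContractError("duplicate (probe, extract, plate, tech_rep) rows")
    if (measurements["signal"] < 0).any():
        raise ContractError("signals must be non-negative")
    return measurements


def pool_technical(measurements: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within (probe, extract, plate)."""
    m = _validate_measurements(measurements)
    return (
        m.groupby(["probe", "extract", "plate"], sort=True)["signal"]
        .mean()
        .reset_index()
    )


def replicate_signals(measurements: pd.DataFrame) -> dict[str, np.ndarray]:
    """Pooled replicate signal vectors keyed by probe name."""
    pooled = pool_technical(measurements)
    return {
        probe: grp["signal"].to_numpy(float)
        for probe, grp in pooled.groupby("probe", sort=True)
    }


def summarize_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-probe n, mean and unbiased standard deviation of pooled replicates."""
    rows = []
    for probe, vals in replicate_signals(measurements).items():
        if len(vals) < 2:
            raise InsufficientReplicationError(
                f"probe {probe!r} has {len(vals)} pooled replicate(s); need >= 2"
            )
        rows.append(
            {
                "probe": probe,
                "n": len(vals),
                "mean_signal": float(np.mean(vals)),
                "sd_signal": float(np.std(vals, ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("probe")


def test_binding(
    probe_signals: Sequence[float],
    negative_signals: Sequence[float],
    alpha: float = 0.05,
) -> BindingTest:
    """Two-sided Welch t-test of probe signals against the negative control."""
    a = np.asarray(probe_signals, float)
    b = np.asarray(negative_signals, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicationError("need >= 2 replicate values per side")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return BindingTest(p_value=1.0, significant=False, degenerate=True)
        return BindingTest(p_value=0.0, significant=True, degenerate=True)
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return BindingTest(p_value=p, significant=p < alpha)


def normalize_signals(
    summaries: pd.DataFrame,
    background_probe: str,
    reference_probe: str,
) -> pd.DataFrame:
    """Add background-subtracted signals and fold differences to a summary table.

    background_subtracted(p) = mean(p) - mean(background);
    fold_difference(p) = background_subtracted(p) / background_subtracted(reference).
    Negative background-subtracted values are retained (flagged, not clamped).
    """
    for probe in (background_probe, reference_probe):
        if probe not in summaries.index:
            raise NormalizationError(f"probe {probe!r} not present in summaries")
    if background_probe == reference_probe:
        raise NormalizationError("reference probe must differ from background probe")
    out = summaries.copy()
    bg = out.loc[background_probe, "mean_signal"]
    out["background_subtracted"] = out["mean_signal"] - bg
    ref = out.loc[reference_probe, "background_subtracted"]
    if ref <= 0:
        raise NormalizationError(
            f"reference probe {reference_probe!r} signal ({ref:g}) does not exceed background"
        )
    out["fold_difference"] = out["background_subtracted"] / ref
    out["negative_flag"] = out["background_subtracted"] < 0
    return out


def correlate_counts(
    folds: Mapping[str, float],
    counts: Mapping[str, int],
) -> float:
    """Sample Pearson correlation between motif counts and fold differences."""
    shared = sorted(set(folds) & set(counts))
    if len(shared) < 3:
        raise ContractError("need >= 3 probes with both a fold and a count")
    x = np.array([counts[p] for p in shared], float)
    y = np.array([folds[p] for p in shared], float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for a constant axis")
    return float(stats.pearsonr(x, y).statistic)


def chi2_interdependence(
    folds: Mapping[str, float],
    counts: Mapping[str, int],
    reference_probe: str,
    motif_class: str = "",
) -> InterdependenceReport:
    """Goodness-of-fit of observed folds against count-proportional expectations.

    Probes whose expected fold is 0 (count 0) contribute no information to
    the ratio model and are excluded; the report records them.
    """
    if reference_probe not in counts or counts[reference_probe] <= 0:
        raise ContractError("reference probe must have a positive motif count")
    shared = sorted(set(folds) & set(counts))
    ref_count = counts[reference_probe]
    included = [p for p in shared if counts[p] > 0]
    excluded = tuple(p for p in shared if counts[p] == 0)
    if len(included) < 2:
        raise ContractError("fewer than 2 probes with a positive expected fold")
    obs = np.array([folds[p] for p in included], float)
    exp = np.array([counts[p] / ref_count for p in included], float)
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = len(included) - 1
    p = float(stats.chi2.sf(statistic, df))
    return InterdependenceReport(
        motif_class=motif_class,
        n_probes=len(included),
        statistic=statistic,
        p_value=p,
        df=df,
        excluded=excluded,
    )


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA across probes; df reported as (k-1, N-k)."""
    if len(groups) < 2:
        raise ContractError("need >= 2 groups")
    arrays = []
    for name, vals in groups.items():
        a = np.asarray(vals, float)
        if len(a) < 2:
            raise InsufficientReplicationError(
                f"group {name!r} has {len(a)} value(s); need >= 2"
            )
        arrays.append(a)
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_between, df_within = k - 1, n_total - k
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return AnovaResult(F=0.0, df_between=df_between, df_within=df_within, p_value=1.0)
    res = stats.f_oneway(*arrays)
    return AnovaResult(
        F=float(res.statistic),
        df_between=df_between,
        df_within=df_within,
        p_value=float(res.pvalue),
    )


def analyze_panel(
    measurements: pd.DataFrame,
    counts_by_class: Mapping[str, Mapping[str, int]],
    background_probe: str,
    reference_probe: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, InterdependenceReport], AnovaResult]:
    """Full qDPI-ELISA analysis of one measurement table.

    Returns the normalized per-probe summary table (with Welch-test
    significance against the background probe), per-class Pearson
    coefficients, per-class interdependence reports, and the one-way ANOVA
    across probes.
    """
    summaries = summarize_replicates(measurements)
    summaries = normalize_signals(summaries, background_probe, reference_probe)
    signals = replicate_signals(measurements)
    pvals, sig = [], []
    for probe in summaries.index:
        if probe == background_probe:
            pvals.append(np.nan)
            sig.append(False)
            continue
        t = test_binding(signals[probe], signals[background_probe], alpha=alpha)
        pvals.append(t.p_value)
        sig.append(t.significant)
    summaries["p_value"] = pvals
    summaries["significant"] = sig

    folds = {
        p: summaries.loc[p, "fold_difference"]
        for p in summaries.index
        if p != background_probe
    }
    pearson: dict[str, float] = {}
    reports: dict[str, InterdependenceReport] = {}
    for cls, counts in counts_by_class.items():
        pearson[cls] = correlate_counts(folds, counts)
        # the ratio model needs a reference with at least one motif of the class
        if counts.get(reference_probe, 0) > 0:
            reports[cls] = chi2_interdependence(
                folds, counts, reference_probe, motif_class=cls
            )
    anova = anova_oneway(signals)
    return summaries, pearson, reports, anova
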