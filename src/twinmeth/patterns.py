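"""Global methylation description: tail fractions, co-twin correlation,
pair/status ANOVA, and the intra-pair variation statistic.

The variation statistic is the standard deviation of *absolute* intra-pair
methylation differences, in percentage points.  Per-pair summaries take the
SD across a probe set within one pair (one point per pair, as plotted
against phenotype discordance); the pooled summary takes the SD over all
pairs and probes at once (the headline repeats-vs-promoters comparison).
Both scopes are exposed because the two readings are not interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, RepeatPanel, StudyDesign

__all__ = [
    "MethylationFractions",
    "VariationSummary",
    "methylation_fractions",
    "sample_correlation",
    "overall_anova",
    "intrapair_variation_sd",
    "correlate_variation_phenotype",
    "variation_ratio_test",
]


@dataclass(frozen=True)
class MethylationFractions:
    """Fractions of probes in the low / intermediate / high methylation tails."""

    low: float
    mid: float
    high: float
    n_classified: int
    n_excluded: int  # all-missing probe rows

    def __post_init__(self) -> None:
        if self.n_classified and abs(self.low + self.mid + self.high - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 over classified probes")


@dataclass
class VariationSummary:
    """SD of absolute intra-pair differences, percentage-point units."""

    scope: Literal["per_pair", "pooled"]
    probe_set: str
    sd: pd.Series | float  # per-pair: Series keyed by pair_id; pooled: float
    n_differences: int
    n_dropped_probes: int = 0


def methylation_fractions(
    beta: BetaMatrix, low: float = 0.25, high: float = 0.75
) -> MethylationFractions:
    """Classify probes by mean beta against strict tail thresholds.

    A probe's methylation level is its mean beta over all non-missing
    samples; levels strictly below ``low`` count as low methylated, strictly
    above ``high`` as highly methylated (a value exactly at a threshold is
    in neither tail).  All-missing probes are excluded and counted.
    """
    if beta.n_probes == 0:
        raise ValueError("empty beta matrix")
    means = beta.values.mean(axis=1, skipna=True)
    excluded = means.isna()
    means = means[~excluded]
    n = len(means)
    if n == 0:
        return MethylationFractions(0.0, 0.0, 0.0, 0, int(excluded.sum()))
    f_low = float((means < low).mean())
    f_high = float((means > high).mean())
    return MethylationFractions(
        low=f_low,
        mid=1.0 - f_low - f_high,
        high=f_high,
        n_classified=n,
        n_excluded=int(excluded.sum()),
    )


def sample_correlation(
    beta: BetaMatrix,
    sample_a: str,
    sample_b: str,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlation of two samples' beta profiles over complete probes.

    Returns (r, two-sided P).  Requires at least 3 probes where both
    samples are non-missing; a constant profile makes the correlation
    undefined and is signalled explicitly.
    """
    a = beta.values[sample_a]
    b = beta.values[sample_b]
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError(
            f"fewer than 3 complete probes between {sample_a!r} and {sample_b!r}"
        )
    x, y = a[ok].to_numpy(), b[ok].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant sample profile: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def overall_anova(beta: BetaMatrix, design: StudyDesign) -> pd.DataFrame:
    """Two-factor ANOVA of all beta values on pair, status and interaction.

    Every non-missing (probe, sample) measurement is one observation in a
    long-format model ``beta ~ pair + status + pair:status`` fitted by OLS
    with sequential (type I) sums of squares in that factor order.  Returns
    a table with F, P and degrees of freedom per factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if design.n_pairs < 2:
        raise ValueError("ANOVA needs at least 2 pairs (interaction unidentifiable)")
    long = beta.values.reset_index().melt(
        id_vars=beta.values.index.name or "index",
        var_name="sample_id",
        value_name="beta",
    )
    long = long.dropna(subset=["beta"])
    meta = design.samples[["pair_id", "status"]]
    long = long.join(meta, on="sample_id")
    model = smf.ols("beta ~ C(pair_id) + C(status) + C(pair_id):C(status)", data=long)
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=1)
    table = table.rename(
        index={
            "C(pair_id)": "pair",
            "C(status)": "status",
            "C(pair_id):C(status)": "pair:status",
            "Residual": "residual",
        }
    )
    return table[["df", "F", "PR(>F)"]].rename(columns={"PR(>F)": "P"})


def _pair_abs_differences(
    data: BetaMatrix | pd.DataFrame,
    design: StudyDesign,
    probe_set,
) -> tuple[pd.DataFrame, int]:
    """|T2D − nonT2D| per (probe, pair) in percentage points.

    Accepts a BetaMatrix (fractions, scaled ×100) or a plain DataFrame
    already in percent (e.g. one element of a RepeatPanel).  Probes with any
    missing pair difference are dropped (complete-pair rule) and counted.
    """
    if isinstance(data, BetaMatrix):
        frame = data.values * 100.0
    else:
        frame = pd.DataFrame(data).astype(float)
    frame = frame.loc[list(probe_set)]
    cols = design.pair_columns()
    cols = cols[cols["t2d"].isin(frame.columns) & cols["control"].isin(frame.columns)]
    diffs = pd.DataFrame(
        {
            pair: (frame[row["t2d"]] - frame[row["control"]]).abs()
            for pair, row in cols.iterrows()
        }
    )
    complete = diffs.dropna(axis=0)
    return complete, len(diffs) - len(complete)


def intrapair_variation_sd(
    data: BetaMatrix | RepeatPanel | pd.DataFrame,
    design: StudyDesign,
    probe_set=None,
    scope: Literal["per_pair", "pooled"] = "per_pair",
    label: str = "",
) -> VariationSummary:
    """SD of absolute intra-pair methylation differences.

    ``per_pair`` gives, for each pair, the SD across the probe set of that
    pair's |differences| (one number per pair); ``pooled`` gives the SD of
    all |differences| across pairs and probes together.  The absolute value
    is taken before the SD, so the statistic is invariant to which co-twin
    is labelled first.
    """
    if isinstance(data, RepeatPanel):
        data = data.pooled([label] if label in data.elements else None)
    if probe_set is None:
        frame = data.values if isinstance(data, BetaMatrix) else pd.DataFrame(data)
        probe_set = frame.index
    diffs, dropped = _pair_abs_differences(data, design, probe_set)
    if diffs.size < 2:
        raise ValueError("fewer than 2 usable intra-pair differences")
    if scope == "per_pair":
        sd = diffs.std(axis=0, ddof=1)
        sd.index.name = "pair_id"
    elif scope == "pooled":
        sd = float(np.std(diffs.to_numpy().ravel(), ddof=1))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return VariationSummary(
        scope=scope,
        probe_set=label or "custom",
        sd=sd,
        n_differences=int(diffs.size),
        n_dropped_probes=dropped,
    )


def correlate_variation_phenotype(
    per_pair: VariationSummary | pd.Series,
    phenotype_deltas: pd.Series,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlate per-pair variation SD with absolute phenotype discordance."""
    sd = per_pair.sd if isinstance(per_pair, VariationSummary) else per_pair
    if not isinstance(sd, pd.Series):
        raise TypeError("per-pair summary required (scope='per_pair')")
    joined = pd.concat([sd.rename("sd"), phenotype_deltas.rename("delta")], axis=1)
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 pairs with both variation and phenotype")
    x, y = joined["sd"].to_numpy(), joined["delta"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    res = fn(x, y)
    return float(res.statistic), float(res.pvalue)


def variation_ratio_test(
    sd_a: float, n_a: int, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Two-sided F-ratio test comparing two pooled variation SDs.

    One interpretation of the repeats-vs-promoters SD comparison; reported
    as such, not as the (unstated) original test.
    """
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 differences per group")
    f = (sd_a / sd_b) ** 2
    p = 2 * min(
        stats.f.sf(f, n_a - 1, n_b - 1),
        stats.f.cdf(f, n_a - 1, n_b - 1),
    )
    return float(f), float(min(p, 1.0))
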