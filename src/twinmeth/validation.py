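"""Bisulfite-sequencing validation summaries and gene-set enrichment.

Clone-count tables (typically 12 sequenced colonies per amplicon) are
summarised as per-site methylation percentages and an unweighted amplicon
mean; paired validation comparisons are one-sided, reflecting the a-priori
hypothesis of replicating the array's direction of change.  Gene-set
enrichment is a one-sided Fisher exact test on a 2×2 table restricted to
the array-represented background, with no multiplicity adjustment (stated
in the result).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CloneTable

__all__ = [
    "EnrichmentResult",
    "clone_methylation_summary",
    "one_sided_paired_validation",
    "fisher_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One gene set's over-representation among differentially methylated genes.

    ``table`` is (hits in set, hits outside, non-hits in set, non-hits
    outside); counts always sum to the background size.  ``fraction_up`` /
    ``fraction_down`` summarise the direction of methylation change among
    hit genes inside the set, when per-gene differences are supplied.
    P-values are one-sided (enrichment) and deliberately not adjusted for
    the number of sets tested.
    """

    set_name: str
    table: tuple[int, int, int, int]
    odds_ratio: float
    p_value: float
    fraction_up: float = float("nan")
    fraction_down: float = float("nan")
    n_dropped_from_set: int = 0
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("Fisher P must lie in (0, 1]")


def clone_methylation_summary(table: CloneTable) -> tuple[pd.Series, float]:
    """Per-site methylation percentages and the unweighted amplicon mean.

    Site % = methylated / (methylated + unmethylated) · 100; the amplicon
    mean averages the site percentages without weighting by clone count.
    Sites with zero clones are excluded and flagged in the log.
    """
    counts = table.counts
    total = counts["n_methylated"] + counts["n_unmethylated"]
    usable = total > 0
    if not usable.any():
        raise ValueError("no site with at least one clone")
    n_zero = int((~usable).sum())
    if n_zero:
        logger.warning(
            "%d site(s) with zero clones excluded from amplicon %s",
            n_zero,
            table.amplicon_id,
        )
    pct = 100.0 * counts.loc[usable, "n_methylated"] / total[usable]
    pct.name = "methylation_pct"
    return pct, float(pct.mean())


def one_sided_paired_validation(
    t2d_values,
    nont2d_values,
    expected_direction: str = "greater",
) -> tuple[float, float]:
    """One-sided paired t-test of T2D vs nonT2D validation measurements.

    ``expected_direction`` states the array finding being replicated:
    ``'greater'`` means T2D methylation is expected higher.  Returns
    (t, one-sided P).  When t falls in the expected direction the one-sided
    P equals half the two-sided P.
    """
    a = np.asarray(t2d_values, dtype=float)
    b = np.asarray(nont2d_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0 and d[0] != 0:
        raise ValueError("zero-variance differences: t undefined")
    if expected_direction not in ("greater", "less"):
        raise ValueError("expected_direction must be 'greater' or 'less'")
    res = stats.ttest_rel(a, b, alternative=expected_direction)
    return float(res.statistic), float(res.pvalue)


def fisher_enrichment(
    hit_genes,
    gene_set,
    background_genes,
    set_name: str = "",
    gene_differences: pd.Series | None = None,
) -> EnrichmentResult:
    """One-sided Fisher exact enrichment of a gene set among hit genes.

    All three collections are de-duplicated; genes in the set but absent
    from the background are dropped with a warning, and hit genes must be a
    subset of the background.  ``gene_differences`` (per-gene mean
    methylation difference, percentage points) optionally supplies the
    direction summary over hit genes inside the set.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    hits = set(hit_genes)
    stray_hits = hits - background
    if stray_hits:
        raise ValueError(
            f"hit gene(s) outside the background: {sorted(stray_hits)[:5]}"
        )
    gset_all = set(gene_set)
    gset = gset_all & background
    dropped = len(gset_all) - len(gset)
    if dropped:
        logger.warning(
            "%d gene(s) of set %s absent from the array background, dropped",
            dropped,
            set_name or "<unnamed>",
        )

    a = len(hits & gset)  # hits in set
    b = len(hits - gset)  # hits outside
    c = len(gset - hits)  # non-hits in set
    d = len(background) - a - b - c  # non-hits outside
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")

    frac_up = frac_down = float("nan")
    if gene_differences is not None:
        in_set = gene_differences.reindex(sorted(hits & gset)).dropna()
        if len(in_set):
            frac_up = float((in_set > 0).mean())
            frac_down = float((in_set < 0).mean())

    return EnrichmentResult(
        set_name=set_name,
        table=(a, b, c, d),
        odds_ratio=float(odds),
        p_value=float(p),
        fraction_up=frac_up,
        fraction_down=frac_down,
        n_dropped_from_set=dropped,
        adjusted=False,
    )
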