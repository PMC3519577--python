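"""Paired differential methylation with permutation family-wise error control.

Per probe, the T2D − nonT2D difference is computed for every complete twin
pair (percentage points) and tested with a one-sample t on the differences.
Family-wise adjustment uses the Westfall–Young maxT resampling procedure:
under the paired null the only exchangeable operation is swapping co-twin
labels within a pair, i.e. flipping the sign of that pair's difference —
jointly across all probes, so the inter-probe correlation structure is
preserved.  For n pairs there are 2^n distinct sign assignments; when that
is small (≤ 4096 by default, i.e. up to 12 pairs) the procedure enumerates
them exactly, otherwise it samples B random flips and uses the
(b + 1)/(B + 1) estimator so no adjusted P is exactly zero.

The step-down variant is the default (probes ordered by |t|, successive
maxima over the less significant tail); the single-step variant (max over
the whole family) is selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, ProbeManifest, StudyDesign

__all__ = [
    "PermutationPlan",
    "DegenerateTestError",
    "paired_differences",
    "paired_t",
    "shapiro_fraction",
    "westfall_young_maxT",
    "run_candidate_analysis",
    "run_genome_wide",
]

logger = logging.getLogger(__name__)

EXHAUSTIVE_CAP = 4096  # 2^n_pairs at or under this -> enumerate all flips


class DegenerateTestError(ValueError):
    """Zero-variance difference vector with a non-zero mean."""


@dataclass(frozen=True)
class PermutationPlan:
    """How to sample the sign-flip null distribution.

    ``mode='auto'`` enumerates all 2^n flips when that is at most ``cap``
    and otherwise samples ``B`` random flips with seed ``seed``.
    """

    mode: Literal["auto", "exhaustive", "sampled"] = "auto"
    B: int = 10_000
    seed: int = 0
    cap: int = EXHAUSTIVE_CAP

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")

    def resolve(self, n_pairs: int) -> tuple[str, int]:
        """Concrete (mode, number of permutations) for a given pair count."""
        n_total = 2**n_pairs if n_pairs < 63 else np.inf
        if self.mode == "exhaustive" or (self.mode == "auto" and n_total <= self.cap):
            if n_total > self.cap:
                raise ValueError(
                    f"exhaustive enumeration of 2^{n_pairs} flips exceeds cap {self.cap}"
                )
            return "exhaustive", int(n_total)
        return "sampled", self.B


def paired_differences(
    beta: BetaMatrix,
    design: StudyDesign,
    probes=None,
    min_pairs: int = 2,
) -> pd.DataFrame:
    """Per-probe intra-pair differences, 100·(β_T2D − β_nonT2D).

    Columns are pair IDs in ascending order; a cell is NaN when either
    co-twin is missing at that probe.  Probes with fewer than ``min_pairs``
    complete pairs are excluded and logged.
    """
    frame = beta.values if probes is None else beta.values.loc[list(probes)]
    cols = design.pair_columns()
    cols = cols[cols["t2d"].isin(frame.columns) & cols["control"].isin(frame.columns)]
    diffs = pd.DataFrame(
        {
            pair: 100.0 * (frame[row["t2d"]] - frame[row["control"]])
            for pair, row in cols.iterrows()
        }
    )
    enough = diffs.notna().sum(axis=1) >= min_pairs
    n_dropped = int((~enough).sum())
    if n_dropped:
        logger.info(
            "%d probe(s) dropped with fewer than %d complete pairs", n_dropped, min_pairs
        )
    return diffs[enough]


def paired_t(differences) -> tuple[float, float, float]:
    """One-sample t-test of paired differences against zero.

    Returns (mean, t, two-sided P from t with n−1 df).  An all-zero vector
    is the degenerate "no difference anywhere" case and yields t = 0,
    P = 1; zero variance with a non-zero mean has no finite t and raises
    :class:`DegenerateTestError`.
    """
    d = np.asarray(pd.Series(differences).dropna(), dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.0, 1.0
        raise DegenerateTestError("zero variance with non-zero mean difference")
    t = mean / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), len(d) - 1)
    return mean, float(t), float(p)


def shapiro_fraction(diffs: pd.DataFrame) -> tuple[float, pd.Series]:
    """Shapiro–Wilk normality screen over per-probe difference vectors.

    Returns the fraction of testable probes with SW P < 0.05 and the
    per-probe P-values.  Vectors shorter than 3 are excluded and counted via
    NaN in the returned series.
    """
    pvals = {}
    for probe, row in diffs.iterrows():
        d = row.dropna().to_numpy()
        if len(d) < 3 or np.ptp(d) == 0:
            pvals[probe] = np.nan
            continue
        pvals[probe] = stats.shapiro(d).pvalue
    series = pd.Series(pvals, name="shapiro_p")
    testable = series.dropna()
    frac = float((testable < 0.05).mean()) if len(testable) else float("nan")
    return frac, series


def _t_matrix(d0: np.ndarray, n: np.ndarray, ss: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """|t| for every probe under every sign assignment, NaN-aware.

    ``d0`` is the probes × pairs difference matrix with missing entries
    zero-filled, ``n`` the per-probe complete-pair count, ``ss`` the
    per-probe sum of squared differences (both invariant under sign flips),
    and ``signs`` a B × pairs matrix of ±1.  A flip on a missing pair is a
    no-op because the zero-filled entry contributes nothing.
    """
    m = d0 @ signs.T  # probes x B, = n * mean
    nn = n[:, None].astype(float)
    mean = m / nn
    var = (ss[:, None] - nn * mean**2) / (nn - 1.0)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean) / np.sqrt(var / nn)
    # zero variance: |t| is 0 for a zero mean, infinite otherwise
    t[np.isnan(t)] = 0.0
    return t


def _observed_t(diffs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    d = diffs.to_numpy(dtype=float)
    missing = np.isnan(d)
    d0 = np.where(missing, 0.0, d)
    n = (~missing).sum(axis=1)
    if np.any(n < 2):
        raise ValueError("every probe needs at least 2 complete pairs")
    ss = (d0**2).sum(axis=1)
    t_obs = _t_matrix(d0, n, ss, np.ones((1, d.shape[1])))[:, 0]
    return d0, n, ss, t_obs


def _sign_matrix_exhaustive(n_pairs: int) -> np.ndarray:
    idx = np.arange(2**n_pairs, dtype=np.uint64)[:, None]
    bits = (idx >> np.arange(n_pairs, dtype=np.uint64)) & 1
    return bits.astype(np.int8) * 2 - 1


def westfall_young_maxT(
    diffs: pd.DataFrame,
    plan: PermutationPlan = PermutationPlan(),
    variant: Literal["step_down", "single_step"] = "step_down",
    chunk: int = 1024,
) -> pd.DataFrame:
    """Westfall–Young maxT adjusted P-values by joint sign-flipping.

    ``diffs`` is a probes × pairs matrix of paired differences (NaN for a
    missing pair).  The same sign assignment is applied to every probe in a
    given permutation, preserving inter-probe correlation.  Returns a frame
    with the observed |t|-ordered adjusted P per probe (original order),
    plus the raw permutation P of each probe and the permutation count.

    Step-down: probes are ordered by decreasing |t|; per permutation the
    running maximum of |t*| from the least significant probe upward gives
    the comparison statistic for each rank; adjusted P-values are forced
    monotone non-decreasing along the ordering.
    """
    d0, n, ss, t_obs = _observed_t(diffs)
    m, n_pairs = d0.shape
    mode, B = plan.resolve(n_pairs)

    order = np.argsort(-t_obs, kind="stable")
    t_sorted = t_obs[order]

    exceed_sorted = np.zeros(m, dtype=np.int64)  # step-down or single-step counts
    exceed_raw = np.zeros(m, dtype=np.int64)

    if mode == "exhaustive":
        all_signs = _sign_matrix_exhaustive(n_pairs)
    else:
        rng = np.random.default_rng(plan.seed)

    done = 0
    while done < B:
        take = min(chunk, B - done)
        if mode == "exhaustive":
            signs = all_signs[done : done + take]
        else:
            signs = rng.integers(0, 2, size=(take, n_pairs), dtype=np.int8) * 2 - 1
        t_perm = _t_matrix(d0, n, ss, signs)  # probes x take
        exceed_raw += (t_perm >= t_obs[:, None] - 1e-12).sum(axis=1)
        tp_sorted = t_perm[order]
        if variant == "step_down":
            succ_max = np.maximum.accumulate(tp_sorted[::-1], axis=0)[::-1]
        elif variant == "single_step":
            succ_max = np.broadcast_to(tp_sorted.max(axis=0), tp_sorted.shape)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        exceed_sorted += (succ_max >= t_sorted[:, None] - 1e-12).sum(axis=1)
        done += take

    if mode == "exhaustive":
        p_sorted = exceed_sorted / B
        p_raw = exceed_raw / B
    else:
        p_sorted = (exceed_sorted + 1) / (B + 1)
        p_raw = (exceed_raw + 1) / (B + 1)

    p_sorted = np.minimum.accumulate(p_sorted[::-1])[::-1]  # enforce monotone
    p_adj = np.empty(m)
    p_adj[order] = p_sorted
    return pd.DataFrame(
        {
            "t": np.sign(d0.sum(axis=1) / n) * t_obs,
            "abs_t": t_obs,
            "p_perm_raw": p_raw,
            "p_adj": p_adj,
        },
        index=diffs.index,
    ).assign(n_permutations=B, mode=mode)


def _differential_table(
    diffs: pd.DataFrame,
    manifest: ProbeManifest,
    plan: PermutationPlan,
    scope: str,
    variant: str,
    drop_incomplete: bool,
) -> tuple[pd.DataFrame, dict]:
    if drop_incomplete:
        before = len(diffs)
        diffs = diffs.dropna(axis=0)
        logger.info("dropped %d incomplete probe(s) from the family", before - len(diffs))
    means, ts, praw, ns = [], [], [], []
    for _, row in diffs.iterrows():
        mean, t, p = paired_t(row)
        means.append(mean)
        ts.append(t)
        praw.append(p)
        ns.append(int(row.notna().sum()))
    adj = westfall_young_maxT(diffs, plan=plan, variant=variant)
    result = pd.DataFrame(
        {
            "gene_symbol": manifest.table["gene_symbol"].reindex(diffs.index),
            "distance_to_tss": manifest.table["distance_to_tss"].reindex(diffs.index),
            "n_pairs": ns,
            "mean_difference": means,
            "t": ts,
            "p_raw": praw,
            "p_adj": adj["p_adj"],
        },
        index=diffs.index,
    )
    # the permutation distribution is discrete; guarantee adjusted >= raw
    result["p_adj"] = np.maximum(result["p_adj"], result["p_raw"])
    result["scope"] = scope
    counts = {
        "n_probes": len(result),
        "n_raw_significant": int((result["p_raw"] < 0.05).sum()),
        "n_adj_significant": int((result["p_adj"] < 0.05).sum()),
        "permutation_mode": adj["mode"].iloc[0] if len(adj) else None,
        "n_permutations": int(adj["n_permutations"].iloc[0]) if len(adj) else 0,
    }
    return result.sort_values("p_raw"), counts


def run_candidate_analysis(
    beta: BetaMatrix,
    design: StudyDesign,
    manifest: ProbeManifest,
    plan: PermutationPlan = PermutationPlan(),
    variant: Literal["step_down", "single_step"] = "step_down",
    drop_incomplete: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Candidate-gene analysis: paired t over the candidate probes with
    maxT adjustment over that family alone."""
    probes = [p for p in manifest.candidate_probes() if p in beta.values.index]
    diffs = paired_differences(beta, design, probes)
    return _differential_table(
        diffs, manifest, plan, "candidate", variant, drop_incomplete
    )


def run_genome_wide(
    beta: BetaMatrix,
    design: StudyDesign,
    manifest: ProbeManifest,
    plan: PermutationPlan = PermutationPlan(),
    variant: Literal["step_down", "single_step"] = "step_down",
    drop_incomplete: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Explorative analysis over all QC-retained probes, full-family maxT."""
    probes = [p for p in manifest.retained_probes() if p in beta.values.index]
    diffs = paired_differences(beta, design, probes)
    return _differential_table(
        diffs, manifest, plan, "genome_wide", variant, drop_incomplete
    )
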