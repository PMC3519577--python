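"""Synthetic twin methylomes with the statistical structure of a discordant
monozygotic-twin methylation study.

The generator states a simple hierarchical world:

* every probe draws a baseline methylation fraction from a three-component
  mixture of Beta distributions (low / intermediate / high), reproducing the
  bimodal marginal distribution of promoter beta values — roughly 64% of
  probes averaging below 0.25 and 13% above 0.75 in skeletal muscle;
* every twin pair perturbs that baseline by a shared normal offset
  (``sigma_pair``) — sharing the pair baseline, not an explicit correlation
  parameter, is what produces the strong co-twin similarity (r ≈ 0.95);
* every individual adds independent normal noise (``sigma_ind``) on the beta
  scale, truncated to [0, 1];
* disease effects are injected as fixed percentage-point shifts added to the
  affected co-twin at nominated probes, and every latent quantity is
  recorded in a :class:`SimulationTruth` so downstream estimates can be
  checked against the values that generated them.

Companion generators produce clinical phenotypes (anthropometry per Table-1
style means/SDs), repetitive-element methylation panels whose intra-pair
variability is optionally coupled to the pair's BMI discordance, and
clone-count tables emulating 12-colony bisulfite sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    REPEAT_SITE_COUNTS,
    STATUS_CONTROL,
    STATUS_T2D,
    BetaMatrix,
    CloneTable,
    ProbeManifest,
    RepeatPanel,
    StudyDesign,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "MUSCLE_CONFIG",
    "ADIPOSE_CONFIG",
    "generate_probe_manifest",
    "generate_twin_beta",
    "generate_phenotypes",
    "generate_repeat_panel",
    "generate_clone_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the twin methylome generator.

    Attributes
    ----------
    n_pairs, n_probes
        Design size.
    mixture_weights
        Probability of a probe belonging to the low / intermediate / high
        methylation component; must sum to 1.
    mixture_shapes
        Beta(a, b) shape pairs of the three components.
    sigma_pair
        SD of the shared per-pair baseline offset (beta scale).
    sigma_ind
        SD of the per-individual noise (beta scale); the main driver of the
        within-pair correlation and of the intra-pair difference SD.
    effect_sites
        Map probe ID → true T2D − nonT2D difference in percentage points.
    repeat_base, repeat_coupling, repeat_noise
        Per-pair intra-pair difference scale for LINE1 is
        ``repeat_base + repeat_coupling · |ΔBMI| + N(0, repeat_noise)``
        (percentage points); D4Z4/NBL2 use ``repeat_base`` uncoupled.
    n_clones
        Colonies per bisulfite-sequencing amplicon.
    tissue
        Tissue label stamped on generated samples.
    seed
        Base seed for all draws.
    """

    n_pairs: int = 11
    n_probes: int = 2000
    mixture_weights: tuple[float, float, float] = (0.64, 0.23, 0.13)
    mixture_shapes: tuple[tuple[float, float], ...] = (
        (2.5, 30.0),
        (10.0, 10.0),
        (30.0, 2.5),
    )
    sigma_pair: float = 0.03
    sigma_ind: float = 0.075
    effect_sites: dict = field(default_factory=dict)
    repeat_base: float = 16.0
    repeat_coupling: float = 1.5
    repeat_noise: float = 1.5
    n_clones: int = 12
    tissue: str = "muscle"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.sigma_pair < 0 or self.sigma_ind < 0:
            raise ValueError("sigma values must be non-negative")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.n_pairs < 1 or self.n_probes < 1:
            raise ValueError("n_pairs and n_probes must be positive")


#: Default skeletal-muscle world: tail fractions 64% / 13%, co-twin r ≈ 0.95.
MUSCLE_CONFIG = SimulationConfig()

#: Default adipose world: tail fractions 65% / 15%, co-twin r ≈ 0.97,
#: five biopsied pairs.
ADIPOSE_CONFIG = SimulationConfig(
    n_pairs=5,
    mixture_weights=(0.65, 0.20, 0.15),
    sigma_ind=0.055,
    tissue="adipose",
)


@dataclass
class SimulationTruth:
    """Latents recorded during generation, for parameter-recovery checks."""

    baseline: pd.Series  # per-probe mixture draw
    component: pd.Series  # per-probe mixture component index
    effects: dict  # probe -> injected T2D - nonT2D difference (pp)
    pair_baseline: pd.DataFrame | None = None  # probes x pairs shared offsets
    pair_scale: pd.Series | None = None  # per-pair repeat difference scale (pp)


# Susceptibility genes examined by the candidate approach (49 symbols).
CANDIDATE_GENES = (
    "ABCC8 ADAMTS9 ADCY5 AGPAT2 AKT2 BSCL2 CAMK1D CAV1 CDC123 CDKAL1 "
    "CDKN2A CDKN2B CEL CIDEC DUSP9 HHEX HMGA2 HNF1A HNF1B HNF4A GCK GCKR "
    "IDE IGF2BP2 INS INSR IRS1 JAZF1 KCNJ11 KCNQ1 KIF11 KLF11 KLF14 LGR5 "
    "LMNA MTNR1B NEUROD1 NOTCH2 PDX1 PPARG PPARGC1A PROX1 RBMS1 SLC30A8 "
    "TBC1D4 TCF7L2 TP53INP1 TSPAN8 WFS1"
).split()

_PROBE_LEN = 50
_SPACER_LEN = 10
_BASES = np.array(list("ACGT"))


def _random_segment(rng: np.random.Generator, length: int, cpg_offset: int) -> str:
    """Random A/C/G/T segment with a CG dinucleotide forced at one offset."""
    seg = rng.choice(_BASES, size=length)
    seg[cpg_offset] = "C"
    seg[cpg_offset + 1] = "G"
    return "".join(seg)


def generate_probe_manifest(
    n_total: int,
    n_multi: int,
    n_snp: int,
    n_candidate: int,
    seed: int = 0,
) -> tuple[ProbeManifest, str]:
    """Generate a probe manifest and the reference it was designed against.

    Each probe interrogates a CpG inside a random 50-bp genomic segment; the
    segment is embedded once in the returned reference (twice for probes
    flagged as multi-aligned), and the probe sequence is the forward
    bisulfite conversion (C→T) of its segment, mirroring the unmethylated
    bead-type design so an in-silico alignment against the converted
    reference recovers it.  Exactly ``n_multi`` probes are flagged
    ``multi_aligned`` and ``n_snp`` further probes ``snp_in_cpg`` (disjoint
    sets); ``n_candidate`` of the clean probes are spread over the 49
    susceptibility genes.

    Returns the manifest together with the generated reference sequence.
    """
    if n_multi + n_snp > n_total:
        raise ValueError("n_multi + n_snp exceeds n_total")
    if n_candidate > n_total - n_multi - n_snp:
        raise ValueError("not enough clean probes for the requested candidates")

    rng = np.random.default_rng(seed)
    flags = np.zeros(n_total, dtype=int)  # 0 clean, 1 multi, 2 snp
    flagged = rng.choice(n_total, size=n_multi + n_snp, replace=False)
    flags[flagged[:n_multi]] = 1
    flags[flagged[n_multi:]] = 2
    clean = np.flatnonzero(flags == 0)
    cand_idx = set(rng.choice(clean, size=n_candidate, replace=False).tolist())

    ref_parts: list[str] = []
    pos = 0
    records = []
    dup_segments: list[str] = []
    for i in range(n_total):
        cpg_offset = int(rng.integers(1, _PROBE_LEN - 2))
        seg = _random_segment(rng, _PROBE_LEN, cpg_offset)
        spacer = "".join(rng.choice(_BASES, size=_SPACER_LEN))
        ref_parts.append(seg)
        ref_parts.append(spacer)
        start = pos
        pos += _PROBE_LEN + _SPACER_LEN
        if flags[i] == 1:
            dup_segments.append(seg)
        gene = (
            CANDIDATE_GENES[i % len(CANDIDATE_GENES)]
            if i in cand_idx
            else f"GENE{i:05d}"
        )
        records.append(
            {
                "probe_id": f"cg{i:08d}",
                "gene_symbol": gene,
                "distance_to_tss": int(rng.integers(-1500, 1501)),
                "probe_sequence": seg.replace("C", "T"),
                "cpg_position": start + cpg_offset,
                "multi_aligned": flags[i] == 1,
                "snp_in_cpg": flags[i] == 2,
                "candidate": i in cand_idx,
            }
        )
    # second copies of multi-aligned segments, appended past the unique region
    for seg in dup_segments:
        spacer = "".join(rng.choice(_BASES, size=_SPACER_LEN))
        ref_parts.append(seg)
        ref_parts.append(spacer)

    table = pd.DataFrame(records).set_index("probe_id")
    manifest = ProbeManifest(table, candidate_genes=tuple(CANDIDATE_GENES))
    return manifest, "".join(ref_parts)


def _sample_ids(n_pairs: int) -> tuple[list[str], list[str]]:
    t2d = [f"pair{p:02d}_{STATUS_T2D}" for p in range(1, n_pairs + 1)]
    ctl = [f"pair{p:02d}_{STATUS_CONTROL}" for p in range(1, n_pairs + 1)]
    return t2d, ctl


def _design_frame(n_pairs: int, tissue: str, sexes: np.ndarray) -> pd.DataFrame:
    t2d, ctl = _sample_ids(n_pairs)
    rows = []
    for p in range(n_pairs):
        for sid, status in ((t2d[p], STATUS_T2D), (ctl[p], STATUS_CONTROL)):
            rows.append(
                {
                    "sample_id": sid,
                    "pair_id": f"pair{p + 1:02d}",
                    "status": status,
                    "tissue": tissue,
                    "sex": sexes[p],
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_twin_beta(
    manifest: ProbeManifest,
    config: SimulationConfig = MUSCLE_CONFIG,
    seed: int | None = None,
) -> tuple[BetaMatrix, StudyDesign, SimulationTruth]:
    """Generate a twin-pair beta matrix with known ground truth.

    Per probe a mixture component and baseline are drawn; per pair the
    baseline is perturbed by ``sigma_pair`` (shared by both co-twins); each
    individual adds ``sigma_ind`` noise, truncated to [0, 1]; injected
    effects are added to the affected co-twin afterwards (effect draws do
    not consume generator state, so the same seed yields the same latent
    world whatever ``effect_sites`` says).
    """
    unknown = set(config.effect_sites) - set(manifest.probe_ids)
    if unknown:
        raise KeyError(f"effect site(s) not in manifest: {sorted(unknown)[:5]}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    probes = list(manifest.probe_ids[: config.n_probes])
    m, n = len(probes), config.n_pairs
    weights = np.asarray(config.mixture_weights)
    comp = rng.choice(len(weights), size=m, p=weights)
    baseline = np.empty(m)
    for k, (a, b) in enumerate(config.mixture_shapes):
        sel = comp == k
        baseline[sel] = rng.beta(a, b, sel.sum())

    pair_base = baseline[:, None] + rng.normal(0.0, config.sigma_pair, (m, n))
    x_t2d = pair_base + rng.normal(0.0, config.sigma_ind, (m, n))
    x_ctl = pair_base + rng.normal(0.0, config.sigma_ind, (m, n))

    sexes = rng.choice(["M", "F"], size=n)

    effects = dict(config.effect_sites)
    if effects:
        idx = {p: i for i, p in enumerate(probes)}
        for probe, delta_pp in effects.items():
            if probe in idx:
                x_t2d[idx[probe], :] += delta_pp / 100.0

    x_t2d = np.clip(x_t2d, 0.0, 1.0)
    x_ctl = np.clip(x_ctl, 0.0, 1.0)

    t2d_ids, ctl_ids = _sample_ids(n)
    values = pd.DataFrame(
        np.concatenate([x_t2d, x_ctl], axis=1),
        index=pd.Index(probes, name="probe_id"),
        columns=t2d_ids + ctl_ids,
    )
    design = StudyDesign(_design_frame(n, config.tissue, sexes))
    beta = BetaMatrix(values, tissue=config.tissue)
    truth = SimulationTruth(
        baseline=pd.Series(baseline, index=probes),
        component=pd.Series(comp, index=probes),
        effects=effects,
        pair_baseline=pd.DataFrame(
            pair_base, index=probes, columns=[f"pair{p:02d}" for p in range(1, n + 1)]
        ),
    )
    return beta, design, truth


# Clinical phenotype means/SDs per status: (nonT2D mean, T2D mean, nonT2D SD,
# T2D SD).  BMI and HbA1c follow the printed twin characteristics; 2-h OGTT
# glucose and GIR are shown only graphically in the source material, so
# clinically realistic defaults are stated here (see docs/methods.md).
PHENOTYPE_PARAMS = {
    "BMI": (30.2, 32.3, 6.3, 6.4),
    "glucose_2h": (8.5, 15.0, 1.5, 3.0),
    "GIR": (6.0, 3.5, 2.0, 1.5),
    "HbA1c": (6.0, 7.7, 0.5, 1.4),
}

#: Within-pair correlation of each phenotype (monozygotic twins share genes
#: and rearing environment, so anthropometric traits correlate strongly).
PHENOTYPE_TWIN_CORR = 0.6


def generate_phenotypes(n_pairs: int, seed: int = 0) -> pd.DataFrame:
    """Per-twin clinical phenotypes, indexed by (pair_id, status).

    Co-twin values share a pair-level component so that they are correlated
    (r = 0.6) while keeping the stated per-status means and SDs; absolute
    intra-pair differences are therefore strictly positive in expectation
    whenever an SD is non-zero.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    rho = PHENOTYPE_TWIN_CORR
    rows = {}
    for pheno, (mu_c, mu_t, sd_c, sd_t) in PHENOTYPE_PARAMS.items():
        shared = rng.normal(0.0, 1.0, n_pairs)
        own_t = rng.normal(0.0, 1.0, n_pairs)
        own_c = rng.normal(0.0, 1.0, n_pairs)
        z_t = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own_t
        z_c = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own_c
        rows[(pheno, STATUS_T2D)] = mu_t + sd_t * z_t
        rows[(pheno, STATUS_CONTROL)] = mu_c + sd_c * z_c

    records = []
    for p in range(1, n_pairs + 1):
        for status in (STATUS_T2D, STATUS_CONTROL):
            rec = {"pair_id": f"pair{p:02d}", "status": status}
            for pheno in PHENOTYPE_PARAMS:
                rec[pheno] = rows[(pheno, status)][p - 1]
            records.append(rec)
    return pd.DataFrame(records).set_index(["pair_id", "status"])


# Assay-level mean methylation of each repetitive element (percent); LINE1
# promoters in somatic tissue sit around 70%, the tandem repeats lower.
REPEAT_LEVELS = {"LINE1": 70.0, "D4Z4": 55.0, "NBL2": 60.0}
_REPEAT_SITE_SD = 5.0  # spread of per-site baselines around the element mean


def generate_repeat_panel(
    design: StudyDesign,
    config: SimulationConfig = MUSCLE_CONFIG,
    seed: int | None = None,
) -> tuple[RepeatPanel, SimulationTruth]:
    """Generate repetitive-element methylation coupled to BMI discordance.

    Each pair receives an intra-pair difference scale for LINE1 equal to
    ``repeat_base + repeat_coupling·|ΔBMI| + N(0, repeat_noise)`` (floored
    at a small positive value); D4Z4 and NBL2 scales omit the coupling term.
    Per site, both co-twins share a site/pair baseline and add independent
    noise of SD ``scale/√2`` so the intra-pair difference has SD ``scale``.
    """
    if design.phenotypes is None:
        raise ValueError("design must carry phenotypes (generate_phenotypes)")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    pairs = design.pair_ids
    dbmi = design.phenotype_delta("BMI").reindex(pairs).to_numpy()
    scales = {}
    noise = rng.normal(0.0, config.repeat_noise, (3, len(pairs)))
    scales["LINE1"] = config.repeat_base + config.repeat_coupling * dbmi + noise[0]
    scales["D4Z4"] = config.repeat_base + noise[1]
    scales["NBL2"] = config.repeat_base + noise[2]
    for k in scales:
        scales[k] = np.maximum(scales[k], 0.5)

    pair_cols = design.pair_columns()
    elements = {}
    for name, n_sites in REPEAT_SITE_COUNTS.items():
        site_base = REPEAT_LEVELS[name] + rng.normal(0.0, _REPEAT_SITE_SD, n_sites)
        cols = {}
        for j, pair in enumerate(pairs):
            shared = site_base + rng.normal(0.0, 3.0, n_sites)
            s = scales[name][j] / np.sqrt(2.0)
            cols[pair_cols.loc[pair, "t2d"]] = shared + rng.normal(0.0, s, n_sites)
            cols[pair_cols.loc[pair, "control"]] = shared + rng.normal(0.0, s, n_sites)
        frame = pd.DataFrame(cols, index=[f"site{k + 1}" for k in range(n_sites)])
        elements[name] = frame.clip(0.0, 100.0)

    truth = SimulationTruth(
        baseline=pd.Series(dtype=float),
        component=pd.Series(dtype=int),
        effects={},
        pair_scale=pd.Series(scales["LINE1"], index=pairs),
    )
    return RepeatPanel(elements), truth


def generate_clone_table(
    true_pct,
    n_clones: int = 12,
    seed: int = 0,
    amplicon_id: str = "",
    **meta,
) -> CloneTable:
    """Binomial clone counts: methylated ~ Binomial(n_clones, true_pct/100)."""
    true_pct = pd.Series(true_pct, dtype=float)
    if ((true_pct < 0) | (true_pct > 100)).any():
        raise ValueError("true percentages must lie in [0, 100]")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    meth = rng.binomial(n_clones, true_pct.to_numpy() / 100.0)
    counts = pd.DataFrame(
        {"n_methylated": meth, "n_unmethylated": n_clones - meth},
        index=true_pct.index,
    )
    return CloneTable(counts, amplicon_id=amplicon_id, **meta)
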