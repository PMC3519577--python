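"""Core containers and tabular IO for the twin methylation pipeline.

The central object is a :class:`BetaMatrix` — a probes × samples array of
methylation fractions (beta values) in ``[0, 1]`` with an explicit missing
mask — accompanied by a :class:`StudyDesign` that records, for every sample,
its twin pair, disease status, tissue and sex, and optionally per-twin
clinical phenotypes.

All file formats are plain tab-separated text; missing beta values are
written as the literal ``NA`` and held internally as ``NaN`` inside a float
array (``NaN`` is a mask marker only — beta 0.0 is a legitimate value and is
never used as a sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_T2D",
    "STATUS_CONTROL",
    "REPEAT_SITE_COUNTS",
    "BetaMatrix",
    "StudyDesign",
    "ProbeManifest",
    "CloneTable",
    "RepeatPanel",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_design",
    "write_design",
    "read_manifest",
    "write_manifest",
    "read_gmt",
    "complete_pairs",
]

STATUS_T2D = "T2D"
STATUS_CONTROL = "nonT2D"

#: Fixed CpG-site counts of the pyrosequenced repetitive elements.
REPEAT_SITE_COUNTS = {"LINE1": 8, "D4Z4": 9, "NBL2": 8}

_MANIFEST_COLUMNS = [
    "gene_symbol",
    "distance_to_tss",
    "probe_sequence",
    "cpg_position",
    "multi_aligned",
    "snp_in_cpg",
    "candidate",
]


class DesignError(ValueError):
    """Raised when a study design violates the paired-twin structure."""


@dataclass
class BetaMatrix:
    """Probes × samples beta values with an explicit missing mask.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with one float column per sample.
        ``NaN`` marks a missing measurement.
    tissue
        Tissue label per sample (single string applied to all samples, or a
        mapping sample → label).
    """

    values: pd.DataFrame
    tissue: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value {arr[i, j]} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if self.tissue is None:
            self.tissue = pd.Series("unknown", index=self.values.columns)
        elif isinstance(self.tissue, str):
            self.tissue = pd.Series(self.tissue, index=self.values.columns)
        else:
            self.tissue = pd.Series(self.tissue).reindex(self.values.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the measurement is missing."""
        return self.values.isna()

    def subset(self, probes: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise KeyError(f"unknown probe(s): {missing[:5]}")
        return BetaMatrix(self.values.loc[list(probes)], tissue=self.tissue)


@dataclass
class StudyDesign:
    """Per-sample pairing/status metadata and optional per-twin phenotypes.

    ``samples`` is indexed by sample ID with columns ``pair_id``, ``status``
    (``T2D`` or ``nonT2D``), ``tissue`` and ``sex``.  ``phenotypes`` is
    indexed by ``(pair_id, status)`` with clinical columns (BMI in kg/m²,
    2-h OGTT glucose in mmol/l, glucose infusion rate, HbA1c in %).
    """

    samples: pd.DataFrame
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"pair_id", "status", "tissue", "sex"}
        missing = required - set(self.samples.columns)
        if missing:
            raise DesignError(f"design table lacks columns {sorted(missing)}")
        bad_status = set(self.samples["status"]) - {STATUS_T2D, STATUS_CONTROL}
        if bad_status:
            raise DesignError(f"unknown status value(s) {sorted(bad_status)}")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise DesignError(f"duplicate sample ID {dup!r}")
        for (pair, tissue), grp in self.samples.groupby(["pair_id", "tissue"]):
            statuses = sorted(grp["status"])
            if statuses != sorted([STATUS_CONTROL, STATUS_T2D]):
                raise DesignError(
                    f"pair {pair!r} in tissue {tissue!r} must have exactly one "
                    f"{STATUS_T2D} and one {STATUS_CONTROL} sample, got {statuses}"
                )
            if grp["sex"].nunique() != 1:
                raise DesignError(f"co-twins of pair {pair!r} differ in sex")

    @property
    def pair_ids(self) -> list:
        return sorted(self.samples["pair_id"].unique())

    @property
    def n_pairs(self) -> int:
        return self.samples["pair_id"].nunique()

    def sample_of(self, pair_id, status: str, tissue: str | None = None) -> str:
        """Sample ID of the given co-twin, optionally within one tissue."""
        sel = (self.samples["pair_id"] == pair_id) & (self.samples["status"] == status)
        if tissue is not None:
            sel &= self.samples["tissue"] == tissue
        hits = self.samples.index[sel]
        if len(hits) != 1:
            raise DesignError(
                f"expected one sample for pair={pair_id!r} status={status} "
                f"tissue={tissue!r}, found {len(hits)}"
            )
        return hits[0]

    def pair_columns(self, tissue: str | None = None) -> pd.DataFrame:
        """One row per pair: sample IDs of the T2D and nonT2D co-twin.

        Rows are ordered by ascending pair ID.
        """
        tab = self.samples
        if tissue is not None:
            tab = tab[tab["tissue"] == tissue]
        rows = []
        for pair in sorted(tab["pair_id"].unique()):
            grp = tab[tab["pair_id"] == pair]
            rows.append(
                {
                    "pair_id": pair,
                    "t2d": grp.index[grp["status"] == STATUS_T2D][0],
                    "control": grp.index[grp["status"] == STATUS_CONTROL][0],
                }
            )
        return pd.DataFrame(rows).set_index("pair_id")

    def phenotype_delta(self, phenotype: str, absolute: bool = True) -> pd.Series:
        """Per-pair T2D − nonT2D phenotype difference (|Δ| by default)."""
        if self.phenotypes is None:
            raise DesignError("design carries no phenotype table")
        wide = self.phenotypes[phenotype].unstack("status")
        delta = wide[STATUS_T2D] - wide[STATUS_CONTROL]
        return delta.abs() if absolute else delta


@dataclass
class ProbeManifest:
    """Probe annotations: gene, TSS distance, sequence, QC flags.

    ``table`` is indexed by probe ID with columns ``gene_symbol``,
    ``distance_to_tss`` (signed bp, negative = upstream, nullable),
    ``probe_sequence`` (50-mer over A/C/G/T), ``cpg_position`` (0-based
    offset of the interrogated CpG in the reference), ``multi_aligned``,
    ``snp_in_cpg`` and ``candidate`` (member of a susceptibility gene)
    booleans.
    """

    table: pd.DataFrame
    candidate_genes: tuple = ()

    def __post_init__(self) -> None:
        missing = set(_MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest lacks columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID {dup!r}")
        seqs = self.table["probe_sequence"].dropna()
        bad = seqs[~seqs.str.fullmatch("[ACGT]*")]
        if len(bad):
            raise ValueError(f"probe {bad.index[0]!r} sequence has illegal characters")
        for col in ("multi_aligned", "snp_in_cpg", "candidate"):
            self.table[col] = self.table[col].astype(bool)
        self.candidate_genes = tuple(self.candidate_genes)
        if self.candidate_genes:
            cand = self.table.loc[self.table["candidate"], "gene_symbol"]
            stray = set(cand) - set(self.candidate_genes)
            if stray:
                raise ValueError(
                    f"candidate probes reference non-candidate gene(s) {sorted(stray)[:5]}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def candidate_probes(self) -> pd.Index:
        return self.table.index[self.table["candidate"]]

    def retained_probes(self) -> pd.Index:
        """Probes passing QC (neither multi-aligned nor SNP-in-CpG)."""
        keep = ~(self.table["multi_aligned"] | self.table["snp_in_cpg"])
        return self.table.index[keep]


@dataclass
class CloneTable:
    """Methylated / unmethylated clone counts per CpG site of one amplicon."""

    counts: pd.DataFrame  # index: site, columns: n_methylated, n_unmethylated
    amplicon_id: str = ""
    pair_id: object = None
    status: str | None = None

    def __post_init__(self) -> None:
        need = {"n_methylated", "n_unmethylated"}
        if not need <= set(self.counts.columns):
            raise ValueError(f"clone table needs columns {sorted(need)}")
        if (self.counts[list(need)] < 0).any().any():
            raise ValueError("clone counts must be non-negative")

    @property
    def n_clones(self) -> pd.Series:
        return self.counts["n_methylated"] + self.counts["n_unmethylated"]


@dataclass
class RepeatPanel:
    """Per-sample per-CpG methylation percentages of repetitive elements.

    ``elements`` maps element name (LINE1, D4Z4, NBL2) to a sites × samples
    DataFrame of percentages in [0, 100].  Site counts are fixed by the
    pyrosequencing assays: LINE1 8, D4Z4 9, NBL2 8.
    """

    elements: Mapping[str, pd.DataFrame]

    def __post_init__(self) -> None:
        self.elements = dict(self.elements)
        for name, frame in self.elements.items():
            expected = REPEAT_SITE_COUNTS.get(name)
            if expected is not None and frame.shape[0] != expected:
                raise ValueError(
                    f"{name} must have {expected} CpG sites, got {frame.shape[0]}"
                )
            arr = frame.to_numpy(dtype=float)
            if np.any((arr < 0) | (arr > 100)):
                raise ValueError(f"{name} percentages outside [0, 100]")

    def pooled(self, names: Iterable[str] | None = None) -> pd.DataFrame:
        """Stack the requested elements into one sites × samples frame."""
        names = list(names) if names is not None else list(self.elements)
        frames = []
        for name in names:
            f = self.elements[name].copy()
            f.index = [f"{name}_{s}" for s in f.index]
            frames.append(f)
        return pd.concat(frames, axis=0)


# ---------------------------------------------------------------------------
# IO


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    beta.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def _read_beta_values(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
    )
    return frame.astype(float)


def read_design(path: str | Path, phenotype_path: str | Path | None = None) -> StudyDesign:
    samples = pd.read_csv(path, sep="\t", index_col="sample_id")
    phenotypes = None
    if phenotype_path is not None:
        phenotypes = pd.read_csv(phenotype_path, sep="\t").set_index(
            ["pair_id", "status"]
        )
    return StudyDesign(samples, phenotypes)


def write_design(design: StudyDesign, path: str | Path,
                 phenotype_path: str | Path | None = None) -> None:
    design.samples.to_csv(path, sep="\t", index_label="sample_id")
    if phenotype_path is not None and design.phenotypes is not None:
        design.phenotypes.reset_index().to_csv(phenotype_path, sep="\t", index=False)


def read_beta_matrix(
    path: str | Path,
    design_path: str | Path,
    phenotype_path: str | Path | None = None,
) -> tuple[BetaMatrix, StudyDesign]:
    """Read a beta-value TSV plus its design table, validating both.

    The matrix has probe IDs in the first column and one column per sample;
    ``NA`` cells become the missing marker.  Every sample column must be
    keyed by the design table (columns sample_id, pair_id, status, tissue,
    sex); a sample absent from the design is an error naming the sample.
    """
    values = _read_beta_values(path)
    design = read_design(design_path, phenotype_path)
    unknown = [s for s in values.columns if s not in design.samples.index]
    if unknown:
        raise DesignError(
            f"sample(s) {unknown} present in the beta matrix but absent from the design"
        )
    tissue = design.samples["tissue"].reindex(values.columns)
    return BetaMatrix(values, tissue=tissue), design


def read_manifest(path: str | Path) -> ProbeManifest:
    table = pd.read_csv(
        path, sep="\t", index_col="probe_id", na_values=["NA"], keep_default_na=False
    )
    for col in ("multi_aligned", "snp_in_cpg", "candidate"):
        table[col] = table[col].astype(int).astype(bool)
    return ProbeManifest(table)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    out = manifest.table.copy()
    for col in ("multi_aligned", "snp_in_cpg", "candidate"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------


def complete_pairs(beta: BetaMatrix, design: StudyDesign, probe: str) -> list:
    """Pairs whose co-twins are both non-missing at ``probe``.

    Returns pair IDs in ascending order; always a subset of the design's
    pairs, and monotone under unmasking (adding data never removes a pair).
    """
    if probe not in beta.values.index:
        raise KeyError(f"unknown probe {probe!r}")
    row = beta.values.loc[probe]
    out = []
    for pair, cols in design.pair_columns().iterrows():
        a, b = cols["t2d"], cols["control"]
        if a in row.index and b in row.index:
            if not (pd.isna(row[a]) or pd.isna(row[b])):
                out.append(pair)
    return out
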