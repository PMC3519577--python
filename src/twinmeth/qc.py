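"""Probe-validity QC: in-silico bisulfite alignment, SNP masking, and
detection-P filtering.

The alignment check mimics, at desk scale, the probe screening of 27K-style
methylation arrays: two "bisulfite-treated" references are built (C→T on the
forward strand, G→A on the reverse), every probe sequence is scanned against
both, and probes hitting more than one location are flagged.  The scan is a
seed-free exact/near-exact sliding comparison with a mismatch budget rather
than a gapped aligner — the criterion of interest is uniqueness, not
alignment score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import BetaMatrix, ProbeManifest

__all__ = [
    "ConvertedReference",
    "QcReport",
    "bisulfite_convert",
    "count_alignments",
    "annotate_alignments",
    "flag_snp_cpg",
    "read_snp_positions",
    "apply_detection_filter",
    "qc_filter",
    "load_reference_fasta",
]

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ConvertedReference:
    """Bisulfite-converted reference strands.

    ``forward`` has every C replaced by T (fully-unmethylated forward
    strand); ``reverse`` has every G replaced by A (the equivalent operation
    read on the reverse strand).  Both preserve length and N characters.
    """

    forward: str
    reverse: str
    source_length: int

    def __post_init__(self) -> None:
        if "C" in self.forward:
            raise ValueError("forward converted reference still contains C")
        if "G" in self.reverse:
            raise ValueError("reverse converted reference still contains G")
        if len(self.forward) != self.source_length or len(self.reverse) != self.source_length:
            raise ValueError("converted strand length differs from source")


@dataclass
class QcReport:
    """Disposition bookkeeping of a probe-filter run.

    Dispositions are mutually exclusive and exhaustive: multi-alignment is
    checked first, then SNP-in-CpG among the remainder, the rest retained.
    """

    n_input: int
    n_excluded_multi: int
    n_excluded_snp: int
    n_retained: int
    disposition: pd.Series  # probe -> {"multi_aligned", "snp_in_cpg", "retained"}

    def __post_init__(self) -> None:
        if self.n_input != self.n_excluded_multi + self.n_excluded_snp + self.n_retained:
            raise ValueError("QC dispositions do not partition the input")

    def to_frame(self) -> pd.DataFrame:
        return self.disposition.rename("disposition").to_frame()

    def summary(self) -> str:
        return (
            f"{self.n_input} probes in; {self.n_excluded_multi} excluded "
            f"(multiple alignments), {self.n_excluded_snp} excluded "
            f"(SNP in CpG); {self.n_retained} retained"
        )


def bisulfite_convert(reference: str) -> ConvertedReference:
    """Build the two in-silico bisulfite-converted reference strands."""
    bad = set(reference.upper()) - _ALPHABET
    if bad:
        raise ValueError(f"illegal reference character(s): {sorted(bad)}")
    ref = reference.upper()
    return ConvertedReference(
        forward=ref.replace("C", "T"),
        reverse=ref.replace("G", "A"),
        source_length=len(ref),
    )


def _scan_exact(probe: str, strand: str) -> int:
    """Count (possibly overlapping) exact occurrences via str.find."""
    count = 0
    pos = strand.find(probe)
    while pos != -1:
        count += 1
        pos = strand.find(probe, pos + 1)
    return count


def _scan_near(probe: np.ndarray, strand: np.ndarray, max_mismatches: int) -> int:
    """Count start positions with <= max_mismatches mismatching characters."""
    k, L = len(probe), len(strand)
    if k > L:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(strand, k)
    mism = (windows != probe).sum(axis=1)
    return int((mism <= max_mismatches).sum())


def count_alignments(
    probe_sequence: str,
    converted: ConvertedReference,
    max_mismatches: int = 0,
) -> int:
    """Distinct start positions of the probe on both converted strands.

    A probe is "uniquely aligned" iff the returned count is exactly 1.
    Exact matching (the default, ``max_mismatches=0``) uses a fast substring
    scan; a positive mismatch budget falls back to a position-by-position
    comparison and is intended for desk-scale references.
    """
    if not probe_sequence:
        raise ValueError("empty probe sequence")
    probe = probe_sequence.upper()
    if max_mismatches == 0:
        return _scan_exact(probe, converted.forward) + _scan_exact(
            probe, converted.reverse
        )
    probe_arr = np.frombuffer(probe.encode(), dtype="S1")
    total = 0
    for strand in (converted.forward, converted.reverse):
        arr = np.frombuffer(strand.encode(), dtype="S1")
        total += _scan_near(probe_arr, arr, max_mismatches)
    return total


def annotate_alignments(
    manifest: ProbeManifest,
    reference: str,
    max_mismatches: int = 0,
) -> ProbeManifest:
    """Recompute ``multi_aligned`` flags by scanning every probe.

    Probes with more than one hit across the two converted strands are
    flagged; zero-hit probes are logged (they indicate a probe designed
    against a different reference) and left unflagged.
    """
    converted = bisulfite_convert(reference)
    table = manifest.table.copy()
    hits = {
        probe: count_alignments(seq, converted, max_mismatches)
        for probe, seq in table["probe_sequence"].items()
    }
    hit_series = pd.Series(hits)
    n_zero = int((hit_series == 0).sum())
    if n_zero:
        logger.warning("%d probe(s) had no alignment against the reference", n_zero)
    table["multi_aligned"] = hit_series > 1
    return ProbeManifest(table, candidate_genes=manifest.candidate_genes)


def read_snp_positions(path: str | Path) -> set[int]:
    """Read SNP coordinates from a 2-column TSV (sequence name, 0-based pos)."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["seq", "pos"])
    return set(tab["pos"].astype(int))


def flag_snp_cpg(manifest: ProbeManifest, snp_positions: set[int]) -> ProbeManifest:
    """Set ``snp_in_cpg`` where a SNP falls on either base of the CpG.

    The interrogated dinucleotide occupies reference offsets
    ``cpg_position`` (the C) and ``cpg_position + 1`` (the G); a SNP on
    either base compromises the probe.
    """
    table = manifest.table.copy()
    cpg = table["cpg_position"].astype(int)
    table["snp_in_cpg"] = [
        (c in snp_positions) or (c + 1 in snp_positions) for c in cpg
    ]
    return ProbeManifest(table, candidate_genes=manifest.candidate_genes)


def apply_detection_filter(
    beta: BetaMatrix,
    detection_p: pd.DataFrame,
    threshold: float = 0.05,
) -> tuple[BetaMatrix, pd.Series]:
    """Mask beta values whose detection P is at or above the threshold.

    The boundary is inclusive (a cell with P exactly at the threshold is
    masked): the rule is "intensity did not exceed background, P ≥ 0.05".
    Returns the masked matrix and the per-sample count of newly masked
    cells.
    """
    detection_p = detection_p.reindex(
        index=beta.values.index, columns=beta.values.columns
    )
    if detection_p.isna().any().any():
        raise ValueError("detection-P matrix does not cover the beta matrix")
    fail = detection_p.to_numpy() >= threshold
    already = beta.values.isna().to_numpy()
    masked = beta.values.mask(pd.DataFrame(fail, index=beta.values.index,
                                           columns=beta.values.columns))
    counts = pd.Series(
        (fail & ~already).sum(axis=0), index=beta.values.columns, name="n_masked"
    )
    return BetaMatrix(masked, tissue=beta.tissue), counts


def qc_filter(manifest: ProbeManifest) -> tuple[ProbeManifest, QcReport]:
    """Apply the sequential probe exclusions and account for every probe.

    Multi-alignment is applied first; SNP-in-CpG only among probes that
    survived it (mirroring "additionally excluded").  The report partitions
    the input exactly, which is asserted on every run.
    """
    table = manifest.table
    multi = table["multi_aligned"]
    snp = ~multi & table["snp_in_cpg"]
    retained = ~multi & ~snp
    disposition = pd.Series("retained", index=table.index)
    disposition[multi] = "multi_aligned"
    disposition[snp] = "snp_in_cpg"
    report = QcReport(
        n_input=len(table),
        n_excluded_multi=int(multi.sum()),
        n_excluded_snp=int(snp.sum()),
        n_retained=int(retained.sum()),
        disposition=disposition,
    )
    logger.info(report.summary())
    kept = ProbeManifest(table[retained].copy(), candidate_genes=manifest.candidate_genes)
    return kept, report


def load_reference_fasta(path: str | Path) -> str:
    """Concatenate all records of a FASTA file into one reference string."""
    return "".join(str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta"))
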