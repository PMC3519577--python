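import numpy as np
import pandas as pd
import pytest

import twinmeth as tm


@pytest.fixture(scope="session")
def small_manifest():
    """100-probe manifest with 5 multi-aligned, 3 SNP-in-CpG, 10 candidates."""
    manifest, reference = tm.generate_probe_manifest(100, 5, 3, 10, seed=11)
    return manifest, reference


@pytest.fixture(scope="session")
def twin_data(small_manifest):
    """Default-world beta matrix, design with phenotypes, and ground truth."""
    manifest, _ = small_manifest
    beta, design, truth = tm.generate_twin_beta(manifest, tm.MUSCLE_CONFIG, seed=7)
    phenos = tm.generate_phenotypes(design.n_pairs, seed=7)
    design = tm.StudyDesign(design.samples, phenos)
    return beta, design, truth


def make_beta(values, sample_ids=None, tissue="muscle"):
    """BetaMatrix from a plain array with autogenerated probe/sample names."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    probes = pd.Index([f"p{i}" for i in range(m)], name="probe_id")
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n)]
    return tm.BetaMatrix(
        pd.DataFrame(values, index=probes, columns=sample_ids), tissue=tissue
    )


def make_paired_design(n_pairs, tissue="muscle"):
    """Design with samples pair{i}_T2D / pair{i}_nonT2D, shared sex per pair."""
    rows = []
    for p in range(1, n_pairs + 1):
        for status in ("T2D", "nonT2D"):
            rows.append(
                {
                    "sample_id": f"pair{p:02d}_{status}",
                    "pair_id": f"pair{p:02d}",
                    "status": status,
                    "tissue": tissue,
                    "sex": "F" if p % 2 else "M",
                }
            )
    return tm.StudyDesign(pd.DataFrame(rows).set_index("sample_id"))
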