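import numpy as np
import pandas as pd
import pytest

from gbspop.variants import MISSING, GenotypeMatrix


def make_gm(dosage, depth=None, depth_fill=30):
    """GenotypeMatrix from a dosage array; missing calls get depth 0."""
    dosage = np.asarray(dosage, dtype=np.int16)
    if depth is None:
        depth = np.where(dosage == MISSING, 0, depth_fill).astype(np.int32)
    return GenotypeMatrix(dosage, np.asarray(depth, dtype=np.int32),
                          [f"S{i}" for i in range(dosage.shape[0])])


def make_vt(positions, chrom="B1"):
    """Variant table for loci at the given positions on one chromosome."""
    positions = list(positions)
    vt = pd.DataFrame({
        "chrom": [chrom] * len(positions),
        "pos": positions,
        "ref": ["A"] * len(positions),
        "alt": ["G"] * len(positions),
    })
    vt["snp_name"] = vt["chrom"] + "_" + vt["pos"].astype(str)
    vt["context"] = "NA"
    vt["effect"] = "NA"
    vt["maf"] = np.nan
    vt["het_rate"] = np.nan
    vt["missing_rate"] = 0.0
    return vt


@pytest.fixture(scope="session")
def small_panel():
    """A small annotated two-population panel shared by read-only tests."""
    from gbspop.simpanel import SimulationConfig, simulate_panel

    cfg = SimulationConfig(n_per_pop=(40, 20), n_chrom=2, chrom_length=1_000_000,
                           n_loci_per_chrom=120, fst_param=0.15, selfing_rate=0.8,
                           missing_rate=0.08, depth_mean=10, seed=11)
    return simulate_panel(cfg)
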