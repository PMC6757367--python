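import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gsdiv import Pedigree


@pytest.fixture
def trio():
    return Pedigree.from_records(
        [("sire1", None, None), ("dam1", None, None), ("kid1", "sire1", "dam1")]
    )


@pytest.fixture
def fullsib_pedigree():
    """Offspring of a full-sib mating between children of two founders."""
    return Pedigree.from_records(
        [
            ("A", None, None),
            ("B", None, None),
            ("S", "A", "B"),
            ("D", "A", "B"),
            ("X", "S", "D"),
        ]
    )


@pytest.fixture
def small_snp_map():
    """Single-autosome map, even 70 kb spacing, 30 SNPs."""
    bp = np.arange(30) * 70_000 + 1
    return pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"s{i}" for i in range(30)],
            "bp": bp.astype(np.int64),
            "cM": bp / 1e6,
        }
    )


def make_panel(geno_rows, bp, ids=None, chrom="1"):
    """Build a GenotypePanel from a genotype array and positions."""
    from gsdiv import GenotypePanel

    geno = np.asarray(geno_rows, dtype=np.int8)
    if geno.ndim == 1:
        geno = geno[None, :]
    if ids is None:
        ids = [f"ind{i}" for i in range(geno.shape[0])]
    snp_map = pd.DataFrame(
        {
            "chrom": chrom,
            "snp_id": [f"s{i}" for i in range(len(bp))],
            "bp": np.asarray(bp, dtype=np.int64),
            "cM": np.asarray(bp, dtype=float) / 1e6,
        }
    )
    return GenotypePanel(list(ids), geno, snp_map)
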