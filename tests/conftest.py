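import numpy as np
import pandas as pd
import pytest

from csiaa import AminoAcidSample, EndMember, EndMemberSet
from csiaa.amino_acids import CANONICAL_AA


@pytest.fixture
def full_sample() -> AminoAcidSample:
    """One sample carrying all 13 amino acids with round-number values."""
    d15n = {
        "Ala": 22.6, "Asp": 17.9, "Glu": 26.3, "Leu": 21.0, "Ile": 26.3,
        "Pro": 19.1, "Val": 19.4, "Gly": 11.4, "Lys": 19.3, "Ser": 11.3,
        "Phe": 16.2, "Tyr": 12.9, "Thr": 8.8,
    }
    mol = {aa: 100.0 / 13 for aa in CANONICAL_AA}
    return AminoAcidSample(
        sample_id="S1", bay="MB", station="E5MB", depth_m=45.0,
        matrix="sinking", d15n=d15n, mol_pct=mol,
    )


@pytest.fixture
def aa_table_csv(tmp_path, full_sample):
    """A valid 13-row long-format amino-acid CSV on disk."""
    from csiaa import write_aa_table

    path = tmp_path / "aa.csv"
    write_aa_table([full_sample], path)
    return path


@pytest.fixture
def two_source_endmembers() -> EndMemberSet:
    """Two well-separated single-tracer sources (10σ apart)."""
    return EndMemberSet((
        EndMember("A", {"t": (0.0, 0.5, None)}),
        EndMember("B", {"t": (5.0, 0.5, None)}),
    ))


@pytest.fixture
def ctd_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "depth_m": [5.0, 20.0, 35.0, 45.0],
        "temp_c": [19.0, 16.0, 14.0, 13.5],
        "sal_psu": [33.8, 34.2, 34.5, 34.6],
        "o2_um": [330.0, 150.0, 40.0, 20.0],
        "ph": [8.3, 8.0, 7.9, 7.8],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230301)
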