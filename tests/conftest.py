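import pytest

from famkit import synthetic_data
from famkit.molecular_evolution import load_reference_pairs
from famkit.motif_scan import scan_ccch


@pytest.fixture(scope="session")
def reference_pairs():
    """Published switchgrass C3H duplicate-pair table (19 pairs)."""
    return load_reference_pairs()


@pytest.fixture(scope="session")
def family_scale_proteome():
    """Synthetic proteome at family scale: 103 proteins, 202 planted motifs."""
    records, truth = synthetic_data.gen_proteome(
        synthetic_data.paper_scale_motif_plan(), seed=20240101
    )
    return records, truth


@pytest.fixture(scope="session")
def family_scale_hits(family_scale_proteome):
    records, _ = family_scale_proteome
    return {r.id: scan_ccch(r) for r in records}
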