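import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chelonia import simgen
from chelonia.core import CallableMask


@pytest.fixture(scope="session")
def turtle_sim():
    """Shared 4 Mb five-species simulation (no migration)."""
    model = simgen.turtle_like_model()
    layout = simgen.GenomeLayout((("s1", 2_000_000), ("s2", 2_000_000)))
    return simgen.simulate_genotypes(model, layout, seed=11)


@pytest.fixture(scope="session")
def turtle_sim_migration():
    """Shared 4 Mb simulation with HH<->OL gene flow after their split."""
    mig = [
        simgen.MigrationEpoch(
            pair=("HH", "OL"), rate=5e-5, start=5_000, end=30_000, direction="both"
        )
    ]
    model = simgen.turtle_like_model(migration=mig)
    layout = simgen.GenomeLayout((("s1", 4_000_000),))
    return simgen.simulate_genotypes(model, layout, seed=13, include_mito=False)


@pytest.fixture
def full_mask():
    return CallableMask.full({"s": 1_000_000})
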