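import numpy as np
import pytest
from hypothesis import settings

from npcbd import fixtures, forcefield, geometry

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_structure():
    """Full default NPC (built once; treat as read-only)."""
    return geometry.build_npc(seed=0)


@pytest.fixture(scope="session")
def mini_structure():
    """Mini NPC, freshly built (not equilibrated); treat as read-only."""
    return fixtures.mini_npc(seed=1)


@pytest.fixture()
def rules():
    return forcefield.InteractionRuleSet()


def brute_force_pairs(fs, positions):
    """Independent O(N^2) nonbonded pair enumeration (test oracle)."""
    n = len(positions)
    excl = set(int(k) for k in fs.excl)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if i * n + j in excl:
                continue
            out.append((i, j))
    return np.array(out, dtype=np.int64)
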