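"""Counter-based child-seed derivation.

Every stochastic stage derives its seed from a master seed plus a fixed
tuple of counters, so adding replicates or reordering jobs never perturbs
the randomness of earlier cells.
"""

from __future__ import annotations

import numpy as np


def child_seed(master: int, *counters: int) -> int:
    """Deterministic child seed below 2**31 for a (master, counters) key."""
    ss = np.random.SeedSequence([int(master), *[int(c) for c in counters]])
    return int(ss.generate_state(1)[0] % (2**31))
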