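"""Deterministic random parameter triples for property tests and scans."""

from __future__ import annotations

import numpy as np

__all__ = ["sample_fixtures"]


def sample_fixtures(seed: int, n: int) -> list[tuple[float, float, float]]:
    """Draw ``n`` parameter triples (alpha1, rho, a), reproducibly.

    alpha1 is a two-decimal value in [0.05, 0.99] (so it always rationalizes
    under the denominator-100 convention); rho and a are log-uniform in
    [0.1, 100].
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    alpha1 = rng.integers(5, 100, size=n) / 100.0
    rho = 10.0 ** rng.uniform(-1.0, 2.0, size=n)
    a = 10.0 ** rng.uniform(-1.0, 2.0, size=n)
    return [(float(al), float(r), float(av)) for al, r, av in zip(alpha1, rho, a)]
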