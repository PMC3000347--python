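"""Sequence windows with planted motifs, for enrichment power studies.

Generates matched sets of "noise-site" and "decoy-site" flanking windows
from the same background composition, with a chosen hexamer planted at a
higher per-window rate in the noise set.  This isolates the enrichment
statistics from the junction-discovery machinery.
"""

from __future__ import annotations

import numpy as np

from .._seq import array_to_seq, random_dna


def _plant(windows: list[str], motif: str, rate: float,
           rng: np.random.Generator) -> list[str]:
    out = []
    m = len(motif)
    for w in windows:
        if len(w) >= m and rng.random() < rate:
            p = int(rng.integers(0, len(w) - m + 1))
            w = w[:p] + motif + w[p + m:]
        out.append(w)
    return out


def motif_spike_windows(n_noise: int, n_decoy: int, length: int, motif: str,
                        noise_rate: float, decoy_rate: float, seed: int
                        ) -> tuple[list[str], list[str]]:
    """Random windows with ``motif`` planted at ``noise_rate`` vs ``decoy_rate``.

    Rates are per-window planting probabilities; with equal rates the two
    sets are exchangeable draws from the same background (the null case).
    """
    rng = np.random.default_rng(seed)
    noise = [array_to_seq(random_dna(length, rng)) for _ in range(n_noise)]
    decoy = [array_to_seq(random_dna(length, rng)) for _ in range(n_decoy)]
    noise = _plant(noise, motif, noise_rate, rng)
    decoy = _plant(decoy, motif, decoy_rate, rng)
    return noise, decoy
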