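"""Low-complexity (poly-base) interval detection.

Finds maximal intervals of length >= ``min_run`` in which a single base
reaches frequency >= ``min_purity``: every window of length ``min_run``
is tested, qualifying windows are merged per dominant base, and
intervals of different bases that overlap are merged under the base most
frequent in the merged span.
"""

from __future__ import annotations

import numpy as np

_BASES = "ACGT"


def _merge_windows(starts: np.ndarray, width: int) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent fixed-width windows into intervals."""
    merged: list[tuple[int, int]] = []
    for s in starts:
        s, e = int(s), int(s) + width
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def detect_low_complexity(
    seq: str,
    min_run: int = 15,
    min_purity: float = 0.9,
) -> list[tuple[int, int, str]]:
    """Return (start, end, base) intervals of low sequence complexity."""
    if min_run < 5:
        raise ValueError("min_run must be >= 5")
    if not (0.5 < min_purity <= 1.0):
        raise ValueError("min_purity must lie in (0.5, 1]")
    seq = seq.upper()
    n = len(seq)
    if n < min_run:
        return []

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    per_base: list[tuple[int, int, str]] = []
    threshold = min_purity * min_run
    for base in _BASES:
        is_base = (arr == ord(base)).astype(np.int32)
        window_counts = np.convolve(is_base, np.ones(min_run, dtype=np.int32),
                                    mode="valid")
        qualifying = np.nonzero(window_counts >= threshold - 1e-9)[0]
        for s, e in _merge_windows(qualifying, min_run):
            per_base.append((s, e, base))

    if not per_base:
        return []
    # merge overlapping intervals across bases, dominant base by count
    per_base.sort()
    merged: list[tuple[int, int, str]] = []
    for s, e, b in per_base:
        if merged and s < merged[-1][1]:
            ps, pe, _ = merged[-1]
            ns, ne = ps, max(pe, e)
            span = seq[ns:ne]
            dom = max(_BASES, key=span.count)
            merged[-1] = (ns, ne, dom)
        else:
            merged.append((s, e, b))
    return merged
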