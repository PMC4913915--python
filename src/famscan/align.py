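"""Global pairwise alignment and percent identity.

Needleman-Wunsch with linear gap penalties and a deterministic traceback
(diagonal preferred over gap-in-a over gap-in-b on score ties).  Identity
is reported as 100 * matched columns / alignment columns, which is what
every downstream rule (duplicate threshold, p-distance) consumes.

The default scoring (+1 match, -1 mismatch, -2 gap) is deliberately simple:
identity, not score, drives the pipeline, and substitution-matrix scoring
is an extension point rather than a default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float  # percent, in [0, 100]

    @property
    def p_distance(self) -> float:
        return 1.0 - self.identity / 100.0


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Optimal global alignment of two amino-acid sequences.

    Raises ValueError on empty input.  The DP fill is vectorized per row;
    the in-row horizontal recurrence uses the running-maximum identity
    ``best[j] = max_k (M[k] + (j-k)*gap)`` computed with a cumulative max.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)

    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    jcol = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], match, mismatch)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + gap
        M = np.maximum(diag, up)
        # best[j] = max(M[j-1], best[j-1] + gap) with best[0] = i*gap
        shifted = np.concatenate(([H[i, 0]], M - gap * jcol))
        H[i, 1:] = np.maximum.accumulate(shifted)[1:] + gap * jcol

    # Deterministic traceback: diagonal > gap in b (up) > gap in a (left).
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    identity = 100.0 * matches / len(aligned_a)
    return Alignment(aligned_a, aligned_b, float(H[n, m]), identity)


def percent_identity(a: str, b: str, **kwargs) -> float:
    return global_align(a, b, **kwargs).identity
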