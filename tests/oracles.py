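"""Independent reference implementations used only to check the package.

These deliberately avoid the package's internal code paths: reverse
complement is a dict loop, Hamming matching is a per-window scan, and
permutation detection enumerates every rotation point of a read and every
genomic occurrence of the rotated window.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def hamming_hits(read: str, genome_seq: str, max_mm: int) -> list[tuple[int, str, int]]:
    """Every (position, strand, mismatches) within max_mm, by direct
    per-window comparison on both strands. N always mismatches."""
    hits = []
    ell = len(read)
    for strand, s in (("+", read), ("-", rc(read))):
        for p in range(len(genome_seq) - ell + 1):
            w = genome_seq[p : p + ell]
            mm = sum(1 for a, b in zip(s, w) if a != b or a == "N" or b == "N")
            if mm <= max_mm:
                hits.append((p, strand, mm))
    return sorted(hits)


def min_mismatch_sliding(read: str, genome_seq: str) -> int:
    """Minimum Hamming distance over all windows/strands via an explicit
    window matrix (numpy sliding-window route, distinct from the package's
    substring-search + offset-accumulation route)."""
    from numpy.lib.stride_tricks import sliding_window_view

    g = np.frombuffer(genome_seq.encode(), dtype=np.uint8)
    best = len(read) + 1
    for s in (read, rc(read)):
        r = np.frombuffer(s.replace("N", "n").encode(), dtype=np.uint8)
        if len(r) > len(g):
            continue
        windows = sliding_window_view(g, len(r))
        best = min(best, int((windows != r).sum(axis=1).min()))
    return best


def occurs_exact(read: str, genome_seq: str) -> bool:
    return read in genome_seq or rc(read) in genome_seq


def rotation_hits(
    read: str, genome_seq: str, k: int = 12, min_transfer: int = 5
) -> set[tuple[str, int, int, int]]:
    """Exhaustive rotation enumeration: for every rotation point s of the
    (oriented) read and every genomic occurrence of the rotated window,
    report (strand, anchor, matched_prefix, relocated_len).

    A junction is only real at the maximal prefix split: the base before
    the window must differ from the base after it (or the window must end
    at a genome edge), otherwise the same read is a rotation of the
    shifted window and the detector reports that split instead.
    """
    L = len(genome_seq)
    hits: set[tuple[str, int, int, int]] = set()
    for strand, oriented in (("+", read), ("-", rc(read))):
        ell = len(oriented)
        for s in range(min_transfer, ell - k + 1):
            m = ell - s
            window = oriented[m:] + oriented[:m]
            a = genome_seq.find(window)
            while a >= 0:
                if a + ell == L or genome_seq[a] != genome_seq[a + ell]:
                    hits.add((strand, a + s, m, s))
                a = genome_seq.find(window, a + 1)
    return hits


def binomial_3sd(p: float, n: int) -> float:
    """Three binomial standard deviations of a proportion estimate."""
    return 3.0 * (p * (1.0 - p) / n) ** 0.5
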