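"""Independent brute-force oracles used to cross-check the implementation.

Deliberately slow and simple: per-start extension for repeat finding, a
plain run scanner for clusters, per-position membership counting for bin
densities. They share no code with the package's vectorized paths.
"""

from __future__ import annotations


def smallest_period(motif: str) -> int:
    return (motif + motif).index(motif, 1)


def brute_force_ssrs(
    seq: str,
    min_copies: tuple[int, ...] = (6, 3, 3, 3, 3, 3),
    allow_partial_tail: bool = True,
) -> list[tuple[int, int, str, int, int]]:
    """All maximal perfect repeats as (start, end, motif, unit, copies), 1-based.

    For each unit size in ascending order and each start position, extends
    the maximal perfect run, then applies left-maximality, primitivity,
    the copy threshold, and the smaller-unit containment rule.
    """
    n = len(seq)
    accepted: list[tuple[int, int, int]] = []  # (start, end, unit)
    out: list[tuple[int, int, str, int, int]] = []
    for u in range(1, 7):
        level = []
        for i in range(n - u):
            motif = seq[i : i + u]
            if "N" in motif:
                continue
            j = i + u
            while j < n and seq[j] != "N" and seq[j] == seq[j - u]:
                j += 1
            total = j - i
            if total < u + 1:
                continue  # no periodic match at all
            copies = total // u
            if copies < min_copies[u - 1]:
                continue
            # left-maximality: the run must not extend to position i-1
            if i > 0 and i - 1 + u < n and seq[i - 1 + u] != "N" and seq[i - 1] == seq[i - 1 + u]:
                continue
            if smallest_period(motif) != u:
                continue
            length = total if allow_partial_tail else copies * u
            start, end = i + 1, i + length
            if any(s <= start and e >= end for s, e, uu in accepted if uu < u):
                continue
            level.append((start, end, motif, u, copies))
        out.extend(level)
        accepted.extend((s, e, u) for s, e, _, _, _ in level)
    return sorted(out)


def brute_force_cluster_runs(classes: list[str]) -> list[tuple[int, int, str]]:
    """Maximal same-class runs of length >= 3 as (start_idx, stop_idx, class)."""
    runs = []
    i = 0
    while i < len(classes):
        j = i
        while j < len(classes) and classes[j] == classes[i]:
            j += 1
        if j - i >= 3:
            runs.append((i, j, classes[i]))
        i = j
    return runs


def per_position_bin_counts(
    ssr_intervals: list[tuple[int, int]], seg_start: int, seg_size: int, d_n: int
) -> list[int]:
    """Per-bin SSR bp by marking every covered position individually."""
    covered = [False] * seg_size
    for s, e in ssr_intervals:
        for p in range(s, e + 1):
            covered[p - seg_start] = True
    n_bins = -(-seg_size // d_n)
    counts = [0] * n_bins
    for off, c in enumerate(covered):
        if c:
            counts[off // d_n] += 1
    return counts
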