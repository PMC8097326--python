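"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive enumeration so they stay independent of the
algorithms they verify; they are only feasible at toy sizes.
"""

from itertools import combinations


def valid_chain(chain, max_gap):
    """A chain is valid if rank_a strictly increases, rank_b is strictly
    monotone (either direction), and consecutive gaps are <= max_gap in
    both coordinates."""
    if len(chain) <= 1:
        return True
    for direction in (1, -1):
        ok = True
        for (ra1, rb1, _), (ra2, rb2, _) in zip(chain, chain[1:]):
            if not (ra1 < ra2 <= ra1 + max_gap):
                ok = False
                break
            db = direction * (rb2 - rb1)
            if not (0 < db <= max_gap):
                ok = False
                break
        if ok:
            return True
    return False


def best_chain_score_bruteforce(anchors, max_gap=20, min_pairs=4):
    """Maximum total score over all valid chains with >= min_pairs anchors.

    ``anchors`` is a list of (rank_a, rank_b, score) triples.
    """
    ordered = sorted(anchors)
    best = 0.0
    for k in range(min_pairs, len(ordered) + 1):
        for combo in combinations(ordered, k):
            if valid_chain(list(combo), max_gap):
                best = max(best, sum(score for _, _, score in combo))
    return best


def nx_lx_bruteforce(lengths, x):
    """N-x and L-x by explicit cumulative scan of descending lengths."""
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    running = 0
    for i, length in enumerate(ordered):
        running += length
        if running * 100 >= x * total:
            return length, i + 1
    raise AssertionError("unreachable")


def link_runs_bruteforce(indices, max_gap):
    """Merge sorted window indices into runs with inter-run gap > max_gap."""
    if not indices:
        return []
    runs = [[indices[0], indices[0]]]
    for idx in indices[1:]:
        if idx - runs[-1][1] - 1 <= max_gap:
            runs[-1][1] = idx
        else:
            runs.append([idx, idx])
    return [tuple(run) for run in runs]
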