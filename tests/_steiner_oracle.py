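"""Independent minimum Steiner tree oracle on the binary hamming hypercube.

The parsimony length of a set of haplotypes (with inferred intermediates
allowed) equals the minimum Steiner tree connecting their presence/absence
vectors in the unit-cost hypercube.  This module computes that minimum with
the Dreyfus-Wagner dynamic program over all 2^k hypercube vertices — a
completely different algorithm from the tree-search the package uses, so it
can serve as an exhaustive cross-check at small k.
"""

from itertools import combinations


def hamming(a: int, b: int) -> int:
    return (a ^ b).bit_count()


def steiner_minimum(terminal_vectors, n_chars: int) -> int:
    """Minimum total edge weight of a Steiner tree spanning the terminals.

    ``terminal_vectors`` are bitmask-encoded profiles over ``n_chars`` binary
    characters; vertices of the hypercube may be used freely as Steiner
    points.
    """
    terminals = sorted(set(terminal_vectors))
    if len(terminals) <= 1:
        return 0
    n_vertices = 1 << n_chars
    t0, rest = terminals[0], terminals[1:]
    k = len(rest)

    INF = float("inf")
    # dp[S][v]: cost of the cheapest tree spanning {rest[i]: i in S} plus v
    dp = [[INF] * n_vertices for _ in range(1 << k)]
    for i, t in enumerate(rest):
        for v in range(n_vertices):
            dp[1 << i][v] = hamming(t, v)

    for S in range(1, 1 << k):
        if S.bit_count() >= 2:
            # merge two subtrees at v
            sub = (S - 1) & S
            while sub:
                comp = S & ~sub
                if sub < comp:  # each unordered partition once
                    for v in range(n_vertices):
                        c = dp[sub][v] + dp[comp][v]
                        if c < dp[S][v]:
                            dp[S][v] = c
                sub = (sub - 1) & S
        # metric closure relaxation (hamming distance is the graph metric)
        best = min(range(n_vertices), key=lambda u: dp[S][u])
        for v in range(n_vertices):
            base = dp[S][v]
            for u in range(n_vertices):
                c = dp[S][u] + hamming(u, v)
                if c < base:
                    base = c
            dp[S][v] = base

    return int(dp[(1 << k) - 1][t0])
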