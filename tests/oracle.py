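"""Independent brute-force oracles used by the test suite.

``brute_force_call`` classifies an origin vector by exhaustive search:
it enumerates *every* pairing of adjacent origin-switch boundaries into
candidate conversion tracts, keeps the maximum-cardinality,
lexicographically earliest valid pairing (events are parsimonious and
assigned left to right), and then applies the CO/NCOGC definitions to
the chosen segmentation.  It shares only the rule constants with the
production caller, not its scanning algorithm.

``fisher_enumeration`` computes the two-sided Fisher exact p-value by
direct summation of hypergeometric point probabilities.
"""

from itertools import combinations
from math import comb

UNKNOWN = -1


def brute_force_call(calls, positions, min_support_co=2, max_ncogc_span=10_000):
    """Return (events, unresolved) as canonical tuples.

    events: sorted list of (class, left_flank, inner_start, inner_end,
    right_flank, n_support); unresolved: list of (left_flank, right_flank).
    """
    obs = [(c, p) for c, p in zip(calls, positions) if c != UNKNOWN]
    if not obs:
        raise ValueError("uninformative vector")
    runs = []  # (origin, [positions...])
    for c, p in obs:
        if runs and runs[-1][0] == c:
            runs[-1][1].append(p)
        else:
            runs.append((c, [p]))
    nb = len(runs) - 1  # boundary j sits between runs j and j+1

    # edge j pairs boundaries (j, j+1) and turns run j+1 into a tract
    allowed = [
        runs[j + 1][1][-1] - runs[j + 1][1][0] <= max_ncogc_span for j in range(nb - 1)
    ]
    best = ()
    for r in range(nb - 1, -1, -1):  # maximize number of tracts
        hit = None
        for combo in combinations(range(nb - 1), r):  # lexicographic order
            if any(not allowed[j] for j in combo):
                continue
            if any(b - a < 2 for a, b in zip(combo, combo[1:])):
                continue  # adjacent edges share a boundary
            hit = combo
            break
        if hit is not None:
            best = hit
            break

    paired = set()
    for j in best:
        paired.update((j, j + 1))

    events, unresolved = [], []
    for j in best:
        tract = runs[j + 1][1]
        events.append(
            (
                "NCOGC",
                runs[j][1][-1],
                tract[0],
                tract[-1],
                runs[j + 2][1][0],
                len(tract),
            )
        )
    for b in range(nb):
        if b in paired:
            continue
        left, right = runs[b][1], runs[b + 1][1]
        left_ok = len(left) >= min_support_co or b == 0
        right_ok = len(right) >= min_support_co
        if left_ok and right_ok:
            events.append(("CO", left[-1], right[0], right[-1], right[0], len(right)))
        else:
            unresolved.append((left[-1], right[0]))
    return sorted(events), sorted(unresolved)


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric point probabilities
    of every same-margin table at most as probable as the observed one."""
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    if min(r1, r2, k, b + d) <= 0:
        raise ValueError("zero margin")
    denom = comb(n, k)

    def prob(x):
        return comb(r1, x) * comb(r2, k - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, k - r2), min(r1, k) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)
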