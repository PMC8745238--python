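"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — nested loops, explicit flood fill,
graph search — and shares no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import Counter, deque

import numpy as np

NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def entropy_bits(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


# ---------------------------------------------------------------------------
# Texture-matrix oracles (levels: 2D int array with 0 outside the mask)
# ---------------------------------------------------------------------------

def glcm_oracle(levels, offsets, distance=1):
    """Per-direction symmetric co-occurrence features, averaged."""
    levels = np.asarray(levels)
    h, w = levels.shape
    per_angle = []
    for dr, dc in offsets:
        pairs = Counter()
        for r in range(h):
            for c in range(w):
                if levels[r, c] == 0:
                    continue
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < h and 0 <= c2 < w and levels[r2, c2] != 0:
                    pairs[(levels[r, c], levels[r2, c2])] += 1
                    pairs[(levels[r2, c2], levels[r, c])] += 1
        total = sum(pairs.values())
        if total == 0:
            continue
        p = {ij: n / total for ij, n in pairs.items()}
        psum = Counter()
        for (i, j), q in p.items():
            psum[i + j] += q
        per_angle.append(
            {
                "autocorrelation": sum(i * j * q for (i, j), q in p.items()),
                "joint_average": sum(i * q for (i, j), q in p.items()),
                "joint_entropy": entropy_bits(p.values()),
                "sum_average": sum(k * q for k, q in psum.items()),
                "sum_entropy": entropy_bits(psum.values()),
            }
        )
    if not per_angle:
        return None
    return {k: float(np.mean([a[k] for a in per_angle])) for k in per_angle[0]}


def gldm_oracle(levels, alpha=0):
    """Dependence features; dependence index = dependent neighbours + 1."""
    levels = np.asarray(levels)
    h, w = levels.shape
    cells = Counter()
    for r in range(h):
        for c in range(w):
            g = levels[r, c]
            if g == 0:
                continue
            d = 0
            for dr, dc in NEIGHBOURS_8:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and levels[r2, c2] != 0:
                    if abs(int(levels[r2, c2]) - int(g)) <= alpha:
                        d += 1
            cells[(int(g), d + 1)] += 1
    total = sum(cells.values())
    p = {gj: n / total for gj, n in cells.items()}
    return {
        "dependence_entropy": entropy_bits(p.values()),
        "high_gray_level_emphasis": sum(q * g**2 for (g, j), q in p.items()),
        "large_dependence_low_gray_level_emphasis": sum(
            q * j**2 / g**2 for (g, j), q in p.items()
        ),
        "low_gray_level_emphasis": sum(q / g**2 for (g, j), q in p.items()),
        "small_dependence_low_gray_level_emphasis": sum(
            q / (j**2 * g**2) for (g, j), q in p.items()
        ),
    }


def _oracle_lines(levels, offset):
    """Scan lines along a direction, as lists of levels."""
    levels = np.asarray(levels)
    h, w = levels.shape
    dr, dc = offset
    starts = []
    for r in range(h):
        for c in range(w):
            rp, cp = r - dr, c - dc
            if not (0 <= rp < h and 0 <= cp < w):
                starts.append((r, c))
    lines = []
    for r, c in starts:
        line = []
        while 0 <= r < h and 0 <= c < w:
            line.append(int(levels[r, c]))
            r, c = r + dr, c + dc
        lines.append(line)
    return lines


def glrlm_oracle(levels, offsets):
    per_angle = []
    for offset in offsets:
        runs = Counter()
        for line in _oracle_lines(levels, offset):
            i = 0
            while i < len(line):
                if line[i] == 0:
                    i += 1
                    continue
                j = i
                while j < len(line) and line[j] == line[i]:
                    j += 1
                runs[(line[i], j - i)] += 1
                i = j
        total = sum(runs.values())
        if total == 0:
            continue
        p = {gr: n / total for gr, n in runs.items()}
        per_angle.append(
            {
                "high_gray_level_run_emphasis": sum(q * g**2 for (g, r), q in p.items()),
                "long_run_low_gray_level_emphasis": sum(
                    q * r**2 / g**2 for (g, r), q in p.items()
                ),
                "low_gray_level_run_emphasis": sum(q / g**2 for (g, r), q in p.items()),
                "short_run_low_gray_level_emphasis": sum(
                    q / (r**2 * g**2) for (g, r), q in p.items()
                ),
            }
        )
    if not per_angle:
        return None
    return {k: float(np.mean([a[k] for a in per_angle])) for k in per_angle[0]}


def glszm_oracle(levels):
    """Zones by explicit 8-connected flood fill."""
    levels = np.asarray(levels)
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = Counter()
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            g = int(levels[r, c])
            size = 0
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                y, x = queue.popleft()
                size += 1
                for dr, dc in NEIGHBOURS_8:
                    y2, x2 = y + dr, x + dc
                    if 0 <= y2 < h and 0 <= x2 < w and not seen[y2, x2] and levels[y2, x2] == g:
                        seen[y2, x2] = True
                        queue.append((y2, x2))
            zones[(g, size)] += 1
    total = sum(zones.values())
    p = {gs: n / total for gs, n in zones.items()}
    return {
        "high_gray_level_zone_emphasis": sum(q * g**2 for (g, s), q in p.items()),
        "low_gray_level_zone_emphasis": sum(q / g**2 for (g, s), q in p.items()),
        "small_area_low_gray_level_emphasis": sum(
            q / (s**2 * g**2) for (g, s), q in p.items()
        ),
    }


# ---------------------------------------------------------------------------
# Sequence / graph oracles
# ---------------------------------------------------------------------------

def is_subsequence(pattern, trace):
    it = iter(trace)
    return all(any(s == t for t in it) for s in pattern)


def chain_can_reach_action(trace, action):
    """BFS on the chain graph: can the initial state reach a state with an
    outgoing ``action`` transition?"""
    # chain: state i --trace[i]--> state i+1
    reachable = {0}
    frontier = deque([0])
    while frontier:
        s = frontier.popleft()
        if s < len(trace) and s + 1 not in reachable:
            reachable.add(s + 1)
            frontier.append(s + 1)
    return any(trace[s] == action for s in reachable if s < len(trace))


def exhaustive_information_gain(values, labels):
    """Max information gain over every possible binary threshold split."""
    values = list(map(float, values))
    labels = list(labels)
    n = len(values)

    def h(ls):
        cnt = Counter(ls)
        return entropy_bits([v / len(ls) for v in cnt.values()])

    best = 0.0
    for t in sorted(set(values)):
        left = [l for v, l in zip(values, labels) if v <= t]
        right = [l for v, l in zip(values, labels) if v > t]
        if not left or not right:
            continue
        gain = h(labels) - (len(left) * h(left) + len(right) * h(right)) / n
        best = max(best, gain)
    return best


def enumerate_accepted_patterns(traces, labels, max_len, min_pos, max_neg,
                                positive="metastatic"):
    """All accepted patterns by direct enumeration over the alphabet."""
    from itertools import product

    alphabet = sorted({s for t in traces for s in t})
    pos = [t for t, l in zip(traces, labels) if l == positive]
    neg = [t for t, l in zip(traces, labels) if l != positive]
    accepted = []
    for length in range(1, max_len + 1):
        for pattern in product(alphabet, repeat=length):
            sp = sum(is_subsequence(pattern, t) for t in pos) / len(pos)
            sn = sum(is_subsequence(pattern, t) for t in neg) / len(neg)
            if sp >= min_pos and sn <= max_neg:
                accepted.append((pattern, sp, sn))
    accepted.sort(key=lambda x: (-x[1], len(x[0]), x[0]))
    return accepted
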