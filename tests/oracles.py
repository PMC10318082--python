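"""Independent brute-force oracles used to validate the implementations.

Each oracle is written directly from the mathematical definition and
shares no code with the package (plain-Python loops, itertools
enumeration); the tests assert agreement on small instances.
"""

from __future__ import annotations

import itertools
import math


def brute_force_lof(values: list[float], k: int) -> list[float]:
    """LOF from the definition: k-distance over the k nearest neighbors
    (ties by index), reachability distance, local reachability density,
    LOF = mean neighbor-LRD / own LRD with inf/inf = 1, finite/inf = 0."""
    n = len(values)
    neighbors: list[list[int]] = []
    for i in range(n):
        others = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (abs(values[i] - values[j]), j),
        )
        neighbors.append(others[:k])

    def kdist(i: int) -> float:
        return abs(values[i] - values[neighbors[i][-1]])

    def lrd(i: int) -> float:
        total = 0.0
        for j in neighbors[i]:
            total += max(kdist(j), abs(values[i] - values[j]))
        mean = total / k
        return math.inf if mean == 0 else 1.0 / mean

    scores = []
    for i in range(n):
        own = lrd(i)
        acc = 0.0
        for j in neighbors[i]:
            other = lrd(j)
            if math.isinf(other) and math.isinf(own):
                acc += 1.0
            elif math.isinf(own):
                acc += 0.0
            elif math.isinf(other):
                acc = math.inf
                break
            else:
                acc += other / own
        scores.append(acc if math.isinf(acc) else acc / k)
    return scores


def brute_force_kmeans_1d(values: list[float], k: int) -> tuple[float, list[int]]:
    """Best contiguous partition of the sorted values into k segments by
    exhaustive enumeration of split points; returns (SSE, labels in the
    original order)."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    xs = [values[i] for i in order]

    def seg_sse(lo: int, hi: int) -> float:  # xs[lo:hi]
        seg = xs[lo:hi]
        m = sum(seg) / len(seg)
        return sum((v - m) ** 2 for v in seg)

    best_sse = math.inf
    best_cuts: tuple[int, ...] = ()
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        sse = sum(seg_sse(bounds[i], bounds[i + 1]) for i in range(k))
        if sse < best_sse - 1e-12:
            best_sse, best_cuts = sse, cuts
    bounds = (0,) + best_cuts + (n,)
    labels = [0] * n
    for c in range(k):
        for pos in range(bounds[c], bounds[c + 1]):
            labels[order[pos]] = c
    return best_sse, labels


def brute_force_threshold(
    values: list[float], truth_bits: list[int]
) -> tuple[float, float]:
    """Exhaustive threshold scan over a dense candidate set (every value
    +/- epsilon); returns (lowest best threshold's accuracy-equivalent
    candidate, best accuracy)."""
    candidates = sorted({v for v in values})
    probes = [candidates[0] - 1.0]
    for a, b in zip(candidates, candidates[1:]):
        probes.append((a + b) / 2.0)
    probes.append(candidates[-1] + 1.0)
    best_t, best_acc = probes[0], -1.0
    for t in probes:
        acc = sum((1 if v > t else 0) == b for v, b in zip(values, truth_bits))
        acc /= len(values)
        if acc > best_acc:
            best_t, best_acc = t, acc
    return best_t, best_acc


def popcount_text(text: str) -> int:
    """Total ones in the 8-bit expansions of a payload's characters."""
    return sum(bin(ord(c)).count("1") for c in text)
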