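"""Independent brute-force oracles for the pipeline's operations.

Everything here is deliberately naive — per-element Python loops, atan2
identities, explicit window recomputation — and shares no code with the
implementation, so agreement is evidence, not tautology.
"""

import math


def naive_displacements(xs, ys):
    return [
        math.dist((xs[i], ys[i]), (xs[i + 1], ys[i + 1]))
        for i in range(len(xs) - 1)
    ]


def naive_yaw(orientations_deg):
    """Signed heading change via atan2 of unit-vector products."""
    out = []
    for i in range(len(orientations_deg) - 1):
        a = math.radians(orientations_deg[i])
        b = math.radians(orientations_deg[i + 1])
        # angle of rotation from a to b
        d = math.degrees(math.atan2(math.sin(b - a), math.cos(b - a)))
        if d >= 180.0:  # atan2 returns (-180, 180]; convention is [-180, 180)
            d -= 360.0
        out.append(d)
    return out


def naive_sliding_mean(values, window):
    """Centred window mean; None where no full window fits."""
    h = (window - 1) // 2
    out = []
    for i in range(len(values)):
        lo, hi = i - h, i + h
        if lo < 0 or hi >= len(values):
            out.append(None)
        else:
            out.append(sum(values[lo : hi + 1]) / window)
    return out


def naive_freezing_count(displacements, epsilon):
    return sum(1 for d in displacements if d <= epsilon)


def naive_aim_score(speeds, window, threshold, epsilon=1e-9, signed=False):
    """Frame-by-frame AIM evaluation; returns (score, qualifying indices)."""
    vs = naive_sliding_mean(speeds, window)
    score = 0
    hits = []
    for i, (v, m) in enumerate(zip(speeds, vs)):
        if m is None or v <= epsilon or m <= epsilon:
            continue
        ratio = math.log10(v / m)
        if (ratio > threshold) if signed else (abs(ratio) > threshold):
            score += 1
            hits.append(i)
    return score, hits


def naive_peak_deviation(speeds, window, epsilon=1e-9):
    vs = naive_sliding_mean(speeds, window)
    best = None
    for v, m in zip(speeds, vs):
        if m is None or m <= epsilon:
            continue
        dev = (v - m) / m * 100.0
        if best is None or dev > best:
            best = dev
    return best
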