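"""Independent reference evaluator for the in-wake fuzzy system.

Written from first principles as plain Python piecewise expressions and
explicit loops — no numpy, no imports from the package's fuzzy engine —
so it can serve as an oracle for the vectorised implementation.  The
membership shapes are spelled out with their numeric breakpoints rather
than derived from shared configuration.
"""

from __future__ import annotations


def aligned(ew: float) -> float:
    a = abs(ew)
    if a <= 0.8:
        return 0.0
    if a <= 1.3:
        return (a - 0.8) / 0.5
    if a <= 1.8:
        return (1.8 - a) / 0.5
    return 0.0


def misaligned(ew: float) -> float:
    return 1.0 - aligned(ew)


def close(ns: float) -> float:
    if ns >= 0.0:
        return 0.0
    if ns >= -0.1:
        return -ns / 0.1
    if ns >= -5.0:
        return (ns + 5.0) / 4.9
    return 0.0


def too_close(ns: float) -> float:
    if ns >= 0.0 or ns <= -0.1:
        return 0.0
    if ns >= -0.05:
        return -ns / 0.05
    return (ns + 0.1) / 0.05


def distant(ns: float) -> float:
    if ns >= -0.1:
        return 0.0
    if ns <= -5.0:
        return 1.0
    return (-0.1 - ns) / 4.9


def same_plane(ud: float) -> float:
    a = abs(ud)
    if a >= 0.75:
        return 0.0
    return 1.0 - a / 0.75


def different_plane(ud: float) -> float:
    return 1.0 - same_plane(ud)


def rule_strengths(ew: float, ns: float, ud: float) -> list[float]:
    return [
        min(aligned(ew), close(ns), same_plane(ud)),
        misaligned(ew),
        too_close(ns),
        distant(ns),
        different_plane(ud),
    ]


def inwake_output(ew: float, ns: float, ud: float) -> float:
    """0-order Takagi–Sugeno output with consequents (1, 0, 0, 0, 0)."""
    strengths = rule_strengths(ew, ns, ud)
    consequents = [1.0, 0.0, 0.0, 0.0, 0.0]
    total = 0.0
    weighted = 0.0
    for s, c in zip(strengths, consequents):
        total += s
        weighted += s * c
    if total == 0.0:
        return 0.0
    return weighted / total
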