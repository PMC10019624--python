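"""Shared small statistics helpers (significance-star labelling)."""

from __future__ import annotations

# thresholds inclusive on the starred side
_STAR_STEPS = [
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
]


def star_label(p: float) -> str:
    """Map a p-value to its significance label (ns above 0.05)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    for threshold, label in _STAR_STEPS:
        if p <= threshold:
            return label
    return "ns"
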