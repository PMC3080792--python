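"""Small report-rendering helpers shared by the CLI and scripts.

Numbers are kept at full precision internally; rounding happens only here,
in the human-readable views.
"""

from __future__ import annotations


def classification_rate(classified: int, matched: int) -> float:
    """Percentage of matched proteins that fell into at least one category."""
    if matched <= 0:
        raise ValueError("matched count must be positive")
    if not 0 <= classified <= matched:
        raise ValueError("classified count must be within [0, matched]")
    return 100.0 * classified / matched


def round1(value: float) -> float:
    """One-decimal rounding used in rendered summaries."""
    return round(value, 1)


def format_percent(classified: int, matched: int) -> str:
    return f"{round1(classification_rate(classified, matched))}%"
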