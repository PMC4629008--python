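"""Minimal Praat TextGrid export for detected nuclei.

Writes the long ("ooTextFile") text format with a single interval tier so
detections can be inspected over the waveform in Praat.
"""
from __future__ import annotations

from typing import Sequence

from .syllables import SyllableNucleus

__all__ = ["write_textgrid"]


def write_textgrid(
    nuclei: Sequence[SyllableNucleus],
    total_duration: float,
    path,
    tier_name: str = "nucleus",
    label: str = "nuc",
) -> None:
    """Write nuclei as labeled intervals on one tier spanning [0, duration]."""
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    bounds = []  # (start, end, text)
    t = 0.0
    for nuc in nuclei:
        onset = max(0.0, min(nuc.onset, total_duration))
        offset = max(onset, min(nuc.offset, total_duration))
        if onset > t:
            bounds.append((t, onset, ""))
        if offset > onset:
            bounds.append((onset, offset, label))
        t = max(t, offset)
    if t < total_duration:
        bounds.append((t, total_duration, ""))
    if not bounds:
        bounds.append((0.0, total_duration, ""))
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {total_duration:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {total_duration:.6f}",
        f"        intervals: size = {len(bounds)}",
    ]
    for i, (a, b, text) in enumerate(bounds, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {a:.6f}",
            f"            xmax = {b:.6f}",
            f'            text = "{text}"',
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
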