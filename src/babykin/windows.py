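"""Sliding-window plan shared by feature building and evaluation."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["WindowPlan", "slide_windows"]


@dataclass(frozen=True)
class WindowPlan:
    """Fixed-width overlapped windows: step = width − overlap."""

    width: int = 500
    overlap: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.width):
            raise ValueError(f"need 0 <= overlap < width, got {self}")

    @property
    def step(self) -> int:
        return self.width - self.overlap


def slide_windows(segment_length: int, plan: WindowPlan = WindowPlan()) -> list[tuple[int, int]]:
    """All (start, end) windows fully inside a segment of the given length.

    Count is floor((L − width) / step) + 1 for L ≥ width, else 0.
    """
    if segment_length < plan.width:
        return []
    n = (segment_length - plan.width) // plan.step + 1
    return [(i * plan.step, i * plan.step + plan.width) for i in range(n)]
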