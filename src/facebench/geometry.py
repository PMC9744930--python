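"""Axis-aligned rectangles for feature layouts and occlusion boxes.

Convention used throughout the package: 0-based pixel coordinates, x to the
right, y downwards; rectangles are half-open integer boxes
``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Rect:
    """Half-open integer rectangle ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "Rect":
        """Build a rectangle of size ``w x h`` centered on ``(cx, cy)``.

        The top-left corner and the side lengths are rounded to the nearest
        integer pixel independently, so the nominal area ``round(w)*round(h)``
        is preserved regardless of the (possibly fractional) center.
        """
        wi, hi = int(round(w)), int(round(h))
        x0 = int(round(cx - w / 2.0))
        y0 = int(round(cy - h / 2.0))
        return cls(x0, y0, x0 + wi, y0 + hi)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return max(0, self.width) * max(0, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def clip(self, canvas_size: tuple[int, int]) -> "Rect":
        """Intersect with a ``(width, height)`` canvas."""
        w, h = canvas_size
        return Rect(
            min(max(self.x0, 0), w),
            min(max(self.y0, 0), h),
            min(max(self.x1, 0), w),
            min(max(self.y1, 0), h),
        )

    def scale(self, fx: float, fy: float) -> "Rect":
        """Rescale by independent per-axis factors, re-rounding to pixels."""
        cx, cy = self.center
        return Rect.from_center(cx * fx, cy * fy, self.width * fx, self.height * fy)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    @property
    def slices(self) -> tuple[slice, slice]:
        """``(row_slice, col_slice)`` for indexing an (H, W, ...) array."""
        return slice(max(self.y0, 0), max(self.y1, 0)), slice(max(self.x0, 0), max(self.x1, 0))


def scale_layout(layout: dict[str, Rect], fx: float, fy: float) -> dict[str, Rect]:
    """Scale every rectangle of a feature layout by per-axis factors."""
    return {name: r.scale(fx, fy) for name, r in layout.items()}
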