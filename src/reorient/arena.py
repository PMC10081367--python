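"""Rectangular arena geometry and the C/G/N/F corner scheme.

The task arena is a rectangle whose width and height differ, so it has
exactly two-fold rotational symmetry.  Each context anchors the four dig
corners to labels:

* ``C`` -- the rewarded corner,
* ``G`` -- its geometric equivalent (the corner related to C by the 180
  degree rotation about the arena center),
* ``N`` -- the corner on the same short wall as C,
* ``F`` -- the corner on the same long wall as C.

Coordinates: origin at the arena's lower-left corner, x rightward,
y upward, all in cm.  Row 0 of any grid built on this arena is the
bottom row; bins are half-open ``[k, k+1)`` cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CORNER_LABELS = ("C", "G", "N", "F")


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular arena with per-context reward-corner anchoring.

    Parameters
    ----------
    width_cm, height_cm
        Side lengths; they must differ (a square would have four-fold
        symmetry and no unique geometric-equivalent corner).
    reward_corners
        Map from context label to the (x, y) position of the rewarded
        corner in that context.  Defaults place the context-A reward at
        the lower-left corner and the context-B reward at the lower-right
        corner, so the geometrically correct diagonal differs between
        contexts.
    """

    width_cm: float = 30.0
    height_cm: float = 20.0
    reward_corners: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("arena sides must be positive")
        if self.width_cm == self.height_cm:
            raise ValueError(
                "arena must be a proper rectangle (width_cm != height_cm)"
            )
        if not self.reward_corners:
            object.__setattr__(
                self,
                "reward_corners",
                {"A": (0.0, 0.0), "B": (self.width_cm, 0.0)},
            )
        corners = self.corners()
        for ctx, pos in self.reward_corners.items():
            if tuple(pos) not in corners:
                raise ValueError(
                    f"reward corner {pos!r} for context {ctx!r} is not an "
                    f"arena corner"
                )

    def corners(self) -> list[tuple[float, float]]:
        w, h = self.width_cm, self.height_cm
        return [(0.0, 0.0), (w, 0.0), (w, h), (0.0, h)]

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_cm / 2.0, self.height_cm / 2.0)

    def rotate180(self, xy: tuple[float, float]) -> tuple[float, float]:
        """Image of a point under the arena's symmetry rotation."""
        return (self.width_cm - xy[0], self.height_cm - xy[1])

    def corner_labels(self, context: str) -> dict[str, tuple[float, float]]:
        """Label -> corner position for one context.

        The mapping is a bijection between {C, G, N, F} and the four
        corners, anchored at that context's rewarded corner.
        """
        if context not in self.reward_corners:
            raise KeyError(f"unknown context {context!r}")
        cx, cy = self.reward_corners[context]
        w, h = self.width_cm, self.height_cm
        return {
            "C": (cx, cy),
            "G": (w - cx, h - cy),
            "N": (cx, h - cy),  # same short wall (shares x side)
            "F": (w - cx, cy),  # same long wall (shares y side)
        }

    def contains(self, x, y) -> bool:
        import numpy as np

        return bool(
            np.all((x >= 0) & (x <= self.width_cm))
            and np.all((y >= 0) & (y <= self.height_cm))
        )
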