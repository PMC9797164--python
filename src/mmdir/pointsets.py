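"""Paired landmark sets and the plain-text point-file format.

Point files carry one image side each; pairing is positional::

    point
    3
    12.5 30.0 -4.25
    ...
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PairedPointSet", "GROUPS", "read_points", "write_points"]

GROUPS = ("soft_tissue", "rigid", "boundary", "unassigned")


@dataclass(frozen=True)
class PairedPointSet:
    """Corresponding landmarks in fixed/moving world coordinates (mm).

    ``fixed_points[i]`` pairs with ``moving_points[i]``; ``groups[i]`` is one
    of :data:`GROUPS`.
    """

    fixed_points: np.ndarray
    moving_points: np.ndarray
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        f = np.atleast_2d(np.asarray(self.fixed_points, dtype=np.float64))
        m = np.atleast_2d(np.asarray(self.moving_points, dtype=np.float64))
        if f.shape != m.shape or f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(
                f"point arrays must both be (P, 3), got {f.shape} and {m.shape}"
            )
        if f.shape[0] < 1:
            raise ValueError("point set must contain at least one pair")
        g = tuple(self.groups) if self.groups else ("unassigned",) * f.shape[0]
        if len(g) != f.shape[0]:
            raise ValueError("one group label per pair required")
        bad = [x for x in g if x not in GROUPS]
        if bad:
            raise ValueError(f"unknown group labels: {sorted(set(bad))}")
        object.__setattr__(self, "fixed_points", f)
        object.__setattr__(self, "moving_points", m)
        object.__setattr__(self, "groups", g)

    def __len__(self) -> int:
        return self.fixed_points.shape[0]

    def subset(self, group: str) -> "PairedPointSet":
        idx = [i for i, g in enumerate(self.groups) if g == group]
        if not idx:
            raise ValueError(f"no pairs in group {group!r}")
        return PairedPointSet(
            self.fixed_points[idx],
            self.moving_points[idx],
            tuple(self.groups[i] for i in idx),
        )

    def group_indices(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self.groups):
            out.setdefault(g, []).append(i)
        return out

    @classmethod
    def from_files(
        cls, fixed_path: str | Path, moving_path: str | Path, groups=()
    ) -> "PairedPointSet":
        return cls(read_points(fixed_path), read_points(moving_path), tuple(groups))


def read_points(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or lines[0] != "point":
        raise ValueError(f"{path}: expected 'point' header")
    n = int(lines[1])
    pts = np.array([[float(v) for v in ln.split()] for ln in lines[2 : 2 + n]])
    if pts.shape != (n, 3):
        raise ValueError(f"{path}: expected {n} 'x y z' lines, got {pts.shape}")
    return pts


def write_points(path: str | Path, pts: np.ndarray) -> None:
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    lines = ["point", str(pts.shape[0])]
    lines += [f"{float(x)!r} {float(y)!r} {float(z)!r}" for x, y, z in pts]
    Path(path).write_text("\n".join(lines) + "\n")
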