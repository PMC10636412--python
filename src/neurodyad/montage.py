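"""Schematic 128-channel montage: labels, frontal clusters, neighbor adjacency.

The montage places channels on a rectangular ``rows x cols`` grid (rows run
front to back, columns left to right).  Two 7-channel clusters flank the
left/right frontal sites used for the asymmetry index, and adjacency is the
4-neighborhood on the grid (used for bad-channel interpolation).

A serialized copy ships as package data (``data/montage128.yaml``) so runs
can point at an edited montage without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

CLUSTER_SIZE = 7


@dataclass(frozen=True)
class Montage:
    """Channel layout: ordered labels, left/right clusters, adjacency."""

    name: str
    labels: tuple[str, ...]
    left_cluster: tuple[str, ...]
    right_cluster: tuple[str, ...]
    adjacency: dict[str, tuple[str, ...]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        for side, cluster in (("left", self.left_cluster), ("right", self.right_cluster)):
            if len(cluster) != CLUSTER_SIZE:
                raise ValueError(
                    f"{side} cluster must have exactly {CLUSTER_SIZE} labels, got {len(cluster)}"
                )
            missing = set(cluster) - set(self.labels)
            if missing:
                raise ValueError(f"{side} cluster labels not in montage: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def neighbors(self, label: str) -> tuple[str, ...]:
        return self.adjacency.get(label, ())

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "labels": list(self.labels),
            "clusters": {"left": list(self.left_cluster), "right": list(self.right_cluster)},
            "adjacency": {k: list(v) for k, v in self.adjacency.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            name=d.get("name", "unnamed"),
            labels=tuple(d["labels"]),
            left_cluster=tuple(d["clusters"]["left"]),
            right_cluster=tuple(d["clusters"]["right"]),
            adjacency={k: tuple(v) for k, v in d.get("adjacency", {}).items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "Montage":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_grid_montage(rows: int = 8, cols: int = 16, name: str = "synthetic-128") -> Montage:
    """Build the schematic grid montage used by the synthetic sessions.

    Channels are labeled ``E1..E{rows*cols}`` in row-major order.  The left
    frontal cluster is a plus-shaped patch of 7 channels centered at grid
    position (2, 4); the right cluster mirrors it across the midline.
    """
    if rows < 4 or cols < 12:
        raise ValueError("grid too small for the frontal clusters")
    labels = tuple(f"E{r * cols + c + 1}" for r in range(rows) for c in range(cols))

    def lab(r: int, c: int) -> str:
        return f"E{r * cols + c + 1}"

    lc, rc = 4, cols - 1 - 4  # mirrored cluster-center columns
    offsets = [(0, 0), (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0)]
    left = tuple(lab(2 + dr, lc + dc) for dr, dc in offsets)
    right = tuple(lab(2 + dr, rc - dc) for dr, dc in offsets)

    adjacency: dict[str, tuple[str, ...]] = {}
    for r in range(rows):
        for c in range(cols):
            nbrs = [
                lab(r + dr, c + dc)
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                if 0 <= r + dr < rows and 0 <= c + dc < cols
            ]
            adjacency[lab(r, c)] = tuple(nbrs)
    return Montage(name=name, labels=labels, left_cluster=left, right_cluster=right, adjacency=adjacency)


def default_montage() -> Montage:
    """Load the packaged 128-channel montage."""
    ref = resources.files("neurodyad").joinpath("data/montage128.yaml")
    with ref.open() as fh:
        return Montage.from_dict(yaml.safe_load(fh))
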