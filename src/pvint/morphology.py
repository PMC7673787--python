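"""Sholl profiles and polar-histogram morphometry of SWC reconstructions.

Conventions
-----------
* Coordinates are in micrometres.  The y axis points along the radial
  (stratum oriens -> stratum lacunosum-moleculare) direction, the x axis
  along the transverse (CA3 -> subiculum) direction, so "horizontal" means
  transverse growth and "vertical" means radial growth.
* 3-D reconstructions are projected onto the x-y plane before any angular
  analysis; Sholl distances use full 3-D length.
* The soma centre is the centroid of all soma-typed nodes.

Angle bands: horizontal = 150-210 deg plus 330-30 deg; vertical = 60-120 deg
plus 240-300 deg.  Each band covers 120 of 360 degrees, so isotropic growth
yields about one third horizontal and one third vertical.  Band membership
is decided by the exact segment angle (boundaries inclusive), not by which
10-degree histogram bin the segment falls in, which avoids quantisation
bias at band edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NEURITE_CLASSES = ("axon", "dendrite")


@dataclass
class SWCNode:
    id: int
    type: str  # soma | axon | dendrite
    x: float
    y: float
    z: float
    radius: float
    parent: int  # -1 for root


@dataclass
class NeuriteTree:
    """A single rooted neuronal reconstruction."""

    nodes: dict  # id -> SWCNode
    root_id: int

    def soma_center(self) -> np.ndarray:
        soma = [n for n in self.nodes.values() if n.type == "soma"]
        if not soma:
            soma = [self.nodes[self.root_id]]
        pts = np.array([[n.x, n.y, n.z] for n in soma])
        return pts.mean(axis=0)

    def segments(self, neurite_class: str | None = None) -> np.ndarray:
        """(n, 2, 3) array of parent->child segments.

        A segment belongs to the class of its *child* node; segments whose
        child is a soma node are never returned.
        """
        segs = []
        for n in self.nodes.values():
            if n.parent == -1 or n.type == "soma":
                continue
            if neurite_class is not None and n.type != neurite_class:
                continue
            p = self.nodes[n.parent]
            segs.append([[p.x, p.y, p.z], [n.x, n.y, n.z]])
        if not segs:
            return np.zeros((0, 2, 3))
        return np.array(segs)

    def total_length(self, neurite_class: str | None = None) -> float:
        segs = self.segments(neurite_class)
        if len(segs) == 0:
            return 0.0
        return float(np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1).sum())

    def rotated(self, angle_deg: float) -> "NeuriteTree":
        """Copy of the tree rigidly rotated about the soma centre (x-y plane)."""
        c = self.soma_center()
        th = np.deg2rad(angle_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        nodes = {}
        for nid, n in self.nodes.items():
            xy = R @ (np.array([n.x, n.y]) - c[:2]) + c[:2]
            nodes[nid] = SWCNode(n.id, n.type, float(xy[0]), float(xy[1]), n.z,
                                 n.radius, n.parent)
        return NeuriteTree(nodes=nodes, root_id=self.root_id)


@dataclass
class ShollProfile:
    radii: np.ndarray          # ring radii, um
    counts: np.ndarray         # intersections per ring
    neurite_class: str

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PolarHistogram:
    bin_edges_deg: np.ndarray   # 37 edges, 0..360
    length_per_bin: np.ndarray  # um
    percent_horizontal: float
    percent_vertical: float

    @property
    def total_length(self) -> float:
        return float(self.length_per_bin.sum())


def sholl(tree: NeuriteTree, neurite_class: str = "axon",
          radius_step: float = 10.0) -> ShollProfile:
    """Count crossings of concentric rings centred on the soma.

    A segment crosses ring radius ``r`` when its endpoint distances satisfy
    ``d_min < r <= d_max`` — an endpoint lying exactly on a ring is counted
    with the inner segment only, so chained collinear segments are never
    double-counted; a segment tangent to a ring (both endpoints outside,
    closest approach inside) is ignored, as the profile is built from
    endpoint distances.
    """
    if radius_step <= 0:
        raise ValueError("radius_step must be > 0")
    segs = tree.segments(neurite_class)
    if len(segs) == 0:
        return ShollProfile(radii=np.zeros(0), counts=np.zeros(0, dtype=int),
                            neurite_class=neurite_class)
    c = tree.soma_center()
    d1 = np.linalg.norm(segs[:, 0] - c, axis=1)
    d2 = np.linalg.norm(segs[:, 1] - c, axis=1)
    dmin, dmax = np.minimum(d1, d2), np.maximum(d1, d2)
    n_rings = int(np.ceil(dmax.max() / radius_step - 1e-9))
    radii = radius_step * np.arange(1, n_rings + 1)
    counts = ((dmin[:, None] < radii[None, :] - 1e-9)
              & (radii[None, :] <= dmax[:, None] + 1e-9)).sum(axis=0)
    return ShollProfile(radii=radii, counts=counts.astype(int),
                        neurite_class=neurite_class)


_H_BANDS = [(150.0, 210.0), (330.0, 360.0), (0.0, 30.0)]
_V_BANDS = [(60.0, 120.0), (240.0, 300.0)]


def _band_length(angles: np.ndarray, lengths: np.ndarray, bands) -> float:
    m = np.zeros(len(angles), dtype=bool)
    for lo, hi in bands:
        m |= (angles >= lo - 1e-9) & (angles <= hi + 1e-9)
    return float(lengths[m].sum())


def polar_histogram(tree: NeuriteTree, neurite_class: str = "axon") -> PolarHistogram:
    """10-degree-bin histogram of projected neurite length by direction.

    Each segment contributes its x-y projected length to the bin of its
    direction angle (atan2 of child minus parent).  Horizontal / vertical
    percentages are fractions of total projected length falling in the
    respective exact angle bands.
    """
    segs = tree.segments(neurite_class)
    if len(segs) == 0:
        raise ValueError(f"tree has no {neurite_class} segments")
    d = segs[:, 1, :2] - segs[:, 0, :2]
    lengths = np.linalg.norm(d, axis=1)
    keep = lengths > 0
    if not keep.any():
        raise ValueError("tree has zero projected length")
    d, lengths = d[keep], lengths[keep]
    angles = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0
    edges = np.arange(0.0, 360.0 + 1e-9, 10.0)
    hist, _ = np.histogram(angles, bins=edges, weights=lengths)
    total = lengths.sum()
    ph = 100.0 * _band_length(angles, lengths, _H_BANDS) / total
    pv = 100.0 * _band_length(angles, lengths, _V_BANDS) / total
    return PolarHistogram(bin_edges_deg=edges, length_per_bin=hist,
                          percent_horizontal=ph, percent_vertical=pv)


def polarity_summary(cohorts: dict, neurite_class: str = "axon") -> pd.DataFrame:
    """Mean +/- SEM horizontal and vertical axon percentages per group.

    ``cohorts`` maps a group label (typically genotype) to a list of trees.
    """
    rows = []
    for group, trees in cohorts.items():
        if len(trees) == 0:
            raise ValueError(f"empty cohort for group {group!r}")
        hs, vs = [], []
        for t in trees:
            p = polar_histogram(t, neurite_class)
            hs.append(p.percent_horizontal)
            vs.append(p.percent_vertical)
        hs, vs = np.array(hs), np.array(vs)
        sem = lambda x: float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
        rows.append({
            "group": group, "n": len(trees),
            "horizontal_mean": float(hs.mean()), "horizontal_sem": sem(hs),
            "vertical_mean": float(vs.mean()), "vertical_sem": sem(vs),
        })
    return pd.DataFrame(rows).set_index("group")
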