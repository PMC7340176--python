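"""Arterial tree data model: a 55-segment human arterial network.

The systemic arterial system is represented as a binary tree of straight
elastic vessel segments.  Each segment carries the geometric and material
parameters that determine wave propagation (length, inner radius, wall
thickness, elastic modulus); each terminal segment is closed by a resistive
peripheral load.  The default tree ships with the package as a versioned CSV
and covers the aortic trunk, coronary, carotid/vertebral, upper-limb,
visceral and lower-limb branches, with named measurement sites at the left
brachial artery, the left posterior tibial (ankle) artery and the infrarenal
abdominal aorta (the stenosis site).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "SegmentGeometry",
    "PatientScale",
    "ArterialTree",
    "load_default_tree",
    "validate_tree",
    "scale_tree",
    "apply_stenosis",
    "check_severity",
]

#: conventional blood properties (CGS units)
BLOOD_DENSITY = 1.05  # g/cm^3
BLOOD_VISCOSITY = 0.04  # poise

_TREE_RESOURCE = "arterial_tree_55.csv"


@dataclass(frozen=True)
class SegmentGeometry:
    """Geometry and elasticity of one arterial segment (CGS units).

    Attributes
    ----------
    length : float
        Segment length l in cm.
    radius : float
        Inner radius r in cm.
    thickness : float
        Wall thickness h in cm (thin-wall regime, h < r).
    elastic_modulus : float
        Young's modulus E of the wall in dyn/cm^2.
    """

    length: float
    radius: float
    thickness: float
    elastic_modulus: float

    def violations(self) -> list[str]:
        out = []
        for name in ("length", "radius", "thickness", "elastic_modulus"):
            if not getattr(self, name) > 0:
                out.append(f"non-positive {name}")
        if self.thickness >= self.radius:
            out.append("thickness >= radius (outside thin-wall regime)")
        return out


@dataclass(frozen=True)
class PatientScale:
    """Multiplicative scale factors for the five varied parameters.

    Each factor multiplies the corresponding nominal quantity tree-wide:
    segment length, diameter (equivalently radius), wall thickness, elastic
    modulus, and terminal (peripheral load) resistance.
    """

    length: float = 1.0
    diameter: float = 1.0
    thickness: float = 1.0
    elasticity: float = 1.0
    peripheral_resistance: float = 1.0

    #: fixed parameter order used everywhere (lexicographic)
    PARAMS = ("diameter", "elasticity", "length", "peripheral_resistance", "thickness")

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in self.PARAMS}

    def validate(self) -> None:
        for p in self.PARAMS:
            v = getattr(self, p)
            if not v > 0:
                raise ValueError(f"scale factor {p!r} must be strictly positive, got {v}")


@dataclass
class ArterialTree:
    """Binary tree of arterial segments with resistive terminal loads."""

    segments: dict[int, SegmentGeometry]
    parent: dict[int, int | None]
    names: dict[int, str] = field(default_factory=dict)
    terminal_load: dict[int, float] = field(default_factory=dict)
    density: float = BLOOD_DENSITY
    viscosity: float = BLOOD_VISCOSITY
    site_map: dict[str, tuple[int, str]] = field(default_factory=dict)

    def children(self, seg_id: int) -> list[int]:
        return sorted(s for s, p in self.parent.items() if p == seg_id)

    @property
    def root(self) -> int:
        roots = [s for s, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree has {len(roots)} roots, expected exactly 1")
        return roots[0]

    def leaves(self) -> list[int]:
        has_child = set(p for p in self.parent.values() if p is not None)
        return sorted(s for s in self.segments if s not in has_child)

    def postorder(self) -> Iterator[int]:
        """Segments ordered children-before-parent (leaf-to-root sweep)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children(node))
        return iter(reversed(order))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children(node)))

    def resolve_site(self, site: str) -> tuple[int, str]:
        try:
            return self.site_map[site]
        except KeyError:
            raise KeyError(
                f"unknown site {site!r}; known sites: {sorted(self.site_map)}"
            ) from None

    def copy(self) -> "ArterialTree":
        return copy.deepcopy(self)


def check_severity(s: float) -> float:
    """Validate a PAD severity (fractional area occlusion), 0 <= s < 1."""
    if not (0.0 <= s < 1.0):
        raise ValueError(
            f"severity must satisfy 0 <= s < 1 (1 means complete occlusion), got {s}"
        )
    return float(s)


def _tree_from_frame(df: pd.DataFrame) -> ArterialTree:
    segments: dict[int, SegmentGeometry] = {}
    parent: dict[int, int | None] = {}
    names: dict[int, str] = {}
    terminal_load: dict[int, float] = {}
    for row in df.itertuples(index=False):
        sid = int(row.id)
        segments[sid] = SegmentGeometry(
            length=float(row.length_cm),
            radius=float(row.radius_cm),
            thickness=float(row.thickness_cm),
            elastic_modulus=float(row.E_dyn_cm2),
        )
        parent[sid] = None if pd.isna(row.parent_id) else int(row.parent_id)
        names[sid] = str(row.name)
        if not pd.isna(row.terminal_R):
            terminal_load[sid] = float(row.terminal_R)
    return ArterialTree(segments=segments, parent=parent, names=names, terminal_load=terminal_load)


def load_tree_csv(path) -> ArterialTree:
    """Load an arterial tree from a CSV table (see the default tree's schema)."""
    return _tree_from_frame(pd.read_csv(path))


def save_tree_csv(tree: ArterialTree, path) -> None:
    rows = []
    for sid in sorted(tree.segments):
        g = tree.segments[sid]
        rows.append(
            dict(
                id=sid,
                name=tree.names.get(sid, f"segment_{sid}"),
                parent_id=tree.parent[sid],
                length_cm=g.length,
                radius_cm=g.radius,
                thickness_cm=g.thickness,
                E_dyn_cm2=g.elastic_modulus,
                terminal_R=tree.terminal_load.get(sid),
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


#: named measurement sites of the default tree: (segment name, end)
DEFAULT_SITES = {
    "brachial": ("l_brachial", "outlet"),
    "ankle": ("l_posterior_tibial", "outlet"),
    "abdominal_aorta": ("abdominal_aorta_d", "inlet"),
}


def load_default_tree() -> ArterialTree:
    """Return the nominal 55-segment arterial tree shipped with the package.

    The measurement sites are the left brachial artery outlet (arm cuff
    level), the left posterior tibial artery outlet (ankle cuff level) and
    the infrarenal abdominal aorta (the modelled stenosis site).  Every call
    returns an independent copy.
    """
    with resources.files("padpulse.data").joinpath(_TREE_RESOURCE).open() as fh:
        tree = _tree_from_frame(pd.read_csv(fh))
    by_name = {n: s for s, n in tree.names.items()}
    tree.site_map = {
        site: (by_name[seg_name], end) for site, (seg_name, end) in DEFAULT_SITES.items()
    }
    return tree


def validate_tree(tree: ArterialTree) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the tree is valid.  Violations are returned rather
    than raised so callers can report all problems at once.
    """
    out: list[str] = []
    roots = [s for s, p in tree.parent.items() if p is None]
    if len(roots) != 1:
        out.append(f"tree must have exactly one root, found {len(roots)}")
    if set(tree.parent) != set(tree.segments):
        out.append("parent map and segment map cover different segment ids")

    # acyclicity: walk up from every node with a visited set
    for sid in tree.segments:
        seen = set()
        node: int | None = sid
        while node is not None:
            if node in seen:
                out.append(f"acyclicity violated on the path from segment {sid}")
                break
            seen.add(node)
            node = tree.parent.get(node)
        else:
            continue
        break

    for sid, geom in tree.segments.items():
        for v in geom.violations():
            out.append(f"segment {sid} ({tree.names.get(sid, '?')}): {v}")

    for sid in tree.segments:
        nkids = len(tree.children(sid))
        if nkids > 2:
            out.append(f"segment {sid} has {nkids} children (max 2)")
    for leaf in tree.leaves():
        if leaf not in tree.terminal_load:
            out.append(f"leaf segment {leaf} ({tree.names.get(leaf, '?')}) lacks a terminal load")
    for sid, r in tree.terminal_load.items():
        if sid not in tree.segments:
            out.append(f"terminal load on unknown segment {sid}")
        elif tree.children(sid):
            out.append(f"terminal load on non-leaf segment {sid}")
        if not r > 0:
            out.append(f"terminal load on segment {sid} must be positive, got {r}")
    for site, (sid, end) in tree.site_map.items():
        if sid not in tree.segments:
            out.append(f"site {site!r} refers to unknown segment {sid}")
        if end not in ("inlet", "outlet"):
            out.append(f"site {site!r} has invalid end {end!r}")
    return out


def scale_tree(tree: ArterialTree, scale: PatientScale | Mapping[str, float]) -> ArterialTree:
    """Apply patient-specific multiplicative scaling; the input is unmodified.

    length scales l; diameter scales r; thickness scales h; elasticity
    scales E; peripheral_resistance scales every terminal load.
    """
    if not isinstance(scale, PatientScale):
        scale = PatientScale(**dict(scale))
    scale.validate()
    new = tree.copy()
    for sid, g in new.segments.items():
        new.segments[sid] = SegmentGeometry(
            length=g.length * scale.length,
            radius=g.radius * scale.diameter,
            thickness=g.thickness * scale.thickness,
            elastic_modulus=g.elastic_modulus * scale.elasticity,
        )
    for sid in new.terminal_load:
        new.terminal_load[sid] *= scale.peripheral_resistance
    return new


def apply_stenosis(tree: ArterialTree, site: str, severity: float) -> ArterialTree:
    """Occlude fraction ``severity`` of the cross-sectional area at ``site``.

    The targeted segment's radius becomes r*sqrt(1 - s) so the lumen area is
    reduced by exactly the fraction s over the whole segment length.  The
    input tree is unmodified.
    """
    s = check_severity(severity)
    sid, _end = tree.resolve_site(site)
    new = tree.copy()
    g = new.segments[sid]
    new.segments[sid] = replace(g, radius=g.radius * (1.0 - s) ** 0.5)
    return new
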