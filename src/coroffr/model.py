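"""Domain data model: patient parameters, blood, and the coronary tree.

The vascular domain is represented as a directed rooted tree of tapered
centerline segments (proximal -> distal), each carrying a linear radius
profile and optional stenosis descriptors.  Surface meshes and image data are
deliberately out of scope: the reduced-order flow solver needs only lengths
and radius profiles.  Node identifiers are opaque strings; 3D coordinates are
optional metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

BRANCH_LABELS = ("AORTA", "LAD", "LCX", "RCA", "OTHER")

#: Coronary segments narrower than this radius (mm) trigger a validation
#: warning.  Mirrors the reconstruction practice of retaining only vessels of
#: diameter >= 1 mm; kept as a warning (not an error) so that synthetic
#: stress tests can go below it.
MIN_CORONARY_RADIUS_MM = 0.5


class TreeValidationError(ValueError):
    """A tree or segment violates a structural invariant."""


class SchemaError(ValueError):
    """A serialized file does not conform to the documented schema."""


@dataclass(frozen=True)
class PatientParameters:
    """Routine clinical measurements driving the boundary conditions.

    Parameters
    ----------
    sbp, dbp : float
        Systolic / diastolic cuff pressure, mmHg.
    hr : float
        Heart rate, beats per minute.
    co : float
        Cardiac output, L/min.
    myocardial_mass : float, optional
        Left-ventricular mass in grams.  Carried as metadata only: the flow
        budget is derived from cardiac output, not from mass allometry.
    """

    sbp: float
    dbp: float
    hr: float
    co: float
    myocardial_mass: float | None = None

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError(
                f"require sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}"
            )
        if self.hr <= 0:
            raise ValueError(f"heart rate must be positive, got {self.hr}")
        if self.co <= 0:
            raise ValueError(f"cardiac output must be positive, got {self.co}")


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood constants (SI)."""

    density: float = 1050.0  # kg/m^3
    viscosity: float = 0.0035  # Pa.s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("blood density and viscosity must be positive")


@dataclass(frozen=True)
class Stenosis:
    """A focal lumen narrowing on a host segment.

    position is the fractional arc length of the lesion midpoint along the
    host segment (0 = proximal end); severity is the fractional *diameter*
    reduction (0.6 means a 60% diameter stenosis); length is the lesion
    length in mm.
    """

    position: float
    severity: float
    length: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.position <= 1.0):
            raise ValueError(f"stenosis position must lie in [0,1], got {self.position}")
        if not (0.0 <= self.severity < 1.0):
            raise ValueError(f"stenosis severity must lie in [0,1), got {self.severity}")
        if self.length <= 0:
            raise ValueError(f"stenosis length must be positive, got {self.length}")


@dataclass
class Segment:
    """A tapered centerline segment with optional stenoses.

    Geometry is in mm.  The radius varies linearly from ``radius_proximal``
    at the proximal node to ``radius_distal`` at the distal node.
    """

    id: str
    proximal_node: str
    distal_node: str
    length: float
    radius_proximal: float
    radius_distal: float
    stenoses: list[Stenosis] = field(default_factory=list)
    branch_label: str = "OTHER"

    @property
    def is_coronary(self) -> bool:
        return self.branch_label != "AORTA"

    def radius_at(self, frac: float) -> float:
        """Unstenosed lumen radius (mm) at fractional arc length ``frac``."""
        return self.radius_proximal + (self.radius_distal - self.radius_proximal) * frac

    def validate(self) -> None:
        if self.length <= 0:
            raise TreeValidationError(f"segment {self.id}: length must be positive")
        if self.radius_proximal <= 0 or self.radius_distal <= 0:
            raise TreeValidationError(f"segment {self.id}: radii must be positive")
        if self.branch_label not in BRANCH_LABELS:
            raise TreeValidationError(
                f"segment {self.id}: branch_label {self.branch_label!r} "
                f"not one of {BRANCH_LABELS}"
            )
        if self.proximal_node == self.distal_node:
            raise TreeValidationError(f"segment {self.id}: self-loop")
        for k, st in enumerate(self.stenoses):
            if st.length > self.length:
                raise TreeValidationError(
                    f"segment {self.id}: stenosis {k} longer than its host segment"
                )
        if self.is_coronary and min(self.radius_proximal, self.radius_distal) < MIN_CORONARY_RADIUS_MM:
            warnings.warn(
                f"segment {self.id}: coronary radius below "
                f"{MIN_CORONARY_RADIUS_MM} mm (sub-millimetre vessel)",
                stacklevel=2,
            )


@dataclass
class CoronaryTree:
    """Directed rooted tree of segments with an aortic stub.

    ``inlet_node`` is the aortic ostium held at the prescribed mean pressure;
    ``systemic_outlet_node`` is the distal end of the aortic stub where the
    systemic (descending-aorta) resistance attaches; every coronary outlet is
    a leaf of a coronary branch.
    """

    nodes: dict[str, tuple[float, float, float] | None]
    segments: list[Segment]
    inlet_node: str
    systemic_outlet_node: str
    coronary_outlet_nodes: list[str]

    # -- topology helpers -------------------------------------------------

    @property
    def segment_map(self) -> dict[str, Segment]:
        return {s.id: s for s in self.segments}

    def out_segments(self, node: str) -> list[Segment]:
        return [s for s in self.segments if s.proximal_node == node]

    def in_segment(self, node: str) -> Segment | None:
        for s in self.segments:
            if s.distal_node == node:
                return s
        return None

    def leaf_nodes(self) -> list[str]:
        proximal = {s.proximal_node for s in self.segments}
        return [n for n in self.nodes if n not in proximal and n != self.inlet_node]

    def interface_nodes(self) -> list[str]:
        """All nodes coupled to a 0D element (coronary outlets + systemic)."""
        return list(self.coronary_outlet_nodes) + [self.systemic_outlet_node]

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise TreeValidationError("duplicate segment ids")
        if self.inlet_node not in self.nodes:
            raise TreeValidationError(f"inlet node {self.inlet_node!r} not in node set")
        if self.systemic_outlet_node not in self.nodes:
            raise TreeValidationError(
                f"systemic outlet {self.systemic_outlet_node!r} not in node set"
            )
        for s in self.segments:
            s.validate()
            for n in (s.proximal_node, s.distal_node):
                if n not in self.nodes:
                    raise TreeValidationError(f"segment {s.id}: unknown node {n!r}")

        indeg: dict[str, int] = {n: 0 for n in self.nodes}
        for s in self.segments:
            indeg[s.distal_node] += 1
        if indeg[self.inlet_node] != 0:
            raise TreeValidationError("inlet node has an incoming segment")
        roots = [n for n, d in indeg.items() if d == 0]
        if roots != [self.inlet_node] and set(roots) != {self.inlet_node}:
            raise TreeValidationError(
                f"expected exactly one root ({self.inlet_node!r}), found {sorted(roots)}"
            )
        for n, d in indeg.items():
            if n != self.inlet_node and d != 1:
                raise TreeValidationError(
                    f"node {n!r} has in-degree {d}; tree requires exactly 1"
                )

        # reachability from the inlet (with in-degree 1 this also rules out cycles)
        seen = {self.inlet_node}
        stack = [self.inlet_node]
        while stack:
            for s in self.out_segments(stack.pop()):
                if s.distal_node not in seen:
                    seen.add(s.distal_node)
                    stack.append(s.distal_node)
        unreachable = set(self.nodes) - seen
        if unreachable:
            raise TreeValidationError(f"nodes unreachable from inlet: {sorted(unreachable)}")

        if not self.coronary_outlet_nodes:
            raise TreeValidationError("tree has no coronary outlet nodes")
        leaves = set(self.leaf_nodes())
        for n in self.coronary_outlet_nodes:
            if n not in leaves:
                raise TreeValidationError(f"coronary outlet {n!r} is not a leaf node")
        if self.systemic_outlet_node in self.coronary_outlet_nodes:
            raise TreeValidationError("systemic outlet listed among coronary outlets")


def subdivide_segment(tree: CoronaryTree, segment_id: str, k: int) -> CoronaryTree:
    """Return a new tree with ``segment_id`` split into ``k`` equal pieces.

    Radii at the cut points follow the linear taper, so viscous resistances
    add in series and the flow solution is unchanged.  Stenoses are assigned
    to the sub-segment containing their midpoint; a lesion longer than a
    sub-segment cannot be represented and raises ``ValueError``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seg = tree.segment_map.get(segment_id)
    if seg is None:
        raise KeyError(segment_id)
    nodes = dict(tree.nodes)
    new_segments: list[Segment] = []
    for s in tree.segments:
        if s.id != segment_id:
            new_segments.append(s)
            continue
        sub_len = s.length / k
        bounds = [s.proximal_node] + [f"{s.id}__cut{i}" for i in range(1, k)] + [s.distal_node]
        for n in bounds[1:-1]:
            nodes[n] = None
        for i in range(k):
            r0 = s.radius_at(i / k)
            r1 = s.radius_at((i + 1) / k)
            stens = []
            for st in s.stenoses:
                j = min(int(st.position * k), k - 1)
                if j != i:
                    continue
                if st.length > sub_len:
                    raise ValueError(
                        f"stenosis of length {st.length} mm does not fit a "
                        f"{sub_len:.3g} mm sub-segment"
                    )
                stens.append(replace(st, position=st.position * k - j))
            new_segments.append(
                Segment(
                    id=f"{s.id}__part{i}",
                    proximal_node=bounds[i],
                    distal_node=bounds[i + 1],
                    length=sub_len,
                    radius_proximal=r0,
                    radius_distal=r1,
                    stenoses=stens,
                    branch_label=s.branch_label,
                )
            )
    out = CoronaryTree(
        nodes=nodes,
        segments=new_segments,
        inlet_node=tree.inlet_node,
        systemic_outlet_node=tree.systemic_outlet_node,
        coronary_outlet_nodes=list(tree.coronary_outlet_nodes),
    )
    out.validate()
    return out
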