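"""Synthetic coronary trees and patient parameters.

The generator emulates the geometry the method is applied to in practice: an
aortic stub feeding a left anterior descending (LAD), left circumflex (LCX)
and right coronary (RCA) branch, each a trunk that sheds side branches at
bifurcations obeying Murray's law (r_parent^3 = r_left^3 + r_right^3) with
radii tapering monotonically away from the root.  Lesions of 40-80% diameter
reduction — the clinically intermediate range the method targets — can be
placed on any branch.

Patient parameters are drawn from the population statistics of a stable
angina cohort: SBP 128 +/- 10 mmHg, DBP 85 +/- 9 mmHg, HR 72 +/- 12.76 bpm,
CO 5.26 +/- 2.6 L/min truncated below at 2 L/min, myocardial mass
126 +/- 34.08 g (metadata only).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .model import CoronaryTree, PatientParameters, Segment, Stenosis

# Proximal radii (mm) at the generous end of the normal range so that an
# unobstructed tree shows < 1% epicardial pressure loss even at hyperemic
# flow; aortic stub short and wide so the ostium is effectively held at the
# prescribed inlet pressure.
ROOT_RADII_MM = {"LAD": 2.6, "LCX": 2.3, "RCA": 2.4}
AORTA_RADIUS_MM = 12.5
AORTA_LENGTH_MM = 40.0
DEFAULT_STENOSIS_LENGTH_MM = 10.0

#: Severities at or above this are rejected: a near-occlusion is outside the
#: validity of the reduced-order loss model.
MAX_SEVERITY = 0.95


def _grow_branch(
    label: str,
    n_junctions: int,
    rng: np.random.Generator,
    nodes: dict,
    segments: list[Segment],
    outlets: list[str],
) -> None:
    r_prox = ROOT_RADII_MM[label] * rng.uniform(0.97, 1.03)
    node = "aorta_out"
    for j in range(n_junctions + 1):
        length = rng.uniform(12.0, 18.0)
        r_dist = r_prox * rng.uniform(0.95, 0.97)
        nid = f"{label}_t{j}"
        nodes[nid] = None
        segments.append(
            Segment(
                id=f"{label}{j}",
                proximal_node=node,
                distal_node=nid,
                length=length,
                radius_proximal=r_prox,
                radius_distal=r_dist,
                branch_label=label,
            )
        )
        if j == n_junctions:
            outlets.append(nid)
            return
        # Murray-compatible bifurcation: the side branch takes a fraction f
        # of the parent's r^3, the trunk continues with the remainder.
        f = rng.uniform(0.28, 0.40)
        r_side = r_dist * f ** (1.0 / 3.0)
        r_cont = r_dist * (1.0 - f) ** (1.0 / 3.0)
        side_len = rng.uniform(10.0, 15.0)
        sid = f"{label}_s{j}"
        nodes[sid] = None
        segments.append(
            Segment(
                id=f"{label}{j}s",
                proximal_node=nid,
                distal_node=sid,
                length=side_len,
                radius_proximal=r_side,
                radius_distal=r_side * 0.95,
                branch_label=label,
            )
        )
        outlets.append(sid)
        r_prox = r_cont
        node = nid


def generate_synthetic_tree(
    n_generations: int = 3,
    stenosis_spec: Iterable[tuple[str, float, float]] = (),
    seed: int = 0,
) -> CoronaryTree:
    """Generate a deterministic coronary-like tree.

    Parameters
    ----------
    n_generations : int
        Controls tree size.  1 gives a single LAD segment off the aortic
        stub; n >= 2 adds LCX and RCA branches, with the LAD trunk shedding
        ``n - 1`` side branches and LCX/RCA ``n - 2`` each.  The default
        (3) yields 7 coronary outlets.
    stenosis_spec : iterable of (branch, severity, position)
        Lesions to place on the first (most proximal) trunk segment of the
        named branch.  severity is fractional diameter reduction in
        [0, 0.95); position is fractional arc length along the segment.
    seed : int
        Seed for the random geometry jitter; identical seeds give identical
        trees.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    stenosis_spec = list(stenosis_spec)
    for branch, severity, position in stenosis_spec:
        if not (0.0 <= severity < MAX_SEVERITY):
            raise ValueError(
                f"stenosis severity {severity} outside [0, {MAX_SEVERITY}) "
                "(near-occlusions are outside model validity)"
            )
        if branch not in ROOT_RADII_MM:
            raise ValueError(f"unknown stenosis branch {branch!r}")

    rng = np.random.default_rng(seed)
    nodes: dict[str, tuple | None] = {"aorta_in": None, "aorta_out": None}
    segments: list[Segment] = [
        Segment(
            id="AO",
            proximal_node="aorta_in",
            distal_node="aorta_out",
            length=AORTA_LENGTH_MM,
            radius_proximal=AORTA_RADIUS_MM,
            radius_distal=AORTA_RADIUS_MM,
            branch_label="AORTA",
        )
    ]
    outlets: list[str] = []
    if n_generations == 1:
        plan = [("LAD", 0)]
    else:
        plan = [
            ("LAD", n_generations - 1),
            ("LCX", n_generations - 2),
            ("RCA", n_generations - 2),
        ]
    for label, njunc in plan:
        _grow_branch(label, njunc, rng, nodes, segments, outlets)

    seg_map = {s.id: s for s in segments}
    for branch, severity, position in stenosis_spec:
        host = seg_map.get(f"{branch}0")
        if host is None:
            raise ValueError(f"branch {branch} absent at n_generations={n_generations}")
        length = min(DEFAULT_STENOSIS_LENGTH_MM, 0.6 * host.length)
        host.stenoses.append(
            Stenosis(position=position, severity=severity, length=length)
        )

    tree = CoronaryTree(
        nodes=nodes,
        segments=segments,
        inlet_node="aorta_in",
        systemic_outlet_node="aorta_out",
        coronary_outlet_nodes=sorted(outlets),
    )
    tree.validate()
    return tree


def murray_residuals(tree: CoronaryTree, exponent: float = 3.0) -> dict[str, float]:
    """Relative Murray-law residual at every coronary bifurcation.

    Only junctions where a coronary parent splits into two or more coronary
    daughters are checked; the aorta-to-ostium take-off is not a Murray
    bifurcation (the coronaries draw a small fixed fraction of the systemic
    flow).
    """
    out: dict[str, float] = {}
    for node in tree.nodes:
        parent = tree.in_segment(node)
        if parent is None or not parent.is_coronary:
            continue
        children = [s for s in tree.out_segments(node) if s.is_coronary]
        if len(children) < 2:
            continue
        rp = parent.radius_distal**exponent
        rc = sum(c.radius_proximal**exponent for c in children)
        out[node] = abs(rp - rc) / rp
    return out


def sample_patient_parameters(seed: int = 0) -> PatientParameters:
    """Draw plausible patient parameters from the cohort distributions.

    Rejection sampling enforces SBP > DBP > 0 and HR > 0; cardiac output is
    truncated below at 2 L/min.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    while True:
        sbp = rng.normal(128.0, 10.0)
        dbp = rng.normal(85.0, 9.0)
        if sbp > dbp > 0:
            break
    while True:
        hr = rng.normal(72.0, 12.76)
        if hr > 0:
            break
    while True:
        co = rng.normal(5.26, 2.6)
        if co >= 2.0:
            break
    while True:
        mass = rng.normal(126.0, 34.08)
        if mass > 0:
            break
    return PatientParameters(sbp=sbp, dbp=dbp, hr=hr, co=co, myocardial_mass=mass)
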