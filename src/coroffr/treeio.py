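"""JSON I/O for coronary trees and patient parameters.

Tree schema (``"schema": "coro-ffrss-tree/1"``)::

    {
      "schema": "coro-ffrss-tree/1",
      "nodes": {"<id>": [x, y, z] | null, ...},          # coordinates in mm
      "segments": [
        {"id": ..., "proximal": ..., "distal": ...,
         "length_mm": ..., "r_prox_mm": ..., "r_dist_mm": ...,
         "branch": "AORTA|LAD|LCX|RCA|OTHER",
         "stenoses": [{"position": ..., "severity": ..., "length_mm": ...}]},
        ...
      ],
      "inlet": "<node id>",
      "systemic_outlet": "<node id>"
    }

Coronary outlets are not stored: on read they are recovered as the leaf
nodes other than the systemic outlet.  Writing is deterministic (sorted
keys), so identical trees serialize byte-identically.

Patient schema: ``{sbp_mmHg, dbp_mmHg, hr_bpm, co_L_min, myocardial_mass_g?}``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .model import (
    BRANCH_LABELS,
    CoronaryTree,
    PatientParameters,
    SchemaError,
    Segment,
    Stenosis,
)

SCHEMA_VERSION = "coro-ffrss-tree/1"


def _number(obj: dict, key: str, ctx: str) -> float:
    if key not in obj:
        raise SchemaError(f"{ctx}: missing required field {key!r}")
    v = obj[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise SchemaError(f"{ctx}.{key}: expected a number, got {v!r}")
    return float(v)


def _string(obj: dict, key: str, ctx: str) -> str:
    if key not in obj:
        raise SchemaError(f"{ctx}: missing required field {key!r}")
    v = obj[key]
    if not isinstance(v, str):
        raise SchemaError(f"{ctx}.{key}: expected a string, got {v!r}")
    return v


def read_tree(path: str | Path) -> CoronaryTree:
    """Read and fully validate a coronary-tree JSON file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a JSON object")
    if doc.get("schema") != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema: expected {SCHEMA_VERSION!r}, got {doc.get('schema')!r}"
        )
    raw_nodes = doc.get("nodes")
    if not isinstance(raw_nodes, dict):
        raise SchemaError("nodes: expected an object mapping id -> [x,y,z] | null")
    nodes: dict[str, tuple[float, float, float] | None] = {}
    for nid, coords in raw_nodes.items():
        if coords is None:
            nodes[nid] = None
        elif isinstance(coords, list) and len(coords) == 3 and all(
            isinstance(c, (int, float)) and not isinstance(c, bool) for c in coords
        ):
            nodes[nid] = (float(coords[0]), float(coords[1]), float(coords[2]))
        else:
            raise SchemaError(f"nodes.{nid}: expected null or [x, y, z]")

    raw_segments = doc.get("segments")
    if not isinstance(raw_segments, list):
        raise SchemaError("segments: expected an array")
    segments: list[Segment] = []
    for i, rs in enumerate(raw_segments):
        ctx = f"segments[{i}]"
        if not isinstance(rs, dict):
            raise SchemaError(f"{ctx}: expected an object")
        branch = _string(rs, "branch", ctx)
        if branch not in BRANCH_LABELS:
            raise SchemaError(f"{ctx}.branch: {branch!r} not one of {BRANCH_LABELS}")
        stenoses = []
        raw_st = rs.get("stenoses", [])
        if not isinstance(raw_st, list):
            raise SchemaError(f"{ctx}.stenoses: expected an array")
        for j, rst in enumerate(raw_st):
            sctx = f"{ctx}.stenoses[{j}]"
            if not isinstance(rst, dict):
                raise SchemaError(f"{sctx}: expected an object")
            try:
                stenoses.append(
                    Stenosis(
                        position=_number(rst, "position", sctx),
                        severity=_number(rst, "severity", sctx),
                        length=_number(rst, "length_mm", sctx),
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{sctx}: {exc}") from exc
        segments.append(
            Segment(
                id=_string(rs, "id", ctx),
                proximal_node=_string(rs, "proximal", ctx),
                distal_node=_string(rs, "distal", ctx),
                length=_number(rs, "length_mm", ctx),
                radius_proximal=_number(rs, "r_prox_mm", ctx),
                radius_distal=_number(rs, "r_dist_mm", ctx),
                stenoses=stenoses,
                branch_label=branch,
            )
        )

    inlet = _string(doc, "inlet", "tree")
    systemic = _string(doc, "systemic_outlet", "tree")
    tree = CoronaryTree(
        nodes=nodes,
        segments=segments,
        inlet_node=inlet,
        systemic_outlet_node=systemic,
        coronary_outlet_nodes=[],
    )
    tree.coronary_outlet_nodes = sorted(
        n for n in tree.leaf_nodes() if n != systemic
    )
    tree.validate()
    return tree


def write_tree(tree: CoronaryTree, path: str | Path) -> None:
    """Validate and serialize a tree; round-trips losslessly via read_tree."""
    tree.validate()
    doc = {
        "schema": SCHEMA_VERSION,
        "nodes": {
            nid: (list(c) if c is not None else None)
            for nid, c in tree.nodes.items()
        },
        "segments": [
            {
                "id": s.id,
                "proximal": s.proximal_node,
                "distal": s.distal_node,
                "length_mm": s.length,
                "r_prox_mm": s.radius_proximal,
                "r_dist_mm": s.radius_distal,
                "branch": s.branch_label,
                "stenoses": [
                    {
                        "position": st.position,
                        "severity": st.severity,
                        "length_mm": st.length,
                    }
                    for st in s.stenoses
                ],
            }
            for s in tree.segments
        ],
        "inlet": tree.inlet_node,
        "systemic_outlet": tree.systemic_outlet_node,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_patient(path: str | Path) -> PatientParameters:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a JSON object")
    mass = None
    if doc.get("myocardial_mass_g") is not None:
        mass = _number(doc, "myocardial_mass_g", "patient")
    try:
        return PatientParameters(
            sbp=_number(doc, "sbp_mmHg", "patient"),
            dbp=_number(doc, "dbp_mmHg", "patient"),
            hr=_number(doc, "hr_bpm", "patient"),
            co=_number(doc, "co_L_min", "patient"),
            myocardial_mass=mass,
        )
    except ValueError as exc:
        raise SchemaError(f"patient: {exc}") from exc


def write_patient(params: PatientParameters, path: str | Path) -> None:
    doc = {
        "sbp_mmHg": params.sbp,
        "dbp_mmHg": params.dbp,
        "hr_bpm": params.hr,
        "co_L_min": params.co,
    }
    if params.myocardial_mass is not None:
        doc["myocardial_mass_g"] = params.myocardial_mass
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
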