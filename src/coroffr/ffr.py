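"""Fractional flow reserve from a converged hyperemic flow solution.

FFR at a point is the ratio of local pressure Pd to the proximal (aortic)
pressure Pa at maximal hyperemia; a value at or below 0.80 marks a
hemodynamically significant (ischemia-causing) stenosis.  The lesion value
is sampled at the distal node of the host segment — a pressure-wire reading
just past the lesion — which is deterministic and conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .boundary import (
    BCConfig,
    DEFAULT_BC_CONFIG,
    build_lpm,
    mean_aortic_pressure,
)
from .hemodynamics import (
    CouplingConfig,
    FlowSolution,
    couple,
)
from .model import BloodProperties, CoronaryTree, PatientParameters

FFR_THRESHOLD = 0.80


@dataclass(frozen=True)
class LesionFFR:
    """FFR attributed to one stenosis descriptor."""

    segment_id: str
    branch: str
    severity: float
    position: float
    sample_node: str
    ffr: float


@dataclass
class FFRField:
    """FFR along the tree plus per-outlet and per-lesion values."""

    node_ffr: dict[str, float]
    distal_ffr: dict[str, float]
    lesion_ffr: list[LesionFFR]
    inlet_pressure_used: float


def compute_ffr(sol: FlowSolution, inlet_pressure: float | None = None) -> FFRField:
    """FFR field of a converged (hyperemic) flow solution.

    ``inlet_pressure`` defaults to the solved pressure at the inlet node, so
    the inlet FFR is exactly 1.
    """
    if not sol.converged:
        raise ValueError("flow solution did not converge; FFR undefined")
    tree = sol.tree
    pa = (
        inlet_pressure
        if inlet_pressure is not None
        else sol.node_pressures[tree.inlet_node]
    )
    if pa <= 0:
        raise ValueError("inlet pressure must be positive")
    node_ffr = {n: p / pa for n, p in sol.node_pressures.items()}
    distal_ffr = {n: node_ffr[n] for n in tree.coronary_outlet_nodes}
    lesions = []
    for seg in tree.segments:
        for st in seg.stenoses:
            lesions.append(
                LesionFFR(
                    segment_id=seg.id,
                    branch=seg.branch_label,
                    severity=st.severity,
                    position=st.position,
                    sample_node=seg.distal_node,
                    ffr=node_ffr[seg.distal_node],
                )
            )
    return FFRField(
        node_ffr=node_ffr,
        distal_ffr=distal_ffr,
        lesion_ffr=lesions,
        inlet_pressure_used=pa,
    )


def classify_ischemia(ffr_value: float, threshold: float = FFR_THRESHOLD) -> bool:
    """True iff ``ffr_value`` <= threshold (inclusive at the boundary)."""
    if not (0.0 < ffr_value <= 1.5):
        raise ValueError(f"FFR value {ffr_value} outside plausible range (0, 1.5]")
    return ffr_value <= threshold


def steady_state_ffr(
    tree: CoronaryTree,
    params: PatientParameters,
    hyperemia: bool = True,
    bc_config: BCConfig = DEFAULT_BC_CONFIG,
    coupling: CouplingConfig = CouplingConfig(),
    blood: BloodProperties = BloodProperties(),
) -> tuple[FlowSolution, FFRField]:
    """End-to-end pipeline: boundary conditions -> coupled solve -> FFR."""
    lpm = build_lpm(tree, params, hyperemia=hyperemia, config=bc_config)
    pa = mean_aortic_pressure(params)
    sol = couple(tree, lpm, pa, cfg=coupling, blood=blood)
    return sol, compute_ffr(sol, pa)


def results_table(field: FFRField, tree: CoronaryTree, threshold: float = FFR_THRESHOLD) -> pd.DataFrame:
    """One row per coronary outlet and per lesion, with ischemia flags."""
    rows = []
    for node in tree.coronary_outlet_nodes:
        seg = tree.in_segment(node)
        v = field.distal_ffr[node]
        rows.append(
            {
                "kind": "outlet",
                "id": node,
                "branch": seg.branch_label if seg else "OTHER",
                "severity": float("nan"),
                "distal_ffr": v,
                "lesion_ffr": float("nan"),
                "ischemic": classify_ischemia(v, threshold),
            }
        )
    for les in field.lesion_ffr:
        rows.append(
            {
                "kind": "lesion",
                "id": les.segment_id,
                "branch": les.branch,
                "severity": les.severity,
                "distal_ffr": float("nan"),
                "lesion_ffr": les.ffr,
                "ischemic": classify_ischemia(les.ffr, threshold),
            }
        )
    return pd.DataFrame(rows)


def node_ffr_table(field: FFRField, sol: FlowSolution) -> pd.DataFrame:
    """Per-node pressures and FFR, exportable for contour-style plotting."""
    return pd.DataFrame(
        {
            "node": list(field.node_ffr),
            "pressure_mmHg": [sol.node_pressures[n] for n in field.node_ffr],
            "ffr": list(field.node_ffr.values()),
        }
    )
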