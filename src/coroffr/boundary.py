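"""Patient-specific boundary conditions.

The vascular domain is driven by a mean aortic pressure at the inlet and by
microcirculatory resistances behind every coronary outlet:

* inlet pressure from the cuff-based mean-arterial-pressure formula
  ``Pa = DBP + (1/3 + HR * 0.0012) * (SBP - DBP)``;
* a resting coronary flow budget of 4% of cardiac output, partitioned among
  outlets by Murray's law (weights proportional to outlet radius cubed);
* per-outlet resting resistance ``R = (Pa - Pv) / Q`` from the healthy-tree
  flow budget (resistances are never derived from a stenosed solve);
* maximal hyperemia modelled as the microcirculatory resistance falling to
  24% of its resting value;
* a systemic (descending-aorta) resistance ``Rdoa = Pa / (0.96 * CO)``
  carrying the remaining 96% of cardiac output.

An inertance L = 0.05 (empirical units) is carried per outlet for fidelity
to the pulsatile circuit the model descends from; at steady state dQ/dt = 0,
so it has no effect on the solution — the 0D solver asserts as much.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import CoronaryTree, PatientParameters
from .units import l_min_to_ml_s


@dataclass(frozen=True)
class BCConfig:
    """Boundary-condition constants exposed for sensitivity studies."""

    murray_exponent: float = 3.0
    coronary_co_fraction: float = 0.04
    venous_pressure_mmHg: float = 0.0
    hyperemia_factor: float = 0.24
    inductance: float = 0.05


DEFAULT_BC_CONFIG = BCConfig()


@dataclass(frozen=True)
class OutletBC:
    """Lumped microcirculatory element behind one coronary outlet.

    Resistances in mmHg.s/mL; venous (reference) pressure in mmHg.
    """

    outlet_node: str
    r_resting: float
    r_hyperemia: float
    inductance: float = 0.05
    venous_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.r_resting <= 0:
            raise ValueError(f"outlet {self.outlet_node}: r_resting must be positive")
        if self.inductance < 0:
            raise ValueError(f"outlet {self.outlet_node}: inductance must be >= 0")


@dataclass
class LumpedParameterModel:
    """All 0D elements: one OutletBC per coronary outlet plus Rdoa."""

    outlets: list[OutletBC]
    r_doa: float
    systemic_node: str
    hyperemia: bool = True

    def __post_init__(self) -> None:
        if self.r_doa <= 0:
            raise ValueError("r_doa must be positive")

    @property
    def outlet_map(self) -> dict[str, OutletBC]:
        return {bc.outlet_node: bc for bc in self.outlets}

    def resistance(self, node: str) -> float:
        """Active resistance (mmHg.s/mL) at an interface node."""
        if node == self.systemic_node:
            return self.r_doa
        bc = self.outlet_map[node]
        return bc.r_hyperemia if self.hyperemia else bc.r_resting

    def venous_pressure(self, node: str) -> float:
        if node == self.systemic_node:
            return 0.0
        return self.outlet_map[node].venous_pressure


def mean_aortic_pressure(params: PatientParameters) -> float:
    """Mean aortic pressure (mmHg) from cuff pressures and heart rate."""
    return params.dbp + (1.0 / 3.0 + params.hr * 0.0012) * (params.sbp - params.dbp)


def total_coronary_flow(
    params: PatientParameters, config: BCConfig = DEFAULT_BC_CONFIG
) -> float:
    """Resting coronary flow budget (mL/s): 4% of cardiac output by default."""
    if params.co <= 0:
        raise ValueError("cardiac output must be positive")
    return config.coronary_co_fraction * l_min_to_ml_s(params.co)


def murray_flow_split(
    tree: CoronaryTree, q_total: float, exponent: float = 3.0
) -> dict[str, float]:
    """Partition ``q_total`` among coronary outlets by Murray's law.

    Weight of outlet i is r_i^exponent / sum_j r_j^exponent, with r_i the
    distal radius of the terminal segment.  The returned flows sum exactly
    to ``q_total``.
    """
    if q_total <= 0:
        raise ValueError("q_total must be positive")
    if not tree.coronary_outlet_nodes:
        raise ValueError("tree has no coronary outlets")
    radii = {}
    for node in tree.coronary_outlet_nodes:
        seg = tree.in_segment(node)
        if seg is None:
            raise ValueError(f"coronary outlet {node!r} has no feeding segment")
        radii[node] = seg.radius_distal
    total_w = sum(r**exponent for r in radii.values())
    return {n: q_total * r**exponent / total_w for n, r in radii.items()}


def resting_resistance(p: float, q: float) -> float:
    """Microcirculatory resistance R = P/Q (mmHg.s/mL)."""
    if q <= 0:
        raise ValueError(f"flow must be positive, got {q}")
    return p / q


def hyperemic_resistance(
    r_resting: float, factor: float = DEFAULT_BC_CONFIG.hyperemia_factor
) -> float:
    """Microcirculatory resistance at maximal hyperemia: 24% of resting."""
    if r_resting <= 0:
        raise ValueError(f"r_resting must be positive, got {r_resting}")
    return factor * r_resting


def aorta_outlet_resistance(pa: float, co: float) -> float:
    """Systemic resistance Rdoa = Pa / (0.96 * CO); CO in mL/s."""
    if co <= 0:
        raise ValueError(f"cardiac output must be positive, got {co}")
    return pa / (0.96 * co)


def build_lpm(
    tree: CoronaryTree,
    params: PatientParameters,
    hyperemia: bool = True,
    config: BCConfig = DEFAULT_BC_CONFIG,
) -> LumpedParameterModel:
    """Compose the full outlet model from patient parameters and geometry."""
    tree.validate()
    pa = mean_aortic_pressure(params)
    q_cor = total_coronary_flow(params, config)
    split = murray_flow_split(tree, q_cor, config.murray_exponent)
    pv = config.venous_pressure_mmHg
    outlets = []
    for node in tree.coronary_outlet_nodes:
        r_rest = resting_resistance(pa - pv, split[node])
        outlets.append(
            OutletBC(
                outlet_node=node,
                r_resting=r_rest,
                r_hyperemia=hyperemic_resistance(r_rest, config.hyperemia_factor),
                inductance=config.inductance,
                venous_pressure=pv,
            )
        )
    r_doa = aorta_outlet_resistance(pa, l_min_to_ml_s(params.co))
    return LumpedParameterModel(
        outlets=outlets,
        r_doa=r_doa,
        systemic_node=tree.systemic_outlet_node,
        hyperemia=hyperemia,
    )
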