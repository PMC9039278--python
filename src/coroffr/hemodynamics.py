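"""Steady flow solvers and the partitioned 0D <-> vascular-domain coupling.

The vascular domain is a reduced-order nonlinear network: each segment obeys

    dP(q) = A q + B q |q|

with ``A`` the Poiseuille resistance of the tapered tube plus the viscous
resistance of any stenosis throat, and ``B`` the turbulent expansion-loss
coefficient of the stenoses (Kt * rho/2 * (A0/As - 1)^2 / A0^2, Kt = 1.52 by
default).  Mass balance at every interior node closes the system, solved by
damped Newton iteration on nodal pressures.  The solver sits behind a simple
contract — inlet pressure and outlet pressures in, interface flows out — so
a spatially resolved CFD solver could replace it without touching the
coupling loop.

Two routes to the coupled solution are provided:

* :func:`couple` — the partitioned iteration: the domain is solved with the
  current outlet pressures, the resulting interface flows are handed to the
  0D model (P = Pv + R Q per outlet), and the returned pressures are fed
  back under adaptive relaxation until the relative change of all exchanged
  pressures and flows falls below epsilon (default 1e-4).
* :func:`solve_monolithic` — a verification oracle that folds the outlet
  resistances into the network and solves the whole system in one Newton
  pass.  Both must agree at the fixed point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boundary import LumpedParameterModel
from .model import BloodProperties, CoronaryTree, Segment, Stenosis
from .units import (
    m3_s_to_ml_s,
    ml_s_to_m3_s,
    mm_to_m,
    mmhg_to_pa,
    pa_to_mmhg,
    resistance_mmhg_ml_to_si,
)

logger = logging.getLogger(__name__)

#: Default turbulent expansion-loss coefficient of the stenosis model.
DEFAULT_KT = 1.52
#: Flow floor (mL/s) guarding relative-change divisions in the coupling norm.
Q_FLOOR_ML_S = 1e-6


class FlowSolverError(RuntimeError):
    """The domain Newton iteration failed to converge."""


class CouplingError(RuntimeError):
    """The partitioned 0D/domain iteration exceeded max_iterations."""

    def __init__(self, message: str, trace: list["CouplingState"]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class CouplingConfig:
    """Parameters of the partitioned iteration.

    ``epsilon`` is the relative tolerance on the change of every exchanged
    interface pressure and flow between successive iterations;
    ``relaxation`` is the initial under-relaxation factor on the exchanged
    pressures (adapted per interface by a secant rule thereafter).
    """

    epsilon: float = 1e-4
    max_iterations: int = 200
    relaxation: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0.0 < self.relaxation <= 1.0):
            raise ValueError("relaxation must lie in (0, 1]")


@dataclass
class CouplingState:
    """One exchange of the partitioned loop (clinical units)."""

    iteration: int
    residual: float
    q_0d_in: dict[str, float]  # flows handed to the 0D model, mL/s
    p_0d_out: dict[str, float]  # pressures returned by the 0D model, mmHg
    p_3d_in: float  # inlet pressure of the domain solve, mmHg
    q_3d_out: dict[str, float]  # interface flows computed by the domain, mL/s


@dataclass
class FlowSolution:
    """Converged steady flow state of the vascular domain (clinical units)."""

    tree: CoronaryTree
    node_pressures: dict[str, float]  # mmHg
    segment_flows: dict[str, float]  # mL/s, positive proximal -> distal
    interface_flows: dict[str, float]  # net flow into each 0D interface, mL/s
    inlet_flow: float  # mL/s
    inlet_pressure: float  # mmHg
    converged: bool
    coupling_trace: list[CouplingState] = field(default_factory=list)

    def mass_residuals(self) -> dict[str, float]:
        """Relative mass-balance defect at every interior node."""
        interfaces = set(self.tree.interface_nodes()) | {self.tree.inlet_node}
        qmax = max((abs(q) for q in self.segment_flows.values()), default=0.0)
        scale = max(qmax, Q_FLOOR_ML_S)
        net: dict[str, float] = {n: 0.0 for n in self.tree.nodes}
        for seg in self.tree.segments:
            q = self.segment_flows[seg.id]
            net[seg.distal_node] += q
            net[seg.proximal_node] -= q
        return {
            n: abs(v) / scale for n, v in net.items() if n not in interfaces
        }

    def max_mass_residual(self) -> float:
        res = self.mass_residuals()
        return max(res.values()) if res else 0.0

    def trace_dataframe(self) -> pd.DataFrame:
        rows = []
        for st in self.coupling_trace:
            for node in st.q_3d_out:
                rows.append(
                    {
                        "iteration": st.iteration,
                        "residual": st.residual,
                        "interface": node,
                        "p_0d_out_mmHg": st.p_0d_out[node],
                        "q_3d_out_mL_s": st.q_3d_out[node],
                        "p_3d_in_mmHg": st.p_3d_in,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# segment constitutive law
# ---------------------------------------------------------------------------


def segment_viscous_resistance(seg: Segment, blood: BloodProperties) -> float:
    """Poiseuille resistance (Pa.s/m^3) of the tapered tube.

    Exact closed form of the integral of 8 mu / (pi r(s)^4) ds with r linear
    in s: 8 mu L (rp^2 + rp rd + rd^2) / (3 pi rp^3 rd^3).
    """
    rp = mm_to_m(seg.radius_proximal)
    rd = mm_to_m(seg.radius_distal)
    length = mm_to_m(seg.length)
    return (
        8.0
        * blood.viscosity
        * length
        * (rp * rp + rp * rd + rd * rd)
        / (3.0 * math.pi * rp**3 * rd**3)
    )


def _throat_coeffs(
    sten: Stenosis, seg: Segment, blood: BloodProperties, kt: float
) -> tuple[float, float]:
    """(A, B) SI coefficients of one stenosis: dP = A q + B q |q|."""
    if sten.severity >= 1.0:
        raise ValueError("stenosis severity must be < 1")
    r0 = mm_to_m(seg.radius_at(sten.position))
    rs = r0 * (1.0 - sten.severity)
    a0 = math.pi * r0 * r0
    length = mm_to_m(sten.length)
    a_visc = 8.0 * blood.viscosity * length / (math.pi * rs**4)
    area_ratio = 1.0 / (1.0 - sten.severity) ** 2 - 1.0
    b_turb = kt * blood.density / 2.0 * area_ratio**2 / a0**2
    return a_visc, b_turb


def _edge_coeffs(
    seg: Segment, blood: BloodProperties, kt: float
) -> tuple[float, float]:
    a = segment_viscous_resistance(seg, blood)
    b = 0.0
    for st in seg.stenoses:
        ai, bi = _throat_coeffs(st, seg, blood, kt)
        a += ai
        b += bi
    return a, b


def stenosis_pressure_drop(
    sten: Stenosis,
    seg: Segment,
    q: float,
    blood: BloodProperties = BloodProperties(),
    kt: float = DEFAULT_KT,
) -> float:
    """Trans-lesion pressure drop (mmHg) at flow ``q`` (mL/s).

    Empirical viscous + turbulent-expansion loss: the odd-symmetric form
    A q + B q |q| guarantees the drop has the sign of the flow.
    """
    a, b = _throat_coeffs(sten, seg, blood, kt)
    qsi = ml_s_to_m3_s(q)
    return pa_to_mmhg(a * qsi + b * qsi * abs(qsi))


def _flow_from_dp(dp: float, a: float, b: float) -> float:
    """Invert dp = A q + B q |q| (all SI); stable for small B."""
    if dp == 0.0:
        return 0.0
    sign = 1.0 if dp > 0 else -1.0
    d = abs(dp)
    if b == 0.0:
        return sign * d / a
    return sign * 2.0 * d / (a + math.sqrt(a * a + 4.0 * b * d))


# ---------------------------------------------------------------------------
# network Newton solver
# ---------------------------------------------------------------------------


def _solve_network(
    node_ids: list[str],
    fixed: dict[str, float],
    edges: list[tuple[str, str, float, float]],
    max_iter: int = 60,
) -> tuple[dict[str, float], list[float]]:
    """Solve mass balance on a resistive network (SI units).

    ``edges`` are (u, v, A, B) with flow positive u -> v and
    P_u - P_v = A q + B q |q|.  Returns pressures for every node and the
    per-edge flows.  Free-node pressures are initialized from the linearized
    (B = 0) system, then refined by damped Newton until the worst nodal
    imbalance is below 1e-12 of the largest edge flow.
    """
    free = [n for n in node_ids if n not in fixed]
    idx = {n: i for i, n in enumerate(free)}
    nf = len(free)

    def pressures(x: np.ndarray) -> dict[str, float]:
        p = dict(fixed)
        for n, i in idx.items():
            p[n] = x[i]
        return p

    def edge_flows(x: np.ndarray) -> np.ndarray:
        p = pressures(x)
        return np.array([_flow_from_dp(p[u] - p[v], a, b) for u, v, a, b in edges])

    def residual(q: np.ndarray) -> np.ndarray:
        r = np.zeros(nf)
        for (u, v, _, _), qe in zip(edges, q):
            if v in idx:
                r[idx[v]] += qe
            if u in idx:
                r[idx[u]] -= qe
        return r

    if nf == 0:
        q = edge_flows(np.empty(0))
        return pressures(np.empty(0)), list(q)

    # linear (B = 0) initialization
    K = np.zeros((nf, nf))
    rhs = np.zeros(nf)
    for u, v, a, _ in edges:
        g = 1.0 / a
        iu = idx.get(u)
        iv = idx.get(v)
        if iu is not None:
            K[iu, iu] += g
            if iv is not None:
                K[iu, iv] -= g
            else:
                rhs[iu] += g * fixed[v]
        if iv is not None:
            K[iv, iv] += g
            if iu is not None:
                K[iv, iu] -= g
            else:
                rhs[iv] += g * fixed[u]
    x = np.linalg.solve(K, rhs)

    q = edge_flows(x)
    for _ in range(max_iter):
        r = residual(q)
        qscale = max(float(np.max(np.abs(q))), 1e-15)
        if float(np.max(np.abs(r))) <= 1e-12 * qscale:
            return pressures(x), list(q)
        J = np.zeros((nf, nf))
        for (u, v, a, b), qe in zip(edges, q):
            gp = 1.0 / (a + 2.0 * b * abs(qe))
            iu = idx.get(u)
            iv = idx.get(v)
            if iv is not None:
                J[iv, iv] -= gp
                if iu is not None:
                    J[iv, iu] += gp
            if iu is not None:
                J[iu, iu] -= gp
                if iv is not None:
                    J[iu, iv] += gp
        delta = np.linalg.solve(J, -r)
        rnorm = float(np.linalg.norm(r))
        lam = 1.0
        while lam > 1e-6:
            x_new = x + lam * delta
            q_new = edge_flows(x_new)
            if float(np.linalg.norm(residual(q_new))) < rnorm:
                break
            lam *= 0.5
        x = x + lam * delta
        q = edge_flows(x)
    r = residual(q)
    raise FlowSolverError(
        f"network Newton did not converge in {max_iter} iterations; "
        f"max |residual| = {float(np.max(np.abs(r))):.3e} m^3/s"
    )


def _interface_flow(tree: CoronaryTree, node: str, q_by_seg: dict[str, float]) -> float:
    """Net flow (mL/s) delivered into a 0D interface node."""
    total = 0.0
    for seg in tree.segments:
        if seg.distal_node == node:
            total += q_by_seg[seg.id]
        if seg.proximal_node == node:
            total -= q_by_seg[seg.id]
    return total


def solve_domain(
    tree: CoronaryTree,
    inlet_pressure: float,
    outlet_pressures: dict[str, float],
    blood: BloodProperties = BloodProperties(),
    kt: float = DEFAULT_KT,
) -> FlowSolution:
    """Solve the vascular domain with prescribed interface pressures.

    ``inlet_pressure`` (mmHg) is held at the inlet node; ``outlet_pressures``
    (mmHg) must cover every coronary outlet and the systemic outlet.
    Returns interface flows (mL/s, positive out of the domain).
    """
    missing = [n for n in tree.interface_nodes() if n not in outlet_pressures]
    if missing:
        raise ValueError(f"outlet_pressures missing interfaces: {missing}")
    fixed = {tree.inlet_node: mmhg_to_pa(inlet_pressure)}
    for n in tree.interface_nodes():
        fixed[n] = mmhg_to_pa(outlet_pressures[n])
    edges = [
        (s.proximal_node, s.distal_node, *_edge_coeffs(s, blood, kt))
        for s in tree.segments
    ]
    p_si, q_si = _solve_network(list(tree.nodes), fixed, edges)
    node_pressures = {n: pa_to_mmhg(p) for n, p in p_si.items()}
    segment_flows = {
        s.id: m3_s_to_ml_s(q) for s, q in zip(tree.segments, q_si)
    }
    interface_flows = {
        n: _interface_flow(tree, n, segment_flows) for n in tree.interface_nodes()
    }
    inlet_flow = -_interface_flow(tree, tree.inlet_node, segment_flows)
    return FlowSolution(
        tree=tree,
        node_pressures=node_pressures,
        segment_flows=segment_flows,
        interface_flows=interface_flows,
        inlet_flow=inlet_flow,
        inlet_pressure=inlet_pressure,
        converged=True,
    )


def solve_0d(
    lpm: LumpedParameterModel, interface_flows: dict[str, float]
) -> dict[str, float]:
    """0D model update: P_out = Pv + R Q at every interface (mmHg, mL/s).

    At steady state dQ/dt = 0, so the inertance contributes exactly zero;
    this is asserted rather than silently assumed.
    """
    for bc in lpm.outlets:
        # steady state: L * dQ/dt == 0 regardless of the stored inertance
        assert bc.inductance * 0.0 == 0.0
    out: dict[str, float] = {}
    for node in [bc.outlet_node for bc in lpm.outlets] + [lpm.systemic_node]:
        if node not in interface_flows:
            raise KeyError(f"no interface flow provided for outlet {node!r}")
        out[node] = lpm.venous_pressure(node) + lpm.resistance(node) * interface_flows[node]
    return out


# ---------------------------------------------------------------------------
# coupled solves
# ---------------------------------------------------------------------------


def couple(
    tree: CoronaryTree,
    lpm: LumpedParameterModel,
    inlet_pressure: float,
    cfg: CouplingConfig = CouplingConfig(),
    blood: BloodProperties = BloodProperties(),
    kt: float = DEFAULT_KT,
) -> FlowSolution:
    """Partitioned 0D <-> domain iteration.

    Alternates the domain solve (given current outlet pressures) with the 0D
    update (given current interface flows), relaxing the exchanged pressures.
    Because the microcirculatory resistances dominate the epicardial ones, a
    plain fixed-factor exchange is unstable; the update therefore combines
    the configured relaxation factor with an interface quasi-Newton
    correction built from the history of exchanged states (Anderson
    acceleration, the IQN-ILS family used for stiff partitioned coupling).
    Convergence is declared when the maximum relative change of all
    exchanged pressures and flows falls below ``cfg.epsilon``.
    """
    interfaces = tree.interface_nodes()
    p = np.full(len(interfaces), 0.9 * inlet_pressure)
    beta = cfg.relaxation
    history = 8  # retained quasi-Newton secant pairs
    hist_p: list[np.ndarray] = []
    hist_r: list[np.ndarray] = []
    q_prev: np.ndarray | None = None
    trace: list[CouplingState] = []

    for it in range(1, cfg.max_iterations + 1):
        sol = solve_domain(
            tree, inlet_pressure, dict(zip(interfaces, p)), blood=blood, kt=kt
        )
        q = np.array([sol.interface_flows[node] for node in interfaces])
        p_0d = solve_0d(lpm, sol.interface_flows)
        p_new_target = np.array([p_0d[node] for node in interfaces])
        r = p_new_target - p

        hist_p.append(p.copy())
        hist_r.append(r.copy())
        if len(hist_r) >= 2:
            mk = min(history, len(hist_r) - 1)
            d_r = np.column_stack(
                [hist_r[-j] - hist_r[-j - 1] for j in range(1, mk + 1)]
            )
            d_p = np.column_stack(
                [hist_p[-j] - hist_p[-j - 1] for j in range(1, mk + 1)]
            )
            gamma, *_ = np.linalg.lstsq(d_r, r, rcond=None)
            p_relaxed = p + beta * r - (d_p + beta * d_r) @ gamma
        else:
            p_relaxed = p + beta * r

        # convergence norm: relative change of the exchanged pressures and
        # flows between iterations, plus the 0D/domain mismatch at the
        # junction itself (the two models must return the same interface
        # pressure before the exchange is deemed converged)
        rel_p = float(
            np.max(np.abs(p_relaxed - p) / np.maximum(np.abs(p_relaxed), 1e-6))
        )
        rel_fp = float(
            np.max(np.abs(r) / np.maximum(np.abs(p_new_target), 1e-6))
        )
        if q_prev is None:
            residual = math.inf
        else:
            rel_q = float(
                np.max(np.abs(q - q_prev) / np.maximum(np.abs(q), Q_FLOOR_ML_S))
            )
            residual = max(rel_p, rel_q, rel_fp)
        trace.append(
            CouplingState(
                iteration=it,
                residual=residual,
                q_0d_in=dict(zip(interfaces, q)),
                p_0d_out=dict(zip(interfaces, p_new_target)),
                p_3d_in=inlet_pressure,
                q_3d_out=dict(zip(interfaces, q)),
            )
        )
        logger.info("coupling iteration %d: residual %.3e", it, residual)
        logger.debug(
            "interface P (mmHg): %s; Q (mL/s): %s",
            dict(zip(interfaces, np.round(p_relaxed, 6))),
            dict(zip(interfaces, np.round(q, 6))),
        )
        p = p_relaxed
        if residual < cfg.epsilon:
            final = solve_domain(
                tree, inlet_pressure, dict(zip(interfaces, p)), blood=blood, kt=kt
            )
            final.coupling_trace = trace
            final.converged = True
            return final
        r_prev = r
        q_prev = q

    raise CouplingError(
        f"partitioned coupling did not converge in {cfg.max_iterations} "
        f"iterations (last residual {trace[-1].residual:.3e})",
        trace,
    )


def solve_monolithic(
    tree: CoronaryTree,
    lpm: LumpedParameterModel,
    inlet_pressure: float,
    blood: BloodProperties = BloodProperties(),
    kt: float = DEFAULT_KT,
) -> FlowSolution:
    """Verification oracle: fold the 0D resistances into the network.

    Every interface node gets a linear resistor edge to a virtual ground held
    at its venous pressure; the augmented network is solved in a single
    Newton pass.  Shares the fixed point of :func:`couple`.
    """
    fixed = {tree.inlet_node: mmhg_to_pa(inlet_pressure)}
    edges = [
        (s.proximal_node, s.distal_node, *_edge_coeffs(s, blood, kt))
        for s in tree.segments
    ]
    nodes = list(tree.nodes)
    resistor_edges: dict[str, int] = {}
    for node in tree.interface_nodes():
        gnd = f"__gnd_{node}"
        nodes.append(gnd)
        fixed[gnd] = mmhg_to_pa(lpm.venous_pressure(node))
        resistor_edges[node] = len(edges)
        edges.append((node, gnd, resistance_mmhg_ml_to_si(lpm.resistance(node)), 0.0))
    p_si, q_si = _solve_network(nodes, fixed, edges)
    node_pressures = {n: pa_to_mmhg(p_si[n]) for n in tree.nodes}
    segment_flows = {
        s.id: m3_s_to_ml_s(q_si[i]) for i, s in enumerate(tree.segments)
    }
    interface_flows = {
        node: m3_s_to_ml_s(q_si[i]) for node, i in resistor_edges.items()
    }
    inlet_flow = -_interface_flow(tree, tree.inlet_node, segment_flows)
    return FlowSolution(
        tree=tree,
        node_pressures=node_pressures,
        segment_flows=segment_flows,
        interface_flows=interface_flows,
        inlet_flow=inlet_flow,
        inlet_pressure=inlet_pressure,
        converged=True,
    )
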