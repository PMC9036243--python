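"""ODE core: plasma -> lumped tissue / primary tumors -> draining nodes.

Compartment network
-------------------
A single plasma pool (volume ``V_p``, non-specific clearance ``CL_p``)
feeds, by convection across the vascular wall, a lumped non-tumor tissue
compartment and each primary-tumor (PT) interstitium:
``flux = L * (1 - sigma_V) * C_p``.  Each PT drains through one or more
afferent lymphatic branches to its tumor-draining lymph node(s) (TDLN);
only free antibody enters the lymph (``L_aff * (1 - sigma_L) * Cf``) and
only a surviving fraction ``Fsurv`` (FcRn salvage during transit, see
:mod:`tdlnpk.transit`) reaches the node.  Efferent lymph returns free
antibody from each node to plasma.  The TDLN has no direct vascular entry
route: high endothelial venules reflect antibody completely
(``sigma_V,TDLN = 1``), so lymph is the only way in.

In PT and TDLN interstitia the antibody binds its target.  Binding is
treated as a quasi-equilibrium algebraic layer: at every right-hand-side
evaluation the total antibody ``Ctot`` and total target ``Rtot`` are
partitioned into free and complexed species by mass action, and turnover
acts on the partition — synthesis ``k_syn = k_deg * R0`` (zero order),
degradation ``k_deg`` on free target, internalization ``k_int`` on the
complex (which also eliminates the bound antibody).

State vector ordering (deterministic): ``[C_p, C_tissue]``, then
``(Ctot, Rtot)`` for each lesion in declaration order, then
``(Ctot, Rtot)`` for each TDLN branch in lesion-major order.  All
concentrations in nM, time in h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ContractError, IntegrationError, InvalidParameterError
from .params import PhysiologyParams, StudyParameterSet, TargetParams, TransitParams
from .transit import transit_survival

__all__ = [
    "BindingSolution",
    "quasi_equilibrium_bind",
    "TDLNCompartment",
    "LesionChain",
    "NetworkSpec",
    "network_from_study",
    "integrate_network",
]

# solver settings shared by every integration in the package
RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class BindingSolution:
    """Free/bound partition of antibody and target at quasi-equilibrium."""

    Cf: float
    Cb: float
    Rfree: float


def quasi_equilibrium_bind(Ctot: float, Rtot: float, Kd: float) -> BindingSolution:
    """Partition total antibody and target by quasi-equilibrium mass action.

    Solves ``Cf * Rfree = Kd * Cb`` with ``Cf + Cb = Ctot`` and
    ``Rfree + Cb = Rtot``.  The complex concentration is the smaller root
    of the binding quadratic, evaluated in the numerically stable form
    ``Cb = 2*Ctot*Rtot / (b + sqrt(disc))`` with ``b = Ctot + Rtot + Kd``
    and the discriminant expanded as
    ``(Ctot - Rtot)^2 + 2*Kd*(Ctot + Rtot) + Kd^2`` — both
    rearrangements avoid cancellation when ``Cb`` approaches
    ``min(Ctot, Rtot)`` (tight binding) or when ``Ctot ~= Rtot``.
    """
    if Ctot < 0.0 or Rtot < 0.0:
        raise InvalidParameterError(
            f"totals must be non-negative, got Ctot={Ctot}, Rtot={Rtot}")
    if Kd <= 0.0:
        raise InvalidParameterError(f"Kd must be > 0, got {Kd}")
    prod = Ctot * Rtot
    if prod == 0.0:
        return BindingSolution(Cf=Ctot, Cb=0.0, Rfree=Rtot)
    b = Ctot + Rtot + Kd
    # cancellation-free expansion of b^2 - 4*Ctot*Rtot
    disc = (Ctot - Rtot) ** 2 + 2.0 * Kd * (Ctot + Rtot) + Kd * Kd
    Cb = 2.0 * prod / (b + math.sqrt(disc))
    Cb = min(Cb, Ctot, Rtot)  # guard round-off
    return BindingSolution(Cf=Ctot - Cb, Cb=Cb, Rfree=Rtot - Cb)


@dataclass(frozen=True)
class TDLNCompartment:
    """One draining-node branch attached to a lesion.

    ``transit=None`` inherits the lesion's transit parameters; a branch
    with its own path length can carry its own.
    """

    label: str
    R02: float
    L_aff: float = 0.004
    L_eff: float = 0.004
    V_isf: float = 5.84e-5
    transit: Optional[TransitParams] = None

    def __post_init__(self) -> None:
        if self.R02 < 0.0:
            raise InvalidParameterError(f"R02 must be non-negative, got {self.R02}")
        if self.L_aff < 0.0:
            raise InvalidParameterError(f"L_aff must be non-negative, got {self.L_aff}")
        if self.L_eff <= 0.0 or self.V_isf <= 0.0:
            raise InvalidParameterError("L_eff and V_isf must be strictly positive")


@dataclass(frozen=True)
class LesionChain:
    """A lesion (primary tumor or metastasis) plus its draining node(s)."""

    label: str
    sigma_v: float
    L_organ: float
    V_isf: float
    target: TargetParams
    transit: TransitParams
    tdlns: Tuple[TDLNCompartment, ...]
    role: str = "primary"  # "primary" | "metastasis"

    def __post_init__(self) -> None:
        if not (0.0 <= self.sigma_v <= 1.0):
            raise InvalidParameterError(f"sigma_v must lie in [0,1], got {self.sigma_v}")
        if self.L_organ <= 0.0 or self.V_isf <= 0.0:
            raise InvalidParameterError("L_organ and V_isf must be strictly positive")
        if len(self.tdlns) == 0:
            raise ContractError(f"lesion {self.label!r} has no draining node")
        labels = [t.label for t in self.tdlns]
        if len(set(labels)) != len(labels):
            raise ContractError(f"duplicate TDLN labels in lesion {self.label!r}")


@dataclass(frozen=True)
class NetworkSpec:
    """Full multi-lesion model: plasma, lumped tissue and lesion chains."""

    V_p: float
    CL_p: float
    sigma_l: float
    L_tissue: float
    sigma_v_tissue: float
    V_isf_tissue: float
    lesions: Tuple[LesionChain, ...]

    def __post_init__(self) -> None:
        if len(self.lesions) == 0:
            raise ContractError("network needs at least one lesion")
        labels = [l.label for l in self.lesions]
        if len(set(labels)) != len(labels):
            raise ContractError("duplicate lesion labels")

    # -- state layout -----------------------------------------------------
    @property
    def n_states(self) -> int:
        n_tdln = sum(len(l.tdlns) for l in self.lesions)
        return 2 + 2 * len(self.lesions) + 2 * n_tdln

    def state_labels(self) -> List[str]:
        labels = ["C_p", "C_tissue"]
        for les in self.lesions:
            labels += [f"Ctot[{les.label}]", f"Rtot[{les.label}]"]
        for les in self.lesions:
            for node in les.tdlns:
                labels += [f"Ctot[{les.label}/{node.label}]",
                           f"Rtot[{les.label}/{node.label}]"]
        return labels

    def tissue_labels(self) -> List[str]:
        """Output tissue labels: plasma, each lesion, each node."""
        out = ["plasma"]
        out += [les.label for les in self.lesions]
        out += [f"{les.label}/{node.label}"
                for les in self.lesions for node in les.tdlns]
        return out

    def initial_state(self, C_p0: float = 0.0) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        y0[0] = C_p0
        i = 2
        for les in self.lesions:
            y0[i + 1] = les.target.R01
            i += 2
        for les in self.lesions:
            for node in les.tdlns:
                y0[i + 1] = node.R02
                i += 2
        return y0


def network_from_study(study: StudyParameterSet) -> NetworkSpec:
    """Single-lesion, single-node network from a registered study."""
    p = study.physiology
    chain = LesionChain(
        label="PT",
        sigma_v=p.sigma_v_pt,
        L_organ=p.L_organ,
        V_isf=p.V_isf_pt,
        target=study.target,
        transit=study.transit,
        tdlns=(TDLNCompartment(
            label="TDLN", R02=study.target.R02,
            L_aff=p.L_aff, L_eff=p.L_eff, V_isf=p.V_isf_tdln,
        ),),
    )
    return NetworkSpec(
        V_p=p.V_p, CL_p=p.CL_p, sigma_l=p.sigma_l,
        L_tissue=p.L_tissue, sigma_v_tissue=p.sigma_v_tissue,
        V_isf_tissue=p.V_isf_tissue, lesions=(chain,),
    )


class _CompiledNetwork:
    """Index maps and pre-computed constants for fast RHS evaluation."""

    def __init__(self, net: NetworkSpec):
        self.net = net
        self.lesion_idx: List[int] = []
        self.tdln_idx: List[List[int]] = []
        self.fsurv: List[List[float]] = []
        i = 2
        for les in net.lesions:
            self.lesion_idx.append(i)
            i += 2
        self.node_ksyn: List[List[float]] = []
        for les in net.lesions:
            idxs, fs, ks = [], [], []
            for node in les.tdlns:
                idxs.append(i)
                tr = node.transit if node.transit is not None else les.transit
                fs.append(transit_survival(tr))
                # a branch with the lesion's own R02 inherits its (possibly
                # pinned) synthesis rate; other branches derive theirs
                tg = les.target
                ks.append(tg.k_syn_tdln if node.R02 == tg.R02
                          else tg.k_deg * node.R02)
                i += 2
            self.tdln_idx.append(idxs)
            self.fsurv.append(fs)
            self.node_ksyn.append(ks)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        net = self.net
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at t={t}", snapshot=y.copy())
        # negative excursions below solver tolerance are clipped before the
        # algebraic binding solve
        y = np.maximum(y, 0.0)
        dy = np.zeros_like(y)
        C_p, C_t = y[0], y[1]
        one_m_sl = 1.0 - net.sigma_l

        # lumped tissue
        in_tissue = net.L_tissue * (1.0 - net.sigma_v_tissue) * C_p
        out_tissue = net.L_tissue * one_m_sl * C_t
        dy[1] = (in_tissue - out_tissue) / net.V_isf_tissue

        dAp = -net.CL_p * C_p - in_tissue + out_tissue  # amount/h into plasma

        for li, les in enumerate(net.lesions):
            i = self.lesion_idx[li]
            Ctot1, Rtot1 = y[i], y[i + 1]
            tg = les.target
            sol1 = quasi_equilibrium_bind(Ctot1, Rtot1, tg.Kd)

            influx1 = les.L_organ * (1.0 - les.sigma_v) * C_p
            dAp -= influx1
            efflux1 = 0.0
            for node, j, fs, ksyn in zip(les.tdlns, self.tdln_idx[li],
                                         self.fsurv[li], self.node_ksyn[li]):
                flux_aff = node.L_aff * one_m_sl * sol1.Cf
                efflux1 += flux_aff
                Ctot2, Rtot2 = y[j], y[j + 1]
                sol2 = quasi_equilibrium_bind(Ctot2, Rtot2, tg.Kd)
                flux_eff = node.L_eff * sol2.Cf
                dy[j] = (flux_aff * fs - flux_eff) / node.V_isf - tg.k_int * sol2.Cb
                dy[j + 1] = ksyn - tg.k_deg * sol2.Rfree - tg.k_int * sol2.Cb
                dAp += flux_eff

            dy[i] = (influx1 - efflux1) / les.V_isf - tg.k_int * sol1.Cb
            dy[i + 1] = tg.k_syn_pt - tg.k_deg * sol1.Rfree - tg.k_int * sol1.Cb

        dy[0] = dAp / net.V_p
        return dy


def integrate_network(
    net: NetworkSpec,
    y0: np.ndarray,
    times: Sequence[float],
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
) -> np.ndarray:
    """Integrate the network ODEs, returning states at ``times``.

    ``times`` must be non-decreasing and start at the initial time.
    Returns an array of shape ``(len(times), n_states)``.

    Raises
    ------
    IntegrationError
        If the solver fails; the exception carries the last state snapshot.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ContractError("need at least two output times")
    if np.any(np.diff(times) < 0):
        raise ContractError("output times must be non-decreasing")
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (net.n_states,):
        raise ContractError(
            f"state has {y0.shape} entries, expected {net.n_states}")
    if np.any(y0 < 0) or not np.all(np.isfinite(y0)):
        raise IntegrationError("invalid initial state", snapshot=y0.copy())

    compiled = _CompiledNetwork(net)
    sol = solve_ivp(
        compiled.rhs, (times[0], times[-1]), y0,
        t_eval=times, method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed: {sol.message}",
            snapshot=sol.y[:, -1] if sol.y.size else y0,
        )
    return sol.y.T
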