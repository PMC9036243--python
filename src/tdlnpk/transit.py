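"""FcRn-salvage survival of antibody during PT -> TDLN lymphatic transit.

Antibody draining from the tumor interstitium travels along lymphatic
vessels to the draining node.  Lymphatic endothelial cells continuously
pinocytose lymph; IgG bound by FcRn in the acidified endosome is recycled
intact and continues downstream, while unbound IgG is degraded.  The net
effect is a survival fraction ``Fsurv`` in (0, 1] applied to the afferent
antibody flux.

The default "power_shape" strategy treats transit as a sequence of
independent uptake events.  Each event removes a fraction
``uptake_prob * (1 - f_FcRn)`` of the passing antibody, where ``f_FcRn``
is the equilibrium FcRn-bound fraction, and the effective number of events
is ``n_ref / dln``: the organ-specific shape factor ``dln`` (roughly, a
measure of how short/efficient the drainage path is) attenuates cumulative
loss.  Survival is therefore strictly increasing in ``dln`` and strictly
decreasing in ``Kd_FcRn``, matching the observed sensitivity directions.

Alternative functional forms can be registered under a new strategy name
without touching the ODE core.
"""

from __future__ import annotations

from typing import Callable, Dict

from .errors import InvalidParameterError
from .params import TransitParams

__all__ = [
    "fcrn_bound_fraction",
    "transit_survival",
    "register_strategy",
    "available_strategies",
]

SurvivalFn = Callable[[TransitParams], float]

_STRATEGIES: Dict[str, SurvivalFn] = {}


def fcrn_bound_fraction(Kd_FcRn: float, FcRn_conc: float) -> float:
    """Equilibrium fraction of pinocytosed antibody bound (and salvaged) by FcRn.

    With endosomal FcRn in large excess over antibody, the bound fraction
    is ``[FcRn] / ([FcRn] + Kd_FcRn)``.

    Parameters
    ----------
    Kd_FcRn : float
        Antibody-FcRn affinity at endosomal pH (nM).
    FcRn_conc : float
        Endothelial FcRn concentration (nM).
    """
    if Kd_FcRn <= 0.0:
        raise InvalidParameterError(f"Kd_FcRn must be > 0, got {Kd_FcRn}")
    if FcRn_conc <= 0.0:
        raise InvalidParameterError(f"FcRn_conc must be > 0, got {FcRn_conc}")
    return FcRn_conc / (FcRn_conc + Kd_FcRn)


def _power_shape(transit: TransitParams) -> float:
    fb = fcrn_bound_fraction(transit.Kd_FcRn, transit.FcRn_conc)
    loss_per_event = transit.uptake_prob * (1.0 - fb)
    n_events = transit.n_ref / transit.dln
    return float((1.0 - loss_per_event) ** n_events)


_STRATEGIES["power_shape"] = _power_shape


def register_strategy(name: str, fn: SurvivalFn, *, overwrite: bool = False) -> None:
    """Register an alternative survival functional form under ``name``."""
    if name in _STRATEGIES and not overwrite:
        raise InvalidParameterError(f"strategy {name!r} already registered")
    _STRATEGIES[name] = fn


def available_strategies() -> tuple:
    return tuple(sorted(_STRATEGIES))


def transit_survival(transit: TransitParams) -> float:
    """Fraction of afferent antibody flux surviving PT -> TDLN transit.

    Dispatches on ``transit.strategy``; the result must lie in (0, 1].
    """
    try:
        fn = _STRATEGIES[transit.strategy]
    except KeyError:
        raise InvalidParameterError(
            f"unknown transit strategy {transit.strategy!r}; "
            f"available: {available_strategies()}"
        ) from None
    f = fn(transit)
    if not (0.0 < f <= 1.0):
        raise InvalidParameterError(
            f"transit survival {f} outside (0, 1] for {transit}"
        )
    return f
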