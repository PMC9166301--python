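"""Reagent titration: pick the antibody concentration with the best SI.

A serial-dilution series (classically 1:2 steps) is acquired, the stain
index computed per concentration, and the best-resolving dilution selected.
The visual "best SI" call is operationalized as: take the maximum-SI
concentration, but if several concentrations sit within ``plateau_tolerance``
of the maximum, take the lowest of them (saturation reached — save reagent)
and set a plateau flag; a strictly rising series that never plateaus selects
the top concentration with an ``unsaturated`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .exceptions import (
    ConfigError,
    InsufficientDataError,
    TitrationFailedError,
    UnseparablePopulationsError,
)
from .fcs_io import EventTable
from .robust_stats import split_pos_neg, stain_index

__all__ = ["TitrationResult", "apply_plateau_rule", "select_concentration"]


@dataclass
class TitrationResult:
    concentrations: np.ndarray
    si_values: np.ndarray
    selected: float
    rule: str
    flags: dict = field(default_factory=dict)


def apply_plateau_rule(
    concentrations,
    si_values,
    plateau_tolerance: float = defaults.PLATEAU_TOLERANCE,
) -> TitrationResult:
    """Selection rule on an already-computed SI-versus-concentration series.

    Exposed separately so the decision logic can be audited on any SI series
    independently of how the stain indices were measured.
    """
    conc = np.asarray(concentrations, dtype=float)
    si = np.asarray(si_values, dtype=float)
    if conc.size != si.size:
        raise ConfigError("concentrations and SI values must align")
    if conc.size < 3:
        raise InsufficientDataError("titration needs >= 3 concentrations")
    order = np.argsort(conc)
    conc, si = conc[order], si[order]
    finite = np.isfinite(si)
    if not finite.any():
        raise TitrationFailedError("no concentration yielded a valid SI")

    si_max = np.nanmax(si[finite])
    plateau = finite & (si >= (1.0 - plateau_tolerance) * si_max)
    selected = float(conc[plateau][0])
    flags = {
        "plateau": int(plateau.sum()) > 1,
        "unsaturated": bool(
            selected == conc[finite][-1]
            and np.all(np.diff(si[finite]) > 0)),
        "unseparable_concentrations": conc[~finite].tolist(),
    }
    rule = ("lowest concentration within "
            f"{plateau_tolerance:.0%} of max SI" if flags["plateau"]
            else "argmax SI")
    return TitrationResult(concentrations=conc, si_values=si,
                           selected=selected, rule=rule, flags=flags)


def select_concentration(
    series,
    detector: str | None = None,
    split_method: str = "truth",
    plateau_tolerance: float = defaults.PLATEAU_TOLERANCE,
    label_key: str = "concentration",
) -> TitrationResult:
    """Select a reagent concentration from a titration series.

    ``series`` is either a list of per-dilution tables (each carrying its
    concentration in ``meta``) or one concatenated table whose
    ``meta[label_key]`` is a per-event concentration vector.  Points where
    the positive/negative split fails are flagged; if no concentration
    separates, the titration failed.
    """
    tables = _explode(series, label_key)
    if len(tables) < 3:
        raise InsufficientDataError("titration needs >= 3 concentrations")
    tables.sort(key=lambda ct: ct[0])
    concs, sis = [], []
    for c, t in tables:
        det = detector or t.meta.get("detector")
        if det is None:
            raise ConfigError("no detector specified for the titration")
        try:
            if split_method == "truth":
                split = split_pos_neg(t.column(det), "truth",
                                      truth=t.meta["truth_pos"])
            else:
                split = split_pos_neg(t.column(det), split_method)
            values = t.column(det)
            si = stain_index(values[split.positive],
                             values[split.negative]).si
        except UnseparablePopulationsError:
            si = float("nan")
        concs.append(c)
        sis.append(si)
    if not np.isfinite(sis).any():
        raise TitrationFailedError(
            "positive and negative populations were unseparable at every "
            "concentration")
    return apply_plateau_rule(concs, sis, plateau_tolerance)


def _explode(series, label_key: str) -> list[tuple[float, EventTable]]:
    if isinstance(series, EventTable):
        labels = series.meta.get(label_key)
        if labels is None:
            raise ConfigError(
                f"concatenated titration needs per-event meta[{label_key!r}]")
        labels = np.asarray(labels, dtype=float)
        out = []
        for c in np.unique(labels):
            mask = labels == c
            sub = EventTable(
                data=series.data[mask], channels=list(series.channels),
                meta={k: (v[mask] if isinstance(v, np.ndarray)
                          and v.shape[:1] == (series.n_events,) else v)
                      for k, v in series.meta.items()})
            out.append((float(c), sub))
        return out
    return [(float(t.meta[label_key]), t) for t in series]
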