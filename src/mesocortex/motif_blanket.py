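"""Flux-exchange motif classification and Markov-blanket detection.

Perturbations of the near-equilibrium field exchange synaptic flux between
small cell groups in four elementary ways, distinguished by three binary
features of the exchange: the class of cells receiving the majority flux
(excitatory vs inhibitory), the directional symmetry of the exchange, and
the lag of the peak induced cross-correlation:

======================  ========  =========  =========
label                   target    symmetry   peak lag
======================  ========  =========  =========
SYM_EE                  E         symmetric  zero
SYM_EI_ZERO_ERROR       I         symmetric  zero
ASYM_EI_CROSS_INHIB.    I         asym.      any
ASYM_EE_LAGGED          E         asym.      nonzero
======================  ========  =========  =========

Zero-error cells are those whose backward (efferent) event stream, advanced
by the conduction delay, exactly predicts the global activity at their
target: the prediction residual vanishes and the forward and backward flows
cancel.  The set of such cells forms a Markov blanket between the global
field and a local map — interior and exterior become conditionally
independent given the blanket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from mesocortex.correlation_metrics import cross_correlogram
from mesocortex.fixtures import MotifFlux
from mesocortex.map_geometry import LocalActivity, LocalMapSpec, StimulusField

log = logging.getLogger(__name__)

__all__ = [
    "MOTIF_LABELS",
    "MotifLabel",
    "BlanketReport",
    "classify_pair_motif",
    "zero_error_residual",
    "detect_markov_blanket",
]

MOTIF_LABELS = (
    "SYM_EE",
    "SYM_EI_ZERO_ERROR",
    "ASYM_EI_CROSS_INHIBITION",
    "ASYM_EE_LAGGED",
    "NONE",
)


@dataclass
class MotifLabel:
    """Motif assignment for one assessed group pair, with evidence scores."""

    label: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in MOTIF_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class BlanketReport:
    """Cells whose forward/backward flows cancel within tolerance."""

    members: list
    residuals: dict
    tolerance: float
    is_separator: bool | None = None


def classify_pair_motif(
    flux: MotifFlux,
    theta_sym: float = 0.2,
    lag_floor_steps: int = 2,
    flux_floor: float = 1e-6,
    tau_max: float | None = None,
) -> MotifLabel:
    """Classify one directed flux exchange into a motif type.

    Decision tree on three features: (1) target class — does the majority
    of exchanged flux land on excitatory or inhibitory cells; (2) symmetry —
    directional asymmetry |phi_ij - phi_ji| / (phi_ij + phi_ji) against
    ``theta_sym``; (3) lag — peak cross-correlation of the groups' pulse
    series at |lag| <= ``lag_floor_steps`` steps (zero-lag) or beyond.
    Exchanges whose total flux falls below ``flux_floor`` are NONE.
    """
    phi_ij = flux.flux_ij_E + flux.flux_ij_I
    phi_ji = flux.flux_ji_E + flux.flux_ji_I
    total = phi_ij + phi_ji
    if total < flux_floor:
        return MotifLabel("NONE", {"total_flux": total})

    e_share = (flux.flux_ij_E + flux.flux_ji_E) / total
    asym = abs(phi_ij - phi_ji) / total
    if tau_max is None:
        tau_max = min(10 * lag_floor_steps * flux.dt, len(flux.series_i) * flux.dt / 5)
    lags, corr, degenerate = cross_correlogram(flux.series_i, flux.series_j, tau_max, flux.dt)
    if degenerate:
        peak_lag_steps = 0.0
    else:
        peak_lag_steps = float(lags[int(np.argmax(np.abs(corr)))] / flux.dt)
    zero_lag = abs(peak_lag_steps) <= lag_floor_steps

    evidence = {
        "total_flux": total,
        "e_share": e_share,
        "asymmetry": asym,
        "peak_lag_steps": peak_lag_steps,
    }
    to_E = e_share >= 0.5
    symmetric = asym <= theta_sym
    if to_E and symmetric:
        label = "SYM_EE"
    elif not to_E and symmetric:
        label = "SYM_EI_ZERO_ERROR"
    elif not to_E:
        label = "ASYM_EI_CROSS_INHIBITION"
    else:
        label = "ASYM_EE_LAGGED"
    evidence["zero_lag"] = zero_lag
    return MotifLabel(label, evidence)


# ---------------------------------------------------------------------------
# zero-error residuals
# ---------------------------------------------------------------------------

def zero_error_residual(
    local: LocalActivity,
    global_field: StimulusField,
    spec: LocalMapSpec,
    bin_width: float | None = None,
    position_tol: float = 1e-6,
) -> dict:
    """Per-cell prediction residual of the backward flow against the global flow.

    Each assessed cell is a distinct local position p with global target P
    (the source stored on its events).  The cell's backward stream is its
    local events advanced back by the conduction delay |P - p| / nu; the
    residual compares the histogram of those predicted global event times
    with the actual global events at P:

        residual = sum_t |h_pred(t) - h_actual(t)| / sum_t (h_pred + h_actual)

    0 iff the backward flow exactly reproduces the global activity at the
    target; approximately 1 for unrelated streams; invariant to a common
    time shift of both streams.
    """
    if len(local) == 0 or len(global_field) == 0:
        raise ValueError("empty event window")
    if bin_width is None:
        all_t = np.concatenate([local.times, global_field.times])
        span = max(all_t.max() - all_t.min(), 1e-12)
        bin_width = span / 50.0

    def key(z: complex) -> tuple[float, float]:
        return (round(z.real / position_tol), round(z.imag / position_tol))

    delays = np.abs(local.sources - local.positions) / spec.nu
    pred_times = local.times - delays

    cells: dict = {}
    for i in range(len(local)):
        cells.setdefault(key(complex(local.positions[i])), []).append(i)

    glob_by_target: dict = {}
    for j in range(len(global_field)):
        glob_by_target.setdefault(key(complex(global_field.positions[j])), []).append(j)

    t0 = min(pred_times.min(), global_field.times.min())
    t1 = max(pred_times.max(), global_field.times.max())
    edges = np.arange(t0, t1 + 2 * bin_width, bin_width)

    residuals: dict = {}
    for ck, idx in cells.items():
        idx = np.asarray(idx)
        target = key(complex(local.sources[idx[0]]))
        h_pred, _ = np.histogram(pred_times[idx], bins=edges, weights=local.amplitudes[idx])
        jdx = np.asarray(glob_by_target.get(target, []), dtype=int)
        if jdx.size:
            h_act, _ = np.histogram(
                global_field.times[jdx], bins=edges, weights=global_field.amplitudes[jdx]
            )
        else:
            h_act = np.zeros(len(edges) - 1)
        denom = h_pred.sum() + h_act.sum()
        residuals[ck] = float(np.abs(h_pred - h_act).sum() / denom) if denom > 0 else 1.0
    return residuals


def detect_markov_blanket(
    residuals: dict,
    tolerance: float,
    graph: nx.Graph | None = None,
    interior: set | None = None,
    exterior: set | None = None,
) -> BlanketReport:
    """Cells whose residual is within tolerance, with a graph-cut check.

    Membership is monotone in tolerance (nested sets).  If a connection
    graph and interior/exterior node sets are supplied, the report also
    states whether removing the blanket separates every interior node from
    every exterior node; the two facts (small residual, separator) are
    reported independently.
    """
    members = [c for c, r in residuals.items() if r <= tolerance]
    is_sep: bool | None = None
    if graph is not None and interior and exterior:
        H = graph.copy()
        H.remove_nodes_from(members)
        is_sep = True
        for a in interior:
            if a in members or a not in H:
                continue
            reachable = nx.node_connected_component(H, a)
            if any(b in reachable for b in exterior if b not in members):
                is_sep = False
                break
    return BlanketReport(
        members=members,
        residuals=dict(residuals),
        tolerance=tolerance,
        is_separator=is_sep,
    )
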