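"""Seeded generators for synthetic inputs.

Everything the simulator consumes can be generated here deterministically:
structured stimuli on the global cortical frame (moving points, oriented
line sweeps, circumferential arcs, radial segments, diffuse noise), flux
pairs constructed to each of the four elementary flux-exchange motifs,
k-factor Gaussian flux matrices for model-order recovery, and the canonical
synchronous-equilibrium oscillator network (symmetric positive couplings
within the E and within the I populations, symmetric negative couplings
between them) whose noise-driven ground state shows zero-lag E-E and I-I
synchrony with E-I anti-phase.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from mesocortex.field_dynamics import OscillatorParams
from mesocortex.map_geometry import GlobalFrame, StimulusField

log = logging.getLogger(__name__)

__all__ = [
    "StimulusSpec",
    "MotifFlux",
    "make_stimulus",
    "make_motif_pair",
    "make_factor_flux",
    "synchronous_equilibrium_params",
]

STIMULUS_KINDS = (
    "moving_point",
    "oriented_line_sweep",
    "circumferential_arc",
    "radial_segment",
    "diffuse_noise",
)


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and sampling of one synthetic stimulus.

    ``kind`` selects the path family; ``center`` anchors arcs and radial
    segments (usually a local-map center); ``start`` is the initial position
    for moving kinds; ``direction`` (radians) the initial heading or radial
    azimuth; ``speed`` in distance/time; events are sampled every ``dt``
    for ``duration`` time units at unit ``amplitude``.
    """

    kind: str
    center: complex = 0j
    start: complex = 1 + 0j
    direction: float = 0.0
    speed: float = 1.0
    duration: float = 1.0
    dt: float = 0.01
    amplitude: float = 1.0
    n_line: int = 11
    line_length: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; choose from {STIMULUS_KINDS}")
        if self.kind != "diffuse_noise" and self.speed <= 0:
            raise ValueError("speed must be positive for moving stimuli")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


def make_stimulus(spec: StimulusSpec, frame: GlobalFrame) -> StimulusField:
    """Sample a stimulus event list along the specified path.

    Deterministic under ``spec.seed``.  Events whose positions leave the
    global frame are clipped (dropped) with a logged warning.
    """
    n = max(2, int(round(spec.duration / spec.dt)))
    t = np.arange(n) * spec.dt
    if spec.kind == "moving_point":
        pos = spec.start + spec.speed * t * np.exp(1j * spec.direction)
        amp = np.full(n, spec.amplitude)
    elif spec.kind == "oriented_line_sweep":
        # a line of n_line points, oriented perpendicular to the sweep
        # direction, translating at the given speed
        offsets = np.linspace(-0.5, 0.5, spec.n_line) * spec.line_length
        normal = np.exp(1j * (spec.direction + math.pi / 2))
        base = spec.start + spec.speed * t * np.exp(1j * spec.direction)
        pos = (base[:, None] + offsets[None, :] * normal).ravel()
        t = np.repeat(t, spec.n_line)
        amp = np.full(pos.size, spec.amplitude)
    elif spec.kind == "circumferential_arc":
        radius = abs(spec.start - spec.center)
        if radius <= 0:
            raise ValueError("start must differ from center for an arc")
        theta0 = np.angle(spec.start - spec.center)
        pos = spec.center + radius * np.exp(1j * (theta0 + spec.speed * t / radius))
        amp = np.full(n, spec.amplitude)
    elif spec.kind == "radial_segment":
        r0 = abs(spec.start - spec.center)
        pos = spec.center + (r0 + spec.speed * t) * np.exp(1j * spec.direction)
        amp = np.full(n, spec.amplitude)
    else:  # diffuse_noise
        rng = np.random.default_rng(spec.seed)
        xmin, xmax, ymin, ymax = frame.extent
        pos = rng.uniform(xmin, xmax, n) + 1j * rng.uniform(ymin, ymax, n)
        t = np.sort(rng.uniform(0.0, spec.duration, n))
        amp = np.full(n, spec.amplitude)

    inside = np.array([frame.contains(complex(P)) for P in pos])
    if not inside.all():
        log.warning(
            "make_stimulus: %d/%d events outside the frame were clipped",
            int((~inside).sum()),
            len(pos),
        )
    return StimulusField(
        positions=pos[inside], times=t[inside], amplitudes=amp[inside], frame=frame
    )


# ---------------------------------------------------------------------------
# motif generators
# ---------------------------------------------------------------------------

@dataclass
class MotifFlux:
    """Directed flux exchange between two cell groups, resolved by target.

    ``flux_ij_E``/``flux_ij_I``: time-averaged synaptic flux from group i to
    the excitatory / inhibitory cells of group j (and symmetrically for
    ``ji``).  ``series_i``/``series_j`` are the groups' excitatory
    pulse-density series used for the lag analysis, sampled at ``dt``.
    """

    flux_ij_E: float
    flux_ij_I: float
    flux_ji_E: float
    flux_ji_I: float
    series_i: np.ndarray
    series_j: np.ndarray
    dt: float = 1.0


def make_motif_pair(label: str, noise_level: float = 0.0, seed: int = 0) -> MotifFlux:
    """Generate a flux pair constructed to one of the four motif types.

    * ``SYM_EE``: equal flux both directions onto excitatory targets;
      zero-lag synchronous series (the antenatal ground state).
    * ``SYM_EI_ZERO_ERROR``: equal flux both directions onto inhibitory
      targets; each group predicts and cancels the other with zero error,
      so the series remain zero-lag synchronous.
    * ``ASYM_EI_CROSS_INHIBITION``: one-way dominant flux onto inhibitory
      targets; the dominant group damps the other.
    * ``ASYM_EE_LAGGED``: one-way dominant flux onto excitatory targets with
      conduction delay; the receiver is a lagged copy of the sender.

    ``noise_level`` in [0, 1] perturbs flux magnitudes (s.d. 0.4 *
    noise_level, multiplicative) and adds white noise of matching s.d. to
    the series.  At noise 0 the classifier recovers the label exactly.
    """
    rng = np.random.default_rng(seed)
    n, dt = 400, 1.0
    period = 20.0
    t = np.arange(n) * dt
    base = np.sin(2 * math.pi * t / period)
    lag_steps = 5
    strong, weak = 1.0, 0.25

    if label == "SYM_EE":
        flux = dict(
            flux_ij_E=strong, flux_ij_I=0.1 * strong, flux_ji_E=strong, flux_ji_I=0.1 * strong
        )
        si, sj = base.copy(), base.copy()
    elif label == "SYM_EI_ZERO_ERROR":
        flux = dict(
            flux_ij_E=0.1 * strong, flux_ij_I=strong, flux_ji_E=0.1 * strong, flux_ji_I=strong
        )
        si, sj = base.copy(), base.copy()  # zero-error cancellation keeps zero-lag synchrony
    elif label == "ASYM_EI_CROSS_INHIBITION":
        flux = dict(
            flux_ij_E=0.1 * strong, flux_ij_I=strong, flux_ji_E=0.1 * weak, flux_ji_I=weak
        )
        si = base.copy()
        sj = -0.6 * base + 0.4 * np.sin(2 * math.pi * t / period * 1.5)  # suppressed, distorted
    elif label == "ASYM_EE_LAGGED":
        flux = dict(
            flux_ij_E=strong, flux_ij_I=0.1 * strong, flux_ji_E=weak, flux_ji_I=0.1 * weak
        )
        si = base.copy()
        sj = np.roll(base, lag_steps)  # receiver lags sender by lag_steps
    else:
        raise ValueError(f"unknown motif label {label!r}")

    if noise_level > 0:
        sd = 0.4 * noise_level
        flux = {k: float(v * max(0.0, 1.0 + rng.normal(scale=sd))) for k, v in flux.items()}
        si = si + rng.normal(scale=noise_level, size=n)
        sj = sj + rng.normal(scale=noise_level, size=n)
    return MotifFlux(series_i=si, series_j=sj, dt=dt, **flux)


# ---------------------------------------------------------------------------
# factor-model flux
# ---------------------------------------------------------------------------

def make_factor_flux(
    k_true: int, n_groups: int, n_samples: int, snr: float, seed: int = 0
) -> np.ndarray:
    """k-factor Gaussian flux matrix (n_groups x n_samples).

    ``X = W Z + E`` with orthonormal loading columns scaled by sqrt(snr),
    unit-variance factors Z and unit-variance noise E, so each factor
    contributes a covariance eigenvalue of ``snr`` against a noise floor
    of 1.
    """
    if not 0 < k_true < n_groups:
        raise ValueError("k_true must be in (0, n_groups)")
    rng = np.random.default_rng(seed)
    W = np.linalg.qr(rng.normal(size=(n_groups, k_true)))[0] * math.sqrt(snr)
    Z = rng.normal(size=(k_true, n_samples))
    return W @ Z + rng.normal(size=(n_groups, n_samples))


# ---------------------------------------------------------------------------
# synchronous-equilibrium network
# ---------------------------------------------------------------------------

def synchronous_equilibrium_params(
    n_e: int = 6,
    n_i: int = 6,
    coupling: float = 0.99,
    natural_freq: float = 1.0,
    damping: float = 0.02,
    extent: float = 4.0,
    seed: int = 0,
) -> tuple[OscillatorParams, list[str]]:
    """Oscillator network whose noise-driven ground state is zero-lag synchrony.

    All E-E and I-I couplings are bidirectionally symmetric and positive;
    all E-I couplings are bidirectionally symmetric and negative.  Under
    diffuse noise the in-phase E mode and in-phase I mode then carry the
    most energy (their effective stiffness is lowest) while the favored E-I
    alignment is anti-phase, reproducing the synchronous-equilibrium
    correlation signature.  ``coupling`` is the total coupling strength per
    group as a fraction of the natural stiffness N^2, divided over partners
    to keep the coupled stiffness positive definite.
    """
    m = n_e + n_i
    labels = ["E"] * n_e + ["I"] * n_i
    is_e = np.array([lb == "E" for lb in labels])
    K = np.zeros((m, m))
    same = np.outer(is_e, is_e) | np.outer(~is_e, ~is_e)
    k_each = coupling * natural_freq**2 / (m - 1)
    K[same] = k_each
    K[~same] = -k_each
    np.fill_diagonal(K, 0.0)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, extent, m) + 1j * rng.uniform(0, extent, m)
    params = OscillatorParams(
        D=np.full(m, damping), N=np.full(m, natural_freq), K=K, positions=pos
    )
    return params, labels


# ---------------------------------------------------------------------------
# stimulus ensembles for postnatal experiments
# ---------------------------------------------------------------------------

def structured_sweep_ensemble(
    map_spec,
    frame: GlobalFrame,
    n_epochs_cycle: int = 6,
    radii: tuple[float, ...] = (1.2, 2.0, 2.8),
    angular_speed: float = 0.75,
    duration: float = 16.0,
    dt: float = 0.15,
) -> list[StimulusField]:
    """Repeated rotating-line drive: circumferential sweeps at several radii.

    Each epoch's stimulus is the superposition of same-phase circumferential
    arcs at the given global radii about the map center — a radial line
    rotating about the center — repeated with identical geometry so that
    the induced flux exchanges are predictable epoch over epoch.
    """
    out = []
    for sd in range(n_epochs_cycle):
        parts = [
            make_stimulus(
                StimulusSpec(
                    kind="circumferential_arc",
                    center=map_spec.p0,
                    start=map_spec.p0 + r,
                    speed=angular_speed * r,
                    duration=duration,
                    dt=dt,
                    seed=sd,
                ),
                frame,
            )
            for r in radii
        ]
        out.append(
            StimulusField(
                positions=np.concatenate([p.positions for p in parts]),
                times=np.concatenate([p.times for p in parts]),
                amplitudes=np.concatenate([p.amplitudes for p in parts]),
                frame=frame,
            )
        )
    return out


def diffuse_control_ensemble(
    frame: GlobalFrame,
    n_epochs_cycle: int = 6,
    duration: float = 16.0,
    dt: float = 0.15,
    seed: int = 100,
) -> list[StimulusField]:
    """Unstructured diffuse-noise drive matched in rate to the sweep ensemble."""
    return [
        make_stimulus(
            StimulusSpec(kind="diffuse_noise", duration=duration, dt=dt, seed=seed + sd),
            frame,
        )
        for sd in range(n_epochs_cycle)
    ]
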