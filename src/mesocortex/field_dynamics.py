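"""Stochastic coupled-oscillator neural field and its eigenmode analysis.

Each oscillator is a small group of interacting excitatory and inhibitory
cells; groups are coupled at longer range through excitatory links.  The
synaptic flux phi_i of group i obeys the damped, driven linear equation

    phi_i'' + D_i phi_i' + N_i^2 phi_i = sum_j K_ij phi_j(t - delay_ij) + xi_i(t)

with damping D_i, natural frequency N_i, coupling matrix K, and a diffuse
white-noise drive xi that is white in time and spatially correlated over the
cortical surface by an isotropic Gaussian kernel (the "spatially diffusing"
noise that drives the field toward synchronous equilibrium).  The linear
field has eigenmodes; their frequencies, dampings and time-averaged energies
feed the Gibbs free-energy measure in :mod:`mesocortex.correlation_metrics`.

Integration uses semi-implicit Euler-Maruyama on the first-order companion
system; with noise off and no delays it reproduces the matrix-exponential
solution of the linear ODE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "OscillatorParams",
    "NoiseDrive",
    "FluxSeries",
    "ModalSpectrum",
    "simulate_field",
    "eigenmodes",
    "modal_energies",
    "companion_matrix",
    "UnstableFieldWarning",
]


class UnstableFieldWarning(UserWarning):
    """Warned when the linearized field has a growing mode."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OscillatorParams:
    """Per-group damping D, natural frequency N, coupling matrix K, delays.

    ``D`` (1/time) and ``N`` (rad/time) are per-group vectors; ``K``
    (1/time^2) is the directed coupling matrix with zero diagonal; ``delays``
    (time), if given, holds per-pair conduction delays, quantized to integer
    multiples of dt at simulation time.  ``positions`` (complex cortical
    coordinates) are only needed for spatially correlated noise.
    """

    D: np.ndarray
    N: np.ndarray
    K: np.ndarray
    delays: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.D = np.atleast_1d(np.asarray(self.D, dtype=float))
        self.N = np.atleast_1d(np.asarray(self.N, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        m = len(self.N)
        if len(self.D) != m or self.K.shape != (m, m):
            raise ValueError("D, N, K dimensions disagree")
        if np.any(self.D < 0):
            raise ValueError("damping must be non-negative")
        if np.any(self.N <= 0):
            raise ValueError("natural frequencies must be positive")
        if not np.all(np.isfinite(self.K)):
            raise ValueError("coupling matrix must be finite")
        np.fill_diagonal(self.K, 0.0)
        if self.delays is not None:
            self.delays = np.asarray(self.delays, dtype=float)
            if self.delays.shape != (m, m):
                raise ValueError("delays must be m x m")
            if np.any(self.delays < 0):
                raise ValueError("delays must be non-negative")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=complex)
            if len(self.positions) != m:
                raise ValueError("positions must have one entry per group")

    @property
    def n_groups(self) -> int:
        return len(self.N)


@dataclass(frozen=True)
class NoiseDrive:
    """Diffuse white-noise drive.

    ``amplitude`` (flux/time^1.5) scales the white-noise increments;
    ``bandwidth`` (rad/time), if finite, applies a first-order low-pass of
    that cutoff to the noise (the wide bandwidth W of the drive);
    ``diffusion_length`` (distance) is the scale of the isotropic Gaussian
    spatial correlation over group positions, 0 meaning spatially
    independent noise.
    """

    amplitude: float = 1.0
    bandwidth: float = np.inf
    diffusion_length: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")
        if self.diffusion_length < 0:
            raise ValueError("diffusion length must be non-negative")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class FluxSeries:
    """Per-group synaptic-flux time series phi_i(t) with fixed step dt."""

    values: np.ndarray  # shape (n_groups, n_steps)
    dt: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.labels:
            self.labels = [f"g{i}" for i in range(self.values.shape[0])]

    @property
    def n_groups(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.values.shape[1] * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.dt

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("dt", data=self.dt)
            f.create_dataset("labels", data=np.array(self.labels, dtype="S"))

    @classmethod
    def from_hdf5(cls, path: str) -> "FluxSeries":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                values=f["values"][()],
                dt=float(f["dt"][()]),
                labels=[s.decode() for s in f["labels"][()]],
            )

    def binned(self, factor: int) -> "FluxSeries":
        """Block-mean downsampling by an integer factor (correlogram binning)."""
        if factor < 1:
            raise ValueError("bin factor must be >= 1")
        if factor == 1:
            return FluxSeries(values=self.values.copy(), dt=self.dt, labels=list(self.labels))
        n = (self.values.shape[1] // factor) * factor
        v = self.values[:, :n].reshape(self.n_groups, -1, factor).mean(axis=2)
        return FluxSeries(values=v, dt=self.dt * factor, labels=list(self.labels))

    def to_csv(self, path: str) -> None:
        """Long format: time, group, value."""
        import pandas as pd

        t = self.times
        pd.DataFrame(
            {
                "time": np.repeat(t, self.n_groups),
                "group": np.tile(self.labels, len(t)),
                "value": self.values.T.ravel(),
            }
        ).to_csv(path, index=False)


@dataclass
class ModalSpectrum:
    """Eigenmode frequencies, dampings, and (optionally) modal energies."""

    frequencies: np.ndarray  # rad/time
    dampings: np.ndarray  # 1/time
    energies: np.ndarray | None = None

    @property
    def total_energy(self) -> float:
        if self.energies is None:
            raise ValueError("no energies attached")
        return float(np.sum(self.energies))


# ---------------------------------------------------------------------------
# eigenmodes
# ---------------------------------------------------------------------------

def companion_matrix(params: OscillatorParams) -> np.ndarray:
    """First-order companion matrix [[0, I], [K - diag(N^2), -diag(D)]]."""
    m = params.n_groups
    A = np.zeros((2 * m, 2 * m))
    A[:m, m:] = np.eye(m)
    A[m:, :m] = params.K - np.diag(params.N**2)
    A[m:, m:] = -np.diag(params.D)
    return A


def eigenmodes(params: OscillatorParams) -> ModalSpectrum:
    """Mode frequencies and dampings of the undelayed linear field.

    Eigenvalues of the companion system come in conjugate pairs
    ``lambda = -damping/2 +/- i*frequency``; one mode is reported per group
    (overdamped real pairs count as zero-frequency modes).
    """
    if params.delays is not None and np.any(params.delays > 0):
        raise ValueError("delayed systems are analyzed only by simulation")
    ev = np.linalg.eigvals(companion_matrix(params))
    cplx = np.sort_complex(ev[ev.imag > 1e-12])
    reals = np.sort(ev[np.abs(ev.imag) <= 1e-12].real)
    freqs = [float(z.imag) for z in cplx]
    damps = [float(-2.0 * z.real) for z in cplx]
    for i in range(0, len(reals) - 1, 2):
        freqs.append(0.0)
        damps.append(float(-(reals[i] + reals[i + 1])))
    order = np.argsort(freqs)
    return ModalSpectrum(
        frequencies=np.asarray(freqs)[order], dampings=np.asarray(damps)[order]
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _spatial_noise_mixer(params: OscillatorParams, noise: NoiseDrive) -> np.ndarray | None:
    """Symmetric square root of the Gaussian spatial correlation, or None."""
    if noise.diffusion_length <= 0 or params.positions is None:
        return None
    pos = params.positions
    d2 = np.abs(pos[:, None] - pos[None, :]) ** 2
    C = np.exp(-d2 / (2.0 * noise.diffusion_length**2))
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return V @ np.diag(np.sqrt(w)) @ V.T


def simulate_field(
    params: OscillatorParams,
    noise: NoiseDrive,
    duration: float,
    dt: float,
    seed: int = 0,
    phi0: np.ndarray | None = None,
    dphi0: np.ndarray | None = None,
) -> FluxSeries:
    """Integrate the noise-driven oscillator field.

    Semi-implicit Euler-Maruyama: the velocity is stepped first and the
    updated velocity advances the flux.  Conduction delays are quantized to
    the nearest integer step and served from a ring buffer of past states.
    Identical (params, noise, seed) give bit-identical output.  An unstable
    linearization (growing mode) is flagged with a warning and logged, not
    raised; non-finite values during integration raise.
    """
    m = params.n_groups
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt * float(np.max(params.N)) >= 0.5:
        raise ValueError("dt too coarse: require dt * max(N) < 0.5")
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one step")

    ev = np.linalg.eigvals(companion_matrix(params))
    if np.any(ev.real > 1e-12):
        warnings.warn(
            "unstable configuration: linearized system has a growing mode",
            UnstableFieldWarning,
            stacklevel=2,
        )
        log.warning("simulate_field: unstable configuration (max Re eig = %.3g)", ev.real.max())

    rng = np.random.default_rng(seed)
    phi = np.zeros(m) if phi0 is None else np.asarray(phi0, dtype=float).copy()
    vel = np.zeros(m) if dphi0 is None else np.asarray(dphi0, dtype=float).copy()

    delay_steps = None
    max_delay = 0
    if params.delays is not None and np.any(params.delays > 0):
        delay_steps = np.rint(params.delays / dt).astype(int)
        max_delay = int(delay_steps.max())

    mixer = _spatial_noise_mixer(params, noise)
    sigma = noise.amplitude / np.sqrt(dt)
    lp_alpha = None
    if np.isfinite(noise.bandwidth):
        lp_alpha = dt * noise.bandwidth / (1.0 + dt * noise.bandwidth)
    lp_state = np.zeros(m)

    out = np.empty((m, n_steps))
    ring = np.zeros((max_delay + 1, m)) if delay_steps is not None else None
    if ring is not None:
        ring[0] = phi
    N2 = params.N**2
    D = params.D
    K = params.K
    cols = np.arange(m)[None, :]

    for step in range(n_steps):
        if noise.amplitude > 0:
            xi = rng.standard_normal(m) * sigma
            if mixer is not None:
                xi = mixer @ xi
            if lp_alpha is not None:
                lp_state = lp_state + lp_alpha * (xi - lp_state)
                xi = lp_state
        else:
            xi = 0.0

        if delay_steps is None:
            coupling = K @ phi
        else:
            past = ring[(step - delay_steps) % (max_delay + 1), cols]
            coupling = np.einsum("ij,ij->i", K, past)

        vel = vel + dt * (-D * vel - N2 * phi + coupling + xi)
        phi = phi + dt * vel
        if ring is not None:
            ring[(step + 1) % (max_delay + 1)] = phi
        out[:, step] = phi

    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite flux values during simulation")
    return FluxSeries(values=out, dt=dt)


# ---------------------------------------------------------------------------
# modal energies
# ---------------------------------------------------------------------------

def modal_energies(series: FluxSeries, params: OscillatorParams) -> ModalSpectrum:
    """Time-averaged energy per eigenmode of a simulated trajectory.

    The stiffness matrix S = diag(N^2) - K is symmetrized and
    eigen-decomposed (S = Q W Q^T); the trajectory is projected onto the
    orthonormal mode coordinates q = Q^T phi, and

        U_i = < qdot_i^2 / 2 + w_i q_i^2 / 2 >_t.

    For symmetric coupling the decomposition is exact, so sum(U_i) equals
    the total field energy.  Mode frequencies reported are sqrt(w_i).
    """
    if series.n_groups != params.n_groups:
        raise ValueError("series and params dimensions disagree")
    S = np.diag(params.N**2) - params.K
    asym = np.abs(S - S.T).max()
    if asym > 1e-9:
        log.info("modal_energies: symmetrizing stiffness (asymmetry %.3g)", asym)
    S = 0.5 * (S + S.T)
    w, Q = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    phi = series.values
    vel = np.gradient(phi, series.dt, axis=1)
    q = Q.T @ phi
    qd = Q.T @ vel
    U = 0.5 * np.mean(qd**2, axis=1) + 0.5 * w * np.mean(q**2, axis=1)
    order = np.argsort(np.sqrt(w))
    return ModalSpectrum(
        frequencies=np.sqrt(w)[order],
        dampings=np.sort(params.D),
        energies=U[order],
    )
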