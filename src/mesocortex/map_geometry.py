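"""Global-to-local map geometry of the cortical patch system.

The cortical surface (the *global map*) is modelled as the complex plane.
Long-axon "patch" cells tile it on a roughly hexagonal grid of spacing ``X``
and project onto small clusters of short-axon cells (*local maps*).  The
projection is an angle-multiplying conformal-modulus map

    p = chirality * p' * (P - p0)^n / |P - p0|^(n-1) + p0

with even integer angle exponent ``n``; it multiplies azimuth about the map
center ``p0`` by ``n`` while scaling radius linearly by ``|p'|``.  For
``n = 2`` the local network is a Moebius-strip-like double cover: a full 360
degrees of global azimuth wraps twice around the local center, so stimulus
orientation (which is a direction modulo 180 degrees) is laid out exactly once
per circuit — an orientation-preference (OP) pinwheel singularity.

Conduction delays along patch axons (finite velocity ``nu``) turn the
projection into a spatiotemporal map: global activity arrives in the local
map with delay |P - p| / nu.  The same wiring run backwards yields motor
back-projection with the inverse timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GlobalFrame",
    "LocalMapSpec",
    "StimulusField",
    "LocalActivity",
    "hex_patch_lattice",
    "global_to_local",
    "local_to_global",
    "op_field",
    "op_circuit_coverage",
    "arc_tangent_rotation",
    "moebius_injectivity_check",
    "project_stimulus",
    "tfp_contrast",
    "motor_backproject",
    "superpose_areas",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class GlobalFrame:
    """A rectangular region of cortical surface tiled by patch-cell clusters.

    Parameters
    ----------
    extent
        ``(xmin, xmax, ymin, ymax)`` in cortical distance units.
    patch_centers
        Complex positions of patch-cell cluster centers.
    X
        Patch spacing (distance units): the separation at which long- and
        short-axon axonal densities are equal.
    """

    extent: tuple[float, float, float, float]
    patch_centers: np.ndarray
    X: float

    def __post_init__(self) -> None:
        if self.X <= 0:
            raise ValueError("patch spacing X must be positive")
        xmin, xmax, ymin, ymax = self.extent
        pc = np.asarray(self.patch_centers, dtype=complex)
        object.__setattr__(self, "patch_centers", pc)
        if pc.size and (
            pc.real.min() < xmin - 1e-9
            or pc.real.max() > xmax + 1e-9
            or pc.imag.min() < ymin - 1e-9
            or pc.imag.max() > ymax + 1e-9
        ):
            raise ValueError("patch centers outside extent")

    def contains(self, P: complex) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return xmin - 1e-9 <= P.real <= xmax + 1e-9 and ymin - 1e-9 <= P.imag <= ymax + 1e-9

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlobalFrame):
            return NotImplemented
        return (
            self.extent == other.extent
            and self.X == other.X
            and np.array_equal(self.patch_centers, other.patch_centers)
        )


@dataclass(frozen=True)
class LocalMapSpec:
    """Parameters of one local map (one mesoanatomical unit).

    ``p0`` is the map center (the OP singularity); ``p_prime`` is the complex
    rotation/scale constant (default argument +90 degrees — the projection is
    rotated a quarter turn because patch-to-local presynapses grow in arcs of
    circles radiating from the center); ``n`` is the even angle-multiplication
    exponent; ``chirality`` flips the sense of OP progression; ``nu`` is the
    axonal conduction velocity.
    """

    p0: complex = 0j
    p_prime: complex = 0.1j
    n: int = 2
    chirality: int = 1
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2 != 0:
            raise ValueError("angle exponent must be even and >= 2")
        if abs(self.p_prime) == 0:
            raise ValueError("p_prime must be nonzero")
        if self.chirality not in (-1, 1):
            raise ValueError("chirality must be +1 or -1")
        if self.nu <= 0:
            raise ValueError("conduction velocity nu must be positive")


@dataclass
class StimulusField:
    """Events on the global map: arrays of position P, time t, amplitude."""

    positions: np.ndarray  # complex
    times: np.ndarray
    amplitudes: np.ndarray
    frame: GlobalFrame | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=complex)
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (len(self.positions) == len(self.times) == len(self.amplitudes)):
            raise ValueError("positions, times, amplitudes must have equal length")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class LocalActivity:
    """Events arrived in a local map, with their global source positions."""

    positions: np.ndarray  # local complex positions p
    times: np.ndarray  # arrival times
    amplitudes: np.ndarray
    sources: np.ndarray  # global source positions P

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=complex)
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.sources = np.asarray(self.sources, dtype=complex)

    def __len__(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------

def hex_patch_lattice(X: float, extent: tuple[float, float, float, float]) -> GlobalFrame:
    """Triangular lattice of patch-cluster centers with spacing ``X``.

    Interior points have exactly six neighbors at distance ``X``; this is the
    hexagonal gridwork the patch system forms when clusters reciprocally link
    at multiples of the density-crossing distance.
    """
    if X <= 0:
        raise ValueError("X must be positive")
    xmin, xmax, ymin, ymax = extent
    if min(xmax - xmin, ymax - ymin) < 3 * X:
        raise ValueError("extent sides must be at least 3X")
    dy = X * math.sqrt(3) / 2.0
    centers = []
    row = 0
    y = ymin
    while y <= ymax + 1e-12:
        x0 = xmin + (X / 2.0 if row % 2 else 0.0)
        x = x0
        while x <= xmax + 1e-12:
            centers.append(complex(x, y))
            x += X
        y += dy
        row += 1
    return GlobalFrame(extent=extent, patch_centers=np.array(centers), X=X)


# ---------------------------------------------------------------------------
# projection and inverse
# ---------------------------------------------------------------------------

def global_to_local(P: complex | np.ndarray, spec: LocalMapSpec) -> complex | np.ndarray:
    """Angle-multiplying projection of global position(s) onto the local map.

    ``p = chirality * p' * (P - p0)^n / |P - p0|^(n-1) + p0``.  The modulus
    law is ``|p - p0| = |p'| |P - p0|`` and the argument law is
    ``arg(p - p0) = n arg(P - p0) + arg(p')`` (chirality +1).
    """
    P = np.asarray(P, dtype=complex)
    w = P - spec.p0
    r = np.abs(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = spec.chirality * spec.p_prime * w**spec.n / r ** (spec.n - 1) + spec.p0
    p = np.where(r == 0, spec.p0, p)
    return complex(p) if p.ndim == 0 else p


def local_to_global(
    p: complex | np.ndarray, spec: LocalMapSpec, sheet: int = 0
) -> complex | np.ndarray:
    """Inverse of :func:`global_to_local` on the chosen branch of the n-th root.

    ``sheet`` in ``{0 .. n-1}`` selects which of the n global preimages is
    returned; for n = 2 the two sheets are antipodes about ``p0``, encoding
    the Moebius double cover.
    """
    if not 0 <= sheet < spec.n:
        raise ValueError(f"sheet must be in [0, {spec.n - 1}]")
    p = np.asarray(p, dtype=complex)
    w = (p - spec.p0) / (spec.chirality * spec.p_prime)
    r = np.abs(w)
    theta = (np.angle(w) + 2.0 * math.pi * sheet) / spec.n
    P = np.where(r == 0, spec.p0, spec.p0 + r * np.exp(1j * theta))
    return complex(P) if P.ndim == 0 else P


# ---------------------------------------------------------------------------
# orientation preference
# ---------------------------------------------------------------------------

def op_field(grid: np.ndarray, spec: LocalMapSpec) -> np.ndarray:
    """Orientation preference (degrees mod 180) at local-map points ``grid``.

    The OP assigned to a local cell is the global azimuth whose image falls
    there:  OP(p) = chirality * (arg(p - p0) - arg(p')) / n, in degrees mod
    180.  OP is continuous everywhere except at the singularity p0; for
    n = 2 one circuit of local azimuth sweeps the full 0-180 OP range exactly
    once, which is the pinwheel.
    """
    grid = np.asarray(grid, dtype=complex)
    ang = np.angle(grid - spec.p0) - np.angle(spec.p_prime)
    op = spec.chirality * ang / spec.n * (180.0 / math.pi)
    return np.mod(op, 180.0)


def op_circuit_coverage(spec: LocalMapSpec, n_samples: int = 360, radius: float = 1.0) -> float:
    """OP range (degrees) covered on one closed circuit of global azimuth.

    Samples ``n_samples`` equally spaced global directions on a circle about
    ``p0``, projects each into the local map, evaluates OP at the image
    points, and measures the covered fraction of [0, 180) by binning at the
    sampling resolution.  For n = 2 the circuit covers exactly 180 degrees.
    """
    theta = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    P = spec.p0 + radius * np.exp(1j * theta)
    p = global_to_local(P, spec)
    op = op_field(p, spec)
    n_bins = max(1, n_samples // 2)
    width = 180.0 / n_bins
    hit = np.zeros(n_bins, dtype=bool)
    # half-width offset keeps samples that sit on bin edges from straddling
    hit[np.floor((op + width / 2.0) / width).astype(int) % n_bins] = True
    return float(hit.sum() * width)


def op_circuit_winding(spec: LocalMapSpec, n_samples: int = 360, radius: float = 1.0) -> int:
    """Winding number of OP over one closed circuit of *local* azimuth."""
    alpha = np.linspace(0.0, 2.0 * math.pi, n_samples + 1)
    p = spec.p0 + radius * np.exp(1j * alpha)
    op = op_field(p, spec)
    d = np.diff(op)
    d = (d + 90.0) % 180.0 - 90.0  # wrap increments to (-90, 90]
    return int(round(abs(d.sum()) / 180.0))


def arc_tangent_rotation(X: float, direction: float, ds: float = 1e-6) -> float:
    """Angle (degrees) between a global radial line and its connection-arc image.

    Patch-to-local presynapses grow along arcs of circles of radius ``X``
    radiating from the map center: the arc serving the radial direction
    ``direction`` (radians) lies on the circle of radius ``X`` centered at
    ``X * exp(i*direction)``, which passes through the map center.  The
    tangent of that arc at the center (the entry radius) is computed by
    numerical differentiation of the arc parametrization and compared with
    the radial direction itself.  The developed geometry rotates the
    projection by 90 degrees.
    """
    if X <= 0:
        raise ValueError("X must be positive")
    c = X * np.exp(1j * direction)  # center of the connection arc's circle

    def arc(s: float) -> complex:
        # starts at the map center (origin) when s = 0
        return c + X * np.exp(1j * (math.pi + direction + s))

    tangent = (arc(ds) - arc(-ds)) / (2 * ds)
    ang = abs(math.degrees(np.angle(tangent / np.exp(1j * direction))))
    ang %= 180.0
    return min(ang, 180.0 - ang) if ang > 90.0 else ang


# ---------------------------------------------------------------------------
# Moebius injectivity
# ---------------------------------------------------------------------------

def moebius_injectivity_check(n: int, n_sheets: int = 2, n_samples: int = 360) -> bool:
    """Is the angle-``n`` projection 1:1 onto a cross-linked sheet network?

    The local network is represented as ``n_sheets`` sheets with antipodal
    identification: a global direction theta lands at local angle
    ``n*theta mod 2pi`` on sheet ``floor(n*theta / 2pi) mod n_sheets``.
    Returns True iff the ``n_samples`` distinct sampled global directions
    occupy distinct (sheet, position) states.  On the two-sheet (Moebius)
    network the smallest even exponent that passes is n = 2; a plain disc
    (one sheet) fails because angle doubling is 2-to-1.
    """
    if n % 2 != 0:
        raise ValueError("angle exponent must be even")
    if n < 2:
        raise ValueError("angle exponent must be >= 2")
    if n_sheets < 1:
        raise ValueError("need at least one sheet")
    theta = np.arange(n_samples) / n_samples * 2.0 * math.pi
    local_angle = np.mod(n * theta, 2.0 * math.pi)
    sheet = np.floor(n * theta / (2.0 * math.pi)).astype(int) % n_sheets
    # quantize positions at well below sampling resolution
    q = np.round(local_angle / (2.0 * math.pi) * n_samples * n * 8).astype(int)
    states = set(zip(sheet.tolist(), q.tolist()))
    return len(states) == n_samples


def smallest_injective_exponent(n_sheets: int = 2, candidates: Sequence[int] = (2, 4, 6)) -> int:
    """Smallest even exponent that projects 1:1 onto the sheet network."""
    for n in candidates:
        if moebius_injectivity_check(n, n_sheets=n_sheets):
            return n
    raise ValueError("no candidate exponent is injective")


# ---------------------------------------------------------------------------
# spatiotemporal projection
# ---------------------------------------------------------------------------

def project_stimulus(stim: StimulusField, spec: LocalMapSpec) -> LocalActivity:
    """Relay global events into the local map with conduction delays.

    Each global event (P, t, a) produces the local event
    (p = global_to_local(P), t + |P - p| / nu, a).
    """
    p = np.asarray(global_to_local(stim.positions, spec), dtype=complex)
    delay = np.abs(stim.positions - p) / spec.nu
    return LocalActivity(
        positions=p,
        times=stim.times + delay,
        amplitudes=stim.amplitudes.copy(),
        sources=stim.positions.copy(),
    )


def motor_backproject(local: LocalActivity, spec: LocalMapSpec) -> StimulusField:
    """Inverse timing of the forward relay: efferent command scheduling.

    A local event at time t destined for global target P is emitted at
    t - |P - p| / nu, so that forward re-projection restores the original
    arrival times exactly.
    """
    delay = np.abs(local.sources - local.positions) / spec.nu
    return StimulusField(
        positions=local.sources.copy(),
        times=local.times - delay,
        amplitudes=local.amplitudes.copy(),
    )


def superpose_areas(
    fields: Iterable[StimulusField], spec: LocalMapSpec, coincidence_tol: float = 1e-12
) -> LocalActivity:
    """Superpose interareal inputs on the global frame, then project.

    Events from all fields are unioned; exactly coincident events (same
    position and time within ``coincidence_tol``) have their amplitudes
    summed before projection.  All fields must share a global frame.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("need at least one stimulus field")
    frames = {id(f.frame) for f in fields if f.frame is not None}
    ref = next((f.frame for f in fields if f.frame is not None), None)
    if ref is not None:
        for f in fields:
            if f.frame is not None and f.frame is not ref and f.frame != ref:
                raise ValueError("mismatched global frames")
    P = np.concatenate([f.positions for f in fields])
    t = np.concatenate([f.times for f in fields])
    a = np.concatenate([f.amplitudes for f in fields])
    # merge coincident events by quantized (position, time) key
    scale = 1.0 / max(coincidence_tol, 1e-300)
    key = np.stack(
        [np.round(P.real * scale), np.round(P.imag * scale), np.round(t * scale)], axis=1
    )
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    amp = np.zeros(len(idx))
    np.add.at(amp, inv, a)
    merged = StimulusField(positions=P[idx], times=t[idx], amplitudes=amp, frame=ref)
    return project_stimulus(merged, spec)


# ---------------------------------------------------------------------------
# temporal-frequency-preference contrast
# ---------------------------------------------------------------------------

def tfp_contrast(
    spec: LocalMapSpec,
    speed: float,
    radius: float | None = None,
    path_length: float | None = None,
    n_events: int = 200,
    start_radius: float = 0.5,
) -> tuple[float, float]:
    """Local event-rate frequency for circumferential vs radial motion.

    Moves a point at ``speed`` along (a) a circumferential arc of radius
    ``radius`` about the map center and (b) an outward radial segment of the
    same path length, projects both through the delayed map, and returns the
    mean local event rate (events per unit arrival time) for each.
    Circumferential sources keep near-equal conduction delays, so arrivals
    stay compressed in time (high temporal frequency); radial sources arrive
    with systematically different delays, stretching the arrival train
    (low temporal frequency).
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if radius is None:
        radius = 3.0
    L = path_length if path_length is not None else radius  # arc length
    if L <= 0:
        raise ValueError("degenerate path length")
    tt = np.linspace(0.0, L / speed, n_events)
    # circumferential arc at constant radius
    phi = speed * tt / radius
    P_circ = spec.p0 + radius * np.exp(1j * phi)
    # radial outward segment, same path length and speed
    P_rad = spec.p0 + (start_radius + speed * tt) * np.exp(1j * 0.0)
    amps = np.ones(n_events)

    def rate(P: np.ndarray) -> float:
        stim = StimulusField(positions=P, times=tt, amplitudes=amps)
        loc = project_stimulus(stim, spec)
        span = float(loc.times.max() - loc.times.min())
        if span <= 0:
            raise ValueError("degenerate arrival train")
        return (n_events - 1) / span

    return rate(P_circ), rate(P_rad)
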