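"""Antenatal self-organization and postnatal refinement of the neural field.

**Antenatal growth.**  A population of excitatory cells (long-axon "patch"
cells and short-axon local cells) mixed with short-axon inhibitory cells is
seeded with a very sparse, almost entirely unidirectional random synaptic
scaffold.  Epoch by epoch the field is simulated as noise-driven coupled
oscillators; plasticity then acts on three time scales:

* fast efficacy ``eps`` — facilitated by coincident pre/post activity,
  depressed in proportion to presynaptic rate, recovering to baseline
  (short-term plasticity / depression);
* slow gain ``g`` — the rate-based sliding-threshold rule
  ``dg ~ pre * post * (post - theta)`` with ``theta`` tracking a slow
  average of post^2 (the floating-hook negative feedback that bounds
  growth and enforces competition);
* structural connectivity ``rho`` — grows where the consolidated drive
  ``g * eps`` is sustained above baseline, decays with disuse, and is
  weighted by the overlap of pre- and postsynaptic axonal density profiles,
  which peaks at the crossing distance X of the long- and short-axon
  density curves.

Because the fast coincidence term is symmetric in the pair, correlated
pairs grow *reciprocal* connectivity: the initially unidirectional links
are progressively replaced by bidirectional ones, the exchanged flux and
effective weights converge toward directional symmetry, and the
population free energy F = A - C falls.  Cells that fail to engage in
synchronous oscillation have low synchrony-weighted activity traces and
are eliminated by apoptosis (energy-homeostasis selection); surviving
patch cells end up with partners near distance X.

**Postnatal refinement.**  Structured moving stimuli, projected through the
global-to-local map with conduction delays, replace the diffuse drive.
Co-activated cells strengthen their couplings (breaking the antenatal
rotational symmetry into circumferential/radial anisotropy), and sustained
predictable E->E exchanges reallocate presynapses toward neighboring
inhibitory targets, converting zero-lag synchronous links into zero-error
(Markov-blanket) and cross-inhibition motifs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from mesocortex import field_dynamics as fd
from mesocortex import map_geometry as mg
from mesocortex.correlation_metrics import free_energy_AC

log = logging.getLogger(__name__)

__all__ = [
    "CellPopulation",
    "SynapseState",
    "GrowthTrajectory",
    "GrowthConfig",
    "FastParams",
    "SlowParams",
    "StructuralParams",
    "init_antenatal_field",
    "axon_density",
    "find_X",
    "update_fast",
    "update_slow",
    "structural_update",
    "apoptosis_step",
    "symmetry_indices",
    "run_antenatal_growth",
    "run_postnatal_refinement",
    "patch_cluster_spacing",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CellPopulation:
    """Cells on the cortical plane: position, E/I type, axon class, vitality."""

    positions: np.ndarray  # complex
    cell_type: np.ndarray  # 'E' or 'I'
    axon_class: np.ndarray  # 'patch' (long axon) or 'local' (short axon)
    alive: np.ndarray  # bool
    activity_trace: np.ndarray  # synchrony-weighted exponential average

    def __post_init__(self) -> None:
        n = len(self.positions)
        for name in ("cell_type", "axon_class", "alive", "activity_trace"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any((self.cell_type == "I") & (self.axon_class == "patch")):
            raise ValueError("inhibitory cells are never patch (long-axon) cells")

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def is_e(self) -> np.ndarray:
        return self.cell_type == "E"


@dataclass
class SynapseState:
    """Directed synaptic state: connectivity rho, slow gain g, fast efficacy eps.

    The effective weight of synapse i->j is ``w = rho * g * eps``; dead
    pre- or postsynaptic cells force all three factors to zero.  ``contact``
    marks pairs with axo-dendritic contact (existing links and their
    reverses) on which structural growth may operate.
    """

    rho: np.ndarray
    g: np.ndarray
    eps: np.ndarray
    contact: np.ndarray

    @property
    def w(self) -> np.ndarray:
        return self.rho * self.g * self.eps

    def kill(self, dead: np.ndarray) -> None:
        for a in (self.rho, self.g, self.eps):
            a[dead, :] = 0.0
            a[:, dead] = 0.0
        self.contact[dead, :] = False
        self.contact[:, dead] = False


@dataclass
class GrowthTrajectory:
    """Per-epoch records of an antenatal or postnatal run."""

    records: list[dict] = field(default_factory=list)
    seed: int | None = None
    config_hash: str | None = None

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def series(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records if key in r])

    def to_jsonl(self, path: str) -> None:
        import json

        with open(path, "w") as f:
            if self.seed is not None:
                f.write(json.dumps({"seed": self.seed, "config_hash": self.config_hash}) + "\n")
            for r in self.records:
                f.write(json.dumps(r) + "\n")


@dataclass(frozen=True)
class FastParams:
    """Short-term efficacy dynamics (facilitation, depression, recovery)."""

    baseline: float = 0.5
    eps_max: float = 1.0
    tau_f: float = 10.0  # recovery time constant (epochs or time units)
    a_facil: float = 1.0  # gain on pre/post coincidence
    a_depress: float = 0.1  # gain on presynaptic rate


@dataclass(frozen=True)
class SlowParams:
    """Sliding-threshold gain rule with floating-hook feedback."""

    eta: float = 0.01
    tau_theta: float = 20.0
    g_max: float = 2.0


@dataclass(frozen=True)
class StructuralParams:
    """Structural growth/decay of connectivity."""

    c_grow: float = 0.08
    baseline: float = 0.52  # g*eps level above which growth occurs (rest sits below)
    lam_active: float = 0.005  # decay rate while in use
    lam_disuse: float = 0.1  # decay rate under disuse
    use_threshold: float = 1e-3
    rho_max: float = 1.5
    rho_floor: float = 1e-3  # below this, after the grace period, rho absorbs to 0
    grace_epochs: int = 5


@dataclass(frozen=True)
class GrowthConfig:
    """Study conditions for an antenatal growth run."""

    n_cells: int = 200
    fraction_I: float = 0.2
    fraction_patch: float = 0.3
    sparsity: float = 0.05
    extent: tuple[float, float, float, float] = (0.0, 8.0, 0.0, 8.0)
    # axon density profiles (Gaussian): local taller/narrower, patch wider
    a_local: float = 1.0
    sigma_local: float = 0.5
    a_patch: float = 0.3
    sigma_patch: float = 2.0
    # field simulation per epoch
    natural_freq: float = 1.0
    damping: float = 0.15
    coupling_scale: float = 0.25  # initial spectral fraction of N^2 given to K
    epoch_duration: float = 60.0
    dt: float = 0.1
    noise_amplitude: float = 1.0
    diffusion_length: float = 1.5
    tau_max: float = 3.0
    n_epochs: int = 300
    # plasticity
    fast: FastParams = FastParams()
    slow: SlowParams = SlowParams()
    structural: StructuralParams = StructuralParams()
    plasticity_enabled: bool = True
    plasticity_dt: float = 1.0  # epoch counts as this much plasticity time
    # apoptosis (an early developmental wave: rounds stop after the
    # stop-fraction of the run, when the surviving scaffold consolidates)
    apoptosis_every: int = 10
    apoptosis_quantile: float = 0.05
    apoptosis_stop_fraction: float = 0.6
    min_population: int = 40
    trace_decay: float = 0.3
    synchrony_weight: float = 1.0  # weighting of correlation vs raw rate in the trace
    # analysis
    excitatory_only_coupling: bool = True
    metric_stride: int = 1


# ---------------------------------------------------------------------------
# axon densities
# ---------------------------------------------------------------------------

def axon_density(amplitude: float, sigma: float, distance: np.ndarray | float) -> np.ndarray:
    """Gaussian axonal density profile a * exp(-d^2 / 2 sigma^2)."""
    d = np.asarray(distance, dtype=float)
    return amplitude * np.exp(-(d**2) / (2.0 * sigma**2))


def find_X(a_local: float, sigma_local: float, a_patch: float, sigma_patch: float) -> float:
    """Crossing distance of the short- and long-axon density profiles.

    The local profile must start higher (a_local > a_patch) and fall faster
    (sigma_local < sigma_patch), giving the unique positive crossing

        X = sqrt( 2 ln(a_local/a_patch) * sl^2 sp^2 / (sp^2 - sl^2) ).

    Scaling both amplitudes by a common factor leaves X unchanged.
    """
    if sigma_patch <= sigma_local:
        raise ValueError("X undefined: patch profile must be wider than local")
    if a_local <= a_patch:
        raise ValueError("X undefined: local profile must dominate at the soma")
    sl2, sp2 = sigma_local**2, sigma_patch**2
    return math.sqrt(2.0 * math.log(a_local / a_patch) * sl2 * sp2 / (sp2 - sl2))


def _pair_growth_kernel(cfg: GrowthConfig, dist: np.ndarray) -> np.ndarray:
    """Distance weighting of reciprocal growth: the lesser axonal density.

    Bidirectional monosynaptic contact requires both partners' axons to
    reach; the limiting factor is min(long-axon, short-axon density), which
    peaks exactly at the crossing distance X.  Normalized to max 1.
    """
    lo = axon_density(cfg.a_local, cfg.sigma_local, dist)
    pa = axon_density(cfg.a_patch, cfg.sigma_patch, dist)
    k = np.minimum(lo, pa)
    if k.max() > 0:
        k = k / k.max()
    # floor keeps coincident non-X contacts consolidating at a reduced rate
    return 0.3 + 0.7 * k


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_antenatal_field(
    n_cells: int,
    fraction_I: float,
    fraction_patch: float,
    sparsity: float,
    extent: tuple[float, float, float, float],
    seed: int,
    config: GrowthConfig | None = None,
) -> tuple[CellPopulation, SynapseState]:
    """Seed the sparse, almost entirely unidirectional antenatal scaffold.

    Cell positions are uniform over the extent; a fraction are inhibitory
    (always short-axon) and a fraction of the excitatory cells are
    long-axon patch cells.  Directed links appear independently with
    probability proportional to the presynaptic cell's axonal density at
    the pair distance, scaled so the mean link probability equals
    ``sparsity``; independence makes reciprocal pairs rare (~sparsity^2).
    """
    if not 0 < sparsity < 0.1:
        raise ValueError("sparsity must be in (0, 0.1)")
    if not (0 < fraction_I < 1 and 0 < fraction_patch < 1):
        raise ValueError("fractions must be in (0, 1)")
    cfg = config or GrowthConfig()
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = extent
    pos = rng.uniform(xmin, xmax, n_cells) + 1j * rng.uniform(ymin, ymax, n_cells)
    n_i = int(round(fraction_I * n_cells))
    cell_type = np.array(["I"] * n_i + ["E"] * (n_cells - n_i))
    rng.shuffle(cell_type)
    axon_class = np.full(n_cells, "local", dtype=object)
    e_idx = np.flatnonzero(cell_type == "E")
    n_patch = int(round(fraction_patch * len(e_idx)))
    axon_class[rng.choice(e_idx, size=n_patch, replace=False)] = "patch"

    dist = np.abs(pos[:, None] - pos[None, :])
    dens = np.where(
        (axon_class == "patch")[:, None],
        axon_density(cfg.a_patch, cfg.sigma_patch, dist),
        axon_density(cfg.a_local, cfg.sigma_local, dist),
    )
    # soften the profile for initial wiring: axo-dendritic contact is
    # promiscuous, so locality is mild at this stage and directions stay
    # nearly independent (keeps reciprocal pairs at ~sparsity^2)
    dens = dens**0.3
    np.fill_diagonal(dens, 0.0)
    # per-presynaptic-cell scaling so that the mean link probability is `sparsity`
    row_mean = dens.sum(axis=1) / (n_cells - 1)
    prob = sparsity * dens / np.maximum(row_mean[:, None], 1e-12)
    np.clip(prob, 0.0, min(1.0, 4.0 * sparsity), out=prob)
    # renormalize the mean after capping
    prob *= sparsity / max(prob.sum() / (n_cells * (n_cells - 1)), 1e-12)
    np.clip(prob, 0.0, 1.0, out=prob)
    links = rng.random((n_cells, n_cells)) < prob
    np.fill_diagonal(links, False)

    rho = np.where(links, 1.0, 0.0)
    g = np.where(links, 1.0, 0.0)
    eps = np.where(links, cfg.fast.baseline, 0.0)
    contact = links | links.T  # reverse directions are available for growth
    np.fill_diagonal(contact, False)
    # reverse contacts start structurally silent but plastic
    rev = contact & ~links
    g[rev] = 1.0
    eps[rev] = cfg.fast.baseline

    pop = CellPopulation(
        positions=pos,
        cell_type=cell_type,
        axon_class=np.asarray(axon_class, dtype=object),
        alive=np.ones(n_cells, dtype=bool),
        activity_trace=np.zeros(n_cells),
    )
    syn = SynapseState(rho=rho, g=g, eps=eps, contact=contact)
    return pop, syn


# ---------------------------------------------------------------------------
# plasticity rules
# ---------------------------------------------------------------------------

def update_fast(
    eps: np.ndarray,
    pre_rate: np.ndarray,
    coincidence: np.ndarray,
    dt: float,
    params: FastParams = FastParams(),
) -> np.ndarray:
    """One step of fast efficacy dynamics.

    ``d eps/dt = (baseline - eps)/tau_f + a_facil * coincidence
    - a_depress * pre_rate * eps``; with no activity eps relaxes to
    baseline with time constant tau_f, sustained presynaptic drive settles
    at the depressed fixed point ``(baseline/tau_f + a_f*c) /
    (1/tau_f + a_d*r)``, and a brief coincident burst transiently
    facilitates.  Bounded in [0, eps_max].
    """
    deps = (params.baseline - eps) / params.tau_f
    deps = deps + params.a_facil * coincidence - params.a_depress * pre_rate * eps
    return np.clip(eps + dt * deps, 0.0, params.eps_max)


def update_slow(
    g: np.ndarray,
    pre_rate: np.ndarray,
    post_rate: np.ndarray,
    theta: np.ndarray,
    dt: float,
    params: SlowParams = SlowParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the sliding-threshold gain rule.

    ``dg/dt = eta * pre * post * (post - theta)`` and the threshold tracks
    ``d theta/dt = (post^2 - theta)/tau_theta``: gains grow only for inputs
    whose postsynaptic activity exceeds the floating threshold, which
    itself rises with sustained activity — the negative feedback that makes
    pathway competition selective and keeps gains bounded.
    ``pre_rate``/``post_rate`` broadcast over the (pre, post) matrix axes.
    """
    dg = params.eta * pre_rate * post_rate * (post_rate - theta)
    g_new = np.clip(g + dt * dg, 0.0, params.g_max)
    theta_new = theta + dt * (np.asarray(post_rate, dtype=float) ** 2 - theta) / params.tau_theta
    return g_new, theta_new


def structural_update(
    rho: np.ndarray,
    g: np.ndarray,
    eps: np.ndarray,
    usage: np.ndarray,
    dt: float,
    params: StructuralParams = StructuralParams(),
    growth_kernel: np.ndarray | float = 1.0,
    dormant_epochs: np.ndarray | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """One step of structural connectivity change.

    Growth is cumulative on the consolidated fast and slow changes:
    ``d rho/dt = c_grow * kernel * max(g*eps - baseline, 0) - lam * rho``
    with ``lam = lam_active`` for synapses in use and ``lam_disuse`` under
    disuse (usage below threshold).  ``growth_kernel`` carries the axonal
    density overlap weighting.  A synapse whose rho has sat below
    ``rho_floor`` for more than ``grace_epochs`` (tracked in
    ``dormant_epochs`` by the caller) is absorbed to exactly zero.  With
    ``normalize`` the total outgoing rho of each cell is rescaled to its
    pre-update total (global competition for presynaptic resource).
    """
    drive = np.maximum(g * eps - params.baseline, 0.0)
    used = usage >= params.use_threshold
    lam = np.where(used, params.lam_active, params.lam_disuse)
    rho_new = rho + dt * (params.c_grow * growth_kernel * drive - lam * rho)
    np.clip(rho_new, 0.0, params.rho_max, out=rho_new)
    if dormant_epochs is not None:
        rho_new[(dormant_epochs > params.grace_epochs) & (rho_new < params.rho_floor)] = 0.0
    if normalize:
        before = rho.sum(axis=1, keepdims=True)
        after = rho_new.sum(axis=1, keepdims=True)
        scale = np.where(after > 0, before / np.maximum(after, 1e-300), 1.0)
        rho_new = rho_new * scale
    return rho_new


# ---------------------------------------------------------------------------
# apoptosis and symmetry metrics
# ---------------------------------------------------------------------------

def apoptosis_step(
    pop: CellPopulation,
    syn: SynapseState,
    quantile: float = 0.05,
    min_population: int = 40,
    energy_floor: float = 0.75,
) -> int:
    """Eliminate the cells least engaged in synchronous activity.

    Live cells are eligible for elimination only when their
    synchrony-weighted activity trace falls below ``energy_floor`` times
    the live median (the energy-homeostasis criterion: only genuinely
    under-consuming cells die); of the eligible, those at or below the
    ``quantile`` value of the live traces are removed and their synapses
    zeroed.  Equal traces remove nobody (the strict-inequality tie rule:
    a uniform population has no under-consumers).  Never reduces the
    population below ``min_population``; refuses (raises) if the criterion
    would kill more than half the live cells in one round.  Returns the
    number of cells removed.
    """
    live = np.flatnonzero(pop.alive)
    if live.size <= min_population:
        return 0
    traces = pop.activity_trace[live]
    floor = energy_floor * float(np.median(traces))
    cut = np.quantile(traces, quantile)
    victims = live[(traces <= cut) & (traces < floor)]
    if victims.size > 0.5 * live.size:
        raise RuntimeError("apoptosis guard: criterion would kill more than half the population")
    if live.size - victims.size < min_population:
        order = np.argsort(pop.activity_trace[victims])
        victims = victims[order][: live.size - min_population]
    if victims.size:
        pop.alive[victims] = False
        dead = np.zeros(pop.n_cells, dtype=bool)
        dead[victims] = True
        syn.kill(dead)
    return int(victims.size)


def symmetry_indices(
    weights: np.ndarray, flux: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Directional asymmetry of flux and of effective weights, both in [0, 1].

    ``sum_{i<j} |x_ij - x_ji| / sum_{i<j} (x_ij + x_ji)`` over (masked)
    pairs: 0 for perfect bidirectional symmetry, 1 for fully unidirectional
    exchange.  All-zero input is undefined and returns NaN with a logged
    warning.
    """

    def _index(x: np.ndarray) -> float:
        xu = np.triu(x, 1)
        xl = np.triu(x.T, 1)
        if mask is not None:
            mu = np.triu(mask | mask.T, 1)
            xu, xl = xu * mu, xl * mu
        tot = (xu + xl).sum()
        if tot == 0:
            log.warning("symmetry_indices: all-zero input, index undefined")
            return float("nan")
        return float(np.abs(xu - xl).sum() / tot)

    return _index(np.asarray(flux, dtype=float)), _index(np.asarray(weights, dtype=float))


# ---------------------------------------------------------------------------
# antenatal run
# ---------------------------------------------------------------------------

def _coupling_from_weights(
    w: np.ndarray,
    is_e: np.ndarray,
    cfg: GrowthConfig,
    scale: float | None = None,
    stability_cap: float = 0.9,
) -> tuple[np.ndarray, float]:
    """Directed coupling matrix K from effective weights.

    Presynaptic inhibitory cells contribute negative coupling.  On the
    first call (``scale`` None) a fixed conversion factor is chosen so the
    initial spectral radius is ``coupling_scale * N^2``; later epochs reuse
    that factor, so consolidation of synaptic weights genuinely increases
    total coupling.  If growth would push the spectral radius past
    ``stability_cap * N^2`` the matrix is clipped back to the cap (the
    field saturates near, but below, instability).  Returns (K, scale).
    """
    signed = np.where(is_e[:, None], w, -w)  # row = presynaptic
    K = signed.T.copy()  # K[i, j]: i receives from j
    if cfg.excitatory_only_coupling:
        K = np.clip(K, 0.0, None)
    if not K.any():
        return K, (scale if scale is not None else 1.0)
    ev = np.linalg.eigvals(K)
    r = np.abs(ev).max()
    if scale is None:
        scale = cfg.coupling_scale * cfg.natural_freq**2 / r if r > 0 else 1.0
    # largest multiple of K that keeps every companion eigenvalue in the
    # stable half-plane with margin: for an eigenvalue k of K the oscillator
    # eigenvalues are -D/2 +/- sqrt(D^2/4 - N^2 + k), stable (with margin)
    # iff |k - q| + Re(k - q) <= 2*(stability_cap*D/2)^2, q = N^2 - D^2/4.
    # Asymmetric coupling (complex k) therefore caps earlier than symmetric:
    # symmetrization genuinely buys stable coupling strength.
    D = cfg.damping
    q = cfg.natural_freq**2 - D**2 / 4.0
    bound = 2.0 * (stability_cap * D / 2.0) ** 2

    def stable(sc: float) -> bool:
        z = sc * ev - q
        return bool(np.all(np.abs(z) + z.real <= bound))

    s_use = scale
    if not stable(s_use):
        lo, hi = 0.0, s_use
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if stable(mid):
                lo = mid
            else:
                hi = mid
        s_use = lo
    return K * s_use, scale


def _epoch_rates_and_corr(
    series: fd.FluxSeries, tau_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell oscillation rates (s.d. of flux) and zero-lag correlations."""
    v = series.values
    rates = v.std(axis=1)
    ok = rates > 0
    Z = np.zeros_like(v)
    Z[ok] = (v[ok] - v[ok].mean(axis=1, keepdims=True)) / rates[ok, None]
    R0 = Z @ Z.T / v.shape[1]
    return rates, R0


def run_antenatal_growth(config: GrowthConfig, seed: int = 0) -> tuple[
    GrowthTrajectory, CellPopulation, SynapseState
]:
    """Full antenatal self-organization run.

    Alternates field simulation, plasticity (fast within the epoch, slow
    and structural between epochs), and periodic apoptosis; logs per-epoch
    free energy F = A - C, flux and weight asymmetry, reciprocal-pair
    fraction, and live-cell count.  Raises on population extinction.
    """
    cfg = config
    pop, syn = init_antenatal_field(
        cfg.n_cells, cfg.fraction_I, cfg.fraction_patch, cfg.sparsity, cfg.extent, seed, cfg
    )
    rng = np.random.default_rng(seed + 1)
    traj = GrowthTrajectory(seed=seed)
    coupling_conv: float | None = None
    removed_prev = 0
    # threshold starts at the homeostatic fixed point of the normalized rates
    theta = np.ones(pop.n_cells)
    dormant = np.zeros((pop.n_cells, pop.n_cells), dtype=int)
    dist = np.abs(pop.positions[:, None] - pop.positions[None, :])
    kernel = _pair_growth_kernel(cfg, dist)

    for epoch in range(cfg.n_epochs):
        live = pop.alive
        idx = np.flatnonzero(live)
        if idx.size == 0:
            raise RuntimeError("population extinction; trajectory: " + repr(traj.records[-5:]))
        w_live = syn.w[np.ix_(idx, idx)]
        K_live, coupling_conv = _coupling_from_weights(
            w_live, pop.is_e[idx], cfg, scale=coupling_conv
        )
        params = fd.OscillatorParams(
            D=np.full(idx.size, cfg.damping),
            N=np.full(idx.size, cfg.natural_freq),
            K=K_live,
            positions=pop.positions[idx],
        )
        noise = fd.NoiseDrive(
            amplitude=cfg.noise_amplitude, diffusion_length=cfg.diffusion_length
        )
        series = fd.simulate_field(
            params,
            noise,
            cfg.epoch_duration,
            cfg.dt,
            seed=int(rng.integers(2**31 - 1)),
        )
        rates, R0 = _epoch_rates_and_corr(series, cfg.tau_max)
        # homeostatic scaling: plasticity sees rates relative to the
        # population mean, so epoch-to-epoch amplitude drift cancels
        mean_rate = rates[rates > 0].mean() if np.any(rates > 0) else 1.0
        rates = rates / max(mean_rate, 1e-12)

        # flux i->j: presynaptic rate through the effective weight
        flux_live = w_live * rates[:, None]

        # synchrony-weighted survival trace: rate x mean positive correlation
        # with connected partners
        conn = (w_live > 0) | (w_live.T > 0)
        posR = np.clip(R0, 0.0, None)
        with np.errstate(invalid="ignore"):
            mean_sync = np.where(
                conn.sum(axis=1) > 0, (posR * conn).sum(axis=1) / np.maximum(conn.sum(axis=1), 1), 0.0
            )
        engagement = rates * (1.0 + cfg.synchrony_weight * mean_sync)
        pop.activity_trace[idx] = (
            (1 - cfg.trace_decay) * pop.activity_trace[idx] + cfg.trace_decay * engagement
        )

        if epoch % cfg.metric_stride == 0 or epoch == cfg.n_epochs - 1:
            structure = free_energy_AC(
                series,
                labels=list(pop.cell_type[idx]),
                tau_max=min(cfg.tau_max, series.duration / 4 - series.dt),
            )
            w_now = syn.w[np.ix_(idx, idx)]
            flux_now = w_now * rates[:, None]
            fa, wa = symmetry_indices(w_now, flux_now)
            present = syn.rho[np.ix_(idx, idx)] > cfg.structural.rho_floor
            n_links = present.sum()
            n_recip = (present & present.T).sum()
            m_live = idx.size
            traj.append(
                epoch=epoch,
                F_AC=structure.F,
                # free energy per ordered pair: the population-size-free form
                # in which minimization continues as cells are eliminated
                F_AC_per_pair=structure.F / max(m_live * (m_live - 1), 1),
                C=structure.C,
                flux_asymmetry=fa,
                weight_asymmetry=wa,
                live_cells=int(pop.alive.sum()),
                reciprocal_fraction=float(n_recip / max(n_links, 1)),
                removed=removed_prev,
            )
        if cfg.plasticity_enabled:
            contact_live = syn.contact[np.ix_(idx, idx)]
            coincidence = np.clip(R0, 0.0, None) * contact_live
            eps_live = syn.eps[np.ix_(idx, idx)]
            eps_new = update_fast(
                eps_live, rates[:, None], coincidence, cfg.plasticity_dt, cfg.fast
            )
            g_live = syn.g[np.ix_(idx, idx)]
            g_new, theta_live = update_slow(
                g_live, rates[:, None], rates[None, :], theta[idx], cfg.plasticity_dt, cfg.slow
            )
            theta[idx] = theta_live
            rho_live = syn.rho[np.ix_(idx, idx)]
            usage = flux_live
            dorm_live = dormant[np.ix_(idx, idx)]
            rho_new = structural_update(
                rho_live,
                g_new,
                eps_new,
                usage,
                cfg.plasticity_dt,
                cfg.structural,
                growth_kernel=kernel[np.ix_(idx, idx)],
                dormant_epochs=dorm_live,
            )
            rho_new = rho_new * contact_live  # growth only at axo-dendritic contacts
            dorm_live = np.where(rho_new < cfg.structural.rho_floor, dorm_live + 1, 0)
            dormant[np.ix_(idx, idx)] = dorm_live
            syn.eps[np.ix_(idx, idx)] = eps_new * contact_live
            syn.g[np.ix_(idx, idx)] = g_new * contact_live
            syn.rho[np.ix_(idx, idx)] = rho_new

        removed = 0
        in_wave = epoch < cfg.apoptosis_stop_fraction * cfg.n_epochs
        if cfg.apoptosis_every and in_wave and (epoch + 1) % cfg.apoptosis_every == 0:
            def _live_radius() -> float:
                live_now = np.flatnonzero(pop.alive)
                w_now = syn.w[np.ix_(live_now, live_now)]
                sgn = np.where(pop.is_e[live_now][:, None], w_now, -w_now).T
                if cfg.excitatory_only_coupling:
                    sgn = np.clip(sgn, 0.0, None)
                return float(np.abs(np.linalg.eigvals(sgn)).max()) if sgn.any() else 0.0

            r_before = _live_radius()
            removed = apoptosis_step(pop, syn, cfg.apoptosis_quantile, cfg.min_population)
            if removed and coupling_conv is not None:
                # synaptic scaling: surviving couplings are homeostatically
                # upregulated so the field's effective coupling is continuous
                # across the removal
                r_after = _live_radius()
                if r_after > 0 and r_before > 0:
                    coupling_conv *= r_before / r_after

        removed_prev = removed

    return traj, pop, syn


def patch_cluster_spacing(pop: CellPopulation, link_radius: float) -> tuple[float, np.ndarray]:
    """Modal nearest-cluster spacing of surviving patch cells.

    Surviving patch cells are grouped by single-linkage at ``link_radius``
    (half the expected spacing is a natural choice); the modal
    nearest-neighbor distance between cluster centroids is returned with
    the full distance set.
    """
    sel = pop.alive & (np.asarray(pop.axon_class) == "patch")
    pts = pop.positions[sel]
    if pts.size < 2:
        raise ValueError("not enough surviving patch cells")
    # single-linkage clustering via union-find on the link graph
    n = len(pts)
    parent = np.arange(n)

    def root(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d = np.abs(pts[:, None] - pts[None, :])
    for a in range(n):
        for b in range(a + 1, n):
            if d[a, b] <= link_radius:
                ra, rb = root(a), root(b)
                if ra != rb:
                    parent[rb] = ra
    labels = np.array([root(a) for a in range(n)])
    centers = np.array([pts[labels == lb].mean() for lb in np.unique(labels)])
    if len(centers) < 2:
        raise ValueError("fewer than two patch clusters")
    dc = np.abs(centers[:, None] - centers[None, :])
    np.fill_diagonal(dc, np.inf)
    nn = dc.min(axis=1)
    if len(nn) >= 4 and nn.std() > 0:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(nn)
        grid = np.linspace(nn.min(), nn.max(), 512)
        modal = float(grid[int(np.argmax(kde(grid)))])
    else:
        modal = float(np.median(nn))
    return modal, nn


# ---------------------------------------------------------------------------
# postnatal refinement
# ---------------------------------------------------------------------------

def make_local_map_field(
    spec: mg.LocalMapSpec,
    n_rings_cells: int = 3,
    n_angles: int = 12,
    n_i: int = 12,
    n_patch: int = 8,
    ring_radii: tuple[float, ...] = (0.6, 1.0, 1.4),
    contact_radius: float = 0.8,
    seed: int = 0,
) -> tuple[CellPopulation, SynapseState]:
    """Construct a developed local-map field with antenatal statistics.

    A controlled stand-in for the output of a long antenatal run, dense
    enough inside one local map for stable postnatal statistics: local
    excitatory cells on rings about the map center, inhibitory partners
    interleaved, and patch (long-axon) cells projecting reciprocally onto
    all local cells.  All contacts start reciprocal and consolidated
    (rho = 1, g = 1, eps = 0.8), the rotationally symmetric end state of
    antenatal growth.
    """
    rng = np.random.default_rng(seed)
    pos: list[complex] = []
    ctype: list[str] = []
    aclass: list[str] = []
    for r in ring_radii[:n_rings_cells]:
        for a in range(n_angles):
            ang = 2 * math.pi * (a + 0.5 * (r != ring_radii[0])) / n_angles
            pos.append(spec.p0 + (r + 0.02 * rng.standard_normal()) * np.exp(1j * ang))
            ctype.append("E")
            aclass.append("local")
    for k in range(n_i):
        ang = 2 * math.pi * k / n_i + 0.2
        r = 0.8 + 0.4 * (k % 2)
        pos.append(spec.p0 + r * np.exp(1j * ang))
        ctype.append("I")
        aclass.append("local")
    for k in range(n_patch):
        ang = 2 * math.pi * k / n_patch + 0.1
        pos.append(spec.p0 + 1.2 * np.exp(1j * ang))
        ctype.append("E")
        aclass.append("patch")
    positions = np.asarray(pos, dtype=complex)
    cell_type = np.asarray(ctype)
    axon_class = np.asarray(aclass, dtype=object)
    n = len(positions)
    dist = np.abs(positions[:, None] - positions[None, :])
    contact = dist <= contact_radius
    is_patch = axon_class == "patch"
    contact |= is_patch[:, None] | is_patch[None, :]  # long axons reach everyone
    np.fill_diagonal(contact, False)
    rho = np.where(contact, 1.0, 0.0)
    # a residue of one-way links survives antenatal symmetrization
    one_way = (rng.random((n, n)) < 0.15) & contact & contact.T
    one_way &= np.triu(np.ones((n, n), dtype=bool), 1)
    rho[one_way.T] = 0.0
    g = np.where(contact, 1.0, 0.0)
    eps = np.where(contact, 0.8, 0.0)
    pop = CellPopulation(
        positions=positions,
        cell_type=cell_type,
        axon_class=axon_class,
        alive=np.ones(n, dtype=bool),
        activity_trace=np.ones(n),
    )
    return pop, SynapseState(rho=rho, g=g, eps=eps, contact=contact)


@dataclass(frozen=True)
class PostnatalConfig:
    """Study conditions for postnatal refinement of one local map."""

    n_epochs: int = 40
    n_time_bins: int = 100
    bin_width: float = 0.2
    local_radius: float = 1.8  # radius of the refined local map about p0
    deposit_sigma: float = 0.15  # arrival deposit spread for short-axon cells
    patch_deposit_sigma: float = 0.8  # long-axon cells integrate over a wide radius
    noise_rate: float = 0.05
    realloc_threshold: float = 0.5  # coincidence needed to count one exceedance
    realloc_fraction: float = 0.5
    realloc_bin_factor: int = 5  # predictability judged on coarsened rates
    realloc_ema_beta: float = 0.3  # epoch-memory of exceedances
    realloc_ema_gate: float = 0.5  # sustained-predictability gate
    coactivation_eta: float = 0.03
    flux_floor: float = 1e-3
    theta_sym: float = 0.2
    lag_floor_steps: int = 2
    n_sectors: int = 6
    n_rings: int = 1


def _local_cell_rates(
    pop: CellPopulation,
    idx: np.ndarray,
    activity: mg.LocalActivity,
    cfg: PostnatalConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-cell rate series from projected arrival events plus a noise floor.

    Short-axon cells respond to arrivals within a narrow deposit radius;
    long-axon (patch) cells integrate arrivals over a much wider radius,
    reflecting their map-wide dendritic/axonal reach.
    """
    n_bins = cfg.n_time_bins
    rates = rng.normal(scale=cfg.noise_rate, size=(idx.size, n_bins))
    sigma = np.where(
        np.asarray(pop.axon_class)[idx] == "patch",
        cfg.patch_deposit_sigma,
        cfg.deposit_sigma,
    )
    if len(activity):
        t0 = activity.times.min()
        bins = np.clip(((activity.times - t0) / cfg.bin_width).astype(int), 0, n_bins - 1)
        for b, p_ev, a_ev in zip(bins, activity.positions, activity.amplitudes):
            dist = np.abs(pop.positions[idx] - p_ev)
            rates[:, b] += a_ev * np.exp(-(dist**2) / (2 * sigma**2))
    return rates


def _group_cells(
    pop: CellPopulation, idx: np.ndarray, spec: mg.LocalMapSpec, cfg: PostnatalConfig
) -> np.ndarray:
    """Partition local cells into angular-sector x radial-ring groups."""
    z = pop.positions[idx] - spec.p0
    ang = np.mod(np.angle(z), 2 * math.pi)
    sector = np.minimum((ang / (2 * math.pi) * cfg.n_sectors).astype(int), cfg.n_sectors - 1)
    r = np.abs(z)
    edges = np.quantile(r, np.linspace(0, 1, cfg.n_rings + 1)[1:-1]) if cfg.n_rings > 1 else []
    ring = np.searchsorted(edges, r)
    return sector * cfg.n_rings + ring


def motif_census(
    pop: CellPopulation,
    syn: SynapseState,
    idx: np.ndarray,
    groups: np.ndarray,
    rate_series: np.ndarray,
    cfg: PostnatalConfig,
) -> dict:
    """Count Fig-style motif labels over all assessed group pairs."""
    from mesocortex.fixtures import MotifFlux
    from mesocortex.motif_blanket import classify_pair_motif

    w = syn.w[np.ix_(idx, idx)]
    is_e = pop.is_e[idx]
    uniq = np.unique(groups)
    census = {lb: 0 for lb in ("SYM_EE", "SYM_EI_ZERO_ERROR", "ASYM_EI_CROSS_INHIBITION", "ASYM_EE_LAGGED", "NONE")}
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            ga = groups == uniq[a]
            gb = groups == uniq[b]
            f_ab_E = float(w[np.ix_(ga & is_e, gb & is_e)].sum())
            f_ab_I = float(w[np.ix_(ga & is_e, gb & ~is_e)].sum())
            f_ba_E = float(w[np.ix_(gb & is_e, ga & is_e)].sum())
            f_ba_I = float(w[np.ix_(gb & is_e, ga & ~is_e)].sum())
            sa = rate_series[ga & is_e].mean(axis=0) if (ga & is_e).any() else np.zeros(rate_series.shape[1])
            sb = rate_series[gb & is_e].mean(axis=0) if (gb & is_e).any() else np.zeros(rate_series.shape[1])
            mf = MotifFlux(
                flux_ij_E=f_ab_E, flux_ij_I=f_ab_I, flux_ji_E=f_ba_E, flux_ji_I=f_ba_I,
                series_i=sa, series_j=sb, dt=cfg.bin_width,
            )
            lab = classify_pair_motif(
                mf, theta_sym=cfg.theta_sym, lag_floor_steps=cfg.lag_floor_steps,
                flux_floor=cfg.flux_floor,
            )
            census[lab.label] += 1
    return census


def circ_radial_ratio(
    pop: CellPopulation, syn: SynapseState, idx: np.ndarray, spec: mg.LocalMapSpec
) -> float:
    """Ratio of circumferential to radial local E-E connection weight.

    Restricted to short-axon (local) excitatory pairs — the intra-map
    connectivity whose antenatal rotational symmetry structured input
    breaks.  A pair is circumferential when the separation vector is closer
    to the tangential direction at the pair midpoint than to the radial one.
    """
    z = pop.positions[idx] - spec.p0
    is_e = pop.is_e[idx] & (np.asarray(pop.axon_class)[idx] != "patch")
    w = syn.w[np.ix_(idx, idx)]
    mid = 0.5 * (z[:, None] + z[None, :])
    sep = z[None, :] - z[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        radial_dir = mid / np.abs(mid)
    cosr = np.abs((sep * np.conj(radial_dir)).real) / np.maximum(np.abs(sep), 1e-12)
    ee = np.outer(is_e, is_e)
    np.fill_diagonal(ee, False)
    circ_mask = (cosr < math.sqrt(0.5)) & ee
    rad_mask = (cosr >= math.sqrt(0.5)) & ee
    wc = w[circ_mask].sum()
    wr = w[rad_mask].sum()
    return float(wc / max(wr, 1e-12))


def run_postnatal_refinement(
    pop: CellPopulation,
    syn: SynapseState,
    spec: mg.LocalMapSpec,
    stimuli: list,
    config: PostnatalConfig = PostnatalConfig(),
    seed: int = 0,
    slow: SlowParams = SlowParams(),
) -> tuple[GrowthTrajectory, dict, dict]:
    """Refine an antenatal field under structured (or control) stimulation.

    ``stimuli`` is a list of StimulusField objects, one drive per epoch
    (cycled).  Each epoch: project the stimulus into the local map with
    conduction delays, derive per-cell rate series, strengthen couplings
    between co-activated excitatory cells (symmetry-breaking Hebbian
    consolidation), and — where a sustained, predictable E->E exchange has
    formed (coincidence above ``realloc_threshold``) — shift a fraction of
    the presynaptic connectivity to the nearest inhibitory neighbor of the
    target, converting synchronous links into zero-error / cross-inhibition
    couplings.  Returns the trajectory and the motif census before and
    after.
    """
    rng = np.random.default_rng(seed)
    near = np.abs(pop.positions - spec.p0) <= config.local_radius
    idx = np.flatnonzero(pop.alive & near)
    if idx.size == 0:
        raise RuntimeError("no live cells in the local map")
    groups = _group_cells(pop, idx, spec, config)
    is_e = pop.is_e[idx]
    is_patch = np.asarray(pop.axon_class)[idx] == "patch"
    local_e = is_e & ~is_patch
    traj = GrowthTrajectory(seed=seed)

    # nearest inhibitory neighbor of every cell (for presynapse reallocation)
    i_idx = np.flatnonzero(~is_e)
    nearest_i = np.zeros(idx.size, dtype=int)
    if i_idx.size:
        for a in range(idx.size):
            d = np.abs(pop.positions[idx[a]] - pop.positions[idx[i_idx]])
            nearest_i[a] = i_idx[int(np.argmin(d))]

    census_before: dict | None = None
    rates = None
    predict_ema = np.zeros((idx.size, idx.size))
    for epoch in range(config.n_epochs):
        stim = stimuli[epoch % len(stimuli)]
        activity = mg.project_stimulus(stim, spec) if len(stim) else mg.LocalActivity(
            positions=np.array([], dtype=complex), times=np.array([]),
            amplitudes=np.array([]), sources=np.array([], dtype=complex),
        )
        rates = _local_cell_rates(pop, idx, activity, config, rng)
        if census_before is None:
            census_before = motif_census(pop, syn, idx, groups, rates, config)

        # co-variation is judged on time-coarsened rates: a moving stimulus
        # activates the cells it sweeps over sequentially, so cells driven
        # by the same sweep co-vary at the sweep timescale, not bin by bin
        f = max(1, config.realloc_bin_factor)
        nb = (rates.shape[1] // f) * f
        coarse = rates[:, :nb].reshape(rates.shape[0], -1, f).mean(axis=2)
        csd = coarse.std(axis=1)
        cok = csd > 0
        Zc = np.zeros_like(coarse)
        Zc[cok] = (coarse[cok] - coarse[cok].mean(axis=1, keepdims=True)) / csd[cok, None]
        co_all = np.clip(Zc @ Zc.T / coarse.shape[1], 0.0, None)

        # Hebbian consolidation between co-activated short-axon E cells:
        # the intra-map coupling whose anisotropy encodes the stimulus
        contact = syn.contact[np.ix_(idx, idx)]
        co = co_all * np.outer(local_e, local_e) * contact
        g_live = syn.g[np.ix_(idx, idx)]
        g_live = np.clip(g_live + config.coactivation_eta * co * (g_live > 0), 0.0, slow.g_max)
        syn.g[np.ix_(idx, idx)] = g_live

        # presynapse reallocation E->E  =>  E->I where exchange is predictable
        # zero-error conversion acts on the patch/local exchange (both
        # directions): predictable flux between a long-axon cell and a
        # local cell shifts its presynapse to the target's inhibitory
        # partner, replacing zero-lag synchrony by mutual cancellation
        patch_local = np.outer(is_patch, is_e) | np.outer(local_e, is_patch & is_e)
        co_coarse = co_all * patch_local * contact
        # predictability = the same exchange exceeding threshold epoch after
        # epoch; unstructured drive lights up different pairs each time and
        # never accumulates
        beta = config.realloc_ema_beta
        predict_ema = (1 - beta) * predict_ema + beta * (
            co_coarse > config.realloc_threshold
        )
        rho_live = syn.rho[np.ix_(idx, idx)]
        strong = (predict_ema > config.realloc_ema_gate) & (rho_live > 0)
        pre_a, post_a = np.nonzero(strong)
        for a, b in zip(pre_a, post_a):
            tgt = nearest_i[b]
            if tgt == b or not i_idx.size:
                continue
            moved = config.realloc_fraction * rho_live[a, b]
            rho_live[a, b] -= moved
            rho_live[a, tgt] += moved
            if syn.g[idx[a], idx[tgt]] == 0:
                syn.g[idx[a], idx[tgt]] = 1.0
            if syn.eps[idx[a], idx[tgt]] == 0:
                syn.eps[idx[a], idx[tgt]] = FastParams().baseline
            syn.contact[idx[a], idx[tgt]] = True
        syn.rho[np.ix_(idx, idx)] = rho_live
        contact = syn.contact[np.ix_(idx, idx)]

        census = motif_census(pop, syn, idx, groups, rates, config)
        traj.append(
            epoch=epoch,
            zero_error_motifs=census["SYM_EI_ZERO_ERROR"],
            cross_inhibition_motifs=census["ASYM_EI_CROSS_INHIBITION"],
            sym_ee_motifs=census["SYM_EE"],
            circ_radial_ratio=circ_radial_ratio(pop, syn, idx, spec),
        )
    census_after = motif_census(pop, syn, idx, groups, rates, config)
    return traj, census_before, census_after
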