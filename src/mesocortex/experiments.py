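"""Named end-to-end experiments and their orchestration.

Each experiment is a pure function of a RunConfig; `run_experiment`
dispatches by name, creates the output directory, and writes metrics
(JSON-lines), figure artifacts, and a manifest carrying the seed, config
hash and library versions, so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from mesocortex import correlation_metrics as cm
from mesocortex import field_dynamics as fd
from mesocortex import fixtures as fx
from mesocortex import growth_engine as ge
from mesocortex import map_geometry as mg

log = logging.getLogger(__name__)

EXPERIMENTS = (
    "antenatal_growth",
    "postnatal_refinement",
    "opmap_render",
    "tfp_contrast",
    "acceptance_suite",
)

__all__ = [
    "RunConfig",
    "run_experiment",
    "render_op_map",
    "synchrony_signature_experiment",
    "zero_lag_experiment",
    "op_targets",
    "EXPERIMENTS",
]


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    experiment: str = "opmap_render"
    seed: int = 0
    out_dir: str = "runs"
    name: str | None = None
    # map geometry
    map_center: complex = 4 + 4j
    p_prime: complex = 0.5j
    n_exponent: int = 2
    chirality: int = 1
    nu: float = 1.0
    patch_spacing: float = 0.8
    extent: tuple[float, float, float, float] = (0.0, 8.0, 0.0, 8.0)
    # growth
    growth: ge.GrowthConfig = field(default_factory=ge.GrowthConfig)
    postnatal: ge.PostnatalConfig = field(default_factory=ge.PostnatalConfig)
    # analysis
    op_grid: int = 121
    tfp_speed: float = 1.0

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.n_exponent < 2 or self.n_exponent % 2:
            raise ValueError("n_exponent must be even and >= 2")
        if self.patch_spacing <= 0 or self.nu <= 0 or self.tfp_speed <= 0:
            raise ValueError("patch_spacing, nu and tfp_speed must be positive")
        if self.op_grid < 8:
            raise ValueError("op_grid too small")

    def map_spec(self) -> mg.LocalMapSpec:
        return mg.LocalMapSpec(
            p0=self.map_center,
            p_prime=self.p_prime,
            n=self.n_exponent,
            chirality=self.chirality,
            nu=self.nu,
        )

    def hash(self) -> str:
        def default(o):
            if isinstance(o, complex):
                return [o.real, o.imag]
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_op_map(
    spec: mg.LocalMapSpec,
    out_png: str | Path | None = None,
    out_csv: str | Path | None = None,
    grid_n: int = 121,
    half_width: float = 1.5,
) -> np.ndarray:
    """Orientation-preference field about the map center, as CSV grid and PNG.

    Uses a cyclic 0-180 degree colormap (the standard OP color-wheel
    convention) and marks the singularity at the center.
    """
    xs = np.linspace(-half_width, half_width, grid_n)
    X, Y = np.meshgrid(xs, xs)
    grid = spec.p0 + X + 1j * Y
    op = mg.op_field(grid, spec)
    if out_csv is not None:
        import pandas as pd

        pd.DataFrame(
            {"x": X.ravel(), "y": Y.ravel(), "op_deg": op.ravel()}
        ).to_csv(out_csv, index=False)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        im = ax.imshow(
            op,
            origin="lower",
            extent=(-half_width, half_width, -half_width, half_width),
            cmap="hsv",
            vmin=0.0,
            vmax=180.0,
        )
        ax.plot(0, 0, "k*", markersize=12)
        ax.set_xlabel("x (cortical distance)")
        ax.set_ylabel("y")
        ax.set_title("orientation preference (deg, mod 180)")
        fig.colorbar(im, ax=ax, label="OP (deg)")
        fig.tight_layout()
        fig.savefig(out_png, dpi=110)
        plt.close(fig)
    return op


# ---------------------------------------------------------------------------
# analysis pipelines used by tests and the acceptance suite
# ---------------------------------------------------------------------------

def op_targets(n_samples: int = 360) -> dict:
    """Closed-form map-geometry quantities: OP coverage, arc rotation, Moebius n."""
    spec = mg.LocalMapSpec(p0=0j, p_prime=0.5j, n=2)
    return {
        "op_circuit_coverage_deg": mg.op_circuit_coverage(spec, n_samples=n_samples),
        "op_winding": mg.op_circuit_winding(spec, n_samples=n_samples),
        "radial_arc_rotation_deg": mg.arc_tangent_rotation(1.0, 0.6),
        "smallest_injective_even_n": mg.smallest_injective_exponent(),
    }


def zero_lag_experiment(
    seed: int,
    n_groups: int = 20,
    n_seeds: int = 10,
    coupling: float = 0.5,
    duration: float = 120.0,
    dt: float = 0.05,
) -> dict:
    """Modal peak lag of pairwise E-E correlograms under symmetric coupling.

    Simulates fully symmetric positive coupling between excitatory groups
    driven by diffuse noise, over several noise seeds, and reports the most
    common peak-lag bin (in steps) across all ordered pairs and seeds.
    """
    rng = np.random.default_rng(seed)
    k_each = coupling / (n_groups - 1)
    K = np.full((n_groups, n_groups), k_each)
    np.fill_diagonal(K, 0.0)
    pos = rng.uniform(0, 4, n_groups) + 1j * rng.uniform(0, 4, n_groups)
    params = fd.OscillatorParams(
        D=np.full(n_groups, 0.15), N=np.ones(n_groups), K=K, positions=pos
    )
    noise = fd.NoiseDrive(amplitude=1.0, diffusion_length=2.0)
    lags_all = []
    per_seed_modal = []
    for s in range(n_seeds):
        series = fd.simulate_field(
            params, noise, duration, dt, seed=int(rng.integers(2**31 - 1))
        )
        cut = int(duration * 0.15 / dt)
        trimmed = fd.FluxSeries(values=series.values[:, cut:], dt=dt)
        st = cm.free_energy_AC(trimmed, labels=["E"] * n_groups, tau_max=3.0)
        off = ~np.eye(n_groups, dtype=bool)
        lag_steps = np.rint(st.peak_lags[off] / dt).astype(int)
        lags_all.append(lag_steps)
        vals, counts = np.unique(lag_steps, return_counts=True)
        per_seed_modal.append(int(vals[np.argmax(counts)]))
    lag_steps = np.concatenate(lags_all)
    vals, counts = np.unique(lag_steps, return_counts=True)
    return {
        "modal_peak_lag_steps": int(vals[np.argmax(counts)]),
        "per_seed_modal": per_seed_modal,
        "zero_lag_fraction": float(np.mean(lag_steps == 0)),
        "n_pairs": int(lag_steps.size),
    }


def synchrony_signature_experiment(
    seed: int,
    duration: float = 2000.0,
    dt: float = 0.1,
    bins_per_period: int = 8,
) -> dict:
    """Detect the antenatal correlation signature on the equilibrium field.

    Simulates the synchronous-equilibrium network, estimates the dominant
    E-I oscillation period from the class-mean difference, bins the series
    at ~period/8 (standard correlogram binning), and runs the signature
    check: E-E and I-I peak at zero lag, E-I at about half a period.
    """
    params, labels = fx.synchronous_equilibrium_params(seed=0)
    series = fd.simulate_field(params, fd.NoiseDrive(1.0), duration, dt, seed=seed)
    cut = int(duration * 0.1 / dt)
    series = fd.FluxSeries(values=series.values[:, cut:], dt=dt)
    period = cm.dominant_period(series, labels)
    factor = max(1, int(round(period / bins_per_period / dt)))
    binned = series.binned(factor)
    st = cm.free_energy_AC(
        binned,
        labels=labels,
        tau_max=min(0.75 * period, binned.duration / 4 - binned.dt),
    )
    report = cm.antenatal_signature_check(st, period=period)
    report["bin_factor"] = factor
    return report


# ---------------------------------------------------------------------------
# experiment dispatch
# ---------------------------------------------------------------------------

def run_experiment(config: RunConfig) -> Path:
    """Execute one named experiment; returns the run directory."""
    config.validate()
    t0 = time.time()
    name = config.name or f"{config.experiment}-seed{config.seed}-{config.hash()}"
    run_dir = Path(config.out_dir) / name
    run_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.experiment == "opmap_render":
        spec = config.map_spec()
        op = render_op_map(
            spec,
            out_png=run_dir / "op_map.png",
            out_csv=run_dir / "op_map.csv",
            grid_n=config.op_grid,
        )
        results = {
            "op_min": float(op.min()),
            "op_max": float(op.max()),
            "coverage_deg": mg.op_circuit_coverage(spec),
            "winding": mg.op_circuit_winding(spec),
        }
    elif config.experiment == "tfp_contrast":
        spec = config.map_spec()
        f_c, f_r = mg.tfp_contrast(spec, speed=config.tfp_speed)
        results = {
            "f_circumferential": f_c,
            "f_radial": f_r,
            "ratio": f_c / f_r,
        }
    elif config.experiment == "antenatal_growth":
        traj, pop, syn = ge.run_antenatal_growth(config.growth, seed=config.seed)
        traj.config_hash = config.hash()
        traj.to_jsonl(run_dir / "trajectory.jsonl")
        _write_edge_list(run_dir / "connectivity.tsv", pop, syn)
        F = traj.series("F_AC_per_pair")
        wa = traj.series("weight_asymmetry")
        rf = traj.series("reciprocal_fraction")
        results = {
            "F_per_pair_first_quarter": float(F[: max(1, len(F) // 4)].mean()),
            "F_per_pair_last_quarter": float(F[-max(1, len(F) // 4):].mean()),
            "weight_asymmetry_initial": float(wa[0]),
            "weight_asymmetry_final": float(wa[-1]),
            "reciprocal_fraction_initial": float(rf[0]),
            "reciprocal_fraction_final": float(rf[-1]),
            "live_cells_final": int(traj.series("live_cells")[-1]),
        }
    elif config.experiment == "postnatal_refinement":
        spec = config.map_spec()
        frame = mg.hex_patch_lattice(config.patch_spacing, config.extent)
        pop, syn = ge.make_local_map_field(spec, seed=config.seed)
        stimuli = fx.structured_sweep_ensemble(spec, frame)
        traj, before, after = ge.run_postnatal_refinement(
            pop, syn, spec, stimuli, config.postnatal, seed=config.seed
        )
        traj.config_hash = config.hash()
        traj.to_jsonl(run_dir / "trajectory.jsonl")
        results = {
            "census_before": before,
            "census_after": after,
            "circ_radial_ratio_initial": float(traj.series("circ_radial_ratio")[0]),
            "circ_radial_ratio_final": float(traj.series("circ_radial_ratio")[-1]),
        }
    elif config.experiment == "acceptance_suite":
        results = dict(op_targets())
        results.update({"zero_lag": zero_lag_experiment(config.seed, n_seeds=3, duration=60.0)})
        results.update({"signature": synchrony_signature_experiment(config.seed, duration=1000.0)})

    with open(run_dir / "results.json", "w") as f:
        json.dump(results, f, indent=2, default=str)
    manifest = {
        "experiment": config.experiment,
        "seed": config.seed,
        "config_hash": config.hash(),
        "wall_time_s": time.time() - t0,
        "versions": _versions(),
    }
    with open(run_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    log.info("run_experiment: %s finished in %.1fs -> %s", config.experiment, manifest["wall_time_s"], run_dir)
    return run_dir


def _versions() -> dict:
    import matplotlib
    import networkx
    import scipy

    import mesocortex

    return {
        "mesocortex": mesocortex.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _write_edge_list(path: Path, pop: ge.CellPopulation, syn: ge.SynapseState) -> None:
    import pandas as pd

    pre, post = np.nonzero(syn.rho > 0)
    pd.DataFrame(
        {
            "pre": pre,
            "post": post,
            "rho": syn.rho[pre, post],
            "g": syn.g[pre, post],
            "eps": syn.eps[pre, post],
        }
    ).to_csv(path, sep="\t", index=False)
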