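"""Free-energy measures on pulse-correlation structure.

Three complementary formulations of the field's variational free energy:

* **Auto-minus-cross**: ``F = A - C``, where A is the population sum of
  peak-normalized pulse autocorrelations (one per non-degenerate group) and
  C the sum over ordered group pairs of the maximum normalized
  cross-correlation within a finite lag window.  As connectivity becomes
  more ordered and reciprocal, synchrony (hence C) rises and F falls.
  C decomposes by excitatory/inhibitory labels as C = C_ee + C_ii + C_ei,ie.

* **Accuracy-minus-complexity**: a k-factor Gaussian model of the inter-group
  correlation matrix is fitted for each candidate dimension k; the Akaike
  information criterion (minimized) selects the number of orthogonal degrees
  of freedom k* needed to represent the partial correlations.

* **Gibbs modal form**: over eigenmode energies U_i, entropy
  S = -sum (U_i/U) ln(U_i/U) and F = U - tau * S; F is minimized over the
  energy simplex exactly at equipartition.

The lag-window normalization of C is a deliberate regularization: the raw
doubly-integrated cross-correlation diverges for stationary series, while
the windowed peak estimate is bounded and preserves the ordering
"more synchrony => larger C => smaller F".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from mesocortex.field_dynamics import FluxSeries

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationStructure",
    "AkaikeResult",
    "cross_correlogram",
    "free_energy_AC",
    "decompose_C",
    "antenatal_signature_check",
    "akaike_dimension",
    "gibbs_free_energy",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CorrelationStructure:
    """Population correlation summary over one epoch.

    ``A``: summed peak-normalized autocorrelation (= count of non-degenerate
    groups).  ``C``: summed peak cross-correlation over ordered pairs within
    the lag window.  ``C_ee``/``C_ii``/``C_ei_ie``: label-partitioned
    components, summing exactly to C.  ``peak_lags[i, j]``: lag (time units)
    of the peak cross-correlation of ordered pair (i, j).  ``peak_corrs``:
    the corresponding peak values.  ``degenerate``: mask of constant
    (zero-variance) groups, excluded from A and C.
    """

    A: float
    C: float
    C_ee: float
    C_ii: float
    C_ei_ie: float
    lag_grid: np.ndarray
    epoch: float
    peak_lags: np.ndarray
    peak_corrs: np.ndarray
    labels: list[str]
    degenerate: np.ndarray
    dt: float

    @property
    def F(self) -> float:
        """Free energy, auto minus cross."""
        return self.A - self.C


@dataclass
class AkaikeResult:
    """Model-order scan of the information criterion.

    ``alpha_curve[k]`` holds the minimized criterion ``-2 lnL(k) + 2 d(k)``
    where d(k) counts the free parameters of the k-factor Gaussian model;
    ``k_star`` is the argmin over k = 0..k_max.
    """

    alpha_curve: np.ndarray
    log_likelihoods: np.ndarray
    k_star: int
    n_params: np.ndarray = field(default_factory=lambda: np.array([]))
    ridge: float = 0.0
    n_collapsed: int = 0


# ---------------------------------------------------------------------------
# correlograms
# ---------------------------------------------------------------------------

def cross_correlogram(
    x: np.ndarray, y: np.ndarray, tau_max: float, dt: float = 1.0
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Pearson-normalized cross-correlation of two series on a lag grid.

    Returns ``(lags, corr, degenerate)`` with lags in time units spanning
    [-tau_max, +tau_max].  Sign convention: a peak at positive lag means y
    lags x (``corr[l] = corr(x[t], y[t+l])``).  Zero-variance input yields
    zeros with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    L = int(round(tau_max / dt))
    n = len(x)
    if n * dt <= 4 * tau_max:
        raise ValueError("series too short: need length*dt > 4*tau_max")
    lags = np.arange(-L, L + 1) * dt
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return lags, np.zeros(2 * L + 1), True
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    full = _signal.correlate(zy, zx, mode="full") / n  # index n-1 <-> lag 0
    corr = full[n - 1 - L : n + L]
    return lags, np.clip(corr, -1.0, 1.0), False


def _pairwise_peak_corrs(
    values: np.ndarray, tau_max: float, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Peak cross-correlation and its lag for every ordered group pair.

    Vectorized over pairs: one (m x m) correlation matrix per lag via matrix
    products of the standardized series.  Returns (peak_corrs, peak_lags,
    degenerate_mask, lag_grid).
    """
    m, n = values.shape
    L = int(round(tau_max / dt))
    lags = np.arange(-L, L + 1) * dt
    sd = values.std(axis=1)
    degenerate = sd == 0
    Z = np.zeros_like(values)
    ok = ~degenerate
    Z[ok] = (values[ok] - values[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    best = np.full((m, m), -np.inf)
    best_lag = np.zeros((m, m))
    for li, ell in enumerate(range(-L, L + 1)):
        if ell >= 0:
            a = Z[:, : n - ell] if ell else Z
            b = Z[:, ell:]
        else:
            a = Z[:, -ell:]
            b = Z[:, : n + ell]
        R = a @ b.T / n  # R[i, j] = corr(x_i[t], x_j[t+ell])
        upd = R > best
        best_lag[upd] = lags[li]
        best = np.maximum(best, R)
    best[degenerate, :] = 0.0
    best[:, degenerate] = 0.0
    np.clip(best, -1.0, 1.0, out=best)
    return best, best_lag, degenerate, lags


# ---------------------------------------------------------------------------
# F = A - C
# ---------------------------------------------------------------------------

def free_energy_AC(
    series: FluxSeries,
    labels: list[str] | np.ndarray | None = None,
    tau_max: float | None = None,
) -> CorrelationStructure:
    """Free energy of one epoch as auto- minus cross-correlation.

    ``A`` counts the non-degenerate groups (each contributes its
    peak-normalized autocorrelation at lag zero, i.e. one); ``C`` sums the
    maximum normalized cross-correlation within +/- tau_max over ordered
    pairs.  ``labels`` assigns 'E' or 'I' to each group for the
    decomposition; default all-'E'.  ``tau_max`` defaults to one dominant
    period estimated from the mean power spectrum, and may not exceed a
    quarter of the epoch.
    """
    values = series.values
    m = values.shape[0]
    if m < 1:
        raise ValueError("need at least one group")
    if labels is None:
        labels = ["E"] * m
    labels = [str(lb).upper() for lb in np.asarray(labels).tolist()]
    if len(labels) != m:
        raise ValueError("labels must cover all groups")
    if tau_max is None:
        tau_max = _dominant_period(series)
    T = series.duration
    if tau_max > T / 4:
        raise ValueError("tau_max exceeds a quarter of the epoch")

    peak, peak_lag, degenerate, lags = _pairwise_peak_corrs(values, tau_max, series.dt)
    n_deg = int(degenerate.sum())
    if n_deg:
        log.info("free_energy_AC: %d degenerate (constant) groups excluded", n_deg)
    A = float(m - n_deg)
    off = ~np.eye(m, dtype=bool)
    C = float(peak[off].sum())
    cee, cii, cei = _decompose(peak, labels)
    return CorrelationStructure(
        A=A,
        C=C,
        C_ee=cee,
        C_ii=cii,
        C_ei_ie=cei,
        lag_grid=lags,
        epoch=T,
        peak_lags=peak_lag,
        peak_corrs=peak,
        labels=labels,
        degenerate=degenerate,
        dt=series.dt,
    )


def _decompose(peak: np.ndarray, labels: list[str]) -> tuple[float, float, float]:
    lab = np.asarray(labels)
    m = len(lab)
    off = ~np.eye(m, dtype=bool)
    e = lab == "E"
    ee = np.outer(e, e) & off
    ii = np.outer(~e, ~e) & off
    mixed = off & ~ee & ~ii
    return float(peak[ee].sum()), float(peak[ii].sum()), float(peak[mixed].sum())


def decompose_C(structure: CorrelationStructure) -> tuple[float, float, float]:
    """Label-partitioned components of C (they sum to C exactly)."""
    return _decompose(structure.peak_corrs, structure.labels)


def _peak_period(x: np.ndarray, dt: float, duration: float) -> float:
    """Period of the strongest Welch spectral peak of one (or more) series."""
    x = np.atleast_2d(x)
    nper = min(x.shape[1], 8192)
    freqs, spec = _signal.welch(
        x - x.mean(axis=1, keepdims=True), fs=1.0 / dt, nperseg=nper, noverlap=nper // 2
    )
    mean_spec = spec.mean(axis=0)
    i = int(np.argmax(mean_spec[1:]) + 1)
    f = freqs[i]
    if 1 <= i < len(freqs) - 1:  # quadratic interpolation of the peak
        lo, mid, hi = np.log(mean_spec[i - 1 : i + 2] + 1e-300)
        denom = lo - 2 * mid + hi
        if denom < 0:
            f = freqs[i] + 0.5 * (lo - hi) / denom * (freqs[1] - freqs[0])
    return min(1.0 / f, duration / 4)


def _dominant_period(series: FluxSeries) -> float:
    """Period of the dominant spectral peak of the population's series."""
    return _peak_period(series.values, series.dt, series.duration)


def dominant_period(series: FluxSeries, labels: list[str] | None = None) -> float:
    """Dominant oscillation period of the population.

    Without labels: period of the strongest peak of the mean power
    spectrum.  With E/I labels: period of the strongest spectral peak of
    the class-mean difference (mean E series minus mean I series) — the
    coordinate in which the synchronous-equilibrium E-I oscillation lives,
    which common broadband drive cancels out of.
    """
    if labels is None:
        return _dominant_period(series)
    lab = np.asarray([str(lb).upper() for lb in labels])
    e = lab == "E"
    if e.all() or not e.any():
        return _dominant_period(series)
    diff = series.values[e].mean(axis=0) - series.values[~e].mean(axis=0)
    return _peak_period(diff, series.dt, series.duration)


# ---------------------------------------------------------------------------
# antenatal signature
# ---------------------------------------------------------------------------

def antenatal_signature_check(
    structure: CorrelationStructure, period: float | None = None, lag_tol_steps: int = 1
) -> dict:
    """Test for the zero-lag synchronous-equilibrium correlation signature.

    At synchronous equilibrium all excitatory cells fire together, all
    inhibitory cells fire together, and E and I fire in anti-phase: E-E and
    I-I cross-correlograms peak at (near) zero lag while E-I pairs peak at
    about half the dominant oscillation period.  Returns a report dict with
    per-class verdicts ('ok', 'violated', or 'not assessable') and the
    overall boolean under key ``'signature'``.
    """
    lab = np.asarray(structure.labels)
    m = len(lab)
    off = ~np.eye(m, dtype=bool)
    live = ~structure.degenerate
    ok_pair = off & np.outer(live, live)
    e = lab == "E"
    classes = {
        "EE": np.outer(e, e) & ok_pair,
        "II": np.outer(~e, ~e) & ok_pair,
        "EI": (np.outer(e, ~e) | np.outer(~e, e)) & ok_pair,
    }
    if period is None:
        period = float(structure.lag_grid[-1])  # tau_max defaults to one period
    report: dict = {"period": period}
    step = structure.dt
    verdicts: dict[str, str] = {}
    for name, mask in classes.items():
        if mask.sum() < 2:
            verdicts[name] = "not assessable"
            continue
        med = float(np.median(np.abs(structure.peak_lags[mask])))
        report[f"median_abs_lag_{name}"] = med
        if name in ("EE", "II"):
            verdicts[name] = "ok" if med <= lag_tol_steps * step + 1e-12 else "violated"
        else:
            half = period / 2.0
            verdicts[name] = "ok" if abs(med - half) <= 0.25 * half else "violated"
    report["verdicts"] = verdicts
    assessable = [v for v in verdicts.values() if v != "not assessable"]
    report["signature"] = bool(assessable) and all(v == "ok" for v in assessable)
    return report


# ---------------------------------------------------------------------------
# Akaike dimension
# ---------------------------------------------------------------------------

def akaike_dimension(flux: np.ndarray, k_max: int, ridge: float = 1e-8) -> AkaikeResult:
    """Minimum-AIC dimension of a k-factor Gaussian model of the flux matrix.

    ``flux`` is (n_groups x n_samples).  For each k a k-factor Gaussian
    model of the inter-group correlation matrix (maximum-likelihood factor
    analysis with heteroscedastic uniquenesses, Sigma_k = L L' + Psi) is
    fitted to the standardized series, and the criterion

        alpha(k) = -2 lnL(k) + 2 d(k),   d(k) = p*k - k(k-1)/2 + p

    is minimized over k = 0..k_max; d(k) counts the model's free parameters
    (loadings modulo rotation, plus uniquenesses).  ``k_star`` estimates the
    number of orthogonal degrees of freedom in the correlation structure.

    Exactly duplicated series are collapsed and constant series excluded
    before fitting (they carry no additional information and make the
    covariance singular); a still rank-deficient correlation matrix is
    ridge-regularized on the diagonal with the logged ``ridge`` value.
    """
    from sklearn.decomposition import FactorAnalysis

    X = np.atleast_2d(np.asarray(flux, dtype=float))
    p0, n = X.shape
    X = np.unique(X, axis=0)
    n_collapsed = p0 - X.shape[0]
    if n_collapsed:
        log.info("akaike_dimension: collapsed %d duplicated series", n_collapsed)
    p = X.shape[0]
    if n <= p:
        raise ValueError("need more time samples than groups")
    if not 0 <= k_max < p:
        raise ValueError("k_max must be in [0, n_groups)")

    sd = X.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        log.info("akaike_dimension: %d constant series excluded", int((~keep).sum()))
        X = X[keep]
        p = X.shape[0]
    Z = ((X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)).T  # n x p
    R = Z.T @ Z / n
    used_ridge = 0.0
    if np.linalg.eigvalsh(R)[0] < 1e-12:
        used_ridge = ridge
        R = R + ridge * np.eye(p)
        log.info("akaike_dimension: ridge %g applied to rank-deficient covariance", ridge)

    lnL = np.empty(k_max + 1)
    d = np.empty(k_max + 1)
    const = p * np.log(2 * np.pi)
    for k in range(k_max + 1):
        if k == 0:
            sigma = np.diag(R)
            logdet = float(np.log(sigma).sum())
            trace = float((np.diag(R) / sigma).sum())
        else:
            fa = FactorAnalysis(n_components=k, random_state=0)
            fa.fit(Z)
            Sigma = fa.components_.T @ fa.components_ + np.diag(
                np.maximum(fa.noise_variance_, 1e-12)
            )
            _, logdet = np.linalg.slogdet(Sigma)
            trace = float(np.trace(np.linalg.solve(Sigma, R)))
        lnL[k] = -0.5 * n * (const + logdet + trace)
        d[k] = p * k - k * (k - 1) / 2 + p
    alpha = -2.0 * lnL + 2.0 * d
    k_star = int(np.argmin(alpha))
    return AkaikeResult(
        alpha_curve=alpha,
        log_likelihoods=lnL,
        k_star=k_star,
        n_params=d,
        ridge=used_ridge,
        n_collapsed=n_collapsed,
    )


# ---------------------------------------------------------------------------
# Gibbs free energy over modes
# ---------------------------------------------------------------------------

def gibbs_free_energy(energies: np.ndarray, tau_scale: float = 1.0) -> tuple[float, float]:
    """Modal entropy and Gibbs free energy ``F = U - tau * S``.

    ``S = -sum (U_i/U) ln(U_i/U)`` with the convention that zero-energy
    modes contribute nothing (x ln x -> 0).  Over the simplex of energy
    splits at fixed total U, F attains its minimum exactly at equipartition,
    where S = ln(m).
    """
    U_i = np.asarray(energies, dtype=float)
    if np.any(U_i < 0):
        raise ValueError("modal energies must be non-negative")
    U = float(U_i.sum())
    if U == 0:
        raise ValueError("total energy is zero")
    frac = U_i / U
    nz = frac > 0
    S = float(-(frac[nz] * np.log(frac[nz])).sum())
    return S, U - tau_scale * S
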