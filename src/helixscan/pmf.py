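"""WHAM free-energy profiles F(R), helical-state populations, and the
quarter-wise convergence check.

The weighted histogram analysis method combines the biased histograms of all
umbrella windows into one unbiased profile by iterating the self-consistent
equations

    rho(b) = n(b) / sum_k N_k exp(f_k - beta V_k(R_b))
    exp(-f_k) = sum_b rho(b) exp(-beta V_k(R_b))

until the window free energies f_k stop changing.  The helical state is the
region R below a calibrated boundary (default 0.15 nm, where helicity drops
through 50%); its equilibrium population follows from Boltzmann-weighting
the profile.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .drmsd import restraint_energy
from .errors import DisconnectedHistogramError, WhamConvergenceError
from .umbrella import KB, WindowSpec, WindowedSamples

logger = logging.getLogger(__name__)

HELICAL_BOUNDARY = 0.15  # nm; R below which a conformation counts as helical


@dataclass
class PmfProfile:
    """Binned free-energy profile F(R) with per-bin uncertainty.

    ``free_energy`` is in kJ/mol, min-shifted to 0; bins with no counts are
    NaN (undefined, never interpolated).
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray            # (n_windows, n_bins)
    temperature: float
    bin_width: float
    uncertainty: np.ndarray | None = None
    converged: bool = True
    window_free_energies: np.ndarray | None = None
    bootstrap_profiles: np.ndarray | None = None  # (n_boot, n_bins)

    def __post_init__(self):
        f = np.asarray(self.free_energy, dtype=float)
        if np.any(np.isfinite(f)):
            f = f - np.nanmin(f)
        self.free_energy = f

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def _histogram(r: np.ndarray, edges: np.ndarray, weights=None) -> np.ndarray:
    return np.histogram(r, bins=edges, weights=weights)[0].astype(float)


def _check_overlap(counts: np.ndarray, windows: Sequence[WindowSpec]) -> None:
    """All windows must form one connected component through shared bins."""
    k = len(counts)
    if k == 1:
        return
    occupied = counts > 0
    adj = [[bool(np.any(occupied[i] & occupied[j])) for j in range(k)] for i in range(k)]
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in range(k):
            if adj[i][j] and j not in seen:
                seen.add(j)
                stack.append(j)
    if len(seen) < k:
        missing = sorted(set(range(k)) - seen)
        r0_in = max(windows[i].restraint.r0 for i in seen)
        r0_out = min(windows[i].restraint.r0 for i in missing)
        raise DisconnectedHistogramError(
            f"window histograms are disconnected between R0 ~ {min(r0_in, r0_out):.3f} "
            f"and {max(r0_in, r0_out):.3f} nm (windows {missing} unreachable)"
        )


def _wham_iterate(
    counts: np.ndarray,
    bias_kt: np.ndarray,
    tol: float,
    max_iter: int,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Solve the WHAM equations in log space.

    Returns (log_rho per bin, f_k per window in kT, iterations used).
    """
    n_k = counts.sum(axis=1)
    n_b = counts.sum(axis=0)
    defined = n_b > 0
    with np.errstate(divide="ignore"):
        log_nb = np.where(defined, np.log(np.where(defined, n_b, 1.0)), -np.inf)
        log_nk = np.log(np.where(n_k > 0, n_k, 1.0))
    f = np.zeros(len(counts)) if f_init is None else f_init.copy()
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_k [log N_k + f_k - b_kb]
        log_den = logsumexp(log_nk[:, None] + f[:, None] - bias_kt, axis=0)
        log_rho = log_nb - log_den
        f_new = -logsumexp(log_rho[None, :] - bias_kt, axis=1, b=defined[None, :].astype(float))
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return log_rho, f, it
    raise WhamConvergenceError(
        f"WHAM did not converge in {max_iter} iterations (residual {delta:.2e} kT)"
    )


def wham(
    samples: WindowedSamples,
    windows: Sequence[WindowSpec] | None = None,
    temperature: float = 300.0,
    bin_width: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    n_boot: int = 0,
    seed: int = 0,
    boot_block: int = 50,
) -> PmfProfile:
    """Free-energy profile F(R) from windowed samples by self-consistent WHAM.

    The profile spans [min R0 - 0.05, max R0 + 0.1] nm.  ``n_boot`` > 0 adds
    a Bayesian bootstrap over each window's sample weights, stored in
    ``bootstrap_profiles`` and summarised as per-bin SD in ``uncertainty``.
    Bootstrap weights are drawn per contiguous block of ``boot_block``
    samples, not per sample, so the interval does not shrink below what the
    trajectory autocorrelation supports.
    """
    if windows is None:
        windows = samples.windows
    windows = list(windows)
    kbt = KB * temperature
    r0s = np.array([w.restraint.r0 for w in windows])
    lo, hi = r0s.min() - 0.05, r0s.max() + 0.1
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array(
        [_histogram(samples.r_values[i], edges) for i in range(len(windows))]
    )
    _check_overlap(counts, windows)
    bias_kt = np.array(
        [[restraint_energy(max(c, 0.0), w.restraint) for c in centers] for w in windows]
    ) / kbt

    log_rho, f, iters = _wham_iterate(counts, bias_kt, tol, max_iter)
    logger.info("wham converged in %d iterations", iters)
    free = np.where(counts.sum(axis=0) > 0, -kbt * log_rho, np.nan)

    boot = None
    sd = None
    if n_boot > 0:
        rng = np.random.default_rng([seed, 99_991])
        boot = np.full((n_boot, len(centers)), np.nan)
        for rep in range(n_boot):
            wlists = []
            for i in range(len(windows)):
                m = len(samples.r_values[i])
                nblk = max(1, m // boot_block)
                blk_w = rng.dirichlet(np.ones(nblk)) * nblk
                w = np.repeat(blk_w, -(-m // nblk))[:m]
                wlists.append(
                    _histogram(samples.r_values[i], edges, weights=w)
                )
            wcounts = np.array(wlists)
            try:
                lr, _, _ = _wham_iterate(wcounts, bias_kt, tol * 10, max_iter, f_init=f)
            except (DisconnectedHistogramError, WhamConvergenceError):
                continue
            fb = np.where(wcounts.sum(axis=0) > 0, -kbt * lr, np.nan)
            boot[rep] = fb - np.nanmin(fb)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(boot, axis=0)

    return PmfProfile(
        bin_centers=centers,
        free_energy=free,
        counts=counts,
        temperature=temperature,
        bin_width=bin_width,
        uncertainty=sd,
        converged=True,
        window_free_energies=f * kbt,
        bootstrap_profiles=boot,
    )


def _population_from_profile(
    centers: np.ndarray,
    free: np.ndarray,
    kbt: float,
    bin_width: float,
    boundary: float,
) -> float:
    defined = np.isfinite(free)
    w = np.zeros_like(centers)
    w[defined] = np.exp(-(free[defined] - np.nanmin(free)) / kbt)
    frac_below = np.clip((boundary - (centers - bin_width / 2)) / bin_width, 0.0, 1.0)
    total = w.sum()
    if total == 0:
        return np.nan
    return float(np.sum(w * frac_below) / total)


def helical_population(
    pmf: PmfProfile,
    temperature: float | None = None,
    boundary: float = HELICAL_BOUNDARY,
) -> float:
    """Boltzmann population of the helical state (R < boundary).

    The bin straddling the boundary contributes proportionally.  Undefined
    bins below the boundary trigger a warning: the population then rests on
    the defined bins only.
    """
    t = pmf.temperature if temperature is None else temperature
    kbt = KB * t
    in_range = (pmf.bin_centers + pmf.bin_width / 2 > 0) & (
        pmf.bin_centers - pmf.bin_width / 2 < boundary
    )
    if np.any(in_range & ~pmf.defined):
        warnings.warn(
            "undefined bins below the helical boundary; population estimate "
            "rests on defined bins only and carries widened uncertainty",
            stacklevel=2,
        )
    return _population_from_profile(
        pmf.bin_centers, pmf.free_energy, kbt, pmf.bin_width, boundary
    )


def helical_population_ci(
    pmf: PmfProfile,
    boundary: float = HELICAL_BOUNDARY,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Population with a bootstrap percentile confidence interval.

    Requires a profile computed with ``n_boot`` > 0.
    """
    p = helical_population(pmf, boundary=boundary)
    if pmf.bootstrap_profiles is None:
        raise ValueError("profile has no bootstrap replicates; rerun wham with n_boot > 0")
    kbt = KB * pmf.temperature
    reps = [
        _population_from_profile(pmf.bin_centers, fb, kbt, pmf.bin_width, boundary)
        for fb in pmf.bootstrap_profiles
        if np.any(np.isfinite(fb))
    ]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanpercentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return p, float(lo), float(hi)


@dataclass
class ConvergenceReport:
    """Four quarter-wise profiles and their mutual deviation (quarters 2-4)."""

    profiles: list  # PmfProfile | None per quarter
    per_bin_deviation: np.ndarray | None
    max_deviation_kt: float
    converged: bool


def convergence_quarters(
    samples: WindowedSamples,
    windows: Sequence[WindowSpec] | None = None,
    temperature: float = 300.0,
    threshold_kt: float = 0.5,
    min_counts: int = 100,
    **wham_kwargs,
) -> ConvergenceReport:
    """Split the data into four contiguous quarters and compare their PMFs.

    A run is flagged converged when, over bins defined in all of quarters
    2-4, the maximum absolute deviation between those quarters' profiles
    (mean-aligned over shared bins) stays below ``threshold_kt`` kBT.  The
    first quarter is reported but excluded from the criterion, since it
    carries any relaxation from the starting structure.  A bin only enters
    the comparison when every compared quarter holds at least ``min_counts``
    samples in it — with fewer, the bin's free energy is shot noise, not
    signal.
    """
    if windows is None:
        windows = samples.windows
    total = sum(len(r) for r in samples.r_values)
    if total < 4 * len(windows):
        raise ValueError("need at least 4 samples per window for quartering")
    kbt = KB * temperature
    profiles = []
    for q in range(4):
        try:
            profiles.append(
                wham(samples.quarter(q), windows, temperature, **wham_kwargs)
            )
        except (DisconnectedHistogramError, WhamConvergenceError) as exc:
            logger.warning("quarter %d undefined: %s", q + 1, exc)
            profiles.append(None)

    late = [p for p in profiles[1:] if p is not None]
    if len(late) < 2:
        return ConvergenceReport(profiles, None, np.inf, False)
    common = np.logical_and.reduce(
        [p.defined & (p.counts.sum(axis=0) >= min_counts) for p in late]
    )
    if not np.any(common):
        return ConvergenceReport(profiles, None, np.inf, False)
    aligned = [p.free_energy - np.mean(p.free_energy[common]) for p in late]
    dev = np.full(len(late[0].free_energy), np.nan)
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            d = np.abs(aligned[i] - aligned[j])
            dev = np.fmax(dev, np.where(common, d, np.nan))
    max_dev_kt = float(np.nanmax(dev) / kbt)
    return ConvergenceReport(profiles, dev, max_dev_kt, max_dev_kt < threshold_kt)
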