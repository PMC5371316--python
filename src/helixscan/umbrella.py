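"""Umbrella sampling along dRMSD with Hamiltonian replica exchange.

Every window shares the model Hamiltonian and differs only in its quadratic
dRMSD restraint (centre R0, force constant k0).  Replicas evolve by
Metropolis Monte Carlo; configuration swaps between neighbouring windows are
attempted periodically with the standard Hamiltonian-replica-exchange
criterion, in which the unbiased energy cancels and only the bias energies
enter:

    P(swap) = min(1, exp(-beta [V_a(x_b) + V_b(x_a) - V_a(x_a) - V_b(x_b)]))
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cg_model import ChainConformation, ModelParameters, MonteCarloSampler
from .drmsd import (
    DrmsdReference,
    RestraintSpec,
    drmsd,
    make_helical_reference,
    restraint_energy,
)
from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

#: Boltzmann constant in kJ mol^-1 K^-1
KB = 0.0083144621

DEFAULT_FORCE_CONSTANT = 1000.0  # kJ mol^-1 nm^-2; package default, sized so
                                 # window widths overlap the default spacing


@dataclass(frozen=True)
class WindowSpec:
    """One umbrella window: its index and restraint."""

    index: int
    restraint: RestraintSpec


def build_windows(
    n_windows: int = 12,
    r_min: float = 0.0,
    r_max: float = 0.5,
    k0: float = DEFAULT_FORCE_CONSTANT,
) -> list[WindowSpec]:
    """Equally spaced windows including both endpoints.

    Defaults reproduce the 12-window 0.0–0.5 nm protocol with spacing
    (r_max - r_min)/(n_windows - 1).
    """
    if n_windows < 2:
        raise InvalidConfigError("need at least 2 windows")
    if r_max <= r_min:
        raise InvalidConfigError("r_max must exceed r_min")
    centres = np.linspace(r_min, r_max, n_windows)
    return [WindowSpec(i, RestraintSpec(r0=float(r), k0=k0)) for i, r in enumerate(centres)]


@dataclass
class ReplicaState:
    """Configuration currently held by one window's replica."""

    coords: np.ndarray | None
    r: float
    restraint: RestraintSpec


def attempt_exchange(
    state_a: ReplicaState,
    state_b: ReplicaState,
    beta: float,
    u: float | None = None,
    rng: np.random.Generator | None = None,
    swap: bool = True,
) -> bool:
    """Metropolis swap attempt between two replicas sharing one Hamiltonian.

    Only the bias (restraint) energies enter the criterion.  ``u`` is the
    uniform deviate used for the decision; if omitted it is drawn from
    ``rng``.  When accepted and ``swap`` is true, the configurations (not the
    restraints) are exchanged in place.
    """
    va_a = restraint_energy(state_a.r, state_a.restraint)
    va_b = restraint_energy(state_b.r, state_a.restraint)
    vb_a = restraint_energy(state_a.r, state_b.restraint)
    vb_b = restraint_energy(state_b.r, state_b.restraint)
    delta = beta * (va_b + vb_a - va_a - vb_b)
    if u is None:
        if rng is None:
            rng = np.random.default_rng()
        u = float(rng.random())
    accepted = delta <= 0.0 or u < np.exp(-delta)
    if accepted and swap:
        state_a.coords, state_b.coords = state_b.coords, state_a.coords
        state_a.r, state_b.r = state_b.r, state_a.r
    return accepted


@dataclass
class WindowedSamples:
    """Per-window trajectories of (step, R, conformation) plus the exchange log.

    ``conformations[w]`` is an (n_saved, n_residues, 3) array, or ``None``
    when only the scalar coordinate was sampled (1-D toy Hamiltonians).
    """

    windows: list[WindowSpec]
    steps: list[np.ndarray]
    r_values: list[np.ndarray]
    conformations: list[np.ndarray] | None
    exchange_log: pd.DataFrame
    segment_id: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_conformations(self, w: int) -> list[ChainConformation]:
        if self.conformations is None:
            raise ValueError("no conformations stored (scalar sampling)")
        return [
            ChainConformation(c, segment_id=self.segment_id)
            for c in self.conformations[w]
        ]

    def exchange_acceptance(self) -> pd.DataFrame:
        """Attempted/accepted counts and fraction per neighbour pair."""
        if self.exchange_log.empty:
            return pd.DataFrame(columns=["window_a", "window_b", "attempted", "accepted", "fraction"])
        g = self.exchange_log.groupby(["window_a", "window_b"])["accepted"]
        out = g.agg(attempted="count", accepted="sum").reset_index()
        out["fraction"] = out["accepted"] / out["attempted"]
        return out

    def quarter(self, q: int) -> "WindowedSamples":
        """Contiguous quarter q (0..3) of every window's samples."""
        if not 0 <= q < 4:
            raise ValueError("quarter index must be 0..3")
        steps, rvals, confs = [], [], [] if self.conformations is not None else None
        for w in range(self.n_windows):
            m = len(self.steps[w])
            lo, hi = (m * q) // 4, (m * (q + 1)) // 4
            steps.append(self.steps[w][lo:hi])
            rvals.append(self.r_values[w][lo:hi])
            if confs is not None:
                confs.append(self.conformations[w][lo:hi])
        return WindowedSamples(
            self.windows, steps, rvals, confs,
            self.exchange_log, self.segment_id, dict(self.metadata),
        )

    def discard_equilibration(self, fraction: float) -> "WindowedSamples":
        """Drop the first ``fraction`` of every window's samples."""
        if not 0 <= fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        steps, rvals, confs = [], [], [] if self.conformations is not None else None
        for w in range(self.n_windows):
            lo = int(len(self.steps[w]) * fraction)
            steps.append(self.steps[w][lo:])
            rvals.append(self.r_values[w][lo:])
            if confs is not None:
                confs.append(self.conformations[w][lo:])
        return WindowedSamples(
            self.windows, steps, rvals, confs,
            self.exchange_log, self.segment_id, dict(self.metadata),
        )


def run_hremd(
    params: ModelParameters,
    windows: Sequence[WindowSpec],
    n_steps: int,
    exchange_interval: int = 500,
    seed: int = 0,
    save_every: int = 1,
    segment_id: str = "",
    reference: DrmsdReference | None = None,
) -> WindowedSamples:
    """Replica-exchange umbrella sampling of the coarse-grained model.

    One replica per window; each evolves under model energy plus its window's
    dRMSD restraint.  Neighbour swaps are attempted every
    ``exchange_interval`` sweeps, alternating even/odd pairs.  Per-replica
    random streams are derived from ``seed`` and the window index, so adding
    windows never perturbs existing streams.
    """
    windows = list(windows)
    if not windows:
        raise InvalidConfigError("need at least one window")
    r0s = [w.restraint.r0 for w in windows]
    if len(windows) > 1 and np.any(np.diff(r0s) <= 0):
        raise InvalidConfigError("window R0 values must be strictly increasing")
    if n_steps < exchange_interval and len(windows) > 1:
        logger.warning("n_steps < exchange_interval: no swaps will be attempted")

    n = params.n_residues
    ref = reference if reference is not None else make_helical_reference(n)
    kbt = KB * params.temperature
    beta = 1.0 / kbt

    def bias_for(spec: RestraintSpec) -> Callable[[np.ndarray], float]:
        def bias(coords: np.ndarray) -> float:
            return restraint_energy(drmsd(coords, ref), spec) / kbt
        return bias

    samplers = [
        MonteCarloSampler(
            params,
            np.random.default_rng([seed, w.index]),
            bias=bias_for(w.restraint),
        )
        for w in windows
    ]
    rng_ex = np.random.default_rng([seed, 1_000_003])

    steps: list[list[int]] = [[] for _ in windows]
    rvals: list[list[float]] = [[] for _ in windows]
    confs: list[list[np.ndarray]] = [[] for _ in windows]
    ex_records = []

    n_exchanges = 0
    for step in range(1, n_steps + 1):
        for s in samplers:
            s.sweep()
        if len(windows) > 1 and step % exchange_interval == 0:
            parity = n_exchanges % 2
            n_exchanges += 1
            for i in range(parity, len(windows) - 1, 2):
                a, b = samplers[i], samplers[i + 1]
                sa = ReplicaState(a.coords, drmsd(a.coords, ref), windows[i].restraint)
                sb = ReplicaState(b.coords, drmsd(b.coords, ref), windows[i + 1].restraint)
                accepted = attempt_exchange(sa, sb, beta, rng=rng_ex)
                if accepted:
                    a.coords, b.coords = sa.coords, sb.coords
                    a.energy = a._total_energy(a.coords)
                    b.energy = b._total_energy(b.coords)
                ex_records.append(
                    {"step": step, "window_a": i, "window_b": i + 1, "accepted": accepted}
                )
        if step % save_every == 0:
            for w, s in enumerate(samplers):
                steps[w].append(step)
                rvals[w].append(drmsd(s.coords, ref))
                confs[w].append(s.coords.copy())

    acc = np.mean([s.acceptance_rate for s in samplers])
    logger.info("run_hremd: %d sweeps x %d windows, MC acceptance %.3f", n_steps, len(windows), acc)
    return WindowedSamples(
        windows=windows,
        steps=[np.array(s, dtype=int) for s in steps],
        r_values=[np.array(r) for r in rvals],
        conformations=[np.array(c) for c in confs],
        exchange_log=pd.DataFrame(
            ex_records, columns=["step", "window_a", "window_b", "accepted"]
        ),
        segment_id=segment_id,
        metadata={
            "seed": seed,
            "n_steps": n_steps,
            "exchange_interval": exchange_interval,
            "variant_name": params.variant_name,
            "temperature": params.temperature,
            "mc_acceptance": float(acc),
        },
    )


def sample_restrained_1d(
    potential: Callable[[float], float],
    windows: Sequence[WindowSpec],
    temperature: float,
    n_steps: int,
    seed: int = 0,
    step_size: float = 0.05,
    x_init: float | None = None,
) -> WindowedSamples:
    """Metropolis sampling of a scalar coordinate under window restraints.

    ``potential`` gives the unbiased energy in kJ/mol as a function of the
    coordinate.  Used for validating the exchange criterion, the
    restraint-only Gaussian marginals, and WHAM against analytic profiles.
    """
    windows = list(windows)
    if not windows:
        raise InvalidConfigError("need at least one window")
    kbt = KB * temperature
    steps, rvals = [], []
    for w in windows:
        rng = np.random.default_rng([seed, w.index])
        x = w.restraint.r0 if x_init is None else x_init
        e = (potential(x) + restraint_energy(max(x, 0.0), w.restraint)) / kbt
        xs = np.empty(n_steps)
        ss = np.arange(1, n_steps + 1)
        for t in range(n_steps):
            xn = x + rng.normal(0.0, step_size)
            u = rng.random()
            if xn >= 0.0:
                en = (potential(xn) + restraint_energy(xn, w.restraint)) / kbt
                if en <= e or u < np.exp(e - en):
                    x, e = xn, en
            xs[t] = x
        steps.append(ss)
        rvals.append(xs)
    return WindowedSamples(
        windows=windows,
        steps=steps,
        r_values=rvals,
        conformations=None,
        exchange_log=pd.DataFrame(columns=["step", "window_a", "window_b", "accepted"]),
        metadata={"seed": seed, "n_steps": n_steps, "temperature": temperature},
    )
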