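"""Orchestration: sequence segmentation, per-segment/per-variant umbrella
scans, aggregation, and report writing.

A scan splits the input sequence into fixed-length segments (default 10
residues, non-overlapping), runs restrained replica-exchange sampling for
every (segment, variant) pair, reconstructs each free-energy profile by
WHAM, and derives helical populations and structural observables.  Failures
are isolated per cell; the scan is fully deterministic under its master
seed.
"""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as hio
from .cg_model import ModelParameters, variant_parameters
from .errors import InvalidConfigError
from .metrics import (
    assign_helicity,
    count_hbond_surrogate,
    daura_cluster,
    dominance_analysis,
    helicity_vs_r,
    radius_of_gyration,
)
from .pmf import helical_population, helical_population_ci, wham
from .umbrella import build_windows, run_hremd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    """One fixed-length window of the scanned sequence, numbered by the
    full-length protein."""

    start_residue: int
    sequence: str


def segment_sequence(
    sequence: str,
    first_residue: int,
    last_residue: int,
    window: int = 10,
    stride: int = 10,
    numbering_start: int = 1,
) -> list[Segment]:
    """Split ``sequence`` into fixed-length segments.

    ``numbering_start`` is the residue number of ``sequence[0]``; segments
    start at ``first_residue`` and advance by ``stride`` while a full window
    fits inside ``last_residue``.  A shorter trailing remainder is dropped
    with a warning.
    """
    sequence = sequence.strip().upper()
    seq_last = numbering_start + len(sequence) - 1
    if first_residue < numbering_start or last_residue > seq_last:
        raise IndexError(
            f"residue range {first_residue}-{last_residue} outside the "
            f"sequence ({numbering_start}-{seq_last})"
        )
    if last_residue - first_residue + 1 < window:
        raise InvalidConfigError("window longer than the requested range")
    segments = []
    start = first_residue
    while start + window - 1 <= last_residue:
        off = start - numbering_start
        segments.append(Segment(start, sequence[off : off + window]))
        start += stride
    covered = segments[-1].start_residue + window - 1
    if covered < last_residue:
        logger.warning(
            "trailing remainder %d-%d shorter than the %d-residue window; dropped",
            covered + 1, last_residue, window,
        )
    return segments


@dataclass
class ScanConfig:
    """Everything a scan needs; hashable to detect semantic changes."""

    sequence: str
    first_residue: int
    last_residue: int
    numbering_start: int = 1
    window: int = 10
    stride: int = 10
    variants: tuple[str, ...] = ("V-TIP3P", "V-TIP4P-s", "V-TIP4P-ws", "V-TIP4P-D")
    n_windows: int = 12
    r_min: float = 0.0
    r_max: float = 0.5
    k0: float = 1000.0
    n_sweeps: int = 3000
    exchange_interval: int = 500
    equilibration_fraction: float = 0.1
    save_every: int = 1
    temperature: float = 300.0
    bin_width: float = 0.01
    n_boot: int = 50
    helical_boundary: float = 0.15
    seed: int = 0
    cluster: bool = True
    cluster_cutoff: float = 0.1
    cluster_max_frames_per_cell: int = 150
    dominance_min_size: int = 100
    helix_bias_overrides: dict[int, float] | None = None

    def __post_init__(self):
        self.sequence = self.sequence.strip().upper()
        self.variants = tuple(self.variants)
        if not self.variants:
            raise InvalidConfigError("need at least one variant")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["helix_bias_overrides"] is not None:
            d["helix_bias_overrides"] = {
                str(k): v for k, v in d["helix_bias_overrides"].items()
            }
        d["variants"] = list(d["variants"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScanConfig":
        d = dict(d)
        if d.get("helix_bias_overrides"):
            d["helix_bias_overrides"] = {
                int(k): float(v) for k, v in d["helix_bias_overrides"].items()
            }
        d["variants"] = tuple(d.get("variants", ()))
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScanConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def _cell_seed(master_seed: int, segment_index: int, variant_index: int) -> int:
    state = np.random.SeedSequence([master_seed, segment_index, variant_index])
    return int(state.generate_state(1)[0] % (2**31))


@dataclass
class CellResult:
    """Outcome of one (segment, variant) cell; ``error`` set on failure."""

    segment_start: int
    variant: str
    seed: int
    p_helix: float | None = None
    p_helix_ci: tuple[float, float] | None = None
    mean_rg: float | None = None
    mean_hbonds: float | None = None
    mean_helicity: float | None = None
    helicity_crossing: float | None = None
    pmf: Any = None               # PmfProfile
    rg_values: np.ndarray | None = None
    hbond_values: np.ndarray | None = None
    error: str | None = None

    def to_dict(self) -> dict[str, Any]:
        d = {
            "segment_start": self.segment_start,
            "variant": self.variant,
            "seed": self.seed,
            "p_helix": self.p_helix,
            "p_helix_ci": list(self.p_helix_ci) if self.p_helix_ci else None,
            "mean_rg": self.mean_rg,
            "mean_hbonds": self.mean_hbonds,
            "mean_helicity": self.mean_helicity,
            "helicity_crossing": self.helicity_crossing,
            "error": self.error,
        }
        if self.pmf is not None:
            d["pmf"] = {
                "bin_centers": self.pmf.bin_centers.tolist(),
                "free_energy": self.pmf.free_energy.tolist(),
                "uncertainty": self.pmf.uncertainty.tolist()
                if self.pmf.uncertainty is not None
                else None,
                "temperature": self.pmf.temperature,
                "bin_width": self.pmf.bin_width,
            }
        else:
            d["pmf"] = None
        d["rg_values"] = self.rg_values.tolist() if self.rg_values is not None else None
        d["hbond_values"] = (
            self.hbond_values.tolist() if self.hbond_values is not None else None
        )
        return d


@dataclass
class ScanResult:
    """All cells of a scan plus per-segment cluster/dominance tables."""

    config: ScanConfig
    segments: list[Segment]
    cells: dict[tuple[int, str], CellResult]
    cluster_tables: dict[int, dict[str, Any]] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def cell(self, segment_start: int, variant: str) -> CellResult:
        return self.cells[(segment_start, variant)]

    def population_table(self) -> pd.DataFrame:
        rows = []
        for (start, variant), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "segment_start": start,
                    "variant": variant,
                    "p_helix": cell.p_helix,
                    "ci_low": cell.p_helix_ci[0] if cell.p_helix_ci else np.nan,
                    "ci_high": cell.p_helix_ci[1] if cell.p_helix_ci else np.nan,
                    "mean_rg": cell.mean_rg,
                    "mean_hbonds": cell.mean_hbonds,
                    "mean_helicity": cell.mean_helicity,
                    "error": cell.error,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict[str, Any]:
        # timestamps live in the manifest, not here, so the summary is
        # byte-identical across reruns of one config
        meta = {k: v for k, v in self.metadata.items() if not k.endswith("_time")}
        return {
            "config": self.config.to_dict(),
            "segments": [
                {"start_residue": s.start_residue, "sequence": s.sequence}
                for s in self.segments
            ],
            "cells": {
                f"{start}|{variant}": cell.to_dict()
                for (start, variant), cell in sorted(self.cells.items())
            },
            "cluster_tables": {
                str(k): v for k, v in sorted(self.cluster_tables.items())
            },
            "metadata": meta,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path_or_text: str | Path) -> dict[str, Any]:
        """Load a scan summary back as a plain dict (arrays as lists)."""
        p = Path(path_or_text) if not str(path_or_text).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(path_or_text)
        return json.loads(text)


def _run_cell(segment: Segment, variant: str, config: ScanConfig, seed: int):
    params = variant_parameters(
        variant, sequence=segment.sequence, temperature=config.temperature
    )
    overrides = config.helix_bias_overrides or {}
    if segment.start_residue in overrides:
        params = dataclasses.replace(
            params,
            helix_bias=np.full(len(segment.sequence), overrides[segment.start_residue]),
        )
    windows = build_windows(config.n_windows, config.r_min, config.r_max, config.k0)
    samples = run_hremd(
        params,
        windows,
        n_steps=config.n_sweeps,
        exchange_interval=config.exchange_interval,
        seed=seed,
        save_every=config.save_every,
        segment_id=f"seg{segment.start_residue}",
    )
    production = samples.discard_equilibration(config.equilibration_fraction)
    profile = wham(
        production,
        windows,
        temperature=config.temperature,
        bin_width=config.bin_width,
        n_boot=config.n_boot,
        seed=seed,
    )
    if config.n_boot > 0:
        p, lo, hi = helical_population_ci(profile, boundary=config.helical_boundary)
        ci = (lo, hi)
    else:
        p = helical_population(profile, boundary=config.helical_boundary)
        ci = None
    rgs, hbonds, helfracs = [], [], []
    for w in range(production.n_windows):
        for conf in production.window_conformations(w):
            rgs.append(radius_of_gyration(conf))
            hbonds.append(count_hbond_surrogate(conf))
            helfracs.append(assign_helicity(conf).fraction)
    curve = helicity_vs_r(production)
    cell = CellResult(
        segment_start=segment.start_residue,
        variant=variant,
        seed=seed,
        p_helix=float(p),
        p_helix_ci=ci,
        mean_rg=float(np.mean(rgs)),
        mean_hbonds=float(np.mean(hbonds)),
        mean_helicity=float(np.mean(helfracs)),
        helicity_crossing=curve.crossing,
        pmf=profile,
        rg_values=np.asarray(rgs),
        hbond_values=np.asarray(hbonds, dtype=float),
    )
    return cell, production


def run_scan(config: ScanConfig) -> ScanResult:
    """Run the full (segment x variant) umbrella-scan workflow.

    Each cell: build windows -> replica-exchange sampling -> WHAM -> helical
    population -> observables.  A failing cell records its error and the
    scan continues.  Per-cell seeds derive from the master seed and the cell
    indices, so results are reproducible cell-by-cell.
    """
    segments = segment_sequence(
        config.sequence,
        config.first_residue,
        config.last_residue,
        config.window,
        config.stride,
        config.numbering_start,
    )
    if not segments:
        raise InvalidConfigError("no segments in range")
    started = datetime.datetime.now().isoformat(timespec="seconds")
    cells: dict[tuple[int, str], CellResult] = {}
    cell_samples: dict[tuple[int, str], Any] = {}
    for si, segment in enumerate(segments):
        for vi, variant in enumerate(config.variants):
            seed = _cell_seed(config.seed, si, vi)
            try:
                cell, production = _run_cell(segment, variant, config, seed)
                cell_samples[(segment.start_residue, variant)] = production
            except Exception as exc:  # noqa: BLE001 — cell isolation is the contract
                logger.exception(
                    "cell (%d, %s) failed", segment.start_residue, variant
                )
                cell = CellResult(
                    segment_start=segment.start_residue,
                    variant=variant,
                    seed=seed,
                    error=f"{type(exc).__name__}: {exc}",
                )
            cells[(segment.start_residue, variant)] = cell
            logger.info(
                "cell (%d, %s): p_helix=%s",
                segment.start_residue,
                variant,
                f"{cell.p_helix:.3f}" if cell.p_helix is not None else cell.error,
            )

    cluster_tables: dict[int, dict[str, Any]] = {}
    if config.cluster and len(config.variants) >= 2:
        for segment in segments:
            cluster_tables[segment.start_residue] = _cluster_segment(
                segment, config, cell_samples
            )
    return ScanResult(
        config=config,
        segments=segments,
        cells=cells,
        cluster_tables=cluster_tables,
        metadata={
            "config_hash": config.config_hash(),
            "master_seed": config.seed,
            "start_time": started,
            "end_time": datetime.datetime.now().isoformat(timespec="seconds"),
        },
    )


def _cluster_segment(
    segment: Segment, config: ScanConfig, cell_samples: dict
) -> dict[str, Any]:
    """Pool frames of all variants for one segment, cluster, and score
    variant dominance."""
    stacks, labels = [], []
    for variant in config.variants:
        samples = cell_samples.get((segment.start_residue, variant))
        if samples is None:
            continue
        frames = np.concatenate(samples.conformations, axis=0)
        take = min(len(frames), config.cluster_max_frames_per_cell)
        idx = np.linspace(0, len(frames) - 1, take).astype(int)
        stacks.append(frames[idx])
        labels.extend([variant] * take)
    if not stacks:
        return {}
    stack = np.concatenate(stacks, axis=0)
    cs = daura_cluster(stack, cutoff=config.cluster_cutoff, labels=labels)
    dom = dominance_analysis(cs, min_size=config.dominance_min_size)
    center_rg = [radius_of_gyration(stack[c]) for c, _ in cs.clusters]
    center_hb = [
        count_hbond_surrogate_safe(stack[c]) for c, _ in cs.clusters
    ]
    return {
        "sizes": cs.sizes.tolist(),
        "centers": [int(c) for c, _ in cs.clusters],
        "center_rg": center_rg,
        "center_hbonds": center_hb,
        "labels_by_variant": {
            v: int(labels.count(v)) for v in config.variants if labels.count(v)
        },
        "dominance": dom.to_dict(orient="records"),
    }


def count_hbond_surrogate_safe(coords: np.ndarray) -> int:
    """H-bond surrogate on a raw coordinate array (no length check failure
    path for the >=5-residue chains the pipeline produces)."""
    from .cg_model import ChainConformation

    return count_hbond_surrogate(ChainConformation(coords))


def write_report(result: ScanResult, out_dir: str | Path) -> list[Path]:
    """Emit per-segment PMF TSVs, summary plots, a machine-readable JSON
    summary, and a run manifest.  Returns the written paths."""
    if not result.cells:
        raise ValueError("empty scan result; nothing to report")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # per-cell PMF tables
    for (start, variant), cell in sorted(result.cells.items()):
        if cell.pmf is None:
            continue
        path = out / f"pmf_seg{start}_{variant}.tsv"
        hio.write_pmf_tsv(cell.pmf, path)
        written.append(path)

    table = result.population_table()
    pop_path = out / "helical_populations.tsv"
    table.to_csv(pop_path, sep="\t", index=False)
    written.append(pop_path)

    # free-energy panels per segment
    n_seg = len(result.segments)
    ncols = min(4, n_seg)
    nrows = -(-n_seg // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False, sharex=True
    )
    for ax, segment in zip(axes.ravel(), result.segments):
        for variant in result.config.variants:
            cell = result.cells[(segment.start_residue, variant)]
            if cell.pmf is not None:
                ax.plot(cell.pmf.bin_centers, cell.pmf.free_energy, label=variant)
        ax.set_title(f"seg {segment.start_residue}", fontsize=9)
        ax.set_xlabel("R (nm)")
        ax.set_ylabel("F (kJ/mol)")
    axes.ravel()[0].legend(fontsize=6)
    for ax in axes.ravel()[n_seg:]:
        ax.axis("off")
    fig.tight_layout()
    p = out / "pmf_profiles.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # helicity-per-segment bars
    fig, ax = plt.subplots(figsize=(1.2 * n_seg + 2, 3))
    width = 0.8 / len(result.config.variants)
    xs = np.arange(n_seg)
    for vi, variant in enumerate(result.config.variants):
        ps = [
            result.cells[(s.start_residue, variant)].p_helix or 0.0
            for s in result.segments
        ]
        ax.bar(xs + vi * width, ps, width, label=variant)
    ax.set_xticks(xs + 0.4 - width / 2)
    ax.set_xticklabels([str(s.start_residue) for s in result.segments])
    ax.set_xlabel("segment start residue")
    ax.set_ylabel("helical population")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = out / "helical_population.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # observable histograms per variant
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    for variant in result.config.variants:
        rg = np.concatenate(
            [
                c.rg_values
                for c in result.cells.values()
                if c.variant == variant and c.rg_values is not None
            ]
            or [np.array([])]
        )
        hb = np.concatenate(
            [
                c.hbond_values
                for c in result.cells.values()
                if c.variant == variant and c.hbond_values is not None
            ]
            or [np.array([])]
        )
        if len(rg):
            ax1.hist(rg, bins=40, histtype="step", density=True, label=variant)
            ax2.hist(
                hb,
                bins=np.arange(hb.max() + 2) - 0.5,
                histtype="step",
                density=True,
                label=variant,
            )
    ax1.set_xlabel("radius of gyration (nm)")
    ax2.set_xlabel("H-bond surrogate count")
    ax1.legend(fontsize=7)
    fig.tight_layout()
    p = out / "observables_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # cluster-size curves and dominance scatter
    if result.cluster_tables:
        fig, ax = plt.subplots(figsize=(5, 3))
        for start, tab in sorted(result.cluster_tables.items()):
            if tab.get("sizes"):
                ax.plot(
                    np.arange(1, len(tab["sizes"]) + 1),
                    tab["sizes"],
                    marker=".",
                    label=f"seg {start}",
                )
        ax.set_xlabel("cluster rank")
        ax.set_ylabel("size")
        ax.set_yscale("log")
        ax.legend(fontsize=6)
        fig.tight_layout()
        p = out / "cluster_sizes.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        rows = []
        for start, tab in sorted(result.cluster_tables.items()):
            for rec in tab.get("dominance", []):
                rec = dict(rec)
                rec["segment_start"] = start
                rec["center_rg"] = tab["center_rg"][rec["cluster_id"]]
                rec["center_hbonds"] = tab["center_hbonds"][rec["cluster_id"]]
                rows.append(rec)
        dom = pd.DataFrame(rows)
        p = out / "dominance.csv"
        dom.to_csv(p, index=False)
        written.append(p)
        if len(dom):
            fig, ax = plt.subplots(figsize=(4.5, 3.5))
            for status, mark in [("dominated", "o"), ("neglected", "x")]:
                sel = dom[dom["status"] == status]
                ax.scatter(
                    sel["center_rg"], sel["center_hbonds"], marker=mark, label=status
                )
            ax.set_xlabel("cluster-center Rg (nm)")
            ax.set_ylabel("cluster-center H-bond surrogate")
            ax.legend(fontsize=7)
            fig.tight_layout()
            p = out / "dominance.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    summary = out / "summary.json"
    result.to_json(summary)
    written.append(summary)

    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "config": result.config.to_dict(),
                "config_hash": result.metadata.get("config_hash"),
                "master_seed": result.metadata.get("master_seed"),
                "start_time": result.metadata.get("start_time"),
                "end_time": result.metadata.get("end_time"),
                "written": [str(w) for w in written],
            },
            indent=1,
        )
    )
    written.append(manifest)
    return written
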