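"""File input/output: Cα-PDB, XYZ, FASTA, and tabular exports.

Internally all coordinates are nm; PDB files use Å (converted on the way in
and out).  PDB stores three decimals in Å, so a PDB round trip quantises
coordinates to 1e-4 nm — reading therefore returns raw coordinate arrays
rather than validated :class:`~helixscan.cg_model.ChainConformation` objects.
The XYZ writer keeps full double precision and round-trips exactly.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cg_model import ChainConformation


def write_ca_pdb(
    conformations: Sequence[ChainConformation] | Sequence[np.ndarray],
    path: str | Path,
) -> None:
    """Write conformations as a Cα-only multi-MODEL PDB (coordinates in Å)."""
    lines = []
    for model, conf in enumerate(conformations, start=1):
        coords = conf.coords if isinstance(conf, ChainConformation) else np.asarray(conf)
        lines.append(f"MODEL     {model:>4d}")
        for i, (x, y, z) in enumerate(coords * 10.0, start=1):
            lines.append(
                f"ATOM  {i:>5d}  CA  ALA A{i:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ca_pdb(path: str | Path) -> list[np.ndarray]:
    """Read Cα coordinates (nm) per MODEL from a PDB file."""
    frames: list[list[list[float]]] = []
    current: list[list[float]] = []
    in_model = False
    for line in Path(path).read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            frames.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM") and line[12:16].strip() == "CA":
            current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    if not in_model and not frames and current:
        frames.append(current)
    if not frames and current:
        frames.append(current)
    return [np.asarray(f, dtype=float) / 10.0 for f in frames]


def write_xyz(
    conformations: Sequence[ChainConformation] | Sequence[np.ndarray],
    path: str | Path,
) -> None:
    """Plain multi-frame XYZ in nm at full double precision."""
    lines = []
    for conf in conformations:
        coords = conf.coords if isinstance(conf, ChainConformation) else np.asarray(conf)
        lines.append(str(len(coords)))
        lines.append("CA trace, nm")
        for x, y, z in coords:
            lines.append(f"CA {x:.17g} {y:.17g} {z:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[np.ndarray]:
    """Read a multi-frame XYZ file written by :func:`write_xyz` (nm)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        frames.append(
            np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        )
        i += 2 + n
    return frames


def read_fasta_sequence(path: str | Path) -> str:
    """First record of a FASTA file as an upper-case one-letter string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def packaged_axin_sequence() -> tuple[str, int]:
    """The packaged synthetic Axin-1-like sequence and its first residue
    number (380).

    This is a synthetic stand-in emulating the helix-propensity architecture
    of human Axin-1 residues 380-490 (helix-prone blocks around 390-420 and
    460-480 flanking a coil-prone linker), not the UniProt sequence.
    """
    from importlib import resources

    with resources.files("helixscan.data").joinpath(
        "axin1_380_490_synthetic.fasta"
    ).open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq).upper(), 380


def write_pmf_tsv(pmf, path: str | Path) -> None:
    """PMF as TSV with columns R, F, SD, n_samples."""
    df = pd.DataFrame(
        {
            "R_nm": pmf.bin_centers,
            "F_kJ_mol": pmf.free_energy,
            "SD_kJ_mol": pmf.uncertainty
            if pmf.uncertainty is not None
            else np.full_like(pmf.bin_centers, np.nan),
            "n_samples": pmf.counts.sum(axis=0).astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_observables_tsv(rows: Iterable[dict], path: str | Path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)
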