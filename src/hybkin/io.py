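"""Readers and writers: topology/configuration text dialect, results bundles.

Files follow the oxDNA plain-text dialect.  Topology::

    <n_nucleotides> <n_strands>
    <strand (1-based)> <base letter> <3' neighbour index or -1> <5' neighbour index or -1>

Configuration (one frame)::

    t = <time>
    b = <Lx> <Ly> <Lz>
    E = <Etot> <U> <K>
    <rx ry rz  a1x a1y a1z  a3x a3y a3z  vx vy vz  Lx Ly Lz>   (one row per nucleotide)

Rows are written at full double precision (%.17g) so write/read round-trips
are bit-exact.  Trajectories are concatenated configuration frames.

Results bundles are directories holding the run configuration snapshot
(YAML), seeds, TSV tables for FFS stages / umbrella profiles / mechanism
census, and a JSON summary; re-running with the same config and seeds
reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    BASES,
    Configuration,
    StrandTopology,
    ValidationError,
    make_configuration,
)


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


_FMT = "%.17g"


def write_topology(topology: StrandTopology, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{topology.n_total} {len(topology.strands)}\n")
        gi = 0
        for s_idx, seq in enumerate(topology.strands, start=1):
            for p, base in enumerate(seq):
                n5 = gi - 1 if p > 0 else -1
                n3 = gi + 1 if p < len(seq) - 1 else -1
                fh.write(f"{s_idx} {base} {n3} {n5}\n")
                gi += 1


def read_topology(path) -> StrandTopology:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty topology file")
    try:
        n_total, n_strands = map(int, lines[0].split())
    except ValueError:
        raise ParseError(path, 1, f"bad header {lines[0]!r}") from None
    if len(lines) - 1 != n_total:
        raise ParseError(
            path, 1, f"header declares {n_total} nucleotides, found {len(lines) - 1} rows"
        )
    strands: List[str] = []
    current: List[str] = []
    current_strand = None
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(path, ln, f"expected 4 fields, got {len(parts)}")
        s_idx, base = parts[0], parts[1]
        if base not in BASES:
            raise ParseError(path, ln, f"unknown base {base!r}")
        if current_strand is None:
            current_strand = s_idx
        if s_idx != current_strand:
            strands.append("".join(current))
            current = []
            current_strand = s_idx
        current.append(base)
    if current:
        strands.append("".join(current))
    if len(strands) != n_strands:
        raise ParseError(
            path, 1, f"header declares {n_strands} strands, found {len(strands)}"
        )
    return StrandTopology(strands)


def write_configuration(config: Configuration, path, time: float = 0.0, mode="w") -> None:
    with open(path, mode) as fh:
        fh.write(f"t = {_FMT % time}\n")
        b = _FMT % config.box
        fh.write(f"b = {b} {b} {b}\n")
        fh.write("E = 0 0 0\n")
        for i in range(config.n):
            row = np.concatenate(
                [config.pos[i], config.a1[i], config.a3[i], config.vel[i], config.angmom[i]]
            )
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_configuration(
    path, topology: StrandTopology, temperature: float = 300.0
) -> Configuration:
    frames = read_trajectory(path, topology, temperature, max_frames=1)
    return frames[0]


def read_trajectory(
    path,
    topology: StrandTopology,
    temperature: float = 300.0,
    max_frames: Optional[int] = None,
) -> List[Configuration]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: List[Configuration] = []
    i = 0
    n = topology.n_total
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("t ="):
            raise ParseError(path, i + 1, f"expected 't =' header, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise ParseError(path, i + 1, "truncated frame header")
        try:
            box = float(lines[i + 1].split("=")[1].split()[0])
        except (IndexError, ValueError):
            raise ParseError(path, i + 2, f"bad box line {lines[i + 1]!r}") from None
        rows = lines[i + 3 : i + 3 + n]
        if len(rows) != n:
            raise ParseError(
                path, i + 3 + len(rows),
                f"frame has {len(rows)} rows, topology declares {n}",
            )
        data = np.empty((n, 15))
        for k, row in enumerate(rows):
            parts = row.split()
            if len(parts) != 15:
                raise ParseError(
                    path, i + 4 + k, f"expected 15 columns, got {len(parts)}"
                )
            try:
                data[k] = [float(x) for x in parts]
            except ValueError:
                raise ParseError(path, i + 4 + k, f"non-numeric value in {row!r}") from None
        cfg = Configuration(
            topology,
            data[:, 0:3].copy(),
            data[:, 3:6].copy(),
            data[:, 6:9].copy(),
            data[:, 9:12].copy(),
            data[:, 12:15].copy(),
            float(box),
            temperature,
        )
        try:
            cfg.validate(tol=1e-6)
        except ValidationError as exc:
            raise ParseError(path, i + 4, f"invalid frame: {exc}") from None
        frames.append(cfg)
        i += 3 + n
        if max_frames is not None and len(frames) >= max_frames:
            break
    if not frames:
        raise ParseError(path, 1, "no frames found")
    return frames


def read_fasta(path) -> List[str]:
    """Sequences (5'->3') from a FASTA file; headers are ignored."""
    seqs: List[str] = []
    current: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
            else:
                current.append(line.upper())
    if current:
        seqs.append("".join(current))
    return seqs


# ---------------------------------------------------------------------------
# run configuration and results bundles
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; serialized into the bundle."""

    preset: Optional[str] = None
    strands: Optional[tuple] = None
    variant: str = "average"
    temperature: float = 300.0
    box: float = 20.0
    scheme: str = "langevin"
    timestep: float = 0.003
    translational_diffusion: float = 1.0
    rotational_diffusion: float = 2.0
    diffusion_scale: float = 1.0
    seed: int = 0
    n_shots: int = 200
    min_crossings: int = 50
    interfaces: Optional[tuple] = None
    native_only: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strands"] = list(d["strands"]) if d["strands"] else None
        d["interfaces"] = list(d["interfaces"]) if d["interfaces"] else None
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "strands" in data and data["strands"]:
            data["strands"] = tuple(data["strands"])
        if "interfaces" in data and data["interfaces"]:
            data["interfaces"] = tuple(data["interfaces"])
        return cls(**data)


class BundleError(ValueError):
    """Results bundle is incomplete."""


def write_results(bundle: dict, out_dir) -> List[str]:
    """Write a results bundle: config + seeds + tables + summary.

    ``bundle`` must contain ``config`` (RunConfig or dict) and ``summary``
    (JSON-serializable); optional entries ``ffs`` (FFSRateEstimate),
    ``profile`` (FreeEnergyProfile), ``census`` (mechanism census rows).
    Raises :class:`BundleError` listing missing required stages.
    """
    missing = [k for k in ("config", "summary") if k not in bundle]
    if missing:
        raise BundleError(f"bundle missing required entries: {missing}")
    os.makedirs(out_dir, exist_ok=True)
    written = []

    cfg = bundle["config"]
    cfg_d = cfg.to_dict() if isinstance(cfg, RunConfig) else dict(cfg)
    p = os.path.join(out_dir, "config.yaml")
    with open(p, "w") as fh:
        yaml.safe_dump(cfg_d, fh, sort_keys=True)
    written.append(p)

    if "ffs" in bundle and bundle["ffs"] is not None:
        est = bundle["ffs"]
        rows = [
            {
                "stage": k,
                "lambda": s.lambda_value,
                "n_shots": s.n_shots,
                "n_success": s.n_success,
                "p": s.p,
                "p_se": s.p_se,
            }
            for k, s in enumerate(est.stages)
        ]
        df = pd.DataFrame(rows)
        p = os.path.join(out_dir, "ffs_stages.tsv")
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)

    if "profile" in bundle and bundle["profile"] is not None:
        prof = bundle["profile"]
        df = pd.DataFrame(
            {
                "n": prof.n,
                "P": prof.probability,
                "F_kT": prof.free_energy_kT,
                "F_kcal_mol": prof.free_energy_kcal_mol,
                "P_se": prof.probability_se,
                "sampled": prof.sampled.astype(int),
            }
        )
        p = os.path.join(out_dir, "free_energy_profile.tsv")
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)

    if "census" in bundle and bundle["census"] is not None:
        df = pd.DataFrame(bundle["census"])
        p = os.path.join(out_dir, "mechanism_census.tsv")
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    p = os.path.join(out_dir, "summary.json")
    with open(p, "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True, default=float)
    written.append(p)
    return written


def structure_log(frames_structures, path) -> None:
    """Per-frame secondary-structure table (TSV)."""
    rows = [ss.to_row(frame=k) for k, ss in enumerate(frames_structures)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
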