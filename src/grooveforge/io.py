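"""Readers and writers for the on-disk formats.

Peptide libraries travel as FASTA (record id = mutation notation joined by
"+", the reference as ``reference``) or as TSV; pulling traces as TSV with a
``# protocol:`` header or as NAMD-SMD-style log lines; score tables as
two-column TSV (see :mod:`grooveforge.scoring`).  All tabular writers emit
``#``-prefixed provenance headers (tool version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import io as _io
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import __version__
from .errors import InputError, TraceFormatError, UnknownResidueError
from .mutation_space import (
    STANDARD_RESIDUES,
    CandidatePeptide,
    Mutation,
    diff_mutations,
)
from .pmf_estimator import PMFProfile, PullingProtocol, PullingTrajectory
from .search_engine import CandidateLibrary, LibraryMember

__all__ = [
    "read_fasta_library",
    "write_fasta_library",
    "write_library_tsv",
    "read_library_tsv",
    "write_trace_tsv",
    "read_trace_tsv",
    "write_namd_smd_log",
    "read_namd_smd_log",
    "read_pulling_traces",
    "write_pmf_tsv",
    "RunConfig",
    "config_hash",
]


def _provenance_header(seed: Optional[int] = None, config: Optional[Mapping] = None) -> str:
    parts = [f"# grooveforge v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return " ".join(parts) + "\n"


def config_hash(config: Mapping) -> str:
    canonical = yaml.safe_dump(dict(config), sort_keys=True)
    return hashlib.sha1(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# FASTA peptide libraries


def write_fasta_library(
    path: os.PathLike | str,
    peptides: Sequence[CandidatePeptide],
) -> None:
    with open(path, "w") as fh:
        for pep in peptides:
            fh.write(f">{pep.notation}\n{pep.sequence}\n")


def read_fasta_library(
    path: os.PathLike | str,
    reference: Optional[str] = None,
) -> List[CandidatePeptide]:
    """Parse a FASTA peptide library.

    Mutation sets come from record ids when they carry the ``G2V+F4W``
    notation; otherwise they are reconstructed by diffing against
    ``reference`` (required in that case).
    """
    text = Path(path).read_text()
    stripped = [ln for ln in text.splitlines() if ln.strip()]
    if stripped and not stripped[0].startswith(">"):
        lineno = next(
            i for i, ln in enumerate(text.splitlines(), 1) if ln.strip()
        )
        raise InputError(f"{path}:{lineno}: expected FASTA header line")
    peptides: List[CandidatePeptide] = []
    with _io.StringIO(text) as fh:
        for title, seq in SimpleFastaParser(fh):
            seq = seq.upper()
            for res in seq:
                if res not in STANDARD_RESIDUES:
                    raise UnknownResidueError(
                        f"{path}: record {title!r} contains "
                        f"non-standard residue {res!r}"
                    )
            record_id = title.split()[0] if title.split() else ""
            if record_id == "reference" or not record_id:
                peptides.append(CandidatePeptide(seq, frozenset()))
            elif all(
                part and part[0].isalpha() and part[-1].isalpha()
                for part in record_id.split("+")
            ) and _looks_like_notation(record_id):
                muts = frozenset(
                    Mutation.parse(part) for part in record_id.split("+")
                )
                peptides.append(CandidatePeptide(seq, muts))
            elif reference is not None:
                peptides.append(
                    CandidatePeptide(seq, diff_mutations(reference, seq))
                )
            else:
                raise InputError(
                    f"{path}: record {record_id!r} has no mutation notation "
                    "and no reference was supplied"
                )
    return peptides


def _looks_like_notation(record_id: str) -> bool:
    try:
        for part in record_id.split("+"):
            Mutation.parse(part)
        return True
    except InputError:
        return False


# ---------------------------------------------------------------------------
# Library TSV

_LIBRARY_COLUMNS = [
    "sequence",
    "mutations",
    "level",
    "cycle",
    "primary_score",
    "secondary_score",
    "parents",
]


def write_library_tsv(
    path: os.PathLike | str,
    library: CandidateLibrary,
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    """Reference first (level 0), then members in acceptance order."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(seed=seed, config=config))
        fh.write(f"# reference={library.reference.sequence} ")
        fh.write(f"scorer={library.scorer_name}\n")
        fh.write("\t".join(_LIBRARY_COLUMNS) + "\n")
        rows = [_member_row(_reference_member(library))]
        rows += [_member_row(m) for m in library.member_list()]
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _reference_member(library: CandidateLibrary) -> LibraryMember:
    return LibraryMember(
        peptide=library.reference,
        primary_score=library.reference_score,
        cycle=0,
    )


def _member_row(m: LibraryMember) -> List[str]:
    parents = ";".join(f"{a}|{b}" for a, b in m.parents) or "-"
    secondary = "-" if m.secondary_score is None else str(m.secondary_score)
    return [
        m.sequence,
        m.peptide.notation if m.peptide.mutations else "-",
        str(m.level),
        str(m.cycle),
        str(m.primary_score),
        secondary,
        parents,
    ]


def read_library_tsv(path: os.PathLike | str) -> CandidateLibrary:
    reference_seq = None
    scorer_name = "table"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line.lstrip("#").split():
                if tok.startswith("reference="):
                    reference_seq = tok.split("=", 1)[1]
                elif tok.startswith("scorer="):
                    scorer_name = tok.split("=", 1)[1]
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _LIBRARY_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    reference: Optional[CandidatePeptide] = None
    members: Dict[str, LibraryMember] = {}
    reference_score = float("nan")
    for _, row in frame.iterrows():
        seq = row["sequence"].upper()
        notation = row["mutations"]
        if notation == "-" or int(row["level"]) == 0:
            reference = CandidatePeptide(seq, frozenset())
            reference_score = float(row["primary_score"])
            continue
        muts = frozenset(Mutation.parse(p) for p in notation.split("+"))
        parents: List[Tuple[str, str]] = []
        if row["parents"] != "-" and isinstance(row["parents"], str):
            for chunk in row["parents"].split(";"):
                a, _, b = chunk.partition("|")
                parents.append((a, b))
        members[seq] = LibraryMember(
            peptide=CandidatePeptide(seq, muts),
            primary_score=float(row["primary_score"]),
            cycle=int(row["cycle"]),
            secondary_score=(
                None
                if row["secondary_score"] == "-"
                else float(row["secondary_score"])
            ),
            parents=parents,
        )
    if reference is None:
        if reference_seq is None:
            raise InputError(f"{path}: no reference row or header")
        reference = CandidatePeptide(reference_seq, frozenset())
    return CandidateLibrary(
        reference=reference,
        reference_score=reference_score,
        scorer_name=scorer_name,
        members=members,
    )


# ---------------------------------------------------------------------------
# Pulling traces

_TRACE_COLUMNS = ["t", "lambda", "xi", "force"]


def write_trace_tsv(
    path: os.PathLike | str, trajectory: PullingTrajectory
) -> None:
    p = trajectory.protocol
    with open(path, "w") as fh:
        fh.write(
            f"# protocol: k={p.k!s} v={p.v!s} lambda0={p.lambda0!s} "
            f"T={p.temperature!s}\n"
        )
        fh.write("\t".join(_TRACE_COLUMNS) + "\n")
        force = trajectory.effective_force()
        for t, lam, xi, f in zip(
            trajectory.time, trajectory.lam, trajectory.xi, force
        ):
            fh.write(f"{t!s}\t{lam!s}\t{xi!s}\t{f!s}\n")


def _parse_protocol_header(path, line: str) -> PullingProtocol:
    fields = {}
    for tok in line.lstrip("#").replace("protocol:", "").split():
        if "=" in tok:
            key, _, val = tok.partition("=")
            fields[key] = float(val)
    try:
        return PullingProtocol(
            k=fields["k"],
            v=fields["v"],
            lambda0=fields.get("lambda0", 0.0),
            temperature=fields.get("T", 310.0),
        )
    except KeyError as exc:
        raise TraceFormatError(
            f"{path}: protocol header missing {exc}"
        ) from None


def read_trace_tsv(
    path: os.PathLike | str,
    protocol: Optional[PullingProtocol] = None,
) -> PullingTrajectory:
    header_protocol = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "protocol:" in line:
                header_protocol = _parse_protocol_header(path, line)
                break
    protocol = header_protocol or protocol
    if protocol is None:
        raise TraceFormatError(f"{path}: no protocol header and none supplied")
    frame = pd.read_csv(
        path, sep="\t", comment="#", float_precision="round_trip"
    )
    for col in ("t", "lambda", "xi"):
        if col not in frame.columns:
            raise TraceFormatError(f"{path}: missing column {col!r}")
    force = frame["force"].to_numpy() if "force" in frame.columns else None
    try:
        return PullingTrajectory(
            time=frame["t"].to_numpy(),
            lam=frame["lambda"].to_numpy(),
            xi=frame["xi"].to_numpy(),
            protocol=protocol,
            force=force,
            source=str(path),
        )
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None


DEFAULT_SMD_COLUMN_MAP = {"step": 1, "position": 2, "force": 3}


def write_namd_smd_log(
    path: os.PathLike | str,
    trajectory: PullingTrajectory,
    timestep: float,
) -> None:
    """Emit SMD-style log lines: ``SMD <step> <position> <force>``.

    ``position`` is the reaction coordinate, ``timestep`` the ns per step.
    """
    force = trajectory.effective_force()
    with open(path, "w") as fh:
        fh.write("Info: synthetic SMD-style log\n")
        for t, xi, f in zip(trajectory.time, trajectory.xi, force):
            step = int(round(t / timestep))
            fh.write(f"SMD {step} {xi!s} {f!s}\n")


def read_namd_smd_log(
    path: os.PathLike | str,
    protocol: PullingProtocol,
    timestep: float,
    column_map: Optional[Mapping[str, int]] = None,
) -> PullingTrajectory:
    """Parse ``SMD``-tagged log lines via a configurable column map.

    ``column_map`` gives token indices (token 0 is the ``SMD`` tag itself)
    for ``step``, ``position`` and ``force``; times are ``step * timestep``;
    the guide position is reconstructed from the protocol schedule.
    """
    cmap = dict(DEFAULT_SMD_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    steps: List[float] = []
    xis: List[float] = []
    forces: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0] != "SMD":
                continue
            try:
                steps.append(float(tokens[cmap["step"]]))
                xis.append(float(tokens[cmap["position"]]))
                forces.append(float(tokens[cmap["force"]]))
            except (IndexError, ValueError):
                raise TraceFormatError(
                    f"{path}:{lineno}: unparsable SMD line"
                ) from None
    if not steps:
        raise TraceFormatError(f"{path}: no SMD lines found")
    time = np.asarray(steps) * timestep
    return PullingTrajectory(
        time=time,
        lam=protocol.lambda_at(time),
        xi=np.asarray(xis),
        protocol=protocol,
        force=np.asarray(forces),
        source=str(path),
    )


def read_pulling_traces(
    path: os.PathLike | str,
    dialect: str = "tsv",
    protocol: Optional[PullingProtocol] = None,
    timestep: Optional[float] = None,
    column_map: Optional[Mapping[str, int]] = None,
) -> List[PullingTrajectory]:
    """Read one trace file or every trace in a directory.

    Directory reads require consistent protocol headers; offenders are
    listed in the error.
    """
    p = Path(path)
    if p.is_dir():
        suffix = "*.tsv" if dialect == "tsv" else "*"
        files = sorted(f for f in p.glob(suffix) if f.is_file())
    else:
        files = [p]
    if not files:
        raise InputError(f"{path}: no trace files found")
    trajectories: List[PullingTrajectory] = []
    for f in files:
        if dialect == "tsv":
            trajectories.append(read_trace_tsv(f, protocol=protocol))
        elif dialect == "namd-smd-log":
            if protocol is None or timestep is None:
                raise InputError(
                    "namd-smd-log dialect needs an explicit protocol "
                    "and timestep"
                )
            trajectories.append(
                read_namd_smd_log(f, protocol, timestep, column_map)
            )
        else:
            raise InputError(f"unknown trace dialect {dialect!r}")
    protocols = {
        (t.protocol.k, t.protocol.v, t.protocol.lambda0, t.protocol.temperature)
        for t in trajectories
    }
    if len(protocols) > 1:
        offenders = sorted(
            {t.source for t in trajectories if t.source is not None}
        )
        raise InputError(
            f"inconsistent protocol headers across traces: {offenders}"
        )
    return trajectories


# ---------------------------------------------------------------------------
# PMF profile TSV


def write_pmf_tsv(
    path: os.PathLike | str,
    profile: PMFProfile,
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(seed=seed, config=config))
        fh.write(
            f"# estimator={profile.estimator} k={profile.spring_constant!s}\n"
        )
        cols = ["xi", "phi", "delta_A"]
        arrays = [profile.xi, profile.phi, profile.delta_A]
        if profile.ci_lo is not None:
            cols += ["ci_lo", "ci_hi"]
            arrays += [profile.ci_lo, profile.ci_hi]
        fh.write("\t".join(cols) + "\n")
        for row in zip(*arrays):
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Fully resolved run settings; round-trips losslessly through YAML."""

    reference: str = "RGTFEGKF"
    exclusions: List[List[str]] = field(
        default_factory=lambda: [["G", "M"]]
    )
    max_level: int = 4
    max_cycles: int = 2
    target_size: Optional[int] = None
    primary_scorer: str = "surrogate"
    secondary_scorer: Optional[str] = None
    pmf_grid: Optional[str] = None  # "start:stop:step"
    estimator: str = "jarzynski"
    bootstrap: int = 0
    seed: int = 0
    out: Optional[str] = None

    def to_yaml(self, path: os.PathLike | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: os.PathLike | str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        return config_hash(asdict(self))
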