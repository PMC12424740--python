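"""File formats and run configuration: PDB, FASTA, OBO ontologies, configs.

Conventions: coordinates in Angstrom; residue indices 0-based internally and
1-based in PDB author numbering; generated chains are single-chain 'A';
multi-state designs are written as MODEL blocks sharing residue numbering.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discrete import MASK

__all__ = [
    "AA1",
    "AA3",
    "tokens_to_seq",
    "seq_to_tokens",
    "ResidueRecord",
    "ProteinStructure",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "write_fasta",
    "read_obo",
    "RunConfig",
    "save_config",
    "load_config",
    "write_outputs",
    "external_adapters",
    "ExternalToolUnavailableError",
    "AdapterSpec",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"  # token i -> one-letter code; 20 = mask ('X')
AA3 = [
    "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
    "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR",
]
_AA3_TO_TOKEN = {a: i for i, a in enumerate(AA3)}
_AA1_TO_TOKEN = {a: i for i, a in enumerate(AA1)}


def tokens_to_seq(tokens: np.ndarray) -> str:
    return "".join(AA1[t] if t < len(AA1) else "X" for t in np.asarray(tokens, dtype=int))


def seq_to_tokens(seq: str) -> np.ndarray:
    try:
        return np.array([MASK if c == "X" else _AA1_TO_TOKEN[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid letter {exc}") from exc


@dataclass
class ResidueRecord:
    name: str  # three-letter residue name
    seq_id: int  # 1-based author numbering
    atoms: Dict[str, np.ndarray]
    chain: str = "A"

    @property
    def identity(self) -> int:
        return _AA3_TO_TOKEN.get(self.name, -1)


@dataclass
class ProteinStructure:
    residues: List[ResidueRecord]

    @property
    def chains(self) -> List[str]:
        seen = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def ca_coords(self) -> np.ndarray:
        return np.stack([r.atoms["CA"] for r in self.residues])

    def identities(self) -> np.ndarray:
        return np.array([r.identity for r in self.residues], dtype=np.int64)


def _validate_pdb_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: malformed coordinate field {line[lo:hi]!r}"
                        ) from None
            elif line.startswith(("ATOM", "HETATM")):
                raise ValueError(f"{path}:{lineno}: truncated ATOM record")


def read_pdb(path: str, model_index: int = 0) -> ProteinStructure:
    """Parse ATOM/HETATM records of one MODEL into a residue list."""
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(path)
    if model_index >= len(st):
        raise ValueError(f"model {model_index} not present in {path}")
    residues: List[ResidueRecord] = []
    for chain in st[model_index]:
        for res in chain:
            atoms = {atom.name: np.array([atom.pos.x, atom.pos.y, atom.pos.z]) for atom in res}
            residues.append(ResidueRecord(res.name, res.seqid.num, atoms, chain.name))
    return ProteinStructure(residues)


def n_models(path: str) -> int:
    return len(gemmi.read_pdb(path))


def write_pdb(
    path: str,
    coords,
    tokens: Optional[np.ndarray] = None,
    chain: str = "A",
) -> None:
    """Write C-alpha traces; a list of coordinate arrays becomes MODEL blocks."""
    models = coords if isinstance(coords, (list, tuple)) else [coords]
    lines: List[str] = []
    multi = len(models) > 1
    serial = 1
    for mi, xyz in enumerate(models, start=1):
        xyz = np.asarray(xyz, dtype=np.float64)
        if multi:
            lines.append(f"MODEL     {mi:>4d}")
        for i, (x, y, z) in enumerate(xyz):
            name = AA3[tokens[i]] if tokens is not None and tokens[i] < 20 else "GLY"
            lines.append(
                f"ATOM  {serial:>5d}  CA  {name:<3s} {chain}{i + 1:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fasta(path: str) -> List[Tuple[str, np.ndarray]]:
    return [(rec.id, seq_to_tokens(str(rec.seq))) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(path: str, records: Sequence[Tuple[str, np.ndarray]]) -> None:
    seqs = [SeqRecord(Seq(tokens_to_seq(t)), id=name, description="") for name, t in records]
    SeqIO.write(seqs, path, "fasta")


def read_obo(path: str) -> Dict[str, List[str]]:
    """Parse an OBO-dialect file into term -> is_a parent lists.

    Only ``id:`` and ``is_a:`` tags of ``[Term]`` stanzas are read.
    """
    ontology: Dict[str, List[str]] = {}
    current: Optional[str] = None
    in_term = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
                current = None
            elif in_term and line.startswith("id:"):
                current = line[3:].strip()
                ontology.setdefault(current, [])
            elif in_term and line.startswith("is_a:") and current is not None:
                parent = line[5:].strip().split("!")[0].strip()
                ontology[current].append(parent)
    return ontology


@dataclass
class RunConfig:
    """Serializable description of a run; a run is reproducible from
    (archived config, seed)."""

    task: str = "cogenerate"
    seed: int = 0
    length: int = 64
    steps: int = 0  # 0 -> one step per residue
    guidance_strength: float = 3.0
    nu: float = 0.5
    gamma: float = 0.5
    term: Optional[int] = None
    out_dir: str = "outputs"
    model: Dict = field(default_factory=dict)
    log_level: str = "INFO"


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def write_outputs(results: List[dict], out_dir: str, config: Optional[RunConfig] = None) -> List[str]:
    """Write design results: PDB per structure (two MODEL blocks for coupled
    designs), FASTA per sequence, metrics as TSV, config archived alongside."""
    os.makedirs(out_dir, exist_ok=True)
    written: List[str] = []
    fasta_records = []
    metrics_rows = []
    for i, res in enumerate(results):
        name = res.get("name", f"design_{i:04d}")
        structures = res.get("structures")
        if structures is not None:
            p = os.path.join(out_dir, f"{name}.pdb")
            write_pdb(p, structures, res.get("tokens"))
            written.append(p)
        if res.get("tokens") is not None:
            fasta_records.append((name, res["tokens"]))
        if res.get("metrics"):
            metrics_rows.append({"name": name, **res["metrics"]})
    if fasta_records:
        p = os.path.join(out_dir, "sequences.fasta")
        write_fasta(p, fasta_records)
        written.append(p)
    if metrics_rows:
        import pandas as pd

        p = os.path.join(out_dir, "metrics.tsv")
        pd.DataFrame(metrics_rows).to_csv(p, sep="\t", index=False)
        written.append(p)
    if config is not None:
        p = os.path.join(out_dir, "config.yaml")
        save_config(config, p)
        written.append(p)
    return written


class ExternalToolUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class AdapterSpec:
    """Documented interface to an external tool that is not bundled."""

    name: str
    purpose: str
    inputs: str
    outputs: str
    command: str

    def run(self, *args, **kwargs):
        raise ExternalToolUnavailableError(
            f"{self.name} is not installed. Expected inputs: {self.inputs}; "
            f"outputs: {self.outputs}; invocation: {self.command}"
        )


def external_adapters() -> Dict[str, AdapterSpec]:
    """Interface stubs for the external screening tools (never invoked here)."""
    specs = [
        AdapterSpec(
            "inverse-folding-tool", "design sequences for a fixed backbone",
            "PDB backbone", "FASTA sequences",
            "proteinmpnn --pdb <in.pdb> --out <seqs.fasta>",
        ),
        AdapterSpec(
            "folding-tool", "refold designed sequences for self-consistency",
            "FASTA sequences", "PDB structures with per-residue confidence",
            "esmfold --fasta <in.fasta> --out <dir>",
        ),
        AdapterSpec(
            "function-predictor", "predict molecular-function terms from structure",
            "directory of PDB files", "per-term probability table (CSV)",
            "predict.py --pdb_dir <dir> --ont mf --output_fn_prefix <out>",
        ),
        AdapterSpec(
            "structure-clusterer", "cluster generated structures by fold",
            "directory of PDB files", "cluster assignment table (TSV)",
            "foldseek easy-cluster <dir> <out> <tmp> --alignment-type 1 "
            "--cov-mode 0 --min-seq-id 0 --tmscore-threshold 0.5",
        ),
        AdapterSpec(
            "cofolding-predictor", "co-fold designs with/without an effector ion",
            "FASTA sequence + optional ligand spec", "ranked PDB predictions",
            "chai fold <in.fasta> <out_dir>",
        ),
    ]
    return {s.name: s for s in specs}
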