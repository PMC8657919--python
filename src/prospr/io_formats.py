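"""Readers and writers for the standard formats the toolkit touches.

Supported formats:

* **a3m / aligned FASTA** multiple sequence alignments.  In a3m, lowercase
  letters are insertions relative to the query and are removed on read so
  every row has exactly the query length.
* **PDB** structures (ATOM records, first model only), via Biopython.
* **HHsuite ``.hhm``** profile files: 20 match-emission columns, 7 transition
  columns, and 3 per-column diversity values.  The integer scores
  (``score = -1000 * log2(p)``) are converted to probabilities on read;
  the null score ``*`` reads as probability 0.
* **HDF5** containers with ``/features``, ``/labels`` and ``/predictions``
  groups for serialized tensors.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np

from .alphabet import GAP, THREE_TO_ONE, sanitize

# sentinel written for probability-0 entries when serializing hhm scores
HHM_NULL_SCORE = 99999


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Alignment:
    """A parsed MSA: the query plus aligned homologs.

    Rows are uppercase strings over the 21-letter alphabet (20 amino acids,
    ``X`` for unknown, ``-`` for gaps), all of length ``L``.  Row 0 is the
    query.
    """

    query_id: str
    sequences: list[str]
    ids: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("alignment must contain at least one sequence")
        L = len(self.sequences[0])
        for k, row in enumerate(self.sequences):
            if len(row) != L:
                name = self.ids[k] if k < len(self.ids) else f"row {k}"
                raise FormatError(
                    f"alignment row '{name}' has length {len(row)}, expected {L}"
                )
        if not self.ids:
            self.ids = [self.query_id] + [f"seq{k}" for k in range(1, self.depth)]

    @property
    def depth(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[0]

    def to_indices(self) -> np.ndarray:
        """(depth, L) int8 array of alphabet indices (gap/unknown -> 20)."""
        from .alphabet import encode_sequence

        return np.array([encode_sequence(s) for s in self.sequences], dtype=np.int8)


def _clean_a3m_row(raw: str) -> str:
    """Apply the a3m convention: drop lowercase insertion columns, map
    '.' to '-', and any non-standard letter to 'X'."""
    out = []
    for ch in raw.strip():
        if ch.islower():
            continue  # insertion relative to the query
        if ch in (".", GAP):
            out.append(GAP)
        else:
            out.append(sanitize(ch))
    return "".join(out)


def read_a3m(path: str | Path) -> Alignment:
    """Read an a3m or aligned-FASTA alignment.

    Lowercase characters (a3m insertions) are removed; every remaining row
    must match the query length.
    """
    path = Path(path)
    text = path.read_text()
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):  # a3m header comment
            continue
        if line.startswith(">"):
            if ids:
                rows.append(_clean_a3m_row("".join(current)))
            ids.append(line[1:].split()[0] if len(line) > 1 else f"seq{len(ids)}")
            current = []
        else:
            if not ids:
                raise FormatError(f"{path}: sequence data before first '>' header")
            current.append(line.strip())
    if ids:
        rows.append(_clean_a3m_row("".join(current)))
    if not rows:
        raise FormatError(f"{path}: empty alignment file")
    L = len(rows[0])
    for name, row in zip(ids, rows):
        if len(row) != L:
            raise FormatError(
                f"{path}: record '{name}' has post-processing length "
                f"{len(row)}, expected query length {L}"
            )
    return Alignment(query_id=ids[0], sequences=rows, ids=ids)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Serialize an Alignment as aligned FASTA (no insertion columns)."""
    with open(path, "w") as fh:
        for name, row in zip(aln.ids, aln.sequences):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Residue:
    """One residue of a chain; ``atoms`` maps atom name -> (3,) Å coords."""

    name: str                       # 3-letter code, 'UNK' for gaps
    atoms: dict[str, np.ndarray]
    resseq: int                     # author numbering, retained for reports
    icode: str = ""
    present: bool = True

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclasses.dataclass
class StructureChain:
    """An ordered protein chain with backbone coordinates.

    Residue order matches sequence order; numbering gaps in the source file
    are recorded explicitly as absent residues (``present=False``) so label
    arrays keep a slot for them.
    """

    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter if r.present else "X" for r in self.residues)

    @property
    def mask(self) -> np.ndarray:
        return np.array([r.present and "CA" in r.atoms for r in self.residues])


_BACKBONE = ("N", "CA", "C", "O", "CB")


def read_pdb_chain(path: str | Path, chain: str) -> StructureChain:
    """Read one chain of a PDB file (ATOM records, first model only).

    Alternate locations are resolved by highest occupancy, ties by first
    occurrence.  Gaps in the author residue numbering are recorded as
    absent residues.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("chain", str(path))
    model = next(structure.get_models())
    available = [c.id for c in model]
    if chain not in available:
        raise FormatError(
            f"{path}: chain '{chain}' not found; available chains: {available}"
        )
    residues: list[Residue] = []
    prev_resseq: int | None = None
    for res in model[chain]:
        if not is_aa(res, standard=False):
            continue
        resseq = res.id[1]
        icode = res.id[2].strip()
        if prev_resseq is not None and resseq > prev_resseq + 1:
            for missing in range(prev_resseq + 1, resseq):
                residues.append(
                    Residue(name="UNK", atoms={}, resseq=missing, present=False)
                )
        atoms: dict[str, np.ndarray] = {}
        for atom in res.get_atoms():
            name = atom.get_name()
            if name not in _BACKBONE:
                continue
            if atom.is_disordered():
                children = atom.disordered_get_list()
                best = max(
                    range(len(children)),
                    key=lambda k: (children[k].get_occupancy() or 0.0, -k),
                )
                atom = children[best]
            if name not in atoms:
                atoms[name] = np.asarray(atom.get_coord(), dtype=float)
        if not np.all([np.isfinite(v).all() for v in atoms.values()]):
            raise FormatError(f"{path}: non-finite coordinates in residue {resseq}")
        residues.append(Residue(name=res.get_resname(), atoms=atoms,
                                resseq=resseq, icode=icode))
        prev_resseq = resseq
    if not residues:
        raise FormatError(f"{path}: chain '{chain}' contains no amino-acid residues")
    return StructureChain(chain_id=chain, residues=residues)


def write_pdb(chain: StructureChain, path: str | Path) -> None:
    """Write a chain as minimal PDB ATOM records (backbone atoms only)."""
    element = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    serial = 1
    with open(path, "w") as fh:
        for res in chain.residues:
            if not res.present:
                continue
            for name in _BACKBONE:
                if name not in res.atoms:
                    continue
                x, y, z = res.atoms[name]
                atom_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {atom_field} {res.name:>3s} "
                    f"{chain.chain_id}{res.resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element[name]:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# HHsuite hhm profiles
# ---------------------------------------------------------------------------

# column layout of the 30-value per-residue profile vector
HHM_EMISSION_ORDER = "ACDEFGHIKLMNPQRSTVWY"
HHM_TRANSITIONS = ("M->M", "M->I", "M->D", "I->M", "I->I", "D->M", "D->D")
HHM_DIVERSITY = ("Neff", "Neff_I", "Neff_D")


@dataclasses.dataclass
class HmmProfile:
    """Per-residue profile: L x 30 (20 emissions, 7 transitions, 3 diversity).

    Emission and transition columns hold probabilities in [0, 1]; diversity
    columns hold effective-sequence counts (Neff).
    """

    values: np.ndarray
    query_id: str = "query"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 30:
            raise FormatError(
                f"profile must be L x 30, got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise FormatError("profile contains non-finite values")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def _score_to_prob(token: str) -> float:
    if token == "*":
        return 0.0
    return float(2.0 ** (-int(token) / 1000.0))


def _prob_to_score(p: float) -> str:
    if p <= 0.0:
        return "*"
    return str(int(round(-1000.0 * math.log2(p))))


def read_hhm(path: str | Path) -> HmmProfile:
    """Parse an HHsuite hhm text profile into an L x 30 probability table."""
    path = Path(path)
    lines = path.read_text().splitlines()
    name = "query"
    i = 0
    while i < len(lines) and not lines[i].startswith("HMM "):
        if lines[i].startswith("NAME"):
            name = lines[i].split(maxsplit=1)[-1].strip()
        i += 1
    if i >= len(lines):
        raise FormatError(f"{path}: no 'HMM' header block found")
    i += 3  # skip the HMM column header, transition header, and null-model row
    rows: list[list[float]] = []
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("//") or not line:
            break
        em_tokens = line.split()
        # emission row: "<aa> <pos> <20 scores> <pos>"
        if len(em_tokens) < 22:
            raise FormatError(f"{path}: truncated emission row at line {i + 1}")
        emissions = [_score_to_prob(t) for t in em_tokens[2:22]]
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: missing transition row after line {i + 1}")
        tr_tokens = lines[i + 1].split()
        if len(tr_tokens) < 10:
            raise FormatError(f"{path}: truncated transition row at line {i + 2}")
        transitions = [_score_to_prob(t) for t in tr_tokens[:7]]
        diversity = [int(t) / 1000.0 if t != "*" else 0.0 for t in tr_tokens[7:10]]
        rows.append(emissions + transitions + diversity)
        i += 2
    if not rows:
        raise FormatError(f"{path}: profile contains no match states")
    return HmmProfile(values=np.array(rows), query_id=name)


def write_hhm(profile: HmmProfile, path: str | Path,
              query_seq: str | None = None) -> None:
    """Serialize a profile in hhm text form (round-trips through read_hhm)."""
    L = profile.length
    seq = query_seq or "X" * L
    with open(path, "w") as fh:
        fh.write("HHsearch 1.5\n")
        fh.write(f"NAME  {profile.query_id}\nLENG  {L}\n")
        fh.write("HMM    " + "\t".join(HHM_EMISSION_ORDER) + "\n")
        fh.write("       " + "\t".join(HHM_TRANSITIONS + HHM_DIVERSITY) + "\n")
        fh.write("       " + "\t".join(["0"] * 10) + "\n")  # null row placeholder
        for k in range(L):
            em = "\t".join(_prob_to_score(p) for p in profile.values[k, :20])
            fh.write(f"{seq[k]} {k + 1}\t{em}\t{k + 1}\n")
            tr = "\t".join(_prob_to_score(p) for p in profile.values[k, 20:27])
            dv = "\t".join(str(int(round(v * 1000))) for v in profile.values[k, 27:30])
            fh.write(f"\t{tr}\t{dv}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# HDF5 tensor containers
# ---------------------------------------------------------------------------

_GROUPS = ("features", "labels", "predictions")


def save_h5(path: str | Path, group: str,
            arrays: dict[str, np.ndarray],
            attrs: dict | None = None) -> None:
    """Store arrays under /<group>/<name>; group is one of the documented
    features/labels/predictions groups."""
    if group not in _GROUPS:
        raise ValueError(f"group must be one of {_GROUPS}, got '{group}'")
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        for name, arr in arrays.items():
            # track_times=False keeps files byte-identical across reruns
            g.create_dataset(name, data=np.asarray(arr), track_times=False)
        for key, val in (attrs or {}).items():
            g.attrs[key] = val


def load_h5(path: str | Path, group: str) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as fh:
        if group not in fh:
            raise FormatError(f"{path}: no '/{group}' group")
        return {name: fh[group][name][()] for name in fh[group]}


def load_h5_attrs(path: str | Path, group: str) -> dict:
    with h5py.File(path, "r") as fh:
        return dict(fh[group].attrs)
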