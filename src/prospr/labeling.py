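"""Training-label derivation from protein structures.

A :class:`LabelSet` holds, for a chain of length L:

* ``dist_bins``: L x L distance classes. Inter-residue Cbeta distances
  (Calpha for glycine) fall into 10 bins with edges at 4, 6, 8, ..., 20 Å;
  the first bin is < 4 Å and the last collects everything >= 20 Å.  Pairs
  with an unresolved residue carry the reserved ignore value -1.
* ``ss``: 9 secondary-structure classes (the 8 DSSP letter codes plus one
  class shared by coil/blank and gap/error).
* ``phi``/``psi``: 36 ten-degree torsion bins over [-180, 180) plus class
  36 for an undefined angle (chain ends, gaps).
* ``asa``: relative accessible surface area in 10 equal bins plus class 10
  for N/A.

Surface area is computed internally (Shrake-Rupley, probe 1.4 Å, fixed
960-point spheres) and normalized by the Tien et al. theoretical maximum
per residue type; a pre-computed DSSP output file is preferred for
secondary structure when available.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import FormatError, Residue, StructureChain

logger = logging.getLogger(__name__)

N_DIST_BINS = 10
DIST_BIN_EDGES = np.array([4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0])
IGNORE = -1          # reserved label excluded from the loss
ANGLE_GAP_CLASS = 36
ASA_NA_CLASS = 10
SS_GAP_CLASS = 8

# fixed, exported DSSP letter -> class table; blank (coil) shares class 7
SS_CLASSES = {"H": 0, "G": 1, "I": 2, "E": 3, "B": 4, "T": 5, "S": 6, " ": 7}

SASA_PROBE_RADIUS = 1.4       # Å, water probe
SASA_N_SPHERE_POINTS = 960
_ELEMENT_RADII = {"N": 1.55, "C": 1.70, "O": 1.52, "S": 1.80}

# theoretical maximum accessible surface area per residue (Tien et al.), Å^2
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_MAX_ASA_DEFAULT = 197.0  # fallback for unknown residue types


@dataclasses.dataclass
class LabelSet:
    dist_bins: np.ndarray   # (L, L) int, 0..9 or IGNORE
    ss: np.ndarray          # (L,) int, 0..8
    phi: np.ndarray         # (L,) int, 0..36
    psi: np.ndarray         # (L,) int, 0..36
    asa: np.ndarray         # (L,) int, 0..10
    mask: np.ndarray        # (L,) bool, residue resolved

    @property
    def length(self) -> int:
        return self.ss.shape[0]

    def as_arrays(self) -> dict[str, np.ndarray]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def cb_coordinate(residue: Residue) -> np.ndarray | None:
    """The distance-defining atom: Cbeta, or Calpha for glycine.

    A non-glycine residue lacking Cbeta falls back to Calpha with a logged
    warning; a residue without Calpha is unresolved (returns None).
    """
    if not residue.present or "CA" not in residue.atoms:
        return None
    if residue.name == "GLY":
        return residue.atoms["CA"]
    if "CB" in residue.atoms:
        return residue.atoms["CB"]
    logger.warning("residue %s %d lacks CB; using CA", residue.name,
                   residue.resseq)
    return residue.atoms["CA"]


def bin_distance(d: float) -> int:
    """10-bin distance class: <4 Å is class 0, then 2 Å bins, >=20 Å is 9."""
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    return int(np.digitize(d, DIST_BIN_EDGES))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             p4: np.ndarray) -> float | None:
    """Signed dihedral angle in degrees in [-180, 180), IUPAC convention.

    Returns None for degenerate (collinear) geometry.
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or norm2 < 1e-9:
        return None
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / norm2))
    ang = math.degrees(math.atan2(y, x))
    if ang >= 180.0:
        ang -= 360.0
    return ang


def bin_angle(a: float | None) -> int:
    """36 ten-degree bins over [-180, 180); undefined angles -> class 36."""
    if a is None:
        return ANGLE_GAP_CLASS
    return min(int(math.floor((a + 180.0) / 10.0)), 35)


def bin_asa(r: float | None) -> int:
    """10 equal relative-ASA bins over [0, 1]; N/A -> class 10."""
    if r is None:
        return ASA_NA_CLASS
    return min(int(math.floor(10.0 * r)), 9)


# ---------------------------------------------------------------------------
# accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _atom_radius(name: str) -> float:
    return _ELEMENT_RADII.get(name[0], 1.70)


def atom_sasa(coords: np.ndarray, radii: np.ndarray,
              probe: float = SASA_PROBE_RADIUS,
              n_points: int = SASA_N_SPHERE_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å²."""
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(len(coords))
    for a in range(len(coords)):
        pts = coords[a] + expanded[a] * sphere
        neighbors = [b for b in tree.query_ball_point(coords[a],
                                                      expanded[a] + max_r)
                     if b != a]
        accessible = np.ones(n_points, dtype=bool)
        for b in neighbors:
            d2 = ((pts - coords[b]) ** 2).sum(axis=1)
            accessible &= d2 > expanded[b] ** 2
        areas[a] = accessible.mean() * 4.0 * np.pi * expanded[a] ** 2
    return areas


def relative_asa(chain: StructureChain, residue_index: int,
                 n_points: int = SASA_N_SPHERE_POINTS) -> float | None:
    """Relative accessible surface area of one residue, clamped to [0, 1].

    None (N/A) when the residue is absent or has no atoms.
    """
    res = chain.residues[residue_index]
    if not res.present or not res.atoms:
        return None
    coords, radii, owner = [], [], []
    for k, r in enumerate(chain.residues):
        for name, xyz in r.atoms.items():
            coords.append(xyz)
            radii.append(_atom_radius(name))
            owner.append(k)
    areas = atom_sasa(np.array(coords), np.array(radii), n_points=n_points)
    owner = np.array(owner)
    asa = areas[owner == residue_index].sum()
    max_asa = MAX_ASA.get(res.name, _MAX_ASA_DEFAULT)
    return float(min(asa / max_asa, 1.0))


def chain_relative_asa(chain: StructureChain,
                       n_points: int = SASA_N_SPHERE_POINTS
                       ) -> list[float | None]:
    """Relative ASA for every residue with one SASA evaluation."""
    coords, radii, owner = [], [], []
    for k, r in enumerate(chain.residues):
        for name, xyz in r.atoms.items():
            coords.append(xyz)
            radii.append(_atom_radius(name))
            owner.append(k)
    if not coords:
        return [None] * len(chain)
    areas = atom_sasa(np.array(coords), np.array(radii), n_points=n_points)
    owner = np.array(owner)
    out: list[float | None] = []
    for k, r in enumerate(chain.residues):
        if not r.present or not r.atoms:
            out.append(None)
            continue
        asa = areas[owner == k].sum()
        out.append(float(min(asa / MAX_ASA.get(r.name, _MAX_ASA_DEFAULT), 1.0)))
    return out


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def parse_dssp(path: str | Path, chain: StructureChain) -> np.ndarray:
    """Parse classic DSSP text output into per-residue classes 0..8."""
    lines = Path(path).read_text().splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = k + 1
            break
    if start is None:
        raise FormatError(f"{path}: no DSSP data header found")
    codes: list[int] = []
    for line in lines[start:]:
        if len(line) < 17:
            continue
        if line[13] == "!":  # chain break record
            codes.append(SS_GAP_CLASS)
            continue
        letter = line[16]
        codes.append(SS_CLASSES.get(letter, 7))
    present = [r.present for r in chain.residues]
    if len(codes) != len(chain):
        # DSSP omits unresolved residues; align against present ones
        if len(codes) == sum(present):
            out = np.full(len(chain), SS_GAP_CLASS, dtype=int)
            out[np.where(present)[0]] = codes
            return out
        raise FormatError(
            f"{path}: DSSP has {len(codes)} residues, chain has {len(chain)}"
        )
    return np.array(codes, dtype=int)


_HB_COUPLING = 0.084 * 332.0  # kcal/mol·Å, Kabsch-Sander electrostatic factor
_HB_CUTOFF = -0.5             # kcal/mol


def _hbond_energy(donor: Residue, acceptor: Residue,
                  donor_prev: Residue | None) -> float:
    """Kabsch-Sander backbone H-bond energy (donor N-H ... O=C acceptor)."""
    need_d = {"N"}
    need_a = {"C", "O"}
    if not need_d <= donor.atoms.keys() or not need_a <= acceptor.atoms.keys():
        return 0.0
    n = donor.atoms["N"]
    c, o = acceptor.atoms["C"], acceptor.atoms["O"]
    if donor_prev is not None and {"C", "O"} <= donor_prev.atoms.keys():
        co = donor_prev.atoms["C"] - donor_prev.atoms["O"]
        h = n + co / np.linalg.norm(co)
    else:
        return 0.0  # no amide H for the first residue
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0
    return _HB_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def assign_secondary_structure(chain: StructureChain) -> np.ndarray:
    """Hydrogen-bond-pattern secondary-structure assignment (DSSP rules).

    Backbone H-bonds are those with Kabsch-Sander energy below -0.5
    kcal/mol; n-turns and bridges then define helices (H/G/I), strands
    (E/B) and turns (T).  Bends (S) are not assigned by this internal
    fallback; parse real DSSP output when those matter.
    """
    L = len(chain)
    res = chain.residues
    hbond = np.zeros((L, L), dtype=bool)  # hbond[d, a]: N-H of d to C=O of a
    for d in range(1, L):
        if not res[d].present:
            continue
        for a in range(L):
            if a == d or abs(a - d) < 2 or not res[a].present:
                continue
            e = _hbond_energy(res[d], res[a], res[d - 1])
            if e < _HB_CUTOFF:
                hbond[d, a] = True
    turn = {n: np.zeros(L, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(L - n):
            if hbond[i + n, i]:
                turn[n][i] = True
    ss = np.full(L, 7, dtype=int)  # default coil
    # turns: any residue inside an n-turn
    for n in (3, 4, 5):
        for i in np.where(turn[n])[0]:
            ss[i + 1: i + n] = np.where(ss[i + 1: i + n] == 7, SS_CLASSES["T"],
                                        ss[i + 1: i + n])
    # bridges / strands
    bridge = np.zeros(L, dtype=bool)
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            para = (hbond[j, i - 1] and hbond[i + 1, j]) or \
                   (hbond[i, j - 1] and hbond[j + 1, i])
            anti = (hbond[j, i] and hbond[i, j]) or \
                   (hbond[j + 1, i - 1] and hbond[i + 1, j - 1])
            if para or anti:
                bridge[i] = bridge[j] = True
    for i in np.where(bridge)[0]:
        ss[i] = SS_CLASSES["B"]
    for i in range(1, L - 1):
        if bridge[i - 1] and bridge[i] or bridge[i] and bridge[i + 1]:
            ss[i] = SS_CLASSES["E"]
    # helices: two consecutive n-turns, 5/4/3 precedence as in DSSP
    for n, code in ((5, "I"), (3, "G"), (4, "H")):
        for i in range(1, L - n):
            if turn[n][i - 1] and turn[n][i]:
                ss[i: i + n] = SS_CLASSES[code]
    for i in range(L):
        if not res[i].present or "CA" not in res[i].atoms:
            ss[i] = SS_GAP_CLASS
    return ss


def secondary_structure(chain: StructureChain,
                        dssp_file: str | Path | None = None) -> np.ndarray:
    if dssp_file is not None:
        return parse_dssp(dssp_file, chain)
    return assign_secondary_structure(chain)


# ---------------------------------------------------------------------------
# full label set
# ---------------------------------------------------------------------------

def distance_labels(chain: StructureChain) -> np.ndarray:
    """(L, L) binned Cbeta distance map; unresolved pairs -> IGNORE."""
    L = len(chain)
    coords = [cb_coordinate(r) for r in chain.residues]
    out = np.full((L, L), IGNORE, dtype=np.int64)
    have = [k for k, c in enumerate(coords) if c is not None]
    if have:
        pts = np.array([coords[k] for k in have])
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        bins = np.digitize(d, DIST_BIN_EDGES)
        out[np.ix_(have, have)] = bins
    return out


def torsion_labels(chain: StructureChain) -> tuple[np.ndarray, np.ndarray]:
    """Binned phi/psi classes; chain ends and gaps get the error class."""
    L = len(chain)
    res = chain.residues
    phi = np.full(L, ANGLE_GAP_CLASS, dtype=np.int64)
    psi = np.full(L, ANGLE_GAP_CLASS, dtype=np.int64)

    def has(r: Residue, names: tuple[str, ...]) -> bool:
        return r.present and all(n in r.atoms for n in names)

    for i in range(L):
        if i > 0 and has(res[i - 1], ("C",)) and has(res[i], ("N", "CA", "C")):
            phi[i] = bin_angle(dihedral(res[i - 1].atoms["C"], res[i].atoms["N"],
                                        res[i].atoms["CA"], res[i].atoms["C"]))
        if i + 1 < L and has(res[i], ("N", "CA", "C")) and has(res[i + 1], ("N",)):
            psi[i] = bin_angle(dihedral(res[i].atoms["N"], res[i].atoms["CA"],
                                        res[i].atoms["C"], res[i + 1].atoms["N"]))
    return phi, psi


def label_chain(chain: StructureChain,
                dssp_file: str | Path | None = None,
                sasa_points: int = SASA_N_SPHERE_POINTS) -> LabelSet:
    """Derive the complete label set for one chain."""
    phi, psi = torsion_labels(chain)
    rasa = chain_relative_asa(chain, n_points=sasa_points)
    asa = np.array([bin_asa(r) for r in rasa], dtype=np.int64)
    ss = secondary_structure(chain, dssp_file)
    mask = chain.mask
    ss = np.where(mask, ss, SS_GAP_CLASS)
    phi = np.where(mask, phi, ANGLE_GAP_CLASS)
    psi = np.where(mask, psi, ANGLE_GAP_CLASS)
    asa = np.where(mask, asa, ASA_NA_CLASS)
    return LabelSet(dist_bins=distance_labels(chain), ss=ss, phi=phi,
                    psi=psi, asa=asa, mask=mask)
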