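"""Synthetic test inputs: ideal-geometry structures and simulated MSAs.

Everything here is a pure function of its seed, so the whole pipeline can be
exercised without any external downloads:

* :func:`ideal_helix` builds a poly-alanine alpha-helix from fixed internal
  coordinates, giving known phi/psi angles and Cbeta distances for label
  oracles.
* :func:`potts_sample` draws sequences from a pairwise 21-state Potts model
  whose only non-zero couplings are planted pairs; recovering those pairs is
  the ground-truth check for direct-coupling analysis.
* :func:`random_msa` makes i.i.d.-mutated copies of a random query.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .alphabet import AMINO_ACIDS, GAP
from .io_formats import Alignment, Residue, StructureChain

# --- ideal stereochemistry constants (Å / degrees), frozen in one place ----
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA_TRANS = 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position of atom D given A-B-C, |CD|, angle(BCD),
    and dihedral(ABCD)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_from_backbone(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # ideal tetrahedral Cbeta for an L-amino acid, from backbone frame
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def ideal_helix(n: int, phi: float = HELIX_PHI, psi: float = HELIX_PSI,
                chain_id: str = "A") -> StructureChain:
    """Poly-alanine chain built from fixed ideal helix internal coordinates.

    Every residue gets N/CA/C/O/CB atoms; interior residues have dihedrals
    (phi, psi) by construction, which labeling code can recompute.
    """
    if n < 4:
        raise ValueError("helix fixture needs at least 4 residues")
    # seed triangle for residue 0
    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1],
                             BOND_C_N, ANGLE_CA_C_N, psi))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i],
                              BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS))
        C.append(_place_atom(C[i - 1], N[i], CA[i],
                             BOND_CA_C, ANGLE_N_CA_C, phi))
    residues = []
    for i in range(n):
        atoms = {"N": N[i], "CA": CA[i], "C": C[i],
                 "CB": _cb_from_backbone(N[i], CA[i], C[i])}
        # carbonyl O anti-periplanar to the next amide N
        atoms["O"] = _place_atom(N[i], CA[i], C[i],
                                 BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
        residues.append(Residue(name="ALA", atoms=atoms, resseq=i + 1))
    return StructureChain(chain_id=chain_id, residues=residues)


def compact_chain(n: int, seed: int = 0, bond: float = 3.8,
                  radius_scale: float = 3.0, chain_id: str = "A"
                  ) -> StructureChain:
    """A compact random-walk chain with contacts at all separation ranges.

    Calpha positions follow a fixed-bond-length random walk biased toward
    the origin, confined to a ball of radius ``radius_scale * n**(1/3)``
    (roughly globular density), so short-, mid- and long-range contacts all
    occur.  Cbeta is placed at unit offset from Calpha.  Useful as a truth
    structure for contact-evaluation oracles; not a physical decoy.
    """
    rng = np.random.default_rng(seed)
    radius = radius_scale * n ** (1.0 / 3.0)
    ca = [np.zeros(3)]
    for _ in range(n - 1):
        while True:
            direction = rng.standard_normal(3)
            # pull toward the origin grows once the walk leaves the ball
            excess = max(np.linalg.norm(ca[-1]) - radius, 0.0)
            pull = -ca[-1] / max(np.linalg.norm(ca[-1]), 1e-9)
            direction = direction + (0.3 + excess) * pull
            direction /= np.linalg.norm(direction)
            nxt = ca[-1] + bond * direction
            if all(np.linalg.norm(nxt - p) > 3.2 for p in ca[-4:]):
                break
        ca.append(nxt)
    residues = []
    for i, pos in enumerate(ca):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        atoms = {"CA": pos, "CB": pos + 1.52 * direction}
        residues.append(Residue(name="ALA", atoms=atoms, resseq=i + 1))
    return StructureChain(chain_id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# Potts-model MSAs with planted couplings
# ---------------------------------------------------------------------------

N_POTTS_STATES = 20  # sampled sequences contain amino acids only, no gaps
GIBBS_BURNIN_SWEEPS = 50


@dataclasses.dataclass
class PottsSpec:
    """Specification of a pairwise Potts sampling problem.

    ``planted_pairs`` are the only site pairs with non-zero couplings; each
    coupling favours identical states with strength ``beta``.  All pairs
    must be separated by at least 5 positions so they fall in the
    sequence-separation ranges contact evaluation cares about.
    """

    L: int
    n_seq: int
    planted_pairs: list[tuple[int, int]]
    beta: float = 1.5
    field_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("coupling strength beta must be positive")
        for i, j in self.planted_pairs:
            if abs(i - j) < 5:
                raise ValueError(f"planted pair {(i, j)} has separation < 5")
            if not (0 <= i < self.L and 0 <= j < self.L):
                raise ValueError(f"planted pair {(i, j)} out of range for L={self.L}")


def make_potts_spec(L: int = 40, n_pairs: int = 8, n_seq: int = 2000,
                    beta: float = 1.5, seed: int = 0) -> PottsSpec:
    """Draw ``n_pairs`` disjoint planted pairs with separation >= 5."""
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    attempts = 0
    while len(pairs) < n_pairs:
        attempts += 1
        if attempts > 10000:
            raise ValueError(f"cannot place {n_pairs} disjoint pairs in L={L}")
        i, j = sorted(rng.choice(L, size=2, replace=False).tolist())
        if j - i < 5 or i in used or j in used:
            continue
        pairs.append((i, j))
        used.update((i, j))
    return PottsSpec(L=L, n_seq=n_seq, planted_pairs=pairs, beta=beta, seed=seed)


def potts_sample(spec: PottsSpec) -> Alignment:
    """Gibbs-sample an MSA from the planted-coupling Potts model.

    ``n_seq`` independent chains are run in parallel for a fixed burn-in of
    50 full sweeps; the final state of each chain is one alignment row.
    The query (row 0) is the first sampled chain.
    """
    rng = np.random.default_rng(spec.seed)
    L, n, q = spec.L, spec.n_seq, N_POTTS_STATES
    fields = rng.normal(0.0, spec.field_noise, size=(L, q))
    partners: list[list[int]] = [[] for _ in range(L)]
    for i, j in spec.planted_pairs:
        partners[i].append(j)
        partners[j].append(i)
    states = rng.integers(0, q, size=(n, L))
    rows_idx = np.arange(n)
    for _ in range(GIBBS_BURNIN_SWEEPS):
        for site in range(L):
            logits = np.broadcast_to(fields[site], (n, q)).copy()
            for p in partners[site]:
                logits[rows_idx, states[:, p]] += spec.beta
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random((n, 1))
            states[:, site] = (probs.cumsum(axis=1) < u).sum(axis=1)
    rows = ["".join(AMINO_ACIDS[s] for s in row) for row in states]
    return Alignment(query_id="potts_query", sequences=rows,
                     ids=[f"potts{k}" for k in range(n)])


def random_msa(L: int, n_seq: int, mutation_rate: float,
               seed: int = 0, gap_rate: float = 0.02) -> Alignment:
    """Random query plus rows mutated i.i.d. at ``mutation_rate`` with
    occasional gaps (never in the query)."""
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    query = aas[rng.integers(0, 20, size=L)]
    rows = ["".join(query)]
    for _ in range(n_seq - 1):
        row = query.copy()
        mut = rng.random(L) < mutation_rate
        row[mut] = aas[rng.integers(0, 20, size=int(mut.sum()))]
        gaps = rng.random(L) < gap_rate
        row[gaps] = GAP
        rows.append("".join(row))
    return Alignment(query_id="random_query", sequences=rows,
                     ids=[f"rand{k}" for k in range(n_seq)])
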