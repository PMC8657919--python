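"""MSA featurization: the L x L x 547 pairwise input tensor.

The channel budget (this toolkit's documented convention; only the totals
547 and 442 are fixed by the distogram input contract) is::

    [  0: 21)  one-hot of residue i (21-letter alphabet)
    [ 21: 42)  one-hot of residue j
    [ 42: 43)  residue index i (raw integer, 0-based)
    [ 43: 44)  residue index j
    [ 44: 74)  30-value profile of residue i (20 emissions, 7 transitions,
               3 diversity values)
    [ 74:104)  30-value profile of residue j
    [104:545)  direct-coupling analysis: the 21 x 21 coupling block of the
               ordered pair (i, j), flattened (441 channels)
    [545:546)  APC-corrected coupling norm of (i, j)
    [546:547)  validity mask (1 on real residues, 0 on padding)

Direct couplings come from inverting the shrinkage-regularized covariance
of the one-hot MSA columns, with the gap state excluded from the inversion
and zero-filled back into the 21 x 21 blocks; coupling strength per pair is
the Frobenius norm of the gap-excluded block, average-product corrected.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alphabet import N_STATES, UNKNOWN_INDEX
from .io_formats import Alignment, HmmProfile

N_INPUT_CHANNELS = 547
N_DCA_CHANNELS = 442
N_COUPLING_CHANNELS = 441

# channel-budget offsets (see module docstring)
CH_ONEHOT_I = slice(0, 21)
CH_ONEHOT_J = slice(21, 42)
CH_INDEX_I = 42
CH_INDEX_J = 43
CH_PROFILE_I = slice(44, 74)
CH_PROFILE_J = slice(74, 104)
CH_COUPLINGS = slice(104, 545)
CH_APC = 545
CH_MASK = 546

DEFAULT_IDENTITY_THRESHOLD = 0.8


@dataclasses.dataclass
class SequenceWeights:
    """Per-row weights down-weighting redundant sequences.

    Row r gets weight 1 / (number of rows within ``identity_threshold``
    fractional identity of r, itself included); Neff is the weight sum.
    """

    weights: np.ndarray
    identity_threshold: float

    @property
    def neff(self) -> float:
        return float(self.weights.sum())


@dataclasses.dataclass
class DcaFeatures:
    """Direct-coupling output: 441 coupling channels + 1 APC score = 442."""

    couplings: np.ndarray   # (L, L, 441) float32
    apc_score: np.ndarray   # (L, L) float64

    @property
    def n_channels(self) -> int:
        return N_COUPLING_CHANNELS + 1


@dataclasses.dataclass
class PairwiseInput:
    """The assembled network input, shape (L, L, 547)."""

    tensor: np.ndarray
    query: str

    @property
    def length(self) -> int:
        return self.tensor.shape[0]


def sequence_weights(aln: Alignment,
                     identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                     ) -> SequenceWeights:
    """Standard identity-based MSA reweighting."""
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError("identity_threshold must lie strictly in (0, 1)")
    idx = aln.to_indices()
    n, L = idx.shape
    counts = np.zeros(n, dtype=np.int64)
    chunk = max(1, int(2**22 / max(n * L, 1)) or 1)
    for start in range(0, n, chunk):
        block = idx[start:start + chunk]  # (b, L)
        ident = (block[:, None, :] == idx[None, :, :]).mean(axis=2)
        counts[start:start + chunk] += (ident >= identity_threshold).sum(axis=1)
    return SequenceWeights(weights=1.0 / counts,
                           identity_threshold=identity_threshold)


def weighted_frequencies(aln: Alignment, w: SequenceWeights,
                         pseudocount: float = 0.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted single-site (L, 21) and pair (L, L, 21, 21) frequencies.

    With ``pseudocount = 0`` the pair table marginalizes exactly to the
    site table; a positive pseudocount spreads uniform mass so no cell is
    exactly zero.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    idx = aln.to_indices()
    n, L = idx.shape
    q = N_STATES
    onehot = np.zeros((n, L, q), dtype=np.float64)
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], idx] = 1.0
    wcol = w.weights[:, None, None]
    neff = w.neff
    site = (onehot * wcol).sum(axis=0)  # (L, q) of weighted counts
    flat = onehot.reshape(n, L * q)
    wflat = flat * w.weights[:, None]
    pair = (wflat.T @ flat).reshape(L, q, L, q).transpose(0, 2, 1, 3)
    site_f = (site + pseudocount / q) / (neff + pseudocount)
    pair_f = (pair + pseudocount / q**2) / (neff + pseudocount)
    return site_f, pair_f


def apc_correct(F: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric coupling-strength matrix.

    ``out(i,j) = F(i,j) - rowmean(i) * rowmean(j) / grandmean`` with all
    means taken over off-diagonal entries.  A zero grand mean returns an
    all-zero matrix.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] != F.shape[1]:
        raise ValueError(f"F must be square, got shape {F.shape}")
    n = F.shape[0]
    if n < 2:
        return np.zeros_like(F)
    offdiag = ~np.eye(n, dtype=bool)
    rowmean = (F * offdiag).sum(axis=1) / (n - 1)
    grand = (F * offdiag).sum() / (n * (n - 1))
    if grand == 0:
        return np.zeros_like(F)
    return F - np.outer(rowmean, rowmean) / grand


def compute_dca(aln: Alignment,
                identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                shrinkage: float | None = None) -> DcaFeatures:
    """Direct-coupling analysis by regularized covariance inversion.

    The 20L x 20L covariance of the one-hot columns (gap state excluded)
    gets ``shrinkage`` added to its diagonal before inversion; the default
    shrinkage is ``4.5 / sqrt(Neff * L)``.  The inverse-covariance blocks
    are the couplings; per-pair strength is the Frobenius norm of the
    block, APC-corrected, with a zero diagonal.
    """
    w = sequence_weights(aln, identity_threshold)
    site_f, pair_f = weighted_frequencies(aln, w, pseudocount=0.0)
    L = aln.length
    q = N_STATES - 1  # gap state excluded from the inverted system
    if shrinkage is None:
        shrinkage = 4.5 / np.sqrt(w.neff * L)
    site = site_f[:, :q]                      # (L, 20)
    pair = pair_f[:, :, :q, :q]               # (L, L, 20, 20)
    cov = pair - site[:, None, :, None] * site[None, :, None, :]
    cov = cov.transpose(0, 2, 1, 3).reshape(L * q, L * q)
    cov[np.diag_indices_from(cov)] += shrinkage
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance inversion failed at shrinkage={shrinkage:.3g}; "
            "retry with a larger shrinkage value"
        ) from exc
    blocks = inv.reshape(L, q, L, q).transpose(0, 2, 1, 3)  # (L, L, 20, 20)
    couplings = np.zeros((L, L, N_STATES, N_STATES), dtype=np.float32)
    couplings[:, :, :q, :q] = blocks
    fnorm = np.sqrt((blocks.astype(np.float64) ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(fnorm, 0.0)
    apc = apc_correct(fnorm)
    np.fill_diagonal(apc, 0.0)
    # 21 * 21 = 441 coupling channels per ordered pair
    return DcaFeatures(couplings=couplings.reshape(L, L, N_STATES**2),
                       apc_score=apc)


def profile_from_msa(aln: Alignment, w: SequenceWeights | None = None
                     ) -> HmmProfile:
    """Profile built directly from the weighted MSA.

    Used when no externally computed hhm profile is available; the layout
    matches :func:`prospr.io_formats.read_hhm` so the two sources are
    interchangeable.  Emissions are weighted residue frequencies (gap mass
    excluded), transitions come from weighted gap-open/extend counts, and
    the diversity columns carry the per-site effective sequence count.
    """
    if w is None:
        w = sequence_weights(aln)
    idx = aln.to_indices()
    n, L = idx.shape
    gaps = np.array([[c in "-.X" for c in row] for row in aln.sequences])
    weights = w.weights
    total = weights.sum()
    values = np.zeros((L, 30), dtype=float)
    for a in range(20):
        values[:, a] = ((idx == a) * weights[:, None]).sum(axis=0) / total
    is_gap = gaps.astype(float)
    # match-state transitions between adjacent columns
    for k in range(L):
        if k + 1 < L:
            m_here = (1.0 - is_gap[:, k]) * weights
            d_here = is_gap[:, k] * weights
            m_next = 1.0 - is_gap[:, k + 1]
            mm = (m_here * m_next).sum() / max(m_here.sum(), 1e-12)
            dm = (d_here * m_next).sum() / max(d_here.sum(), 1e-12)
        else:
            mm, dm = 1.0, 1.0
        values[k, 20] = mm          # M->M
        values[k, 21] = 0.0         # M->I (insertions removed on read)
        values[k, 22] = 1.0 - mm    # M->D
        values[k, 23] = 1.0         # I->M
        values[k, 24] = 0.0         # I->I
        values[k, 25] = dm          # D->M
        values[k, 26] = 1.0 - dm    # D->D
    site_neff = ((1.0 - is_gap) * weights[:, None]).sum(axis=0)
    values[:, 27] = site_neff
    values[:, 28] = site_neff
    values[:, 29] = site_neff
    return HmmProfile(values=values, query_id=aln.query_id)


def assemble_input(aln: Alignment, profile: HmmProfile,
                   dca: DcaFeatures) -> PairwiseInput:
    """Assemble the (L, L, 547) network input from its components."""
    L = aln.length
    if profile.length != L:
        raise ValueError(
            f"profile length {profile.length} does not match MSA length {L}"
        )
    if dca.apc_score.shape != (L, L):
        raise ValueError(
            f"DCA shape {dca.apc_score.shape} does not match MSA length {L}"
        )
    from .alphabet import encode_sequence

    q_idx = np.array(encode_sequence(aln.query))
    onehot = np.zeros((L, N_STATES), dtype=np.float32)
    onehot[np.arange(L), q_idx] = 1.0
    x = np.zeros((L, L, N_INPUT_CHANNELS), dtype=np.float32)
    x[:, :, CH_ONEHOT_I] = onehot[:, None, :]
    x[:, :, CH_ONEHOT_J] = onehot[None, :, :]
    idx = np.arange(L, dtype=np.float32)
    x[:, :, CH_INDEX_I] = idx[:, None]
    x[:, :, CH_INDEX_J] = idx[None, :]
    prof = profile.values.astype(np.float32)
    x[:, :, CH_PROFILE_I] = prof[:, None, :]
    x[:, :, CH_PROFILE_J] = prof[None, :, :]
    x[:, :, CH_COUPLINGS] = dca.couplings
    x[:, :, CH_APC] = dca.apc_score.astype(np.float32)
    x[:, :, CH_MASK] = 1.0
    return PairwiseInput(tensor=x, query=aln.query)


def featurize(aln: Alignment, profile: HmmProfile | None = None,
              identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
              shrinkage: float | None = None) -> PairwiseInput:
    """One-call pipeline: weights -> DCA (+ internal profile) -> input."""
    w = sequence_weights(aln, identity_threshold)
    if profile is None:
        profile = profile_from_msa(aln, w)
    dca = compute_dca(aln, identity_threshold, shrinkage)
    return assemble_input(aln, profile, dca)
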