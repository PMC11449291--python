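"""Site-scoring methods compared on sector inference.

All methods start from single- and two-site state frequencies of an MSA,
optionally regularised with a pseudocount a:

    f~_i(s)      = a/q   + (1-a) f_i(s)
    f~_ij(s,s')  = a/q^2 + (1-a) f_ij(s,s')          (i != j)
    f~_ii(s,s')  = delta(s,s') f~_i(s)

On top of these, the module provides

* ``conservation`` -- per-site Kullback-Leibler divergence from uniform
  (entropy-based, in [0, 1]);
* ``covariance_two_state`` / ``covariance_full`` -- the scalar +/-1
  covariance and the blocked q-state covariance;
* ``icod_two_state`` / ``icod_natural`` -- Inverse Covariance Off-Diagonal:
  invert the pseudocounted covariance and zero its diagonal.  For
  equilibrium data under quadratic selection on an additive trait the
  off-diagonal entries approximate kappa * D_i * D_j;
* ``sca_matrix`` -- Statistical Coupling Analysis: covariance weighted
  elementwise by conservation factors phi, compressed per site pair by
  Frobenius norm;
* ``mutual_information`` -- pairwise MI from pseudocounted frequencies;
* ``apc_correct`` -- average product correction;
* ``eigen_analysis`` -- sorted eigendecomposition with a fixed sign rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqsim import BinaryMSA

__all__ = [
    "FrequencyTables",
    "SiteScoreMatrix",
    "SiteScoreVector",
    "pseudocount_frequencies",
    "conservation",
    "covariance_two_state",
    "covariance_full",
    "icod_two_state",
    "icod_natural",
    "apc_correct",
    "sca_matrix",
    "mutual_information",
    "eigen_analysis",
]

ICOD_PSEUDOCOUNT = 1e-5  # default for two-state synthetic data
ICOD_NATURAL_PSEUDOCOUNT = 0.05
MI_PSEUDOCOUNT = 1e-3
SCA_PSEUDOCOUNT = 1e-6  # numerical safety only
CONDITION_LIMIT = 1e12
_PHI_EPS = 1e-6


@dataclass(frozen=True)
class FrequencyTables:
    """Pseudocount-corrected state frequencies of an integer-coded MSA.

    ``f1`` has shape (L, q); ``f2`` has shape (L, L, q, q) with the
    diagonal blocks f~_ii(s, s') = delta(s, s') f~_i(s).
    """

    f1: np.ndarray
    f2: np.ndarray
    a: float
    q: int


@dataclass(frozen=True)
class SiteScoreMatrix:
    values: np.ndarray  # (L, L) symmetric
    method: str
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SiteScoreVector:
    values: np.ndarray  # (L,)
    method: str
    eigen_rank: Optional[int] = None  # 0 = largest eigenvalue
    eigenvalue: Optional[float] = None
    sign_flipped: bool = False


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def _as_state_matrix(msa, q: int) -> np.ndarray:
    """Integer state matrix in {0..q-1}; binary +/-1 spins map -1->0, +1->1."""
    if isinstance(msa, BinaryMSA):
        msa = msa.sequences
    arr = np.asarray(msa)
    if arr.dtype.kind in "if" and q == 2 and np.isin(arr, (-1, 1)).all():
        arr = ((arr + 1) // 2).astype(np.int64)
    arr = arr.astype(np.int64, copy=False)
    if arr.min() < 0 or arr.max() >= q:
        raise ValueError(f"states must lie in 0..{q - 1}")
    return arr


def _one_hot(states: np.ndarray, q: int) -> np.ndarray:
    M, L = states.shape
    X = np.zeros((M, L * q), dtype=float)
    cols = np.arange(L) * q
    X[np.arange(M)[:, None], cols[None, :] + states] = 1.0
    return X


def pseudocount_frequencies(msa, a: float = 0.0, q: int = 2) -> FrequencyTables:
    """Single- and two-site frequencies with pseudocount weight ``a``."""
    if not 0 <= a <= 1:
        raise ValueError("pseudocount a must be in [0, 1]")
    states = _as_state_matrix(msa, q)
    M, L = states.shape
    X = _one_hot(states, q)
    f1 = (X.sum(axis=0) / M).reshape(L, q)
    raw2 = (X.T @ X / M).reshape(L, q, L, q).transpose(0, 2, 1, 3)
    f1t = a / q + (1 - a) * f1
    f2t = a / q**2 + (1 - a) * raw2
    idx = np.arange(L)
    diag = np.zeros((L, q, q))
    diag[:, np.arange(q), np.arange(q)] = f1t
    f2t[idx, idx] = diag
    return FrequencyTables(f1=f1t, f2=f2t, a=a, q=q)


def conservation(msa, q: int = 2, a: float = 0.0) -> SiteScoreVector:
    """Entropy-based conservation, 1 - sum_s f_i(s) log_q f_i(s), in [0, 1].

    No pseudocount is applied by default; 0 * log 0 is taken as 0.
    """
    states = _as_state_matrix(msa, q)
    M, L = states.shape
    f1 = np.stack([(states == s).mean(axis=0) for s in range(q)], axis=1)
    f1 = a / q + (1 - a) * f1
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f1 > 0, f1 * np.log(f1) / np.log(q), 0.0)
    return SiteScoreVector(values=1.0 + terms.sum(axis=1), method="conservation")


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------


def covariance_two_state(msa, a: float = 0.0) -> SiteScoreMatrix:
    """Scalar covariance of +/-1 spins, C_ij = <s_i s_j> - <s_i><s_j>.

    With pseudocount a the entries become
    C_ij = (1-a)<s_i s_j> - (1-a)^2 <s_i><s_j>  (i != j) and
    C_ii = (1-a)^2 (1 - <s_i>^2) + a(2-a).
    """
    seqs = msa.sequences if isinstance(msa, BinaryMSA) else np.asarray(msa)
    if not np.isin(seqs, (-1, 1)).all():
        raise ValueError("two-state covariance requires +/-1 entries")
    if not 0 <= a <= 1:
        raise ValueError("pseudocount a must be in [0, 1]")
    S = seqs.astype(float)
    M = S.shape[0]
    mean = S.mean(axis=0)
    second = S.T @ S / M
    C = (1 - a) * second - (1 - a) ** 2 * np.outer(mean, mean)
    np.fill_diagonal(C, (1 - a) ** 2 * (1 - mean**2) + a * (2 - a))
    return SiteScoreMatrix(values=C, method="covariance", meta={"pseudocount": a})


def covariance_full(
    msa,
    a: float = 0.0,
    q: int = 2,
    drop_states: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Blocked covariance C_ij(s, s') = f~_ij(s, s') - f~_i(s) f~_j(s').

    Returns an (L*q', L*q') matrix with q' = q, or q' = q - 1 when
    ``drop_states`` gives a per-site reference state to gauge away.
    """
    freqs = pseudocount_frequencies(msa, a=a, q=q)
    L = freqs.f1.shape[0]
    C = freqs.f2 - freqs.f1[:, None, :, None] * freqs.f1[None, :, None, :]
    if drop_states is not None:
        drop_states = np.asarray(drop_states, dtype=int)
        if drop_states.shape != (L,):
            raise ValueError("drop_states must give one reference state per site")
        keep = np.array([[s for s in range(q) if s != drop_states[i]] for i in range(L)])
        C = C[np.arange(L)[:, None, None, None], np.arange(L)[None, :, None, None],
              keep[:, None, :, None], keep[None, :, None, :]]
        qp = q - 1
    else:
        qp = q
    return C.transpose(0, 2, 1, 3).reshape(L * qp, L * qp)


# ---------------------------------------------------------------------------
# ICOD
# ---------------------------------------------------------------------------


def _checked_inverse(C: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            f"covariance matrix is ill-conditioned (cond={cond:.3g}); "
            "increase the pseudocount"
        )
    inv = np.linalg.inv(C)
    return (inv + inv.T) / 2


def icod_two_state(msa, a: float = ICOD_PSEUDOCOUNT) -> SiteScoreMatrix:
    """Inverse covariance with zero diagonal, for +/-1 spin alignments.

    Off-diagonal entries approximate kappa * D_i * D_j on equilibrium
    data, so the top eigenvector recovers the mutational-effect vector.
    """
    C = covariance_two_state(msa, a=a).values
    inv = _checked_inverse(C)
    np.fill_diagonal(inv, 0.0)
    return SiteScoreMatrix(values=inv, method="icod", meta={"pseudocount": a})


def icod_natural(
    msa,
    ref_seq,
    a: float = ICOD_NATURAL_PSEUDOCOUNT,
    q: int = 20,
    apply_apc: bool = False,
) -> SiteScoreMatrix:
    """ICOD for categorical (amino-acid) alignments in the
    reference-sequence gauge.

    The state carried by ``ref_seq`` at each site is dropped (q-1 states
    per site), the pseudocounted blocked covariance is inverted, each
    (q-1) x (q-1) site-pair block is compressed by Frobenius norm, the
    diagonal is zeroed, and APC is optionally applied.
    """
    states = _as_state_matrix(msa, q)
    ref = np.asarray(ref_seq, dtype=int)
    L = states.shape[1]
    if ref.shape != (L,):
        raise ValueError("reference sequence length must match the MSA")
    C = covariance_full(states, a=a, q=q, drop_states=ref)
    inv = _checked_inverse(C)
    qp = q - 1
    blocks = inv.reshape(L, qp, L, qp)
    frob = np.sqrt(np.einsum("iajb,iajb->ij", blocks, blocks))
    np.fill_diagonal(frob, 0.0)
    if apply_apc:
        frob = apc_correct(frob)
    return SiteScoreMatrix(
        values=frob, method="icod", meta={"pseudocount": a, "gauge": "reference", "apc": apply_apc}
    )


def apc_correct(matrix) -> np.ndarray:
    """Average product correction: subtract (row mean * column mean) /
    overall mean, all means taken over off-diagonal entries."""
    Mt = np.asarray(matrix.values if isinstance(matrix, SiteScoreMatrix) else matrix, float)
    L = Mt.shape[0]
    off = ~np.eye(L, dtype=bool)
    row_mean = (Mt * off).sum(axis=1) / (L - 1)
    all_mean = (Mt * off).sum() / (L * (L - 1))
    if all_mean == 0:
        warnings.warn("APC skipped: mean of off-diagonal entries is zero")
        return Mt.copy()
    out = Mt - np.outer(row_mean, row_mean) / all_mean
    out[~off] = Mt[~off]
    return out


# ---------------------------------------------------------------------------
# SCA
# ---------------------------------------------------------------------------


def sca_weights(f1: np.ndarray, background: np.ndarray, eps: float = _PHI_EPS) -> np.ndarray:
    """Conservation factors phi_i(s) = |ln[f(1-qbar) / ((1-f) qbar)]|,
    the gradient of the relative entropy of f against the background."""
    f = np.clip(f1, eps, 1 - eps)
    qbar = np.clip(background, eps, 1 - eps)[None, :]
    return np.abs(np.log(f * (1 - qbar) / ((1 - f) * qbar)))


def sca_matrix(
    msa,
    a: float = SCA_PSEUDOCOUNT,
    q: int = 2,
    background: Optional[np.ndarray] = None,
    weighted: bool = True,
) -> SiteScoreMatrix:
    """Statistical Coupling Analysis matrix.

    The blocked covariance is weighted elementwise by the conservation
    factors phi_i(s) and each q x q site-pair block is compressed to a
    scalar by Frobenius norm.  For two-state data the background defaults
    to (0.5, 0.5); for proteins, pass the amino-acid background.
    """
    if background is None:
        background = np.full(q, 1.0 / q)
    background = np.asarray(background, float)
    if background.shape != (q,) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background frequencies must have length q and sum to 1")
    freqs = pseudocount_frequencies(msa, a=a, q=q)
    L = freqs.f1.shape[0]
    C = freqs.f2 - freqs.f1[:, None, :, None] * freqs.f1[None, :, None, :]
    if weighted:
        phi = sca_weights(freqs.f1, background)
        C = C * phi[:, None, :, None] * phi[None, :, None, :]
    frob = np.sqrt(np.einsum("ijab,ijab->ij", C, C))
    return SiteScoreMatrix(
        values=frob, method="sca", meta={"pseudocount": a, "weighted": weighted}
    )


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def mutual_information(
    msa, a: float = MI_PSEUDOCOUNT, q: int = 2, zero_diagonal: bool = True
) -> SiteScoreMatrix:
    """Pairwise mutual information (natural log) from pseudocounted
    frequencies.  The diagonal (self-information) is zeroed by default so
    the eigen-analysis parallels ICOD."""
    freqs = pseudocount_frequencies(msa, a=a, q=q)
    prod = freqs.f1[:, None, :, None] * freqs.f1[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(freqs.f2 > 0, freqs.f2 / np.where(prod > 0, prod, 1.0), 1.0)
        terms = np.where(freqs.f2 > 0, freqs.f2 * np.log(ratio), 0.0)
    mi = terms.sum(axis=(2, 3))
    if zero_diagonal:
        np.fill_diagonal(mi, 0.0)
    return SiteScoreMatrix(values=mi, method="mi", meta={"pseudocount": a})


# ---------------------------------------------------------------------------
# eigendecomposition
# ---------------------------------------------------------------------------


def eigen_analysis(matrix, which="largest", sym_tol: float = 1e-8):
    """Eigenpair of a symmetric site-score matrix.

    ``which`` is "largest", "smallest", or an integer rank (0 = largest
    eigenvalue).  The eigenvector is unit-norm with the sign flipped so
    its largest-magnitude component is positive.
    """
    name = None
    if isinstance(matrix, SiteScoreMatrix):
        name = matrix.method
        matrix = matrix.values
    A = np.asarray(matrix, float)
    scale = max(np.abs(A).max(), 1.0)
    if np.abs(A - A.T).max() > sym_tol * scale:
        raise ValueError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh((A + A.T) / 2)
    vals, vecs = vals[::-1], vecs[:, ::-1]  # descending
    if which == "largest":
        rank = 0
    elif which == "smallest":
        rank = vals.size - 1
    else:
        rank = int(which)
        if not 0 <= rank < vals.size:
            raise ValueError("eigenvalue rank out of range")
    v = vecs[:, rank]
    flipped = v[np.argmax(np.abs(v))] < 0
    if flipped:
        v = -v
    vector = SiteScoreVector(
        values=v,
        method=f"eigenvector-of-{name}" if name else "eigenvector",
        eigen_rank=rank,
        eigenvalue=float(vals[rank]),
        sign_flipped=bool(flipped),
    )
    return float(vals[rank]), vector
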