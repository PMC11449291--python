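"""Numba kernels for Metropolis dynamics on binary sequences.

The inner loop is a single-spin-flip Metropolis chain on the quadratic
trait Hamiltonian H(s) = (kappa/2) (D.s - tau*)^2.  The trait value
tau = D.s is maintained incrementally, so one proposal costs O(1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Sentinel returned when the chain stalls (too many consecutive rejections).
STALLED = -1


@njit(cache=True)
def metropolis_chain(seq, D, kappa, tau_star, n_accept, seed, max_stall, log):
    """Run a Metropolis chain until ``n_accept`` flips have been accepted.

    ``seq`` (int8, entries -1/+1) is modified in place.  Accepted flip
    sites are written to ``log`` (int32, length >= n_accept) so a run can
    be replayed exactly.  Returns the number of accepted flips, or
    ``STALLED`` if ``max_stall`` consecutive proposals were rejected.
    """
    np.random.seed(seed)
    L = seq.shape[0]
    tau = 0.0
    for i in range(L):
        tau += D[i] * seq[i]
    accepted = 0
    stall = 0
    while accepted < n_accept:
        i = np.random.randint(0, L)
        dtau = -2.0 * D[i] * seq[i]
        # dH = H(after) - H(before) with the shared quadratic expanded
        dH = 0.5 * kappa * dtau * (dtau + 2.0 * (tau - tau_star))
        if dH <= 0.0 or np.random.random() < np.exp(-dH):
            seq[i] = -seq[i]
            tau += dtau
            log[accepted] = i
            accepted += 1
            stall = 0
        else:
            stall += 1
            if stall >= max_stall:
                return STALLED
    return accepted


@njit(cache=True)
def pairwise_hamming_mean(msa):
    """Mean fraction of differing sites over all unordered row pairs.

    Uses the +/-1 Gram identity d(x, y) = (1 - x.y/L) / 2 accumulated
    pair by pair to avoid materialising an M x M matrix.
    """
    M, L = msa.shape
    total = 0.0
    for a in range(M):
        for b in range(a + 1, M):
            agree = 0
            for k in range(L):
                if msa[a, k] == msa[b, k]:
                    agree += 1
            total += 1.0 - agree / L
    return total / (M * (M - 1) / 2)
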