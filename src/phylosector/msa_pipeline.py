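"""Processing of categorical (protein-like) alignments and DMS tables.

This module carries the machinery used to confront site-scoring methods
with experimental per-site mutational effects: MSA filtering, Jukes-Cantor
distance, phylogenetic-cutoff subsampling, nearest-neighbour gap
imputation, aggregation of per-cutoff eigenvectors, reduction of deep
mutational scanning (DMS) tables to per-site scores, Gaussian(-mixture)
binarisation of those scores, and alignment diversity metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as spsignal
from scipy import stats as spstats
from scipy.optimize import minimize_scalar
from sklearn.mixture import GaussianMixture

__all__ = [
    "CategoricalMSA",
    "DMSTable",
    "AMINO_ACIDS",
    "GAP",
    "PHYLO_CUTOFF_GRID",
    "filter_msa",
    "jukes_cantor_distance",
    "cutoff_subsample",
    "impute_gaps_nearest",
    "aggregate_eigenvectors",
    "dms_site_scores",
    "binarise_dms",
    "mean_pairwise_hamming_protein",
    "effective_depth",
    "overlap_counts",
    "top_sites",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}

# Jukes-Cantor phylogenetic cutoffs used to build nested-diversity MSAs.
PHYLO_CUTOFF_GRID = (0.4, 0.6, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2.0)

JC_DISTANCE_CAP = 10.0  # saturated pairs are treated as maximally distant

COLUMN_GAP_LIMIT = 0.30
SEQUENCE_GAP_LIMIT = 0.20


@dataclass(frozen=True)
class CategoricalMSA:
    """An alignment over the 20 amino acids plus gap, as an (M, L) array of
    single characters, with named rows and a designated reference row."""

    sequences: np.ndarray  # (M, L) of '<U1'
    ids: tuple
    reference_id: str

    def __post_init__(self):
        seqs = np.asarray(self.sequences, dtype="<U1")
        if seqs.ndim != 2:
            raise ValueError("sequences must be 2-D")
        if len(self.ids) != seqs.shape[0]:
            raise ValueError("one id per sequence required")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference {self.reference_id!r} not present")
        object.__setattr__(self, "sequences", seqs)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def M(self) -> int:
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        return self.sequences.shape[1]

    @property
    def reference_row(self) -> int:
        return self.ids.index(self.reference_id)

    @property
    def reference(self) -> np.ndarray:
        return self.sequences[self.reference_row]

    def to_states(self, alphabet: str = AMINO_ACIDS) -> np.ndarray:
        """Integer coding by position in ``alphabet``; gaps are not allowed."""
        lut = {c: k for k, c in enumerate(alphabet)}
        try:
            return np.vectorize(lut.__getitem__, otypes=[np.int64])(self.sequences)
        except KeyError as err:
            raise ValueError(f"symbol outside alphabet: {err}") from None

    @classmethod
    def from_strings(cls, pairs, reference_id: str) -> "CategoricalMSA":
        ids = [p[0] for p in pairs]
        seqs = np.array([list(p[1]) for p in pairs], dtype="<U1")
        return cls(sequences=seqs, ids=tuple(ids), reference_id=reference_id)

    @classmethod
    def from_fasta(cls, path, reference_id: str) -> "CategoricalMSA":
        from Bio import SeqIO

        pairs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        return cls.from_strings(pairs, reference_id)


@dataclass(frozen=True)
class DMSTable:
    """Per-site DMS summary: minimum log-enrichment scores, the fitted
    binarisation cutoff, and the resulting sector labels."""

    scores: np.ndarray
    modality: str = "unset"  # "unimodal" or "bimodal"
    cutoff: float = np.nan
    labels: Optional[np.ndarray] = None
    sites: Optional[np.ndarray] = None
    fit: dict = field(default_factory=dict)

    @property
    def L_S(self) -> int:
        return int(np.sum(self.labels)) if self.labels is not None else 0


# ---------------------------------------------------------------------------
# filtering and distances
# ---------------------------------------------------------------------------


def filter_msa(msa: CategoricalMSA, reference_id: Optional[str] = None) -> CategoricalMSA:
    """Standard alignment cleanup, in this fixed order: keep only columns
    where the reference is non-gap, drop columns with > 30% gaps, then
    drop sequences with > 20% gaps.  The reference row is always kept."""
    if reference_id is None:
        reference_id = msa.reference_id
    if reference_id not in msa.ids:
        raise ValueError(f"reference {reference_id!r} not present")
    seqs = msa.sequences
    ref_row = msa.ids.index(reference_id)
    keep_cols = seqs[ref_row] != GAP
    seqs = seqs[:, keep_cols]
    gap_frac_col = (seqs == GAP).mean(axis=0)
    seqs = seqs[:, gap_frac_col <= COLUMN_GAP_LIMIT]
    gap_frac_seq = (seqs == GAP).mean(axis=1) if seqs.shape[1] else np.ones(seqs.shape[0])
    keep_rows = (gap_frac_seq <= SEQUENCE_GAP_LIMIT) | (np.arange(seqs.shape[0]) == ref_row)
    seqs = seqs[keep_rows]
    ids = tuple(np.asarray(msa.ids, dtype=object)[keep_rows])
    if seqs.size == 0:
        raise ValueError("filtering removed the whole alignment")
    return CategoricalMSA(sequences=seqs, ids=ids, reference_id=reference_id)


def jukes_cantor_distance(seq_a, seq_b, q: int = 20, d_max: float = JC_DISTANCE_CAP) -> float:
    """Jukes-Cantor evolutionary distance between two aligned sequences.

    d = -((q-1)/q) ln(1 - q p / (q-1)) with p the fraction of differing
    sites among sites where neither sequence is gapped; saturated pairs
    (argument <= 0) are capped at ``d_max``.
    """
    a = np.asarray(list(seq_a) if isinstance(seq_a, str) else seq_a)
    b = np.asarray(list(seq_b) if isinstance(seq_b, str) else seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    usable = (a != GAP) & (b != GAP)
    if not usable.any():
        raise ValueError("no comparable (gap-free) sites")
    p = float((a[usable] != b[usable]).mean())
    arg = 1.0 - q * p / (q - 1)
    if arg <= 0:
        return float(d_max)
    return float(min(-(q - 1) / q * np.log(arg), d_max))


def distances_to_reference(msa: CategoricalMSA, q: int = 20) -> np.ndarray:
    ref = msa.reference
    return np.array([jukes_cantor_distance(row, ref, q=q) for row in msa.sequences])


def cutoff_subsample(msa: CategoricalMSA, cutoff: float, q: int = 20) -> CategoricalMSA:
    """Retain only sequences within ``cutoff`` Jukes-Cantor distance of the
    reference (the "phylogenetic cutoff" subsampling)."""
    d = distances_to_reference(msa, q=q)
    keep = d <= cutoff
    keep[msa.reference_row] = True
    seqs = msa.sequences[keep]
    ids = tuple(np.asarray(msa.ids, dtype=object)[keep])
    if seqs.shape[0] == 0:
        raise ValueError("cutoff leaves an empty alignment")
    return CategoricalMSA(sequences=seqs, ids=ids, reference_id=msa.reference_id)


def impute_gaps_nearest(msa: CategoricalMSA, q: int = 20) -> CategoricalMSA:
    """Replace each gap by the state carried at that site by the nearest
    sequence (Jukes-Cantor) that is non-gap there.  Ties go to the
    smallest row index; non-gap symbols are never altered."""
    seqs = msa.sequences.copy()
    M = seqs.shape[0]
    gap_rows = np.nonzero((seqs == GAP).any(axis=1))[0]
    if gap_rows.size == 0:
        return msa
    dist = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            dist[i, j] = dist[j, i] = jukes_cantor_distance(msa.sequences[i], msa.sequences[j], q=q)
    for m in gap_rows:
        order = np.argsort(dist[m], kind="stable")  # ties -> smallest row index
        order = order[order != m]
        for site in np.nonzero(seqs[m] == GAP)[0]:
            for donor in order:
                if msa.sequences[donor, site] != GAP:
                    seqs[m, site] = msa.sequences[donor, site]
                    break
            else:
                raise ValueError(f"all sequences gapped at site {site}")
    return CategoricalMSA(sequences=seqs, ids=msa.ids, reference_id=msa.reference_id)


# ---------------------------------------------------------------------------
# eigenvector aggregation across cutoffs
# ---------------------------------------------------------------------------


def aggregate_eigenvectors(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Component-wise sum of per-cutoff eigenvectors after sign alignment.

    Each vector's sign is flipped if its Pearson correlation with the
    first vector is negative; the overall sign of the sum stays arbitrary
    and downstream scoring uses absolute values.
    """
    if len(vectors) == 0:
        raise ValueError("need at least one vector")
    arrs = [np.asarray(getattr(v, "values", v), float) for v in vectors]
    L = arrs[0].size
    if any(v.size != L for v in arrs):
        raise ValueError("vectors must all have the same length")
    total = arrs[0].copy()
    for v in arrs[1:]:
        r = np.corrcoef(arrs[0], v)[0, 1]
        total += -v if r < 0 else v
    return total


# ---------------------------------------------------------------------------
# DMS tables
# ---------------------------------------------------------------------------


def dms_site_scores(table: pd.DataFrame) -> DMSTable:
    """Reduce a long per-mutation table to per-site scores by taking the
    minimum (most deleterious) log-enrichment at each site.

    ``table`` needs columns ``site`` and ``score``; sites with no
    measurements are simply absent from the output.
    """
    if not {"site", "score"}.issubset(table.columns):
        raise ValueError("table must have 'site' and 'score' columns")
    clean = table.dropna(subset=["score"])
    missing = sorted(set(table["site"]) - set(clean["site"]))
    if missing:
        warnings.warn(f"sites with no usable measurement dropped: {missing}")
    grouped = clean.groupby("site")["score"].min().sort_index()
    return DMSTable(scores=grouped.to_numpy(float), sites=grouped.index.to_numpy())


def _density_minimum(gmm: GaussianMixture, lo: float, hi: float) -> float:
    def neg_density(x):
        return np.exp(gmm.score_samples(np.array([[x]])))[0]

    res = minimize_scalar(neg_density, bounds=(lo, hi), method="bounded")
    return float(res.x)


def _kde_peaks(scores: np.ndarray) -> np.ndarray:
    kde = spstats.gaussian_kde(scores)  # Scott's rule bandwidth
    grid = np.linspace(scores.min(), scores.max(), 512)
    dens = kde(grid)
    peaks, _ = spsignal.find_peaks(dens, prominence=0.05 * dens.max())
    return grid[peaks]


def binarise_dms(
    scores, modality: str = "auto", random_state: int = 0
) -> DMSTable:
    """Fit the per-site score distribution and threshold it into sector /
    non-sector labels.

    A one- and a two-component Gaussian mixture are fitted; unless
    ``modality`` overrides it, the model with the lower BIC wins.  The
    cutoff is the fitted mean (unimodal) or the density minimum between
    the two component means (bimodal).  If a kernel-density estimate
    shows more than two peaks, the bimodal fit is restricted to the
    scores below the third-most-negative peak, i.e. to the two most
    negative peaks.  Sites scoring below the cutoff are labelled sector.
    """
    if isinstance(scores, DMSTable):
        sites, scores = scores.sites, scores.scores
    else:
        sites = None
    x = np.asarray(scores, float)
    if modality not in ("auto", "unimodal", "bimodal"):
        raise ValueError("modality must be 'auto', 'unimodal' or 'bimodal'")
    X = x.reshape(-1, 1)
    fit_x = x
    peaks = _kde_peaks(x)
    if peaks.size > 2:
        limit = np.sort(peaks)[2]  # third-most-negative peak location
        restricted = x[x < limit]
        if restricted.size >= 10:
            fit_x = restricted
    gmm1 = GaussianMixture(1, random_state=random_state).fit(X)
    gmm2 = GaussianMixture(2, random_state=random_state).fit(fit_x.reshape(-1, 1))
    if modality == "auto":
        use_bimodal = gmm2.bic(fit_x.reshape(-1, 1)) < gmm1.bic(fit_x.reshape(-1, 1))
    else:
        use_bimodal = modality == "bimodal"
    if use_bimodal and gmm2.weights_.min() < 0.01:
        warnings.warn("degenerate mixture component; falling back to unimodal fit")
        use_bimodal = False
    if use_bimodal:
        means = np.sort(gmm2.means_.ravel())
        cutoff = _density_minimum(gmm2, means[0], means[1])
        chosen = "bimodal"
        fit = {"means": means, "weights": np.sort(gmm2.weights_.ravel())}
    else:
        cutoff = float(gmm1.means_.ravel()[0])
        chosen = "unimodal"
        fit = {"means": gmm1.means_.ravel(), "weights": gmm1.weights_.ravel()}
    labels = x < cutoff
    return DMSTable(
        scores=x, modality=chosen, cutoff=float(cutoff), labels=labels, sites=sites, fit=fit
    )


# ---------------------------------------------------------------------------
# diversity metrics and overlap counting
# ---------------------------------------------------------------------------


def _normalized_hamming_matrix(msa: CategoricalMSA) -> np.ndarray:
    seqs = msa.sequences
    M = seqs.shape[0]
    d = np.zeros((M, M))
    for i in range(M):
        diff = (seqs[i] != seqs).mean(axis=1)
        d[i] = diff
    return d


def mean_pairwise_hamming_protein(msa: CategoricalMSA) -> float:
    """Mean normalized Hamming distance over all unordered sequence pairs."""
    if msa.M < 2:
        raise ValueError("need at least two sequences")
    d = _normalized_hamming_matrix(msa)
    iu = np.triu_indices(msa.M, k=1)
    return float(d[iu].mean())


def effective_depth(msa: CategoricalMSA, theta: float = 0.2) -> float:
    """Diversity-corrected alignment depth M_eff = sum_m 1 / n_m, where
    n_m counts the sequences (self included) within normalized Hamming
    distance ``theta`` of sequence m."""
    if msa.M < 2:
        raise ValueError("need at least two sequences")
    d = _normalized_hamming_matrix(msa)
    n_m = (d < theta).sum(axis=1)
    return float(np.sum(1.0 / n_m))


def top_sites(scores, n: int) -> np.ndarray:
    """Indices of the n largest |score| sites; ties break by site index."""
    s = np.abs(np.asarray(getattr(scores, "values", scores), float))
    order = np.lexsort((np.arange(s.size), -s))
    return np.sort(order[:n])


def overlap_counts(sites_a, sites_b, truth) -> tuple[int, int, int]:
    """True-positive overlap between two methods' predicted site sets.

    Returns (both, only_a, only_b): counts of truly functional sites
    (per the boolean ``truth`` labels) found by both methods, by the
    first only, and by the second only.
    """
    truth = np.asarray(truth, dtype=bool)
    sa, sb = set(np.asarray(sites_a, int).tolist()), set(np.asarray(sites_b, int).tolist())
    if max(sa | sb, default=0) >= truth.size:
        raise ValueError("site index beyond the label vector")
    tp = {i for i in range(truth.size) if truth[i]}
    both = len(sa & sb & tp)
    only_a = len((sa - sb) & tp)
    only_b = len((sb - sa) & tp)
    return both, only_a, only_b
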