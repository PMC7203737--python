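"""Model-fit evaluation: correlation of k-mer counts with model scores.

A learned mixture is judged by how well it predicts the occurrence
counts of short words in the training reads: k-mers (8-mers or 10-mers)
are counted over both strands, collapsed to canonical form, and scored
under the mixture; the squared Pearson correlation R^2 between counts
and scores summarizes the fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .adm import marginals, reverse_complement
from .alphabet import encode_reads
from .dimer import DimerSpec
from .mixture import MixtureModel

__all__ = [
    "count_kmers",
    "score_kmer",
    "score_kmers",
    "r_squared",
    "evaluate_model",
    "most_frequent_kmer",
]

_POW4 = {k: 4 ** np.arange(k)[::-1] for k in range(1, 17)}


def _kmer_codes(enc: np.ndarray, k: int):
    """Canonical integer code of every N-free window of width k."""
    n, L = enc.shape
    if k > L:
        raise ValueError(f"k={k} exceeds read length {L}")
    S = L - k + 1
    fwd = np.zeros((n, S), dtype=np.int64)
    rev = np.zeros((n, S), dtype=np.int64)
    ok = np.ones((n, S), dtype=bool)
    p4 = _POW4[k]
    for h in range(k):
        col = enc[:, h : h + S].astype(np.int64)
        ok &= col < 4
        colc = np.minimum(col, 3)
        fwd += colc * p4[h]
        rev += (3 - colc) * p4[k - 1 - h]
    return np.minimum(fwd, rev)[ok]


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for h in range(k):
        out.append("ACGT"[(code >> (2 * (k - 1 - h))) & 3])
    return "".join(out)


def count_kmers(reads, k: int) -> pd.Series:
    """Sliding-window k-mer counts, both strands collapsed to canonical
    form (a k-mer and its reverse complement share one entry, keyed by
    the lexicographically smaller); windows containing N are skipped."""
    enc = reads if isinstance(reads, np.ndarray) else encode_reads(reads)
    codes = _kmer_codes(enc, k)
    uniq, cnt = np.unique(codes, return_counts=True)
    idx = [_decode_kmer(int(c), k) for c in uniq]
    return pd.Series(cnt, index=idx, name="count")


def score_kmers(
    model: MixtureModel, kmers, log_space: bool = False, collapse: bool = False
) -> np.ndarray:
    """Mixture score of each k-mer.

    The score of word ``w`` is the mixture-weighted, placement-averaged
    probability of observing ``w`` in a read window: every component is
    slid across ``w`` on both strands (components may extend past the
    word; overhanging component positions are marginalized via the
    component marginals, and uncovered word positions are scored by the
    background), each placement weighted by ``lambda / N`` with ``N``
    the number of (offset, strand) placements, plus the pure-background
    term ``lambda_0 * P_bg(w)``.

    With ``collapse`` the inputs are canonical strand-collapsed k-mers
    and each non-self-complementary word's score is doubled (its class
    pools the occurrences of the word and its reverse complement).
    """
    kmers = list(kmers)
    if not kmers:
        return np.zeros(0)
    k = len(kmers[0])
    if any(len(w) != k for w in kmers):
        raise ValueError("all k-mers must have equal length")
    W = encode_reads(kmers).astype(np.intp)
    if np.any(W > 3):
        raise ValueError("k-mers must be over ACGT")
    m = W.shape[0]
    bgp = model.background.stationary()
    bg_full = np.prod(bgp[W], axis=1)
    scores = model.lam_bg * bg_full

    for key in model.component_keys():
        lam = model.component_lambda(key)
        if lam <= 0:
            continue
        adm = model.component_adm(key)
        wc = adm.length
        nplace = 2 * (k + wc - 1)
        for variant in (adm, reverse_complement(adm)):
            marg = marginals(variant)
            for t in range(1 - wc, k):
                p0, p1 = max(0, t), min(k, t + wc)
                c0 = p0 - t
                if c0 == 0:
                    P = variant.initial[W[:, p0]].copy()
                else:
                    P = marg[c0][W[:, p0]].copy()
                for c in range(c0 + 1, p1 - t):
                    P *= variant.trans[c - 1, W[:, p0 + c - c0 - 1], W[:, p0 + c - c0]]
                bg_cov = np.prod(bgp[W[:, p0:p1]], axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    flank = np.where(bg_cov > 0, bg_full / bg_cov, 0.0)
                scores += (lam / nplace) * P * flank
    if collapse:
        from .alphabet import revcomp

        pal = np.array([w == revcomp(w) for w in kmers])
        scores = np.where(pal, scores, 2.0 * scores)
    return np.log(scores) if log_space else scores


def score_kmer(model: MixtureModel, kmer: str) -> float:
    """Score a single k-mer (see :func:`score_kmers`)."""
    return float(score_kmers(model, [kmer])[0])


def r_squared(
    counts: pd.Series,
    scores: np.ndarray | pd.Series,
    log_log: bool = False,
    min_count: int = 0,
) -> float:
    """Squared Pearson correlation between k-mer counts and scores.

    ``log_log`` correlates log counts with log scores; ``min_count``
    drops low-count k-mers first.  Raises on degenerate variance.
    """
    x = counts.to_numpy(dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("counts and scores must align")
    keep = x >= max(min_count, 1 if log_log else 0)
    if log_log:
        keep &= y > 0
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need at least two k-mers with nonzero count")
    if log_log:
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: counts or scores are constant")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def evaluate_model(
    model: MixtureModel,
    reads,
    k: int = 8,
    log_log: bool = False,
    min_count: int = 0,
):
    """Count, score and correlate in one call.

    Returns (table, r2) where the table has one row per observed
    canonical k-mer with its count and model score.
    """
    counts = count_kmers(reads, k)
    scores = score_kmers(model, counts.index, collapse=True)
    table = pd.DataFrame({"count": counts, "score": scores})
    return table, r_squared(counts, scores, log_log=log_log, min_count=min_count)


def most_frequent_kmer(reads, k: int) -> str:
    """Most frequent canonical k-mer of the reads: a cheap seed guess."""
    counts = count_kmers(reads, k)
    return str(counts.idxmax())
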