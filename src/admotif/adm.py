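"""Adjacent dinucleotide matrices (ADMs): inhomogeneous first-order Markov
chains over DNA positions.

An ADM of length ``L`` consists of an initial distribution over the four
bases at position 1 and, for every later position ``h``, a 4x4 matrix of
conditionals ``P(X_h = b | X_{h-1} = a)``.  The probability of a sequence
``a_1 .. a_L`` is the chain product ``initial(a_1) * prod_h P(a_h|a_{h-1})``.

The canonical on-disk layout is a 16 x L matrix whose rows are indexed by
dinucleotides AA..TT and whose first column holds the initial distribution
replicated across the four predecessor rows (position 1 has no
predecessor, but this keeps the file a uniform 16-row matrix).

A PPM (order-zero position probability matrix) is the degenerate ADM whose
conditionals do not depend on the predecessor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import ALPHABET, COMPLEMENT, IUPAC, validate_iupac

_ATOL = 1e-9


@dataclass
class ADM:
    """First-order inhomogeneous Markov chain over DNA positions.

    Parameters
    ----------
    initial
        Probability vector over A,C,G,T for position 1, shape (4,).
    trans
        Conditionals for positions 2..L, shape (L-1, 4, 4);
        ``trans[h-1][a, b] = P(X_{h+1} = b | X_h = a)`` with 0-based h.
    name
        Optional label used in serialization.
    """

    initial: np.ndarray
    trans: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float).reshape(-1, 4, 4)
        self.validate()

    @property
    def length(self) -> int:
        return self.trans.shape[0] + 1

    def validate(self) -> None:
        if self.initial.shape != (4,):
            raise ValueError(f"initial must have shape (4,), got {self.initial.shape}")
        if np.any(self.initial < -_ATOL) or np.any(self.initial > 1 + _ATOL):
            raise ValueError("initial distribution entries outside [0, 1]")
        if abs(self.initial.sum() - 1.0) > _ATOL:
            raise ValueError(f"initial distribution sums to {self.initial.sum()!r}, not 1")
        if self.trans.size:
            if np.any(self.trans < -_ATOL) or np.any(self.trans > 1 + _ATOL):
                raise ValueError("transition entries outside [0, 1]")
            rows = self.trans.sum(axis=2)
            if np.any(np.abs(rows - 1.0) > _ATOL):
                h, a = np.unravel_index(np.argmax(np.abs(rows - 1.0)), rows.shape)
                raise ValueError(
                    f"conditional row (position {h + 2}, predecessor "
                    f"{ALPHABET[a]}) sums to {rows[h, a]!r}, not 1"
                )

    # -- conversions -------------------------------------------------------

    def matrix16(self) -> np.ndarray:
        """16 x L layout: rows AA..TT; column 0 replicates the initial."""
        out = np.empty((16, self.length))
        out[:, 0] = np.tile(self.initial, 4)
        for h in range(self.length - 1):
            out[:, h + 1] = self.trans[h].reshape(16)
        return out

    @classmethod
    def from_matrix16(cls, mat: np.ndarray, name: str = "") -> "ADM":
        mat = np.asarray(mat, dtype=float)
        if mat.shape[0] != 16:
            raise ValueError(f"expected 16 rows, got {mat.shape[0]}")
        initial = mat[:4, 0]
        trans = np.stack([mat[:, h].reshape(4, 4) for h in range(1, mat.shape[1])]) \
            if mat.shape[1] > 1 else np.empty((0, 4, 4))
        return cls(initial, trans, name=name)

    def copy(self) -> "ADM":
        return ADM(self.initial.copy(), self.trans.copy(), name=self.name)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ADM)
            and self.length == other.length
            and np.array_equal(self.initial, other.initial)
            and np.array_equal(self.trans, other.trans)
        )


@dataclass
class PPM:
    """Order-zero motif model: independent per-position base distributions."""

    probs: np.ndarray  # (L, 4), rows sum to 1

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PPM probs must have shape (L, 4)")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > _ATOL):
            raise ValueError("PPM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def to_adm(self, name: str = "") -> ADM:
        """Embed as the ADM whose conditionals ignore the predecessor."""
        trans = np.repeat(self.probs[1:, None, :], 4, axis=1)
        return ADM(self.probs[0], trans, name=name)


@dataclass
class BackgroundModel:
    """Homogeneous background chain for positions outside motif instances.

    Order zero by default: a single mononucleotide distribution.  An
    order-one variant (4x4 transition matrix plus initial distribution)
    is supported; its stationary distribution is computed on demand.
    """

    probs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    trans: np.ndarray | None = None  # order-one if given

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > _ATOL:
            raise ValueError("background distribution must sum to 1")
        if self.trans is not None:
            self.trans = np.asarray(self.trans, dtype=float)
            if self.trans.shape != (4, 4):
                raise ValueError("background transition matrix must be 4x4")
            if np.any(np.abs(self.trans.sum(axis=1) - 1.0) > _ATOL):
                raise ValueError("background transition rows must sum to 1")

    @property
    def order(self) -> int:
        return 0 if self.trans is None else 1

    def stationary(self) -> np.ndarray:
        """Stationary distribution (the mononucleotide probs at order 0)."""
        if self.trans is None:
            return self.probs
        vals, vecs = np.linalg.eig(self.trans.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()

    def matrix(self) -> np.ndarray:
        """4x4 conditional representation (order-0 rows are replicated)."""
        if self.trans is not None:
            return self.trans
        return np.tile(self.probs, (4, 1))

    def copy(self) -> "BackgroundModel":
        return BackgroundModel(
            self.probs.copy(), None if self.trans is None else self.trans.copy()
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def seq_probability(adm: ADM, seq) -> float:
    """Probability of ``seq`` under the chain; ``seq`` may be str or codes."""
    x = _as_codes(seq)
    if x.shape[0] != adm.length:
        raise ValueError(
            f"sequence length {x.shape[0]} does not match model length {adm.length}"
        )
    if np.any(x > 3):
        raise ValueError("sequence contains non-ACGT symbols")
    p = adm.initial[x[0]]
    for h in range(1, adm.length):
        p *= adm.trans[h - 1, x[h - 1], x[h]]
    return float(p)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        from .alphabet import encode

        return encode(seq).astype(np.intp)
    return np.asarray(seq, dtype=np.intp)


def marginals(adm: ADM) -> np.ndarray:
    """Per-position base distributions, shape (L, 4).

    ``m_1`` is the initial distribution; ``m_h = m_{h-1} @ P_h``.
    """
    out = np.empty((adm.length, 4))
    out[0] = adm.initial
    for h in range(1, adm.length):
        out[h] = out[h - 1] @ adm.trans[h - 1]
    return out


def consensus(adm: ADM) -> str:
    """Highest-probability sequence by max-product dynamic programming.

    Ties are broken toward the alphabetically smaller base at each
    backtracking step (last position first), which makes the result
    deterministic.
    """
    L = adm.length
    with np.errstate(divide="ignore"):
        li = np.log(adm.initial)
        lt = np.log(adm.trans) if adm.trans.size else adm.trans
    # V[h, b]: best log-prob of a prefix ending in base b at position h
    V = np.empty((L, 4))
    back = np.zeros((L, 4), dtype=np.intp)
    V[0] = li
    for h in range(1, L):
        cand = V[h - 1][:, None] + lt[h - 1]  # (prev a, next b)
        best = cand.max(axis=0)
        # smallest predecessor index achieving the max (within tolerance)
        back[h] = np.argmax(cand >= best[None, :] - 1e-12, axis=0)
        V[h] = best
    path = np.empty(L, dtype=np.intp)
    path[-1] = int(np.argmax(V[-1] >= V[-1].max() - 1e-12))
    for h in range(L - 1, 0, -1):
        path[h - 1] = back[h, path[h]]
    return "".join(ALPHABET[b] for b in path)


def reverse_complement(adm: ADM) -> ADM:
    """The ADM of the reverse-complemented site.

    Satisfies ``P_rc(s) = P(revcomp(s))`` for every sequence ``s``: the
    time reversal of a Markov chain is again Markov, so the construction
    is exact.  Built by forming the position-wise joint dinucleotide
    distributions ``q_h(a,b) = m_{h-1}(a) P(b|a)``, reversing and
    complementing them, and renormalizing to conditionals.  Predecessor
    states with zero marginal mass yield undefined conditionals; these
    rows are replaced by the uniform distribution with a warning (such
    states are unreachable, so sequence probabilities are unaffected).
    """
    L = adm.length
    m = marginals(adm)
    c = COMPLEMENT[:4].astype(np.intp)
    new_initial = m[L - 1][c]
    new_trans = np.empty_like(adm.trans)
    warned = False
    for j in range(1, L):
        # junction into new position j+1 mirrors original junction L-j -> L-j+1
        h = L - j  # original 0-based junction index into trans
        q = m[h - 1][:, None] * adm.trans[h - 1]  # q(a, b)
        qr = q[np.ix_(c, c)].T  # q'(a', b') = q(comp b', comp a')
        rows = qr.sum(axis=1)
        zero = rows <= 0.0
        if np.any(zero):
            warned = True
            qr[zero] = 0.25
            rows[zero] = 1.0
        new_trans[j - 1] = qr / rows[:, None]
    if warned:
        warnings.warn(
            "reverse_complement: zero-mass predecessor states replaced by "
            "uniform conditionals (unreachable states)",
            RuntimeWarning,
            stacklevel=2,
        )
    s = new_initial.sum()
    return ADM(new_initial / s, new_trans, name=adm.name + "_rc" if adm.name else "")


def seed_to_adm(seed: str, match_weight: float = 0.8, name: str = "") -> ADM:
    """Initial ADM for an IUPAC seed.

    At each position the bases allowed by the IUPAC code share
    ``match_weight`` equally and the disallowed bases share
    ``1 - match_weight`` equally.  The result is order-zero (conditionals
    independent of the predecessor); EM immediately introduces order-one
    structure.
    """
    validate_iupac(seed)
    if not 0.0 < match_weight <= 1.0:
        raise ValueError(f"match_weight must be in (0, 1], got {match_weight}")
    cols = np.empty((len(seed), 4))
    for pos, ch in enumerate(seed.upper()):
        allowed = IUPAC[ch]
        col = np.full(4, 0.0)
        if len(allowed) == 4:
            col[:] = 0.25
        else:
            col[:] = (1.0 - match_weight) / (4 - len(allowed))
            col[list(allowed)] = match_weight / len(allowed)
        cols[pos] = col
    return PPM(cols).to_adm(name=name or seed)


def adm_from_counts(
    initial_counts: np.ndarray,
    trans_counts: np.ndarray,
    pseudocount: float = 0.01,
    name: str = "",
) -> ADM:
    """Maximum-likelihood ADM from weighted dinucleotide counts.

    ``pseudocount`` is added to every cell before row normalization.
    With pseudocount 0, conditional rows of predecessors that were never
    observed are undefined; they are filled with the uniform
    distribution (such states are unreachable under the estimate, so
    sequence probabilities are unaffected).  All-zero counts overall
    with pseudocount 0 are an error.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    init = np.asarray(initial_counts, dtype=float) + pseudocount
    trans = np.asarray(trans_counts, dtype=float).reshape(-1, 4, 4) + pseudocount
    if np.any(init < 0) or np.any(trans < 0):
        raise ValueError("counts must be nonnegative")
    s = init.sum()
    if s <= 0:
        raise ValueError("all-zero counts with zero pseudocount")
    rows = trans.sum(axis=2)
    dead = rows <= 0
    if np.any(dead):
        trans[dead] = 0.25
        rows[dead] = 1.0
    return ADM(init / s, trans / rows[:, :, None], name=name)


def sample(adm: ADM, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` sequences from the chain; returns (n, L) uint8 codes."""
    L = adm.length
    out = np.empty((n, L), dtype=np.uint8)
    u = rng.random((n, L))
    out[:, 0] = np.searchsorted(np.cumsum(adm.initial), u[:, 0], side="right")
    for h in range(1, L):
        cum = np.cumsum(adm.trans[h - 1], axis=1)  # (4, 4)
        rows = cum[out[:, h - 1].astype(np.intp)]
        out[:, h] = (u[:, h, None] >= rows).sum(axis=1)
    np.clip(out, 0, 3, out=out)
    return out
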