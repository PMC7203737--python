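"""ZOOPS mixture EM for learning monomer + dimer ADM mixtures from reads.

Each read is assumed to contain at most one motif occurrence (zero or
one occurrence per sequence).  The E-step computes, per read, a
posterior over (component, start, strand) plus a background-only mass;
the M-step re-estimates mixing weights, monomer chains (from monomeric
occurrences and well-separated dimer half-sites only), bridging
components and the background.  Heuristics from the reference procedure
are included: restriction of learning to windows within a Hamming
neighborhood of the current consensus sequences, and permanent removal
of dimer cells whose mixing weight collapses.

All kernels are vectorized over reads; the implementation is exact EM
when the Hamming radius is infinite and pruning is disabled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import COMPLEMENT, RC_DINUC, encode, encode_reads, revcomp
from .adm import (
    ADM,
    BackgroundModel,
    adm_from_counts,
    consensus,
    reverse_complement,
    seed_to_adm,
)
from .dimer import ORIENTATION_FLAGS, DimerSpec, bridging_window, orient_pair
from .mixture import MixtureModel, model_distance

__all__ = [
    "TrainingConfig",
    "ReadData",
    "PosteriorTable",
    "EMResult",
    "log_likelihood",
    "e_step",
    "hamming_filter",
    "m_step",
    "prune_weak_dimers",
    "run_em",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Hyperparameters of the learner.

    ``pairs`` lists the monomer index pairs whose dimers are searched;
    spacing intervals default to [-floor(min(l1,l2)/2), 10] per pair.
    ``delta`` is the independence threshold on the spacing; ``rho`` the
    Hamming radius of the seed-driven restriction (None means no
    restriction; the conventional defaults are 2 for order-zero models
    and 3 for ADMs).  ``epsilon`` bounds the parameter change (weighted
    maximum norm) between consecutive iterations at convergence.
    """

    pairs: list = field(default_factory=list)
    spacing: dict = field(default_factory=dict)  # (k1,k2) -> (dmin, dmax)
    delta: int = 4
    maxiter: int = 150
    epsilon: float = 1e-3
    rho: int | None = 3
    order: int = 1
    prune_threshold: float = 1e-4
    prune_start: int = 3
    pruning: bool = True
    filter_scope: str = "matrices"  # Hamming filter limits "matrices" or "all"
    pseudocount: float = 0.01
    match_weight: float = 0.8
    lam_bg_init: float = 0.5
    estimate_background: bool = True
    background: BackgroundModel | None = None
    flank_left: str = ""
    flank_right: str = ""
    include_th_homodimer: bool = False

    def __post_init__(self):
        if self.order == 0 and self.rho == 3:
            self.rho = 2
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.filter_scope not in ("matrices", "all"):
            raise ValueError("filter_scope must be 'matrices' or 'all'")


# ---------------------------------------------------------------------------
# read container
# ---------------------------------------------------------------------------

class ReadData:
    """Encoded read matrix plus the precomputed index tables the
    vectorized kernels need (dinucleotide codes, N masks, prefix sums).

    Reads of unequal length are right-padded with the N code; padding is
    treated exactly like an ambiguous base.  ``core`` marks positions
    that may contribute to background re-estimation (constant flanks and
    N positions are excluded).
    """

    def __init__(self, reads, flank_left: str = "", flank_right: str = ""):
        if isinstance(reads, np.ndarray):
            seqs = None
            enc = reads.astype(np.uint8)
            if flank_left or flank_right:
                from .alphabet import encode

                nl, nr = len(flank_left), len(flank_right)
                full = np.full((enc.shape[0], enc.shape[1] + nl + nr), 4, np.uint8)
                full[:, nl : nl + enc.shape[1]] = enc
                if nl:
                    full[:, :nl] = encode(flank_left)
                if nr:
                    full[:, nl + enc.shape[1] :] = encode(flank_right)
                enc = full
        else:
            seqs = [flank_left + r + flank_right for r in reads]
            enc = encode_reads(seqs)
        self.enc = enc
        self.n, self.L = enc.shape
        self.flank = (len(flank_left), len(flank_right))
        isn = enc == 4
        a = enc[:, :-1].astype(np.intp)
        b = enc[:, 1:].astype(np.intp)
        D = a * 4 + b
        D[(a > 3) | (b > 3)] = 16
        self.D = D
        rc_ext = np.append(RC_DINUC, 16)
        self.Drc = rc_ext[D]
        self.cumN = np.zeros((self.n, self.L + 1), dtype=np.int32)
        np.cumsum(isn, axis=1, out=self.cumN[:, 1:])
        core = (~isn).astype(float)
        nl, nr = self.flank
        if nl:
            core[:, :nl] = 0.0
        if nr:
            core[:, self.L - nr :] = 0.0
        self.core = core
        self._valid: dict[int, np.ndarray] = {}
        self._nvalid: dict[int, np.ndarray] = {}

    def valid(self, w: int) -> np.ndarray:
        """Boolean (n, L-w+1): window [j, j+w) contains no N/padding."""
        if w not in self._valid:
            if w > self.L:
                raise ValueError(
                    f"component of length {w} exceeds read length {self.L}"
                )
            self._valid[w] = (self.cumN[:, w:] - self.cumN[:, :-w]) == 0
        return self._valid[w]

    def nvalid(self, w: int) -> np.ndarray:
        if w not in self._nvalid:
            self._nvalid[w] = self.valid(w).sum(axis=1)
        return self._nvalid[w]


def as_read_data(reads, config: TrainingConfig | None = None) -> ReadData:
    if isinstance(reads, ReadData):
        return reads
    c = config or TrainingConfig()
    return ReadData(reads, c.flank_left, c.flank_right)


# ---------------------------------------------------------------------------
# background tables
# ---------------------------------------------------------------------------

class _BgTables:
    """Per-dataset window probabilities under the background chain."""

    def __init__(self, bg: BackgroundModel, data: ReadData):
        self.bg = bg
        self.data = data
        enc = data.enc.astype(np.intp)
        if bg.order == 0:
            with np.errstate(divide="ignore"):
                tab = np.append(np.log(bg.probs), 0.0)  # N contributes factor 1
            lb = tab[enc]
            self.cum = np.zeros((data.n, data.L + 1))
            np.cumsum(lb, axis=1, out=self.cum[:, 1:])
            self._entry = None
        else:
            pi = bg.stationary()
            with np.errstate(divide="ignore"):
                ent = np.append(np.log(pi), 0.0)
                tr = np.append(np.log(bg.trans).reshape(16), 0.0)
            self._entry = ent[enc]
            ltr = tr[np.minimum(data.D, 16)]
            self.cum = np.zeros((data.n, data.L))
            np.cumsum(ltr, axis=1, out=self.cum[:, 1:])
        self._win: dict[int, np.ndarray] = {}

    def win_log(self, w: int) -> np.ndarray:
        """(n, L-w+1) log-probability of each window under the background."""
        if w not in self._win:
            if self.bg.order == 0:
                self._win[w] = self.cum[:, w:] - self.cum[:, :-w]
            else:
                S = self.data.L - w + 1
                self._win[w] = (
                    self._entry[:, :S] + self.cum[:, w - 1 :] - self.cum[:, : S]
                )
        return self._win[w]

    def read_log(self) -> np.ndarray:
        """log P_bg of every full read (N positions contribute factor 1)."""
        if self.bg.order == 0:
            return self.cum[:, -1]
        return self._entry[:, 0] + self.cum[:, -1]


# ---------------------------------------------------------------------------
# window kernels
# ---------------------------------------------------------------------------

def _window_ratios(adm: ADM, data: ReadData, bgt: _BgTables) -> np.ndarray:
    """(n, S) ratios P_adm(window) / P_bg(window); 0 where the window
    touches an N."""
    w = adm.length
    S = data.L - w + 1
    if S <= 0:
        raise ValueError(
            f"component of length {w} does not fit in reads of length {data.L}"
        )
    enc = data.enc.astype(np.intp)
    W = np.append(adm.initial, 0.0)[enc[:, :S]]
    for h in range(1, w):
        tab = np.append(adm.trans[h - 1].reshape(16), 0.0)
        W *= tab[data.D[:, h - 1 : h - 1 + S]]
    with np.errstate(over="ignore"):
        W /= np.exp(bgt.win_log(w))
    return W


def _hamming_windows(data: ReadData, cons: np.ndarray) -> np.ndarray:
    """(n, S) Hamming distance of every window to consensus codes."""
    w = cons.shape[0]
    S = data.L - w + 1
    out = np.zeros((data.n, S), dtype=np.int16)
    for h in range(w):
        out += data.enc[:, h : h + S] != cons[h]
    return out


def _window_adm_counts(data: ReadData, Q: np.ndarray, w: int, rc_frame: bool):
    """Posterior-weighted dinucleotide counts of windows in motif frame.

    ``Q[i, j]`` is the posterior mass of a placement of width ``w``
    starting at read position ``j``.  With ``rc_frame`` the instance is
    the reverse complement of the window, and counts are mapped into
    motif coordinates accordingly.
    """
    S = Q.shape[1]
    qr = Q.ravel()
    trans = np.zeros((w - 1, 4, 4))
    if not rc_frame:
        init = np.bincount(
            data.enc[:, :S].ravel().astype(np.intp), weights=qr, minlength=5
        )[:4]
        for h in range(1, w):
            c = np.bincount(
                data.D[:, h - 1 : h - 1 + S].ravel(), weights=qr, minlength=17
            )[:16]
            trans[h - 1] = c.reshape(4, 4)
    else:
        comp_first = COMPLEMENT[data.enc[:, w - 1 : w - 1 + S]].astype(np.intp)
        init = np.bincount(comp_first.ravel(), weights=qr, minlength=5)[:4]
        for h in range(1, w):
            c = np.bincount(
                data.Drc[:, w - 1 - h : w - 1 - h + S].ravel(),
                weights=qr,
                minlength=17,
            )[:16]
            trans[h - 1] = c.reshape(4, 4)
    return init, trans


# ---------------------------------------------------------------------------
# posterior table
# ---------------------------------------------------------------------------

@dataclass
class PosteriorTable:
    """Per-read ZOOPS posterior over (component, start, strand) plus a
    background-only mass.  ``resp[key]`` holds two (n, S) arrays, one per
    strand; per-read masses sum to 1."""

    model: MixtureModel
    data: ReadData
    resp: dict
    bg_mass: np.ndarray
    ll: float

    def component_mass(self, key) -> float:
        pp, pm = self.resp[key]
        return float(pp.sum() + pm.sum())

    def read_totals(self) -> np.ndarray:
        tot = self.bg_mass.copy()
        for pp, pm in self.resp.values():
            tot += pp.sum(axis=1) + pm.sum(axis=1)
        return tot


def _component_geometry(model: MixtureModel, key):
    """Half-site layout of a component on both strands.

    Returns (width, halves_plus, halves_minus) where each half is a
    tuple (monomer index, rc flag, offset within the window).
    """
    if not isinstance(key, DimerSpec):
        k = key[1]
        w = model.monomers[k].length
        return w, [(k, False, 0)], [(k, True, 0)]
    spec = key
    f1, f2 = ORIENTATION_FLAGS[spec.o]
    l1 = model.monomers[spec.k1].length
    l2 = model.monomers[spec.k2].length
    w = l1 + l2 + spec.d
    plus = [(spec.k1, f1, 0), (spec.k2, f2, l1 + spec.d)]
    minus = [(spec.k2, not f2, 0), (spec.k1, not f1, l2 + spec.d)]
    return w, plus, minus


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def _component_ratio_arrays(model, data, bgt, mono_cache):
    """Yield (key, width, Rplus, Rminus) with likelihood ratios against
    the background for every mixture component."""

    def mono_ratio(k: int, rc: bool) -> np.ndarray:
        if (k, rc) not in mono_cache:
            adm = model.monomers[k]
            if rc:
                adm = reverse_complement(adm)
            mono_cache[(k, rc)] = _window_ratios(adm, data, bgt)
        return mono_cache[(k, rc)]

    for key in model.component_keys():
        if not isinstance(key, DimerSpec):
            k = key[1]
            w = model.monomers[k].length
            yield key, w, mono_ratio(k, False), mono_ratio(k, True)
            continue
        spec = key
        w, plus, minus = _component_geometry(model, spec)
        S = data.L - w + 1
        if S <= 0:
            raise ValueError(
                f"dimer {spec.label()} of length {w} does not fit in reads "
                f"of length {data.L}"
            )
        if spec.d >= model.delta:
            # independence: ratio factorizes into the two half-site ratios
            # (the gap is background, so its ratio is exactly 1)
            v = data.valid(w)[:, :S]
            (k1, f1, _), (k2, f2, off2) = plus
            rp = mono_ratio(k1, f1)[:, :S] * mono_ratio(k2, f2)[:, off2 : off2 + S]
            rp = rp * v
            (k1m, f1m, _), (k2m, f2m, off2m) = minus
            rm = mono_ratio(k1m, f1m)[:, :S] * mono_ratio(k2m, f2m)[:, off2m : off2m + S]
            rm = rm * v
        else:
            tau = model.dimer_adm(spec).adm
            rp = _window_ratios(tau, data, bgt)
            rm = _window_ratios(reverse_complement(tau), data, bgt)
        yield key, w, rp, rm


def e_step(model: MixtureModel, reads, config: TrainingConfig | None = None):
    """ZOOPS posterior of every admissible placement under ``model``.

    The posterior of (component k, start j, strand) is proportional to
    ``lam_k / N_ik * P_bg(flanks) * P_k(window)`` and the background-only
    mass to ``lam_0 * P_bg(read)``; masses are normalized per read.  The
    table also carries the exact log-likelihood of the data.
    """
    data = as_read_data(reads, config)
    bgt = _BgTables(model.background, data)
    mono_cache: dict = {}
    denom = np.full(data.n, model.lam_bg)
    stored = {}
    for key, w, rp, rm in _component_ratio_arrays(model, data, bgt, mono_cache):
        lam = model.component_lambda(key)
        nv = 2 * data.nvalid(w)
        weight = np.where(nv > 0, lam / np.maximum(nv, 1), 0.0)
        sp = rp * weight[:, None]
        sm = rm * weight[:, None]
        denom += sp.sum(axis=1) + sm.sum(axis=1)
        stored[key] = (sp, sm)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(bgt.read_log() + np.log(denom)))
    safe = np.where(denom > 0, denom, 1.0)
    inv = 1.0 / safe
    for sp, sm in stored.values():
        sp *= inv[:, None]
        sm *= inv[:, None]
    bg_mass = model.lam_bg * inv
    bg_mass[denom <= 0] = 1.0
    return PosteriorTable(model=model, data=data, resp=stored, bg_mass=bg_mass, ll=ll)


def log_likelihood(model: MixtureModel, reads, config: TrainingConfig | None = None) -> float:
    """Exact ZOOPS mixture log-likelihood of the reads under ``model``."""
    data = as_read_data(reads, config)
    bgt = _BgTables(model.background, data)
    mono_cache: dict = {}
    denom = np.full(data.n, model.lam_bg)
    for key, w, rp, rm in _component_ratio_arrays(model, data, bgt, mono_cache):
        lam = model.component_lambda(key)
        nv = 2 * data.nvalid(w)
        weight = np.where(nv > 0, lam / np.maximum(nv, 1), 0.0)
        denom += (rp.sum(axis=1) + rm.sum(axis=1)) * weight
    with np.errstate(divide="ignore"):
        return float(np.sum(bgt.read_log() + np.log(denom)))


# ---------------------------------------------------------------------------
# Hamming restriction
# ---------------------------------------------------------------------------

def hamming_filter(
    post: PosteriorTable,
    rho: int | None,
    consensuses: list[str] | None = None,
) -> PosteriorTable:
    """Drop placements outside the Hamming-``rho`` neighborhood of the
    current consensus sequences and renormalize per read.

    For dimers the restriction applies to each half-site against its
    (oriented) monomer consensus with radius ``rho`` per half-site.
    Reads with no surviving placement become background-only.  ``rho``
    None (or infinite) is a no-op.
    """
    if rho is None or (isinstance(rho, float) and math.isinf(rho)):
        return post
    model, data = post.model, post.data
    cons = consensuses or [consensus(m) for m in model.monomers]
    enc_cons = {}
    for k, c in enumerate(cons):
        enc_cons[(k, False)] = encode(c).astype(np.intp)
        enc_cons[(k, True)] = encode(revcomp(c)).astype(np.intp)
    hd_cache: dict = {}

    def hd(k: int, rc: bool) -> np.ndarray:
        if (k, rc) not in hd_cache:
            hd_cache[(k, rc)] = _hamming_windows(data, enc_cons[(k, rc)])
        return hd_cache[(k, rc)]

    resp = {}
    for key, (pp, pm) in post.resp.items():
        w, plus, minus = _component_geometry(model, key)
        S = pp.shape[1]
        maskp = np.ones((data.n, S), dtype=bool)
        for k, rc, off in plus:
            maskp &= hd(k, rc)[:, off : off + S] <= rho
        maskm = np.ones((data.n, S), dtype=bool)
        for k, rc, off in minus:
            maskm &= hd(k, rc)[:, off : off + S] <= rho
        resp[key] = (pp * maskp, pm * maskm)
    tot = post.bg_mass.copy()
    for pp, pm in resp.values():
        tot += pp.sum(axis=1) + pm.sum(axis=1)
    dead = tot <= 0
    tot[dead] = 1.0
    inv = 1.0 / tot
    for pp, pm in resp.values():
        pp *= inv[:, None]
        pm *= inv[:, None]
    bg_mass = post.bg_mass * inv
    bg_mass[dead] = 1.0
    return PosteriorTable(
        model=model, data=data, resp=resp, bg_mass=bg_mass, ll=post.ll
    )


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _collapse_order0(init: np.ndarray, trans: np.ndarray):
    """Reduce dinucleotide counts to per-column base counts (PPM mode)."""
    w = trans.shape[0] + 1
    cols = np.zeros((w, 4))
    cols[0] = init
    for h in range(1, w):
        cols[h] = trans[h - 1].sum(axis=0)
    return cols


def m_step(
    post: PosteriorTable,
    config: TrainingConfig | None = None,
    filtered: PosteriorTable | None = None,
    monomer_count_log: dict | None = None,
) -> MixtureModel:
    """Re-estimate all mixture parameters from a posterior table.

    Monomer chains are learned from monomeric placements and from
    half-sites of dimers whose spacing is at least ``delta`` — never
    from half-sites of closer dimers, whose windows are distorted by the
    partner site.  Bridging components are learned from the bridging
    windows of close-dimer placements.  Counts from minus-strand
    placements are reverse-complemented into motif coordinates.  The
    background is re-estimated from posterior-weighted non-motif
    positions (unless held fixed).

    ``filtered`` is the Hamming-restricted posterior: the restriction
    limits the learning of the chains, so when given it supplies the
    dinucleotide counts for monomer and bridging matrices, while mixing
    weights and the background still come from the full posterior.

    ``monomer_count_log`` (optional, for instrumentation) collects the
    total count mass each component contributed to each monomer.
    """
    config = config or TrainingConfig()
    model, data = post.model, post.data
    mat_post = filtered if filtered is not None else post
    n = data.n
    p = model.p
    monomeric_mode = len(model.pairs) == 0

    agg: dict = {}  # (k, rc) -> (n, S_k) aggregated posterior of half-sites

    def agg_add(k: int, rc: bool, off: int, P: np.ndarray, src_key) -> None:
        w = model.monomers[k].length
        S_k = data.L - w + 1
        if (k, rc) not in agg:
            agg[(k, rc)] = np.zeros((n, S_k))
        agg[(k, rc)][:, off : off + P.shape[1]] += P
        if monomer_count_log is not None:
            monomer_count_log[(src_key, k)] = (
                monomer_count_log.get((src_key, k), 0.0) + float(P.sum())
            )

    lam_new: dict = {}
    psi_counts: dict[DimerSpec, np.ndarray] = {}
    cover = np.zeros((n, data.L + 1))

    for key, (pp, pm) in post.resp.items():
        w, plus, minus = _component_geometry(model, key)
        S = pp.shape[1]
        lam_new[key] = (pp.sum() + pm.sum()) / n
        # coverage for background subtraction
        cover[:, :S] += pp + pm
        cover[:, w : w + S] -= pp + pm
        fpp, fpm = mat_post.resp[key]
        is_dimer = isinstance(key, DimerSpec)
        use_for_monomers = (not is_dimer) or key.d >= model.delta or monomeric_mode
        if use_for_monomers:
            for strand_resp, halves in ((fpp, plus), (fpm, minus)):
                for k, rc, off in halves:
                    agg_add(k, rc, off, strand_resp, key)
        if is_dimer and key.d < model.delta:
            spec = key
            a, _ = orient_pair(
                model.monomers[spec.k1], model.monomers[spec.k2], spec.o
            )
            start, width = bridging_window(a.length, spec.d)
            counts = psi_counts.setdefault(spec, np.zeros((width, 4, 4)))
            for c in range(width):
                u = start + c
                if u == 0:
                    bp = np.bincount(
                        data.enc[:, :S].ravel().astype(np.intp),
                        weights=fpp.ravel(),
                        minlength=5,
                    )[:4]
                    bm = np.bincount(
                        COMPLEMENT[data.enc[:, w - 1 : w - 1 + S]]
                        .ravel()
                        .astype(np.intp),
                        weights=fpm.ravel(),
                        minlength=5,
                    )[:4]
                    counts[c] += np.tile(bp + bm, (4, 1)) / 4.0
                    continue
                cp = np.bincount(
                    data.D[:, u - 1 : u - 1 + S].ravel(),
                    weights=fpp.ravel(),
                    minlength=17,
                )[:16]
                cm = np.bincount(
                    data.Drc[:, w - 1 - u : w - 1 - u + S].ravel(),
                    weights=fpm.ravel(),
                    minlength=17,
                )[:16]
                counts[c] += cp.reshape(4, 4) + cm.reshape(4, 4)

    # ---- monomers ----
    new_monomers = []
    for k in range(p):
        w = model.monomers[k].length
        init = np.zeros(4)
        trans = np.zeros((w - 1, 4, 4))
        total = 0.0
        for rc in (False, True):
            if (k, rc) not in agg:
                continue
            Q = agg[(k, rc)]
            total += float(Q.sum())
            i0, t0 = _window_adm_counts(data, Q, w, rc_frame=rc)
            init += i0
            trans += t0
        if total <= 1e-12:
            warnings.warn(
                f"monomer {k} received no posterior mass; re-initialized uniform",
                RuntimeWarning,
                stacklevel=2,
            )
            new_monomers.append(
                ADM(np.full(4, 0.25), np.full((w - 1, 4, 4), 0.25),
                    name=model.monomers[k].name)
            )
            continue
        if config.order == 0:
            cols = _collapse_order0(init, trans) + config.pseudocount
            cols /= cols.sum(axis=1, keepdims=True)
            from .adm import PPM

            new_monomers.append(PPM(cols).to_adm(name=model.monomers[k].name))
        else:
            new_monomers.append(
                adm_from_counts(init, trans, config.pseudocount,
                                name=model.monomers[k].name)
            )

    # ---- bridging components ----
    new_psi = {}
    for spec, counts in psi_counts.items():
        c = counts + config.pseudocount
        if config.order == 0:
            cols = c.sum(axis=1)  # (width, 4)
            cols /= cols.sum(axis=1, keepdims=True)
            new_psi[spec] = np.repeat(cols[:, None, :], 4, axis=1)
        else:
            new_psi[spec] = c / c.sum(axis=2, keepdims=True)

    # ---- background ----
    resid = np.clip(1.0 - np.cumsum(cover[:, :-1], axis=1), 0.0, 1.0) * data.core
    if config.estimate_background and model.background.order == 0:
        bcounts = np.bincount(
            data.enc.ravel().astype(np.intp), weights=resid.ravel(), minlength=5
        )[:4]
        bcounts += config.pseudocount
        new_bg = BackgroundModel(bcounts / bcounts.sum())
    else:
        new_bg = model.background.copy()

    # ---- weights ----
    lam_bg_new = float(post.bg_mass.mean())
    total = lam_bg_new + sum(lam_new.values())
    scale = 1.0 / total if total > 0 else 1.0
    lam_mono = np.array([lam_new[("mono", k)] for k in range(p)]) * scale
    lam_dimer = {
        s: v * scale for s, v in lam_new.items() if isinstance(s, DimerSpec)
    }

    return MixtureModel(
        background=new_bg,
        monomers=new_monomers,
        pairs=dict(model.pairs),
        delta=model.delta,
        psi=new_psi,
        lam_bg=lam_bg_new * scale,
        lam_mono=lam_mono,
        lam_dimer=lam_dimer,
        pruned=set(model.pruned),
    )


# ---------------------------------------------------------------------------
# pruning & driver
# ---------------------------------------------------------------------------

def prune_weak_dimers(model: MixtureModel, threshold: float) -> MixtureModel:
    """Permanently remove dimer cells with mixing weight below threshold.

    The removed weight is reassigned to the background; monomers are
    never pruned.  Removed cells appear as empty entries in COB tables.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = model.copy()
    for spec in list(out.lam_dimer):
        if out.lam_dimer[spec] < threshold:
            out.lam_bg += out.lam_dimer.pop(spec)
            out.psi.pop(spec, None)
            out.pruned.add(spec)
    return out


@dataclass
class EMResult:
    """Final model plus the per-iteration trace of the EM search."""

    model: MixtureModel
    n_iter: int
    converged: bool
    ll_trace: list
    dist_trace: list
    initial_model: MixtureModel | None = None


def run_em(reads, seeds, config: TrainingConfig | None = None) -> EMResult:
    """Learn a monomer/dimer ADM mixture from reads and IUPAC seeds.

    Monomer chains are initialized from the seeds, bridging components
    at the expected (zero-deviation) slices, and the mixing weight split
    as half background, half uniform over the live components.  Each
    iteration runs E-step, Hamming restriction, M-step and weak-dimer
    pruning, until the weighted-maximum-norm change between consecutive
    models falls below ``epsilon`` or ``maxiter`` is reached.
    """
    config = config or TrainingConfig()
    data = as_read_data(reads, config)
    monomers = [
        seed_to_adm(s, config.match_weight, name=f"monomer_{k}")
        for k, s in enumerate(seeds)
    ]
    for m in monomers:
        if m.length > data.L:
            raise ValueError(
                f"seed of length {m.length} exceeds read length {data.L}"
            )
    pairs = config.spacing or [tuple(pr) for pr in config.pairs]
    model = MixtureModel.initialize(
        monomers,
        pairs=pairs,
        delta=config.delta,
        background=config.background or BackgroundModel(),
        lam_bg=config.lam_bg_init,
        include_th_homodimer=config.include_th_homodimer,
    )
    model0 = model.copy()
    ll_trace, dist_trace = [], []
    converged = False
    it = 0
    for it in range(1, config.maxiter + 1):
        post = e_step(model, data, config)
        ll_trace.append(post.ll)
        fpost = hamming_filter(post, config.rho)
        if (
            fpost is not post
            and model.total_signal() > 0
            and sum(fpost.component_mass(k) for k in fpost.resp) <= 0
        ):
            raise RuntimeError(
                "no placement survived the Hamming restriction; consider a "
                "larger rho or different seeds"
            )
        if config.filter_scope == "all":
            new_model = m_step(fpost, config)
        else:
            new_model = m_step(post, config, filtered=fpost)
        if config.pruning and it >= config.prune_start:
            new_model = prune_weak_dimers(new_model, config.prune_threshold)
        dist = model_distance(new_model, model)
        dist_trace.append(dist)
        model = new_model
        if dist < config.epsilon:
            converged = True
            break
    return EMResult(
        model=model,
        n_iter=it,
        converged=converged,
        ll_trace=ll_trace,
        dist_trace=dist_trace,
        initial_model=model0,
    )
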