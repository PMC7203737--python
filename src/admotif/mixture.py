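"""The full motif mixture: background, monomer ADMs, dimers and weights.

A mixture model is the triple (theta, psi, lambda): monomer chains plus
the background, bridging components for every close dimer, and mixing
weights over every monomer, every live dimer cell and the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adm import ADM, BackgroundModel, marginals
from .dimer import (
    DimerADM,
    DimerSpec,
    build_dimer,
    bridging_window,
    default_spacing_interval,
    expected_bridging,
    orient_pair,
    pair_orientations,
)

_ATOL = 1e-9

#: component key for a monomer: ("mono", k); dimers use their DimerSpec.
MonoKey = tuple


@dataclass
class MixtureModel:
    """Probabilistic mixture of monomeric and dimeric motif chains.

    ``pairs`` maps each learned monomer pair (k1, k2) to its spacing
    interval (dmin, dmax).  Dimers with spacing >= ``delta`` are pure
    products of their monomers; closer dimers carry a bridging component
    in ``psi`` (conditional blocks of shape (|d|+2, 4, 4)).
    """

    background: BackgroundModel
    monomers: list[ADM]
    pairs: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    delta: int = 4
    psi: dict[DimerSpec, np.ndarray] = field(default_factory=dict)
    lam_bg: float = 1.0
    lam_mono: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lam_dimer: dict[DimerSpec, float] = field(default_factory=dict)
    pruned: set[DimerSpec] = field(default_factory=set)

    def __post_init__(self):
        self.lam_mono = np.asarray(self.lam_mono, dtype=float)
        if self.lam_mono.size == 0:
            self.lam_mono = np.zeros(len(self.monomers))
        self.validate()

    # ------------------------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.monomers)

    def validate(self) -> None:
        if self.lam_mono.shape != (self.p,):
            raise ValueError("lam_mono must have one weight per monomer")
        lams = [self.lam_bg, *self.lam_mono, *self.lam_dimer.values()]
        if any(l < -_ATOL for l in lams):
            raise ValueError("mixing weights must be nonnegative")
        total = float(sum(lams))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mixing weights sum to {total!r}, not 1")
        for spec in self.lam_dimer:
            if spec.pair not in self.pairs:
                raise ValueError(f"dimer {spec.label()} references unknown pair")
            if spec.d < self.delta and spec not in self.psi:
                raise ValueError(
                    f"dimer {spec.label()} with d < delta={self.delta} lacks psi"
                )

    def total_signal(self) -> float:
        return float(self.lam_mono.sum() + sum(self.lam_dimer.values()))

    def dimer_specs(self) -> list[DimerSpec]:
        return sorted(self.lam_dimer)

    def component_keys(self) -> list:
        """Monomers first, then dimer specs in sorted order."""
        return [("mono", k) for k in range(self.p)] + self.dimer_specs()

    def component_lambda(self, key) -> float:
        if isinstance(key, DimerSpec):
            return float(self.lam_dimer[key])
        return float(self.lam_mono[key[1]])

    def dimer_adm(self, spec: DimerSpec) -> DimerADM:
        return build_dimer(
            self.monomers[spec.k1],
            self.monomers[spec.k2],
            spec,
            self.psi.get(spec),
            self.delta,
            self.background,
        )

    def component_adm(self, key) -> ADM:
        if isinstance(key, DimerSpec):
            return self.dimer_adm(key).adm
        return self.monomers[key[1]]

    def deviation(self, spec: DimerSpec) -> np.ndarray:
        """kappa for a close dimer: psi minus the expected bridging slice."""
        if spec not in self.psi:
            raise ValueError(f"dimer {spec.label()} has no bridging component")
        exp = expected_bridging(
            self.monomers[spec.k1], self.monomers[spec.k2], spec.o, spec.d,
            self.background,
        )
        return self.psi[spec] - exp

    def copy(self) -> "MixtureModel":
        return MixtureModel(
            background=self.background.copy(),
            monomers=[m.copy() for m in self.monomers],
            pairs=dict(self.pairs),
            delta=self.delta,
            psi={s: a.copy() for s, a in self.psi.items()},
            lam_bg=self.lam_bg,
            lam_mono=self.lam_mono.copy(),
            lam_dimer=dict(self.lam_dimer),
            pruned=set(self.pruned),
        )

    # ------------------------------------------------------------------
    @classmethod
    def initialize(
        cls,
        monomers: list[ADM],
        pairs: dict[tuple[int, int], tuple[int, int]] | list | None = None,
        delta: int = 4,
        background: BackgroundModel | None = None,
        lam_bg: float = 0.5,
        include_th_homodimer: bool = False,
    ) -> "MixtureModel":
        """Starting mixture: all grid dimers live, psi at the expected
        slices (zero deviation), remaining weight uniform over components."""
        background = background or BackgroundModel()
        if pairs is None:
            pairs = {}
        if isinstance(pairs, (list, tuple, set)):
            pairs = {
                tuple(p): default_spacing_interval(
                    monomers[p[0]].length, monomers[p[1]].length
                )
                for p in pairs
            }
        specs = []
        for (k1, k2), (dmin, dmax) in pairs.items():
            lmin = min(monomers[k1].length, monomers[k2].length)
            if dmin <= -lmin:
                raise ValueError(
                    f"dmin={dmin} allows overlaps as long as a monomer (pair {k1},{k2})"
                )
            for o in pair_orientations(k1, k2, include_th_homodimer):
                for d in range(dmin, dmax + 1):
                    specs.append(DimerSpec(k1, k2, o, d))
        n_comp = len(monomers) + len(specs)
        lam_each = (1.0 - lam_bg) / n_comp if n_comp else 0.0
        psi = {}
        for s in specs:
            if s.d < delta:
                psi[s] = expected_bridging(
                    monomers[s.k1], monomers[s.k2], s.o, s.d, background
                )
        return cls(
            background=background,
            monomers=[m.copy() for m in monomers],
            pairs=dict(pairs),
            delta=delta,
            psi=psi,
            lam_bg=lam_bg if n_comp else 1.0,
            lam_mono=np.full(len(monomers), lam_each),
            lam_dimer={s: lam_each for s in specs},
        )


# ---------------------------------------------------------------------------
# weighted maximum norm between two mixtures
# ---------------------------------------------------------------------------

def _check_structure(m1: MixtureModel, m2: MixtureModel) -> None:
    problems = []
    if m1.p != m2.p:
        problems.append(f"monomer counts {m1.p} vs {m2.p}")
    else:
        for k in range(m1.p):
            if m1.monomers[k].length != m2.monomers[k].length:
                problems.append(
                    f"monomer {k} lengths {m1.monomers[k].length} vs "
                    f"{m2.monomers[k].length}"
                )
    if set(m1.pairs) != set(m2.pairs):
        problems.append(f"pair sets {sorted(m1.pairs)} vs {sorted(m2.pairs)}")
    if m1.delta != m2.delta:
        problems.append(f"delta {m1.delta} vs {m2.delta}")
    if problems:
        raise ValueError("mixture structures differ: " + "; ".join(problems))


def model_distance(m1: MixtureModel, m2: MixtureModel) -> float:
    """Weighted maximum norm between two mixtures of the same structure.

    Per component the distance contribution is
    ``max(|lam1 - lam2|, min(lam1, lam2) * max |matrix1 - matrix2|)``:
    weight differences count at face value while matrix differences are
    weighted by the strength of the weaker of the two components.  The
    mixing parameters range over monomers and dimers only (the
    background weight is the derived quantity ``1 - sum(lam)``, so it
    carries no term of its own); the background chain itself is part of
    the model and its matrix difference is weighted like any other.  A
    dimer cell live in only one model enters with the other weight as 0
    (so only its weight difference counts).  The result is 0 iff the
    parametrizations are identical.
    """
    _check_structure(m1, m2)
    bgdiff = float(np.max(np.abs(m1.background.matrix() - m2.background.matrix())))
    d = min(m1.lam_bg, m2.lam_bg) * bgdiff
    for k in range(m1.p):
        l1, l2 = m1.lam_mono[k], m2.lam_mono[k]
        mdiff = float(
            np.max(np.abs(m1.monomers[k].matrix16() - m2.monomers[k].matrix16()))
        )
        d = max(d, abs(l1 - l2), min(l1, l2) * mdiff)
    for spec in set(m1.lam_dimer) | set(m2.lam_dimer):
        l1 = m1.lam_dimer.get(spec, 0.0)
        l2 = m2.lam_dimer.get(spec, 0.0)
        d = max(d, abs(l1 - l2))
        if spec in m1.psi and spec in m2.psi:
            mdiff = float(np.max(np.abs(m1.psi[spec] - m2.psi[spec])))
            d = max(d, min(l1, l2) * mdiff)
    return float(d)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def select_submodel(model: MixtureModel, fraction: float = 0.85) -> MixtureModel:
    """Strongest-components submodel (the "85% rule").

    Components are added in decreasing order of their mixing weight
    (ties: monomers first, then lexicographic dimer spec) until the
    selected fraction of the total non-background signal reaches
    ``fraction``.  Weights of selected components are preserved;
    removed component mass is reassigned to the background so the
    result remains a proper mixture, and removed dimers are recorded as
    pruned.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    total = model.total_signal()
    if total <= 0:
        return model.copy()

    def sort_key(key):
        is_dimer = isinstance(key, DimerSpec)
        return (-model.component_lambda(key), is_dimer, key if is_dimer else key[1])

    order = sorted(model.component_keys(), key=sort_key)
    selected, acc = [], 0.0
    for key in order:
        selected.append(key)
        acc += model.component_lambda(key)
        if acc / total >= fraction - _ATOL:
            break
    sel = set(selected)
    out = model.copy()
    removed = 0.0
    for k in range(out.p):
        if ("mono", k) not in sel:
            removed += out.lam_mono[k]
            out.lam_mono[k] = 0.0
    for spec in list(out.lam_dimer):
        if spec not in sel:
            removed += out.lam_dimer.pop(spec)
            out.psi.pop(spec, None)
            out.pruned.add(spec)
    out.lam_bg += removed
    out.validate()
    return out


def column_shuffled_decoy(model: MixtureModel, rng: np.random.Generator) -> MixtureModel:
    """Decoy mixture with the columns of every monomer ADM permuted.

    Used as a mismatched reference in evaluation: it has the same
    composition (weights, dimer grid, column marginal mass) but the
    positional structure of every motif is destroyed.  Bridging
    components are reset to the expected slices of the shuffled
    monomers.
    """
    shuffled = []
    for m in model.monomers:
        L = m.length
        perm = rng.permutation(L)
        while L > 1 and np.array_equal(perm, np.arange(L)):
            perm = rng.permutation(L)
        marg = marginals(m)
        initial = marg[perm[0]]
        blocks = []
        for h in perm[1:]:
            blocks.append(np.tile(m.initial, (4, 1)) if h == 0 else m.trans[h - 1])
        trans = np.stack(blocks) if blocks else np.empty((0, 4, 4))
        shuffled.append(ADM(initial, trans, name=(m.name or "m") + "_shuf"))
    psi = {}
    for spec in model.psi:
        psi[spec] = expected_bridging(
            shuffled[spec.k1], shuffled[spec.k2], spec.o, spec.d, model.background
        )
    return MixtureModel(
        background=model.background.copy(),
        monomers=shuffled,
        pairs=dict(model.pairs),
        delta=model.delta,
        psi=psi,
        lam_bg=model.lam_bg,
        lam_mono=model.lam_mono.copy(),
        lam_dimer=dict(model.lam_dimer),
        pruned=set(model.pruned),
    )
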