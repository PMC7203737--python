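"""Dimeric motif models composed of two monomer ADMs.

A dimer is parametrized by the two monomer indices, a relative
orientation ``o`` in {HT, HH, TT, TH} (realized by reverse-complementing
one or both monomers) and a signed spacing ``d``: the distance from the
right end of the first (oriented) monomer to the left end of the second.
Negative ``d`` means the monomers overlap by ``|d|`` bases.

For spacings at or above the independence threshold ``delta`` the dimer
distribution is the "product" of the two monomer chains with background
in the gap (the *expected* model).  Below ``delta`` the ``|d| + 2``
middle columns (the gap or overlap plus one flanking column on each
side) are replaced by a learned *bridging* component ``psi``; the
difference ``kappa = psi - expected middle`` is the explicit signature
of binding co-operativity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adm import ADM, BackgroundModel, marginals, reverse_complement

ORIENTATIONS = ("HT", "HH", "TT", "TH")
#: For homodimers TH duplicates HT by strand symmetry and is dropped.
HOMODIMER_ORIENTATIONS = ("HT", "HH", "TT")

#: orientation -> (reverse-complement first monomer?, second monomer?)
ORIENTATION_FLAGS = {
    "HT": (False, False),
    "TT": (True, False),
    "TH": (True, True),
    "HH": (False, True),
}


@dataclass(frozen=True, order=True)
class DimerSpec:
    """One dimer cell: monomer pair, orientation and signed spacing."""

    k1: int
    k2: int
    o: str
    d: int

    def __post_init__(self):
        if self.o not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.o!r}")
        if self.k1 == self.k2 and self.o == "TH":
            raise ValueError("homodimers use orientations HT, HH, TT only")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.k1, self.k2)

    def label(self) -> str:
        return f"{self.k1},{self.k2},{self.o},{self.d}"


def pair_orientations(k1: int, k2: int, include_th: bool = False):
    """Orientations searched for a pair; homodimers drop TH unless forced."""
    if k1 == k2 and not include_th:
        return HOMODIMER_ORIENTATIONS
    return ORIENTATIONS


def default_spacing_interval(l1: int, l2: int) -> tuple[int, int]:
    """Default spacing grid [-floor(min(l1,l2)/2), 10]."""
    return (-(min(l1, l2) // 2), 10)


def orient_pair(theta1: ADM, theta2: ADM, o: str) -> tuple[ADM, ADM]:
    """The two monomer chains as they appear left-to-right in the dimer."""
    rc1, rc2 = ORIENTATION_FLAGS[o]
    a = reverse_complement(theta1) if rc1 else theta1
    b = reverse_complement(theta2) if rc2 else theta2
    return a, b


def bridging_window(l1: int, d: int) -> tuple[int, int]:
    """(start column, width) of the bridging window inside the dimer.

    ``l1`` is the length of the first *oriented* monomer.  The window is
    the gap/overlap columns plus one flanking column on each side, so
    its width is ``|d| + 2``; it starts at column ``l1 - 1 + min(d, 0)``
    (0-based).
    """
    return l1 - 1 + min(d, 0), abs(d) + 2


def slice_blocks(adm: ADM, start: int, width: int) -> np.ndarray:
    """Conditional blocks for columns start..start+width-1 of ``adm``.

    Block ``c`` is the 4x4 conditional entering column ``start + c``;
    block 0 at ``start == 0`` is the initial distribution replicated
    across predecessor rows.
    """
    if start < 0 or start + width > adm.length:
        raise ValueError(
            f"window [{start}, {start + width}) outside model of length {adm.length}"
        )
    out = np.empty((width, 4, 4))
    for c in range(width):
        j = start + c
        out[c] = np.tile(adm.initial, (4, 1)) if j == 0 else adm.trans[j - 1]
    return out


def expected_dimer(
    theta1: ADM, theta2: ADM, o: str, d: int, bg: BackgroundModel | None = None
) -> ADM:
    """Dimer ADM expected under independence of the two monomers.

    After orienting, the first monomer's columns are followed by ``d``
    background columns and then the second monomer, whose initial
    distribution is used as the conditional entering its first column
    (the independence junction).  For ``d < 0`` the overlapped columns
    get the renormalized elementwise product of the two monomers'
    position marginals (order zero within the overlap) and the first
    post-overlap column of the second monomer re-enters with its own
    conditionals.
    """
    bg = bg or BackgroundModel()
    a, b = orient_pair(theta1, theta2, o)
    l1, l2 = a.length, b.length
    if d <= -min(l1, l2):
        raise ValueError(
            f"overlap {-d} must be shorter than both monomers ({l1}, {l2})"
        )
    total = l1 + l2 + d
    blocks = []  # conditionals entering columns 1..total-1
    if d >= 0:
        initial = a.initial.copy()
        blocks.extend(a.trans)
        gap_block = bg.matrix()
        for _ in range(d):
            blocks.append(gap_block.copy())
        blocks.append(np.tile(b.initial, (4, 1)))
        blocks.extend(b.trans)
    else:
        k = -d
        ma, mb = marginals(a), marginals(b)
        initial = a.initial.copy()
        blocks.extend(a.trans[: l1 - k - 1])
        for t in range(k):  # overlap columns l1-k .. l1-1
            prod = ma[l1 - k + t] * mb[t]
            s = prod.sum()
            if s <= 0:
                raise ValueError(
                    f"overlap column {t} has zero joint mass; monomers disagree"
                )
            blocks.append(np.tile(prod / s, (4, 1)))
        blocks.extend(b.trans[k - 1 :])
    trans = np.stack(blocks) if blocks else np.empty((0, 4, 4))
    if trans.shape[0] != total - 1:
        raise AssertionError("dimer length bookkeeping error")
    name = f"E({theta1.name or 'm1'},{theta2.name or 'm2'},{o},{d})"
    return ADM(initial, trans, name=name)


@dataclass
class DimerADM:
    """A composed dimeric ADM together with its structural spec."""

    spec: DimerSpec
    adm: ADM


def build_dimer(
    theta1: ADM,
    theta2: ADM,
    spec: DimerSpec,
    psi: np.ndarray | None,
    delta: int,
    bg: BackgroundModel | None = None,
) -> DimerADM:
    """Compose the dimer ADM for ``spec``.

    For ``d >= delta`` this is exactly the expected model and ``psi``
    must be None.  For ``d < delta`` the bridging window of the expected
    model is replaced by ``psi`` (shape ``(|d|+2, 4, 4)`` of conditional
    blocks).
    """
    exp = expected_dimer(theta1, theta2, spec.o, spec.d, bg)
    if spec.d >= delta:
        if psi is not None:
            raise ValueError(
                f"dimer {spec.label()} has spacing >= delta={delta}; no bridging "
                "component is allowed"
            )
        return DimerADM(spec, exp)
    if psi is None:
        raise ValueError(f"dimer {spec.label()} with d < delta={delta} requires psi")
    a, _ = orient_pair(theta1, theta2, spec.o)
    start, width = bridging_window(a.length, spec.d)
    psi = np.asarray(psi, dtype=float)
    if psi.shape != (width, 4, 4):
        raise ValueError(
            f"bridging component for {spec.label()} must have shape "
            f"({width}, 4, 4), got {psi.shape}"
        )
    initial = exp.initial.copy()
    trans = exp.trans.copy()
    for c in range(width):
        j = start + c
        if j == 0:
            initial = psi[0][0].copy()
        else:
            trans[j - 1] = psi[c]
    adm = ADM(initial, trans, name=f"tau({spec.label()})")
    return DimerADM(spec, adm)


def expected_bridging(
    theta1: ADM, theta2: ADM, o: str, d: int, bg: BackgroundModel | None = None
) -> np.ndarray:
    """Bridging-window slice of the expected (independent) dimer model."""
    exp = expected_dimer(theta1, theta2, o, d, bg)
    a, _ = orient_pair(theta1, theta2, o)
    start, width = bridging_window(a.length, d)
    return slice_blocks(exp, start, width)


def deviation(psi: np.ndarray, expected_mid: np.ndarray) -> np.ndarray:
    """Co-operativity deviation kappa = psi - expected bridging slice.

    Each 4-entry conditional block of the result sums to zero because
    both inputs are row-stochastic.
    """
    psi = np.asarray(psi, dtype=float)
    expected_mid = np.asarray(expected_mid, dtype=float)
    if psi.shape != expected_mid.shape:
        raise ValueError(
            f"shape mismatch: psi {psi.shape} vs expected {expected_mid.shape}"
        )
    return psi - expected_mid


# ---------------------------------------------------------------------------
# COB tables
# ---------------------------------------------------------------------------

class COBTable:
    """Co-operative binding table: mixing weights over orientation x spacing.

    Cells that were pruned during learning carry no value; display
    values are integer multiples of 0.001 (round half up).
    """

    def __init__(self, pair, dmin: int, dmax: int, values=None, pruned=None):
        self.pair = tuple(pair)
        self.dmin, self.dmax = int(dmin), int(dmax)
        self.orientations = pair_orientations(*self.pair)
        self.values: dict[tuple[str, int], float] = dict(values or {})
        self.pruned: set[tuple[str, int]] = set(pruned or ())
        for (o, d), lam in self.values.items():
            if lam < 0:
                raise ValueError(f"negative mixing weight at ({o}, {d})")

    def to_frame(self) -> pd.DataFrame:
        cols = list(range(self.dmin, self.dmax + 1))
        df = pd.DataFrame(np.nan, index=list(self.orientations), columns=cols)
        for (o, d), lam in self.values.items():
            df.loc[o, d] = lam
        return df

    def display_frame(self) -> pd.DataFrame:
        """Weights as integer multiples of 0.001 (round half up); pruned empty."""
        df = self.to_frame()
        return df.map(lambda v: "" if np.isnan(v) else str(int(np.floor(v / 0.001 + 0.5))))

    def total(self) -> float:
        return float(sum(self.values.values()))


def assemble_cob(lambdas, pair, pruned=(), dmin=None, dmax=None) -> COBTable:
    """Collect mixing weights of one monomer pair into a COB table.

    ``lambdas`` maps DimerSpec -> weight; ``pruned`` is a set of specs
    removed during learning (shown as empty cells).
    """
    specs = [s for s in lambdas if s.pair == tuple(pair)]
    pr = [s for s in pruned if s.pair == tuple(pair)]
    ds = [s.d for s in specs] + [s.d for s in pr]
    if dmin is None:
        dmin = min(ds) if ds else 0
    if dmax is None:
        dmax = max(ds) if ds else 0
    return COBTable(
        pair,
        dmin,
        dmax,
        values={(s.o, s.d): lambdas[s] for s in specs},
        pruned={(s.o, s.d) for s in pr},
    )
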