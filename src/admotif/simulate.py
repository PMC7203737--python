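"""Synthetic read generation from a motif mixture (ZOOPS process).

Each read independently draws a mixture component (background-only with
probability ``lam_0``); a motif instance is sampled from the component's
chain (dimers include their bridging columns), reverse-complemented for
a fair-coin minus strand, placed at a uniformly random admissible start
and surrounded by background bases.  The generator emulates the
enriched fixed-length read sets produced by HT-SELEX-style experiments;
it does not model enrichment cycles, PCR bias or sequencing errors.

The module also builds the reference fixtures used throughout the test
suite: a homodimer "sanity" mixture around a HOXB13-like monomer, and a
two-close-motifs mixture for probing the Hamming restriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import COMPLEMENT, decode
from .adm import ADM, BackgroundModel, sample, seed_to_adm
from .dimer import DimerSpec, default_spacing_interval, expected_bridging
from .mixture import MixtureModel

__all__ = [
    "SimulationSpec",
    "generate_reads",
    "build_sanity_model",
    "sanity_dimer_profile",
    "example_bridging_deviation",
    "hoxb13_standin",
    "load_supplementary_monomer",
    "two_motif_fixture",
]


@dataclass
class SimulationSpec:
    """Inputs of one simulation: mixture, read count, read length, rng."""

    model: MixtureModel
    n: int
    length: int
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one read")


def generate_reads(spec: SimulationSpec):
    """Simulate reads; returns (list of sequences, ground-truth table).

    The truth table has one row per read with columns ``read``,
    ``component`` ("background" or the component label), ``start``
    (0-based, -1 for background-only) and ``strand`` (+/-/.).
    """
    model, n, L = spec.model, spec.n, spec.length
    rng = np.random.default_rng(spec.seed)
    keys = model.component_keys()
    comp_adms = [model.component_adm(k) for k in keys]
    for key, adm in zip(keys, comp_adms):
        if adm.length > L:
            label = key.label() if isinstance(key, DimerSpec) else f"monomer_{key[1]}"
            raise ValueError(
                f"component {label} of length {adm.length} exceeds read length {L}"
            )
    lams = np.array([model.component_lambda(k) for k in keys] + [model.lam_bg])
    lams = lams / lams.sum()
    choice = rng.choice(len(keys) + 1, size=n, p=lams)

    bg = model.background
    if bg.order == 0:
        reads = rng.choice(4, size=(n, L), p=bg.probs).astype(np.uint8)
    else:
        reads = np.empty((n, L), dtype=np.uint8)
        pi = bg.stationary()
        reads[:, 0] = rng.choice(4, size=n, p=pi)
        cum = np.cumsum(bg.trans, axis=1)
        u = rng.random((n, L))
        for t in range(1, L):
            rows = cum[reads[:, t - 1].astype(np.intp)]
            reads[:, t] = (u[:, t, None] >= rows).sum(axis=1)

    comp_col = np.full(n, "background", dtype=object)
    start_col = np.full(n, -1)
    strand_col = np.full(n, ".", dtype=object)
    for ci, (key, adm) in enumerate(zip(keys, comp_adms)):
        idx = np.flatnonzero(choice == ci)
        if idx.size == 0:
            continue
        w = adm.length
        inst = sample(adm, idx.size, rng)
        minus = rng.random(idx.size) < 0.5
        inst[minus] = COMPLEMENT[inst[minus]][:, ::-1]
        starts = rng.integers(0, L - w + 1, size=idx.size)
        for r, j, row in zip(idx, starts, inst):
            reads[r, j : j + w] = row
        label = key.label() if isinstance(key, DimerSpec) else f"monomer_{key[1]}"
        comp_col[idx] = label
        start_col[idx] = starts
        strand_col[idx] = np.where(minus, "-", "+")

    truth = pd.DataFrame(
        {
            "read": np.arange(n),
            "component": comp_col,
            "start": start_col,
            "strand": strand_col,
        }
    )
    seqs = [decode(row) for row in reads]
    return seqs, truth


# ---------------------------------------------------------------------------
# reference fixtures
# ---------------------------------------------------------------------------

def sanity_dimer_profile() -> list[tuple[str, int, float]]:
    """Homodimer cells and weights of the reference sanity mixture
    (total signal fraction 0.30; background 0.70)."""
    return [
        ("HT", 4, 0.061),
        ("HH", 4, 0.055),
        ("HH", 2, 0.068),
        ("TT", 2, 0.034),
        ("HH", 5, 0.082),
    ]


def example_bridging_deviation(width: int, strength: float = 0.15) -> np.ndarray:
    """A hand-specified co-operativity deviation for a bridging window.

    Zero outside the interior columns; the interior conditional rows
    shift ``strength`` of probability toward one base (A in the first
    interior column, T in the last), which is safely within [0, 1] when
    added to a background-filled gap.  Rows sum to zero, as any
    deviation must.
    """
    if not 0 < strength <= 0.7:
        raise ValueError("strength must be in (0, 0.7]")
    kappa = np.zeros((width, 4, 4))
    up, down = strength, -strength / 3
    if width >= 3:
        kappa[1] = np.tile([up, down, down, down], (4, 1))
    if width >= 4:
        kappa[width - 2] = np.tile([down, down, down, up], (4, 1))
    return kappa


def build_sanity_model(
    monomer: ADM,
    dimers: list[tuple[str, int, float]] | None = None,
    deviations: dict[tuple[str, int], np.ndarray] | None = None,
    total_signal: float | None = None,
    delta: int = 4,
    spacing: tuple[int, int] | None = None,
    background: BackgroundModel | None = None,
) -> MixtureModel:
    """Homodimer mixture used by the generated-data sanity experiments.

    ``dimers`` lists (orientation, spacing, weight) cells; the dimer
    ADMs are the expected (independent) models, optionally with a
    hand-specified deviation added to the bridging window of cells with
    ``d < delta``.  ``total_signal`` rescales the listed weights to a
    chosen total signal fraction.
    """
    dimers = dimers if dimers is not None else sanity_dimer_profile()
    deviations = deviations or {}
    background = background or BackgroundModel()
    spacing = spacing or default_spacing_interval(monomer.length, monomer.length)
    weights = np.array([w for _, _, w in dimers], dtype=float)
    if total_signal is not None:
        weights = weights * (total_signal / weights.sum())
    if weights.sum() >= 1.0:
        raise ValueError("dimer weights must sum to less than 1")
    lam_dimer, psi = {}, {}
    for (o, d, _), w in zip(dimers, weights):
        spec = DimerSpec(0, 0, o, d)
        lam_dimer[spec] = float(w)
        if d < delta:
            exp = expected_bridging(monomer, monomer, o, d, background)
            kappa = deviations.get((o, d))
            if kappa is None:
                psi[spec] = exp
            else:
                kappa = np.asarray(kappa, dtype=float)
                bridged = exp + kappa
                if np.any(bridged < -1e-12) or np.any(bridged > 1 + 1e-12):
                    raise ValueError(
                        f"deviation for ({o}, {d}) pushes probabilities outside [0, 1]"
                    )
                psi[spec] = np.clip(bridged, 0.0, 1.0)
        elif deviations.get((o, d)) is not None:
            raise ValueError(
                f"cell ({o}, {d}) has spacing >= delta={delta}; it is an expected "
                "model and cannot carry a deviation"
            )
    return MixtureModel(
        background=background,
        monomers=[monomer.copy()],
        pairs={(0, 0): spacing},
        delta=delta,
        psi=psi,
        lam_bg=float(1.0 - weights.sum()),
        lam_mono=np.zeros(1),
        lam_dimer=lam_dimer,
    )


def hoxb13_standin(match_weight: float = 0.85) -> ADM:
    """Synthetic stand-in for a HOXB13-like monomer ADM (seed CYMRTAAAA).

    This is NOT a matrix estimated from experimental data: it is built
    from the IUPAC seed and then given deterministic first-order
    structure by coupling the degenerate positions (the Y at position 2
    with the M at position 3, and the M with the R at position 4), the
    kind of adjacent dependence the order-one model exists to capture.
    Use :func:`load_supplementary_monomer` to substitute a real matrix.
    """
    adm = seed_to_adm("CYMRTAAAA", match_weight, name="HOXB13_standin_synthetic")
    trans = adm.trans.copy()
    C, A, G, T = 1, 0, 2, 3
    # position 2 (Y: C/T) -> position 3 (M: A/C): C prefers A, T prefers C
    trans[1][C] = _norm([0.70, 0.22, 0.04, 0.04])
    trans[1][T] = _norm([0.25, 0.67, 0.04, 0.04])
    # position 3 (M: A/C) -> position 4 (R: A/G): A prefers G, C prefers A
    trans[2][A] = _norm([0.30, 0.05, 0.60, 0.05])
    trans[2][C] = _norm([0.62, 0.05, 0.28, 0.05])
    return ADM(adm.initial, trans, name=adm.name)


def _norm(v):
    v = np.asarray(v, dtype=float)
    return v / v.sum()


def load_supplementary_monomer(path) -> ADM:
    """Load a 16 x L monomer matrix from a text file (e.g. a published
    supplementary matrix) for use in place of the synthetic stand-in."""
    from .modelio import load_adm

    return load_adm(path)


def two_motif_fixture(
    fraction: float,
    seeds: tuple[str, str] = ("CACGTGTT", "CACGTCAT"),
    match_weight: float = 0.9,
) -> MixtureModel:
    """Mixture of two monomers with nearby consensus sequences.

    Both monomers get weight ``fraction`` (so the background weight is
    ``1 - 2 * fraction``); the default seeds are Hamming distance 2
    apart, within the "close consensus" regime where a small Hamming
    radius helps at low signal.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    m1 = seed_to_adm(seeds[0], match_weight, name="motif_a")
    m2 = seed_to_adm(seeds[1], match_weight, name="motif_b")
    return MixtureModel(
        background=BackgroundModel(),
        monomers=[m1, m2],
        pairs={},
        lam_bg=1.0 - 2 * fraction,
        lam_mono=np.array([fraction, fraction]),
    )
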