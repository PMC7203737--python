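"""Plain-text readers and writers: reads, ADM matrices, model bundles.

A model bundle is a directory of small human-readable files (one matrix
per file plus a YAML metadata sheet) so that models diff cleanly and
round-trip at serialized precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from .adm import ADM, BackgroundModel, marginals
from .alphabet import DINUC_LABELS
from .dimer import DimerSpec, assemble_cob
from .mixture import MixtureModel

_FORMAT_VERSION = 1
_VALID = set("ACGTN")


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def read_sequences(path, fmt: str | None = None) -> list[str]:
    """Load reads from FASTA or one-sequence-per-line text.

    Sequences are uppercased; characters other than A, C, G, T, N are
    rejected with the offending line number.  Trailing blank lines in
    plain files are ignored.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "fasta" if first.startswith(">") else "plain"
    reads: list[str] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            s = str(rec.seq).upper()
            bad = set(s) - _VALID
            if bad:
                raise ValueError(
                    f"record {rec.id}: invalid characters {sorted(bad)} in {path}"
                )
            reads.append(s)
    elif fmt == "plain":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip().upper()
                if not s:
                    continue
                bad = set(s) - _VALID
                if bad:
                    raise ValueError(
                        f"line {lineno}: invalid characters {sorted(bad)} in {path}"
                    )
                reads.append(s)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not reads:
        raise ValueError(f"no sequences found in {path}")
    return reads


def describe_reads(reads) -> dict:
    lengths = np.array([len(r) for r in reads])
    return {
        "n_reads": int(lengths.size),
        "min_length": int(lengths.min()),
        "max_length": int(lengths.max()),
        "mean_length": float(lengths.mean()),
    }


def write_fasta(reads, path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f">{prefix}{i}\n{r}\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def save_adm(adm: ADM, path) -> None:
    """Write the 16 x L dinucleotide layout (first column = initial)."""
    mat = adm.matrix16()
    with open(path, "w") as fh:
        fh.write(f">{adm.name or 'adm'} length={adm.length}\n")
        for r, lab in enumerate(DINUC_LABELS):
            fh.write(lab + "\t" + "\t".join(f"{v:.12g}" for v in mat[r]) + "\n")


def load_adm(path) -> ADM:
    """Read a 16 x L matrix file; rows are renormalized at parse
    precision and rejected if off by more than 1e-6."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(">"):
            raise ValueError(f"{path}: missing '>' header line")
        name = header[1:].split()[0]
        rows = {}
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows[parts[0]] = [float(v) for v in parts[1:]]
    if set(rows) != set(DINUC_LABELS):
        raise ValueError(f"{path}: expected 16 dinucleotide rows AA..TT")
    mat = np.array([rows[lab] for lab in DINUC_LABELS])
    adm = ADM.from_matrix16(_renormalize16(mat, path), name=name)
    return adm


def _renormalize16(mat: np.ndarray, path) -> np.ndarray:
    out = mat.copy()
    init = out[:4, 0]
    s = init.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"{path}: initial distribution sums to {s}, not 1")
    if abs(s - 1.0) > 1e-9:  # renormalize only when parse precision demands
        init = init / s
    out[:, 0] = np.tile(init, 4)
    for h in range(1, out.shape[1]):
        blocks = out[:, h].reshape(4, 4)
        sums = blocks.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(
                f"{path}: conditional row at column {h + 1} sums to "
                f"{sums[np.argmax(np.abs(sums - 1))]}, not 1"
            )
        bad = np.abs(sums - 1.0) > 1e-9
        blocks[bad] = blocks[bad] / sums[bad, None]
        out[:, h] = blocks.reshape(16)
    return out


def save_ppm(ppm, path, name: str = "ppm") -> None:
    """Write an order-zero matrix: 4 labeled rows (A, C, G, T) x L."""
    probs = ppm.probs if hasattr(ppm, "probs") else np.asarray(ppm, dtype=float)
    with open(path, "w") as fh:
        fh.write(f">{name} length={probs.shape[0]}\n")
        for i, lab in enumerate("ACGT"):
            fh.write(
                lab + "\t" + "\t".join(f"{v:.12g}" for v in probs[:, i]) + "\n"
            )


def load_ppm(path):
    """Read a 4 x L order-zero matrix file written by :func:`save_ppm`."""
    from .adm import PPM

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith(">"):
            raise ValueError(f"{path}: missing '>' header line")
        rows = {}
        for line in fh:
            parts = line.split()
            if parts:
                rows[parts[0]] = [float(v) for v in parts[1:]]
    if set(rows) != set("ACGT"):
        raise ValueError(f"{path}: expected 4 rows labeled A, C, G, T")
    probs = np.array([rows[b] for b in "ACGT"]).T
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(f"{path}: column sums deviate from 1")
    bad = np.abs(sums - 1.0) > 1e-9
    probs[bad] = probs[bad] / sums[bad, None]
    return PPM(probs)


def save_blocks_tsv(blocks: np.ndarray, path, header: str) -> None:
    """Serialize (width, 4, 4) conditional/deviation blocks as a
    16 x width TSV with dinucleotide row labels."""
    width = blocks.shape[0]
    with open(path, "w") as fh:
        fh.write(f"# {header} width={width}\n")
        for r, lab in enumerate(DINUC_LABELS):
            a, b = divmod(r, 4)
            fh.write(
                lab
                + "\t"
                + "\t".join(f"{blocks[c, a, b]:.12g}" for c in range(width))
                + "\n"
            )


def load_blocks_tsv(path) -> np.ndarray:
    with open(path) as fh:
        fh.readline()
        rows = {}
        for line in fh:
            parts = line.split()
            if parts:
                rows[parts[0]] = [float(v) for v in parts[1:]]
    width = len(next(iter(rows.values())))
    out = np.empty((width, 4, 4))
    for r, lab in enumerate(DINUC_LABELS):
        a, b = divmod(r, 4)
        out[:, a, b] = rows[lab]
    return out


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

def _spec_slug(spec: DimerSpec) -> str:
    d = f"m{-spec.d}" if spec.d < 0 else str(spec.d)
    return f"{spec.k1}_{spec.k2}_{spec.o}_{d}"


def save_model(model: MixtureModel, outdir) -> Path:
    """Write a model bundle directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": _FORMAT_VERSION,
        "delta": int(model.delta),
        "lam_bg": float(model.lam_bg),
        "lam_mono": [float(v) for v in model.lam_mono],
        "pairs": {
            f"{k1},{k2}": [int(a), int(b)]
            for (k1, k2), (a, b) in model.pairs.items()
        },
        "lam_dimer": {s.label(): float(v) for s, v in model.lam_dimer.items()},
        "pruned": sorted(s.label() for s in model.pruned),
        "background": {
            "order": model.background.order,
            "probs": [float(v) for v in model.background.probs],
            "trans": None
            if model.background.trans is None
            else [[float(v) for v in row] for row in model.background.trans],
        },
    }
    with open(outdir / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    for k, m in enumerate(model.monomers):
        save_adm(m, outdir / f"monomer_{k}.adm")
    for spec, psi in model.psi.items():
        save_blocks_tsv(
            psi, outdir / f"psi_{_spec_slug(spec)}.tsv", f"bridging {spec.label()}"
        )
        save_blocks_tsv(
            model.deviation(spec),
            outdir / f"deviation_{_spec_slug(spec)}.tsv",
            f"deviation {spec.label()}",
        )
    for pair in model.pairs:
        cob = assemble_cob(
            model.lam_dimer,
            pair,
            pruned=model.pruned,
            dmin=model.pairs[pair][0],
            dmax=model.pairs[pair][1],
        )
        cob.display_frame().to_csv(
            outdir / f"cob_{pair[0]}_{pair[1]}.tsv", sep="\t"
        )
    return outdir


def _parse_label(label: str) -> DimerSpec:
    k1, k2, o, d = label.split(",")
    return DimerSpec(int(k1), int(k2), o, int(d))


def load_model(path) -> MixtureModel:
    """Load a model bundle written by :func:`save_model`."""
    path = Path(path)
    meta_file = path / "metadata.yaml"
    if not meta_file.exists():
        raise FileNotFoundError(f"model bundle metadata missing: {meta_file}")
    with open(meta_file) as fh:
        meta = yaml.safe_load(fh)
    monomers = []
    k = 0
    while (path / f"monomer_{k}.adm").exists():
        monomers.append(load_adm(path / f"monomer_{k}.adm"))
        k += 1
    if len(monomers) != len(meta["lam_mono"]):
        raise ValueError(
            f"bundle {path}: {len(monomers)} monomer files but "
            f"{len(meta['lam_mono'])} monomer weights"
        )
    lam_dimer = {_parse_label(lab): v for lab, v in meta["lam_dimer"].items()}
    psi = {}
    for spec in lam_dimer:
        if spec.d < meta["delta"]:
            f = path / f"psi_{_spec_slug(spec)}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"bundle {path}: missing bridging file {f}")
            psi[spec] = load_blocks_tsv(f)
    bg = meta["background"]
    background = BackgroundModel(
        np.array(bg["probs"]),
        None if bg.get("trans") is None else np.array(bg["trans"]),
    )
    pairs = {
        tuple(int(x) for x in key.split(",")): tuple(val)
        for key, val in meta["pairs"].items()
    }
    return MixtureModel(
        background=background,
        monomers=monomers,
        pairs=pairs,
        delta=int(meta["delta"]),
        psi=psi,
        lam_bg=float(meta["lam_bg"]),
        lam_mono=np.array(meta["lam_mono"], dtype=float),
        lam_dimer=lam_dimer,
        pruned={_parse_label(lab) for lab in meta.get("pruned", [])},
    )


# ---------------------------------------------------------------------------
# logo data export
# ---------------------------------------------------------------------------

def export_logo_data(matrix, kind: str = "adm") -> dict:
    """Structured data behind a dinucleotide ("river-lake") logo.

    For an ADM: per-position circle radii (the marginal base
    probabilities) and per-junction edge weights (the joint
    dinucleotide probabilities).  For a deviation (signed blocks), the
    edge weights are split into positive and negative channels.
    JSON-serializable.
    """
    if kind == "adm":
        adm: ADM = matrix
        m = marginals(adm)
        edges = []
        for h in range(1, adm.length):
            q = m[h - 1][:, None] * adm.trans[h - 1]
            edges.append({DINUC_LABELS[a * 4 + b]: float(q[a, b])
                          for a in range(4) for b in range(4)})
        return {
            "kind": "adm",
            "length": adm.length,
            "radii": [{b: float(v) for b, v in zip("ACGT", row)} for row in m],
            "edges": edges,
        }
    if kind == "deviation":
        dev = np.asarray(matrix, dtype=float)
        pos, neg = [], []
        for c in range(dev.shape[0]):
            p = {
                DINUC_LABELS[a * 4 + b]: float(dev[c, a, b])
                for a in range(4)
                for b in range(4)
                if dev[c, a, b] > 0
            }
            n = {
                DINUC_LABELS[a * 4 + b]: float(-dev[c, a, b])
                for a in range(4)
                for b in range(4)
                if dev[c, a, b] < 0
            }
            pos.append(p)
            neg.append(n)
        return {"kind": "deviation", "width": dev.shape[0],
                "positive": pos, "negative": neg}
    raise ValueError(f"unknown kind {kind!r}")


def export_logo_json(matrix, path, kind: str = "adm") -> None:
    with open(path, "w") as fh:
        json.dump(export_logo_data(matrix, kind=kind), fh, indent=1)
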