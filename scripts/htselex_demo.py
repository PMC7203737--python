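"""Optional real-data demo: learn a dimeric motif mixture from a
user-supplied HT-SELEX read file and report the 8-mer R^2 fit.

This script is not part of the automated checks — it needs externally
downloaded reads (e.g. a published 40 bp HT-SELEX library).  Typical
invocation, mirroring the dimeric analyses of nuclear-receptor-style
factors with two half-site seeds and constant flanks:

    python scripts/htselex_demo.py --reads hnf4a.fastq-derived.txt \
        --seeds RGKYCA,AGTCCA --pairs 0:0,0:1,1:1 \
        --flank-left GACTGG --flank-right TCC --outdir out_hnf4a
"""

import argparse
from pathlib import Path

from admotif import TrainingConfig, evaluate_model, run_em, select_submodel
from admotif.modelio import describe_reads, read_sequences, save_model


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--reads", required=True)
    ap.add_argument("--seeds", required=True, help="comma-separated IUPAC seeds")
    ap.add_argument("--pairs", default="", help="e.g. '0:0,0:1,1:1'")
    ap.add_argument("--rho", type=int, default=3)
    ap.add_argument("--maxiter", type=int, default=150)
    ap.add_argument("--flank-left", default="")
    ap.add_argument("--flank-right", default="")
    ap.add_argument("--k", type=int, default=8)
    ap.add_argument("--outdir", required=True)
    args = ap.parse_args()

    reads = read_sequences(args.reads)
    print("reads:", describe_reads(reads))
    seeds = [s for s in args.seeds.split(",") if s]
    pairs = [tuple(int(x) for x in p.split(":")) for p in args.pairs.split(",") if p]
    cfg = TrainingConfig(
        pairs=pairs,
        rho=args.rho,
        maxiter=args.maxiter,
        flank_left=args.flank_left,
        flank_right=args.flank_right,
    )
    res = run_em(reads, seeds, cfg)
    print(f"EM: {res.n_iter} iterations, converged={res.converged}")

    out = Path(args.outdir)
    save_model(res.model, out / "model")
    sub = select_submodel(res.model, 0.85)
    save_model(sub, out / "submodel")

    table, r2 = evaluate_model(sub, reads, k=args.k)
    table.to_csv(out / f"kmer_{args.k}_fit.tsv", sep="\t", index_label="kmer")
    print(f"submodel R^2 over {len(table)} canonical {args.k}-mers: {r2:.3f}")


if __name__ == "__main__":
    main()
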