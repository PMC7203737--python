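"""Helper: suggest an EM seed as the most frequent canonical l-mer.

    python scripts/suggest_seed.py --reads reads.fa --length 8
"""

import argparse

from admotif import most_frequent_kmer
from admotif.modelio import read_sequences


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--reads", required=True)
    ap.add_argument("--length", type=int, default=8,
                    help="anticipated motif length")
    args = ap.parse_args()
    reads = read_sequences(args.reads)
    print(most_frequent_kmer(reads, args.length))


if __name__ == "__main__":
    main()
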