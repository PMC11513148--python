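#!/usr/bin/env python
"""Call differentially abundant proteins in the two SILAC contrasts and
overlap them: volcano tables (mean −log2 H/L, background-test p, BH-adjusted
p, significance at −log2 ≥ 0.3 & p ≤ 0.05) plus the shared-membrane-protein
overlap classification.  Run 01_simulate.py first.
"""

from _common import make_config, parse_args

from qcprof import pipeline as pl


def main() -> None:
    args = parse_args(__doc__)
    report = pl.run(make_config(args.seed, args.out, ["silac"]))
    s = report["stages"]["silac"]
    print(f"contrast A: {s['n_significant_A']} significant proteins")
    print(f"contrast B: {s['n_significant_B']} significant proteins")
    print(f"overlap classes: {s['overlap_classes']}")
    print(f"tables: {args.out}/volcano_A.tsv, volcano_B.tsv, overlap.tsv")


if __name__ == "__main__":
    main()
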