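#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume:

two SILAC peptide-ratio contrasts with planted effect sets sharing five
proteins, a short-TMD and a long-TMD membrane proteome (FASTA + topology in
both dialects), a yeast-like lipidome with planted C-26/C-28 asymmetric
species enrichment, and two bilayer trajectories (5 Å and 2.5 Å dimples).
"""

from _common import make_config, parse_args

from qcprof import pipeline as pl


def main() -> None:
    args = parse_args(__doc__)
    report = pl.run(make_config(args.seed, args.out, ["simulate"]))
    s = report["stages"]["simulate"]
    print(f"wrote synthetic inputs to {args.out}/")
    print(
        f"planted SILAC effects: {s['planted_A']} in contrast A, "
        f"{s['planted_B']} in contrast B, {s['planted_overlap']} shared"
    )


if __name__ == "__main__":
    main()
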