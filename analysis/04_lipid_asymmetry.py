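#!/usr/bin/env python
"""Test per-species mol%/class differences between WT and mutant lipidomes
(unpaired pooled-variance t per species, two-stage step-up FDR at Q = 1%
within each lipid class) and classify the discoveries by acyl-chain
asymmetry.  Run 01_simulate.py first.
"""

from _common import make_config, parse_args

from qcprof import pipeline as pl


def main() -> None:
    args = parse_args(__doc__)
    report = pl.run(make_config(args.seed, args.out, ["lipids"]))
    s = report["stages"]["lipids"]
    print(
        f"{s['n_discoveries']} of {s['n_species']} species discovered at Q=1%; "
        f"{s['n_asymmetric_discoveries']} are asymmetric (Δchain ≥ 6 C)"
    )
    print(f"table: {args.out}/lipid_comparison.tsv")


if __name__ == "__main__":
    main()
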