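#!/usr/bin/env python
"""Profile transmembrane-domain signatures of the two synthetic protein
sets: per-TMD tables (oriented cytosolic → luminal), length medians and
quartiles, fractions of short TMDs (≤ 16 / ≤ 18 residues) and of high
TMD-count proteins (> 10).  Run 01_simulate.py first.
"""

from _common import make_config, parse_args

from qcprof import pipeline as pl


def main() -> None:
    args = parse_args(__doc__)
    report = pl.run(make_config(args.seed, args.out, ["tmd"]))
    s = report["stages"]["tmd"]
    for name in ("short", "long"):
        sig = s[name]
        print(
            f"{name}-TMD set: {sig['n_tmds']} TMDs in {sig['n_proteins']} proteins, "
            f"median {sig['median_length']:.0f} aa, "
            f"frac ≤18 aa {sig['frac_tmds_le_18']:.2f}, "
            f"frac shortest ≤16 {sig['frac_proteins_shortest_le_16']:.2f}"
        )
    print(f"median length delta (short − long): "
          f"{s['comparison']['delta_median_length']:.1f} aa")


if __name__ == "__main__":
    main()
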