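#!/usr/bin/env python
"""Map bilayer thickness for the two trajectories (2 Å grid, trailing 40%
of frames), summarize the local thinning (bulk minus map minimum), and
difference the two conditions.  Run 01_simulate.py first.
"""

from _common import make_config, parse_args

from qcprof import pipeline as pl


def main() -> None:
    args = parse_args(__doc__)
    report = pl.run(make_config(args.seed, args.out, ["thickness"]))
    s = report["stages"]["thickness"]
    for name in ("wt", "mut"):
        print(
            f"{name}: bulk {s[name]['bulk_thickness']:.2f} Å, "
            f"min {s[name]['min_thickness']:.2f} Å, "
            f"max thinning {s[name]['max_thinning']:.2f} Å"
        )
    print(f"Δ max-thinning (wt − mut): {s['delta_max_thinning']:.2f} Å")
    print(f"maps: {args.out}/thickness_map_wt.tsv, thickness_map_mut.tsv")


if __name__ == "__main__":
    main()
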