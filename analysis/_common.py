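"""Shared run configuration for the numbered analysis scripts."""

import argparse

from qcprof import pipeline as pl

DEFAULT_OUT = "results/analysis"


def make_config(seed: int, out_dir: str, stages: list[str]) -> pl.RunConfig:
    cfg = pl.validate_config(f"seed: {seed}\nout_dir: '{out_dir}'")
    return cfg.model_copy(update={"stages": stages})


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=DEFAULT_OUT)
    return ap.parse_args()
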