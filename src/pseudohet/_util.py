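"""Shared helpers: seeded RNG streams and TSV table I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd

MAX_SEED = 2**31 - 1


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG stream derived from a single master seed.

    Every source of randomness in the package draws from one of these, so a
    pipeline run and an isolated module test that use the same master seed
    and stream name see identical draws.
    """
    ss = np.random.SeedSequence([int(seed) % MAX_SEED, _name_key(name)])
    return np.random.default_rng(ss)


def _name_key(name: str) -> int:
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % MAX_SEED
    return h


def write_table(df: pd.DataFrame, path) -> None:
    """TSV with a single commented header line (``#col1<TAB>col2...``)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        if len(df):
            df.to_csv(fh, sep="\t", header=False, index=False,
                      float_format="%.10g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing commented header line")
        cols = header[1:].split("\t")
        df = pd.read_csv(fh, sep="\t", names=cols)
    return df
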