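"""Trait and flight-style table I/O and developmental-class coding.

Trait tables are headered delimited text (comma by default) with the fixed
columns ``species, humerus_mm, radius_mm, carpometacarpus_mm, femur_mm,
tibiotarsus_mm, tarsometatarsus_mm, mass_g, dev_class``.  Developmental
classes follow the graded system: altricial grades 1-2 collapse to the
binary label ``altricial``, precocial grades 1-3 to ``precocial``; the
intermediate semialtricial/semiprecocial grades are retained for
compositional colouring only and are ``excluded`` from the binary split.
"""

from __future__ import annotations

import pandas as pd

from .simulate import BONES

__all__ = [
    "DEV_CLASSES",
    "dev_binary",
    "read_trait_table",
    "write_trait_table",
    "read_flight_table",
    "write_flight_table",
    "TRAIT_COLUMNS",
]

DEV_CLASSES = (
    "altricial1",
    "altricial2",
    "semialtricial",
    "semiprecocial",
    "precocial1",
    "precocial2",
    "precocial3",
)

TRAIT_COLUMNS = ("species", *BONES, "mass_g", "dev_class")

_BINARY = {
    "altricial1": "altricial",
    "altricial2": "altricial",
    "precocial1": "precocial",
    "precocial2": "precocial",
    "precocial3": "precocial",
    "semialtricial": "excluded",
    "semiprecocial": "excluded",
}


def dev_binary(dev_class: str) -> str:
    """Binary developmental strategy for a graded class label."""
    try:
        return _BINARY[dev_class]
    except KeyError:
        raise ValueError(
            f"unknown developmental class {dev_class!r}; expected one of {DEV_CLASSES}"
        ) from None


def read_trait_table(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a species trait table."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if df["species"].duplicated().any():
        dups = sorted(df.loc[df["species"].duplicated(), "species"])
        raise ValueError(f"duplicate species in trait table: {dups}")
    numeric = list(BONES) + ["mass_g"]
    if (df[numeric] <= 0).any().any():
        raise ValueError("bone lengths and masses must be strictly positive")
    df["dev_class"].map(dev_binary)  # raises on unknown labels
    return df.set_index("species", drop=False)


def write_trait_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.loc[:, list(TRAIT_COLUMNS)].to_csv(path, sep=sep, index=False)


def read_flight_table(path, sep: str = ",") -> pd.DataFrame:
    """Read a species x flight-style binary presence/absence table."""
    df = pd.read_csv(path, sep=sep).set_index("species")
    bad = ~df.isin([0, 1]).all()
    if bad.any():
        raise ValueError(f"non-binary flight-style columns: {list(df.columns[bad])}")
    return df


def write_flight_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index_label="species")
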