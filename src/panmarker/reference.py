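"""Loaders for the bundled reference data of the 22-target assay.

The package ships the published assay tables it models: the primer pairs
per species/subspecies, the four standard-curve fits most relevant to
probiotic products, the taxon vocabulary, and the label-claim survey of
33 commercial products.  These are inputs for the quantification and
monitoring layers and for cross-checking the design rules.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .qpcr import StandardCurve, Taxonomy, efficiency_from_slope

__all__ = [
    "data_path",
    "load_taxonomy",
    "load_standard_curves",
    "load_monitoring",
    "load_primer_pairs",
]


def data_path(name: str) -> Path:
    return Path(str(resources.files("panmarker").joinpath("data", name)))


def load_taxonomy() -> Taxonomy:
    df = pd.read_csv(data_path("taxonomy.tsv"), sep="\t", comment="#")
    species: dict[str, list[str]] = {}
    nonspecific: list[str] = []
    for _, row in df.iterrows():
        if row["kind"] == "species":
            species.setdefault(row["label"], [])
        elif row["kind"] == "subspecies":
            species.setdefault(row["parent"], []).append(row["label"])
        else:
            nonspecific.append(row["label"])
    return Taxonomy(species=species, nonspecific=nonspecific)


def load_standard_curves() -> dict[str, StandardCurve]:
    df = pd.read_csv(data_path("standard_curves.tsv"), sep="\t", comment="#")
    curves = {}
    for _, row in df.iterrows():
        curves[row["taxon"]] = StandardCurve(
            taxon=row["taxon"],
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r_squared=float(row["r_squared"]),
            efficiency_percent=efficiency_from_slope(float(row["slope"])),
        )
    return curves


def load_monitoring() -> pd.DataFrame:
    """Product survey with ``labeled`` / ``detected`` as lists of taxa."""
    df = pd.read_csv(data_path("monitoring.tsv"), sep="\t", comment="#")
    for col in ("labeled", "detected"):
        df[col] = df[col].apply(lambda s: [t.strip() for t in s.split("|")])
    return df


def load_primer_pairs():
    from .io import read_primer_table

    return read_primer_table(data_path("bifidobacterium_primers.tsv"))
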