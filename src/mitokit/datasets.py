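"""Loaders for the small published reference tables shipped with the package.

These are the printed gene annotation and base-composition tables for the
seven *Typhlomys* mitogenomes; they let the geometry and skew machinery be
exercised against published numbers without downloading any sequence data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .model import AnnotatedMitogenome, GeneFeature

__all__ = [
    "huangshanensis_annotation",
    "huangshanensis_skeleton",
    "typhlomys_genome_compositions",
    "huangshanensis_region_compositions",
]

_DATA = resources.files("mitokit") / "data"


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def huangshanensis_annotation() -> tuple[list[GeneFeature], int]:
    """The 37-gene annotation of the T. huangshanensis mitogenome.

    Returns the ordered feature list and the genome length (16,497 bp).
    The sequence itself is not bundled; geometry-only analyses do not
    need it.
    """
    genome_length = None
    features: list[GeneFeature] = []
    with open(_data_path("huangshanensis_annotation.tsv")) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# genome_length:"):
                genome_length = int(line.split(":")[1])
                continue
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, start, end, strand, cls = line.split("\t")
            features.append(GeneFeature(name=name, feature_class=cls,
                                        start=int(start), end=int(end),
                                        strand=strand))
    assert genome_length is not None
    return features, genome_length


def huangshanensis_skeleton() -> AnnotatedMitogenome:
    """The published annotation attached to an undetermined (all-N) sequence.

    Suitable for geometry computations; composition requires real bases.
    """
    features, n = huangshanensis_annotation()
    return AnnotatedMitogenome(identifier="PQ825598", sequence="N" * n,
                               circular=True, features=features)


def typhlomys_genome_compositions() -> pd.DataFrame:
    """Whole-genome printed compositions for the seven Typhlomys taxa."""
    return pd.read_csv(_data_path("typhlomys_genome_compositions.tsv"),
                       sep="\t", comment="#")


def huangshanensis_region_compositions() -> pd.DataFrame:
    """Printed per-region compositions of the T. huangshanensis mitogenome."""
    return pd.read_csv(_data_path("huangshanensis_region_compositions.tsv"),
                       sep="\t", comment="#")
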