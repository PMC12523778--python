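"""Codon extraction, start/stop tabulation, and relative synonymous codon
usage (RSCU) under the vertebrate mitochondrial genetic code.

RSCU for a codon c in a synonymous family of size n_i with counts x is

    RSCU(c) = n_i * x_c / sum over the family of x

i.e. the observed count divided by the count expected if every synonymous
codon were used equally; values sum to the family size, and average 1,
within each family.  Under NCBI translation table 2 (vertebrate
mitochondrion) TGA codes Trp, ATA codes Met, and AGA/AGG join TAA/TAG as
stops — so Ser and Leu are both 6-codon families minus the reassignments:
Leu keeps 6 codons, Ser keeps 6 (AGC/AGT plus the TCN box).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable

from .model import AnnotatedMitogenome, GeneFeature, ValidationError, feature_sequence

__all__ = [
    "GeneticCode",
    "VERTEBRATE_MITO",
    "RscuTable",
    "coding_sequence",
    "start_stop_codons",
    "codon_counts",
    "rscu",
]

_BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in product(_BASES, repeat=3)]


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    ``forward`` maps every sense codon to a one-letter amino acid;
    ``stops`` is the stop-codon set.  Built from the NCBI tables via
    Biopython; the default throughout the package is table 2.
    """

    table_id: int
    name: str
    forward: dict[str, str]
    stops: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(t.forward_table)
        stops = frozenset(t.stop_codons)
        if len(forward) + len(stops) != 64:
            raise ValidationError(f"NCBI table {table_id} is not a complete code")
        return cls(table_id=table_id, name=t.names[0], forward=forward,
                   stops=stops)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def translate(self, codon: str) -> str:
        """One-letter amino acid, '*' for stops."""
        if codon in self.stops:
            return "*"
        try:
            return self.forward[codon]
        except KeyError:
            raise ValidationError(f"not an unambiguous codon: {codon!r}") from None

    def family(self, codon: str) -> tuple[str, ...]:
        """All sense codons encoding the same amino acid as ``codon``."""
        aa = self.translate(codon)
        if aa == "*":
            return tuple(sorted(self.stops))
        return tuple(sorted(c for c, a in self.forward.items() if a == aa))

    def families(self) -> dict[str, tuple[str, ...]]:
        """amino acid -> sorted synonymous codon family (sense codons only)."""
        fam: dict[str, list[str]] = {}
        for codon, aa in self.forward.items():
            fam.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(codons)) for aa, codons in fam.items()}


#: vertebrate mitochondrial code (NCBI translation table 2)
VERTEBRATE_MITO = GeneticCode.from_ncbi(2)

#: canonical mitochondrial start codons seen in vertebrate PCGs
MITO_START_CODONS = frozenset({"ATG", "ATA", "ATT", "ATC", "GTG"})


def coding_sequence(genome: AnnotatedMitogenome, pcg: GeneFeature,
                    remove_stop: bool = False,
                    code: GeneticCode = VERTEBRATE_MITO) -> str:
    """In-frame encoded-strand CDS of a protein-coding gene.

    The 3' end is trimmed to a codon boundary (vertebrate mito genes often
    end on incomplete T/TA stops completed by polyadenylation).  With
    ``remove_stop`` the terminal codon is dropped when it is a stop under
    ``code``.
    """
    if pcg.feature_class != "PCG":
        raise ValidationError(f"{pcg.name}: not a protein-coding gene")
    seq = feature_sequence(genome, pcg)
    seq = seq[: len(seq) - len(seq) % 3]
    if remove_stop and len(seq) >= 3 and code.is_stop(seq[-3:]):
        seq = seq[:-3]
    if len(seq) < 3:
        raise ValidationError(f"{pcg.name}: no complete codons after trimming")
    return seq


def start_stop_codons(genome: AnnotatedMitogenome
                      ) -> dict[str, tuple[str, str, bool]]:
    """Per-PCG (start codon, terminal codon, terminal_complete).

    The terminal entry is the final in-frame codon when the gene length is
    a multiple of 3, otherwise the trailing 1-2 nt verbatim with the
    completeness flag False.
    """
    out = {}
    for pcg in genome.pcgs:
        seq = feature_sequence(genome, pcg)
        tail = len(seq) % 3
        if tail == 0:
            out[pcg.name] = (seq[:3], seq[-3:], True)
        else:
            out[pcg.name] = (seq[:3], seq[-tail:], False)
    return out


def codon_counts(cds_list: list[str]) -> tuple[Counter, int]:
    """Pooled codon counts over in-frame sequences.

    Returns (counts, n_skipped) where codons containing non-ACGT symbols
    are skipped and tallied.  Stop codons are counted here; the RSCU step
    excludes them from the synonymous-family denominators.
    """
    counts: Counter = Counter()
    skipped = 0
    for cds in cds_list:
        if len(cds) % 3:
            raise ValidationError("CDS length must be a multiple of 3")
        seq = cds.upper()
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if set(codon) <= set(_BASES):
                counts[codon] += 1
            else:
                skipped += 1
    return counts, skipped


@dataclass
class RscuTable:
    """Per-codon usage and RSCU plus the family bookkeeping behind it."""

    code: GeneticCode
    counts: dict[str, int]
    amino_acid: dict[str, str]
    rscu: dict[str, float]
    family_size: dict[str, int]   # amino acid -> n_i
    family_total: dict[str, int]  # amino acid -> total codon count
    split_sixfold: bool = False

    def frame(self, rna: bool = True) -> pd.DataFrame:
        """Tidy table sorted by amino acid; codons in RNA alphabet by
        default to match the usual RSCU bar plots."""
        rows = []
        for codon in sorted(self.rscu, key=lambda c: (self.amino_acid[c], c)):
            shown = codon.replace("T", "U") if rna else codon
            rows.append((self.amino_acid[codon], shown, self.counts.get(codon, 0),
                         self.rscu[codon]))
        return pd.DataFrame(rows, columns=["amino_acid", "codon", "count", "rscu"])


def _rscu_families(code: GeneticCode,
                   split_sixfold: bool) -> dict[str, tuple[str, ...]]:
    fams = code.families()
    if not split_sixfold:
        return fams
    out: dict[str, tuple[str, ...]] = {}
    for aa, codons in fams.items():
        if len(codons) == 6:
            boxes: dict[str, list[str]] = {}
            for c in codons:
                boxes.setdefault(c[:2], []).append(c)
            # the 4-codon box keeps the bare label, 2-codon boxes get suffixes
            for prefix, box in sorted(boxes.items()):
                label = aa if len(box) == 4 else f"{aa}_{prefix}"
                out[label] = tuple(box)
        else:
            out[aa] = codons
    return out


def rscu(counts: Counter | dict[str, int],
         code: GeneticCode = VERTEBRATE_MITO,
         split_sixfold: bool = False) -> RscuTable:
    """Relative synonymous codon usage over sense codons.

    Families are synonymous codon sets under ``code`` (one family per amino
    acid by default; ``split_sixfold`` separates 6-codon families into
    their 2- and 4-codon boxes).  Codons of an unused family get RSCU 0.
    """
    families = _rscu_families(code, split_sixfold)
    amino_acid: dict[str, str] = {}
    rscu_values: dict[str, float] = {}
    family_size: dict[str, int] = {}
    family_total: dict[str, int] = {}
    for label, codons in families.items():
        n_i = len(codons)
        total = sum(counts.get(c, 0) for c in codons)
        family_size[label] = n_i
        family_total[label] = total
        for c in codons:
            amino_acid[c] = label
            x = counts.get(c, 0)
            rscu_values[c] = (n_i * x / total) if total else 0.0
    sense = {c: int(counts.get(c, 0)) for c in rscu_values}
    return RscuTable(code=code, counts=sense, amino_acid=amino_acid,
                     rscu=rscu_values, family_size=family_size,
                     family_total=family_total, split_sixfold=split_sixfold)


def genome_rscu(genome: AnnotatedMitogenome,
                code: GeneticCode = VERTEBRATE_MITO,
                remove_stop: bool = True,
                split_sixfold: bool = False) -> RscuTable:
    """Pooled RSCU over all 13 PCGs of one genome (the per-species view)."""
    cds = [coding_sequence(genome, p, remove_stop=remove_stop, code=code)
           for p in genome.pcgs]
    counts, _ = codon_counts(cds)
    return rscu(counts, code=code, split_sixfold=split_sixfold)


def write_rscu_table(table: RscuTable, path: str | Path,
                     rna: bool = True) -> None:
    table.frame(rna=rna).to_csv(path, sep="\t", index=False,
                                float_format="%.4f")
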