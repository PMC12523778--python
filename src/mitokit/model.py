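"""Domain model for annotated circular mitochondrial genomes.

A vertebrate mitogenome is a circular DNA molecule of roughly 16.5 kb
carrying 37 genes: 13 protein-coding genes (PCGs), 22 tRNAs and 2 rRNAs,
plus one major non-coding control region (D-loop).  Genes live on both
strands of the duplex; by convention the *heavy* (H, majority-coding, "J")
strand is the one stored 5'->3' in the sequence databases, and *light*
(L, minority, "N") strand genes are read as the reverse complement of the
stored sequence.

Coordinates are 1-based and inclusive throughout, matching GenBank and the
tabular gene-organization layouts used in mitogenome papers.  A feature
with ``end < start`` spans the origin of the circular molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "AnnotatedMitogenome",
    "ValidationError",
    "reverse_complement",
    "feature_sequence",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "FEATURE_CLASSES",
]

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control_region")

#: accepted strand spellings -> canonical {H, L}
_STRAND_SYNONYMS = {
    "H": "H", "L": "L",
    "+": "H", "-": "L", "−": "L",  # unicode minus as printed in tables
    "J": "H", "N": "L",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


class ValidationError(ValueError):
    """An annotation violates the circular-genome model."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_strand(token: str) -> str:
    try:
        return _STRAND_SYNONYMS[str(token).strip()]
    except KeyError:
        raise ValidationError(f"unknown strand token: {token!r}") from None


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region on a circular mitogenome.

    ``start``/``end`` are 1-based inclusive; ``end < start`` is legal only
    for features spanning the origin.  ``strand`` is ``H`` or ``L``; it is
    ignored for the control region, which is not a transcribed gene.
    """

    name: str
    feature_class: str
    start: int
    end: int
    strand: str = "H"

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"{self.name}: feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}")
        object.__setattr__(self, "strand", canonical_strand(self.strand))
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"{self.name}: coordinates must be >= 1")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int) -> int:
        if genome_length <= 0:
            raise ValidationError("genome_length must be positive")
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class AnnotatedMitogenome:
    """A circular nucleotide sequence plus its ordered gene annotation.

    ``sequence`` is the H strand, 5'->3'.  Features are kept sorted by
    start coordinate; every analysis stage consumes this object.
    """

    identifier: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def add_feature(self, feature: GeneFeature) -> None:
        self.features.append(feature)
        self.features.sort(key=lambda f: (f.start, f.end))

    def features_of_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.features_of_class("PCG")

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def validate(self, strict: bool = False) -> None:
        """Check coordinate sanity; in strict mode also the 37-gene census.

        Raises :class:`ValidationError` on the first violation.
        """
        n = len(self.sequence)
        if n == 0:
            raise ValidationError(f"{self.identifier}: empty sequence")
        seen: set[tuple[str, int]] = set()
        for f in self.features:
            if not (1 <= f.start <= n and 1 <= f.end <= n):
                raise ValidationError(
                    f"{self.identifier}/{f.name}: coordinates ({f.start},{f.end}) "
                    f"outside sequence of length {n}")
            if f.wraps_origin and not self.circular:
                raise ValidationError(
                    f"{self.identifier}/{f.name}: origin-spanning feature on a "
                    "linear genome")
            key = (f.name, f.start)
            if key in seen:
                raise ValidationError(
                    f"{self.identifier}: duplicate feature {key}")
            seen.add(key)
        if strict:
            expected = {"PCG": 13, "tRNA": 22, "rRNA": 2}
            for cls, want in expected.items():
                got = len(self.features_of_class(cls))
                if got != want:
                    raise ValidationError(
                        f"{self.identifier}: expected {want} {cls} features, "
                        f"found {got}")


def feature_sequence(genome: AnnotatedMitogenome, feature: GeneFeature) -> str:
    """5'->3' sequence of the encoded gene.

    H-strand features are a plain slice of the genome; L-strand features
    are the reverse complement of that slice.  Origin-spanning features
    concatenate the tail and head of the circular sequence.
    """
    n = len(genome.sequence)
    if not (1 <= feature.start <= n and 1 <= feature.end <= n):
        raise ValidationError(
            f"{feature.name}: coordinates out of range for genome of length {n}")
    if feature.wraps_origin:
        if not genome.circular:
            raise ValidationError(
                f"{feature.name}: origin-spanning feature on a linear genome")
        raw = genome.sequence[feature.start - 1:] + genome.sequence[:feature.end]
    else:
        raw = genome.sequence[feature.start - 1:feature.end]
    if feature.strand == "L" and feature.feature_class != "control_region":
        return reverse_complement(raw)
    return raw


# ---------------------------------------------------------------------------
# GenBank I/O

_GENBANK_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                  "D-loop": "control_region"}
_CLASS_GENBANK = {v: k for k, v in _GENBANK_CLASS.items()}


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def _from_seqfeature(feat: SeqFeature, genome_length: int) -> GeneFeature | None:
    cls = _GENBANK_CLASS.get(feat.type)
    if cls is None:
        return None
    loc = feat.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # a join(tail, head) across the origin
        start = int(parts[-1].start) + 1
        end = int(parts[0].end)
    else:
        start = int(loc.start) + 1
        end = int(loc.end)
    strand = "L" if loc.strand == -1 else "H"
    name = _feature_name(feat) if cls != "control_region" else "D-loop"
    gf = GeneFeature(name=name, feature_class=cls, start=start, end=end,
                     strand=strand)
    if not (1 <= gf.start <= genome_length and 1 <= gf.end <= genome_length):
        raise ValidationError(
            f"{name}: GenBank coordinates outside sequence length {genome_length}")
    return gf


def read_genbank(path: str | Path) -> AnnotatedMitogenome:
    """Read an annotated mitogenome from a GenBank flat file.

    CDS features become PCGs, tRNA/rRNA map to their classes, D-loop to the
    control region; complement locations become L-strand features.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq)
    if not seq:
        raise ValidationError(f"{path}: GenBank record has no ORIGIN sequence")
    circular = record.annotations.get("topology", "circular") == "circular"
    features = []
    for feat in record.features:
        gf = _from_seqfeature(feat, len(seq))
        if gf is not None:
            features.append(gf)
    genome = AnnotatedMitogenome(identifier=record.id or record.name,
                                 sequence=seq, circular=circular,
                                 features=features)
    genome.validate(strict=False)
    return genome


def _to_seqfeature(f: GeneFeature, genome_length: int) -> SeqFeature:
    strand = -1 if f.strand == "L" and f.feature_class != "control_region" else 1
    if f.wraps_origin:
        loc = CompoundLocation([
            SimpleLocation(f.start - 1, genome_length, strand),
            SimpleLocation(0, f.end, strand),
        ])
    else:
        loc = SimpleLocation(f.start - 1, f.end, strand)
    ftype = _CLASS_GENBANK[f.feature_class]
    qualifiers = {} if f.feature_class == "control_region" else {"gene": [f.name]}
    return SeqFeature(location=loc, type=ftype, qualifiers=qualifiers)


def write_genbank(genome: AnnotatedMitogenome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                       name=genome.identifier[:16].replace(" ", "_"),
                       description="mitochondrion, complete genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.features = [_to_seqfeature(f, len(genome.sequence))
                       for f in genome.features]
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + feature-table I/O

TABLE_HEADER = ("name", "from", "to", "strand", "class")

_TABLE_CLASS = {"PCG": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "control_region": "control_region", "D-loop": "control_region",
                "control": "control_region"}


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Return (identifier, sequence) of the single record in a FASTA file."""
    record = SeqIO.read(str(path), "fasta")
    return record.id, str(record.seq)


def write_fasta(genome: AnnotatedMitogenome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                       description="")
    SeqIO.write(record, str(path), "fasta")


def read_feature_table(seq_path: str | Path,
                       table_path: str | Path) -> AnnotatedMitogenome:
    """Read a genome from a FASTA file plus a tab-separated annotation table.

    Table columns: ``name  from  to  strand  class`` where strand is one of
    +/-, H/L or J/N and class one of PCG/tRNA/rRNA/control_region.
    """
    identifier, seq = read_fasta(seq_path)
    features = []
    with open(table_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "name":
                continue
            if len(parts) < 5:
                raise ValidationError(
                    f"{table_path}:{lineno}: expected 5 tab-separated columns")
            name, start_s, end_s, strand, cls = parts[:5]
            try:
                start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
            except ValueError:
                raise ValidationError(
                    f"{table_path}:{lineno}: non-numeric coordinates "
                    f"{start_s!r}/{end_s!r}") from None
            if cls not in _TABLE_CLASS:
                raise ValidationError(
                    f"{table_path}:{lineno}: unknown class token {cls!r}")
            features.append(GeneFeature(name=name,
                                        feature_class=_TABLE_CLASS[cls],
                                        start=start, end=end, strand=strand))
    genome = AnnotatedMitogenome(identifier=identifier, sequence=seq,
                                 features=features)
    genome.validate(strict=False)
    return genome


def write_feature_table(genome: AnnotatedMitogenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_HEADER) + "\n")
        for f in genome.features:
            strand = "+" if f.strand == "H" else "-"
            fh.write(f"{f.name}\t{f.start}\t{f.end}\t{strand}\t"
                     f"{f.feature_class}\n")
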