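"""Seeded generator of annotated circular mitogenomes with known ground truth.

The generator realizes the standard vertebrate 37-gene arrangement — by
default the published *T. huangshanensis* gene order and spacing, including
the 43 bp ATP8/ATP6 and 7 bp ND4L/ND4 overlaps and a control region between
trnP and trnF — with every protein-coding gene a valid open reading frame
under the vertebrate mitochondrial code and the whole molecule matched to a
target base composition.  Everything planted (coordinates, strand census,
composition, per-gene CDS, substitution counts in derived genomes) is
recorded in a ground-truth ledger so each analysis stage can be checked
exactly.

Overlapping reading frames are the delicate part: a base inside the
ATP8/ATP6 overlap is simultaneously an ATP8 codon position and an ATP6
codon position, so codon sampling filters candidates against *every*
protein-coding frame covering the affected positions before committing.

tRNA, rRNA, spacer and control-region bases are composition-matched random
nucleotides with no secondary-structure realism.  There is no evolutionary
simulation along a tree: derived genomes differ from the base genome by
exactly the planned per-gene single-nucleotide substitution counts, each in
a distinct codon, never creating a stop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import datasets
from .codons import ALL_CODONS, VERTEBRATE_MITO, GeneticCode
from .model import (AnnotatedMitogenome, GeneFeature, ValidationError,
                    feature_sequence, write_fasta, write_feature_table)

__all__ = [
    "GeneSlot",
    "GenomeSpec",
    "MutationPlan",
    "generate_genome",
    "mutate_cds",
    "generate_species_pair",
    "default_gene_order",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GeneSlot:
    """One gene of the layout: identity plus length and gap to the next gene
    (negative gap = overlap with the next gene)."""

    name: str
    feature_class: str
    strand: str
    length: int
    gap_after: int = 0


def default_gene_order() -> list[GeneSlot]:
    """The published 37-gene layout with its real spacers and overlaps.

    Derived from the bundled T. huangshanensis annotation; the control
    region (between the last slot, trnP, and the first, trnF) is supplied
    separately via :class:`GenomeSpec`.
    """
    features, _n = datasets.huangshanensis_annotation()
    slots = []
    for i, f in enumerate(features):
        length = f.end - f.start + 1
        if i + 1 < len(features):
            gap = features[i + 1].start - f.end - 1
        else:
            gap = 0  # the control region follows the final slot
        slots.append(GeneSlot(name=f.name, feature_class=f.feature_class,
                              strand=f.strand, length=length, gap_after=gap))
    return slots


@dataclass
class GenomeSpec:
    """Recipe for one synthetic mitogenome.

    ``composition`` is the target whole-genome (A, C, G, T) percentage
    vector; the default is the published T. huangshanensis composition.
    ``at3_bias`` multiplies the sampling weight of codons ending in A or T,
    planting the A/T-ending codon preference seen in real mitogenomes.
    """

    seed: int = 0
    identifier: str = "synthetic_mitogenome"
    gene_order: list[GeneSlot] = field(default_factory=default_gene_order)
    control_region_length: int = 1064
    composition: tuple[float, float, float, float] = (34.3, 23.9, 11.6, 30.2)
    at3_bias: float = 2.0
    composition_tol: float = 1.0

    def __post_init__(self):
        if self.control_region_length <= 0:
            raise ValidationError("control region length must be positive")
        if abs(sum(self.composition) - 100.0) > 1e-6:
            raise ValidationError("composition percentages must sum to 100")
        for slot in self.gene_order:
            if slot.length <= 0:
                raise ValidationError(f"{slot.name}: non-positive length")
            if slot.gap_after < 0 and -slot.gap_after >= slot.length:
                raise ValidationError(
                    f"{slot.name}: overlap {-slot.gap_after} not shorter than "
                    f"the gene")


@dataclass(frozen=True)
class MutationPlan:
    """Planted substitution counts for one CDS: ``n_syn`` synonymous and
    ``n_nonsyn`` nonsynonymous single-nucleotide changes, each in a distinct
    codon, none creating a stop."""

    n_syn: int = 0
    n_nonsyn: int = 0


# ---------------------------------------------------------------------------
# layout -> coordinates

def _layout(spec: GenomeSpec) -> tuple[list[GeneFeature], int]:
    features = []
    start = 1
    for slot in spec.gene_order:
        end = start + slot.length - 1
        features.append(GeneFeature(name=slot.name,
                                    feature_class=slot.feature_class,
                                    start=start, end=end, strand=slot.strand))
        start = end + slot.gap_after + 1
    genome_length = features[-1].end + spec.control_region_length
    return features, genome_length


def _reading_positions(f: GeneFeature) -> tuple[list[int], bool]:
    """0-based genomic positions of a gene in reading order, plus whether
    encoded bases are complements of the stored strand."""
    span = list(range(f.start - 1, f.end))
    if f.strand == "L":
        return span[::-1], True
    return span, False


# ---------------------------------------------------------------------------
# codon-level sequence construction

def _base_probs(composition) -> dict[str, float]:
    total = sum(composition)
    return {b: composition[i] / total for i, b in enumerate("ACGT")}


def _codon_weights(probs: dict[str, float], at3_bias: float,
                   code: GeneticCode) -> dict[str, float]:
    weights = {}
    for codon in ALL_CODONS:
        if code.is_stop(codon):
            continue
        w = probs[codon[0]] * probs[codon[1]] * probs[codon[2]]
        if codon[2] in "AT":
            w *= at3_bias
        weights[codon] = w
    return weights


class _Builder:
    """Mutable genome-under-construction with frame-aware codon placement."""

    def __init__(self, spec: GenomeSpec, rng: np.random.Generator,
                 code: GeneticCode):
        self.spec = spec
        self.rng = rng
        self.code = code
        self.features, self.n = _layout(spec)
        self.seq: list[str | None] = [None] * self.n
        self.pcgs = [f for f in self.features if f.feature_class == "PCG"]
        # position -> list of (pcg index, offset in reading frame)
        self.frame_index: dict[int, list[tuple[int, int]]] = {}
        self.frames = []
        for idx, f in enumerate(self.pcgs):
            positions, comp = _reading_positions(f)
            self.frames.append((positions, comp))
            for off, pos in enumerate(positions):
                self.frame_index.setdefault(pos, []).append((idx, off))
        probs = _base_probs(spec.composition)
        self.codon_weights = _codon_weights(probs, spec.at3_bias, code)
        self.base_probs = probs

    # -- encoded-base accessors -------------------------------------------
    def _get(self, pos: int, comp: bool) -> str | None:
        b = self.seq[pos]
        return None if b is None else (_COMP[b] if comp else b)

    def _set(self, pos: int, comp: bool, base: str) -> None:
        self.seq[pos] = _COMP[base] if comp else base

    def _frame_codon(self, pcg_idx: int, codon_idx: int) -> str | None:
        """Codon of a PCG frame, or None unless fully determined."""
        positions, comp = self.frames[pcg_idx]
        bases = []
        for off in range(3 * codon_idx, 3 * codon_idx + 3):
            if off >= len(positions):
                return None
            b = self._get(positions[off], comp)
            if b is None:
                return None
            bases.append(b)
        return "".join(bases)

    def _creates_foreign_stop(self, touched: list[int],
                              own_idx: int) -> bool:
        """Would any *other* PCG frame now contain a complete stop codon at a
        non-terminal position?"""
        for pos in touched:
            for idx, off in self.frame_index.get(pos, []):
                if idx == own_idx:
                    continue
                codon_idx = off // 3
                positions, _ = self.frames[idx]
                n_codons = len(positions) // 3
                if codon_idx >= n_codons - 1:
                    continue  # terminal codon of that gene may be its stop
                codon = self._frame_codon(idx, codon_idx)
                if codon is not None and self.code.is_stop(codon):
                    return True
        return False

    # -- codon placement ---------------------------------------------------
    def place_codon(self, pcg_idx: int, codon_idx: int,
                    candidates: list[str]) -> None:
        """Write one codon of a PCG, choosing among ``candidates`` those
        compatible with already-fixed bases and creating no stop in any
        overlapping frame."""
        positions, comp = self.frames[pcg_idx]
        offs = range(3 * codon_idx, 3 * codon_idx + 3)
        fixed = [self._get(positions[o], comp) for o in offs]
        viable = [c for c in candidates
                  if all(f is None or f == c[i] for i, f in enumerate(fixed))]
        if not viable:
            raise ValidationError(
                f"{self.pcgs[pcg_idx].name}: codon {codon_idx} infeasible "
                f"(fixed bases {fixed})")
        # weighted order without replacement (exponential-keys trick), so the
        # fallback after a frame conflict still respects the codon weights
        weights = np.array([self.codon_weights.get(c, 1e-9) for c in viable])
        keys = self.rng.exponential(1.0, len(viable)) / weights
        order = list(np.argsort(keys))
        for i in order:
            codon = viable[i]
            saved = [self.seq[positions[o]] for o in offs]
            touched = [positions[o] for o in offs]
            for k, o in enumerate(offs):
                self._set(positions[o], comp, codon[k])
            if not self._creates_foreign_stop(touched, pcg_idx):
                return
            for pos, b in zip(touched, saved):
                self.seq[pos] = b
        raise ValidationError(
            f"{self.pcgs[pcg_idx].name}: codon {codon_idx} blocked by "
            "overlapping reading frames")

    def place_terminal(self, pcg_idx: int) -> None:
        positions, comp = self.frames[pcg_idx]
        tail = len(positions) % 3
        if tail == 0:
            n_codons = len(positions) // 3
            self.place_codon(pcg_idx, n_codons - 1,
                             ["TAA", "TAG"])
        else:
            # incomplete stop completed by polyadenylation: T or TA
            bases = "TA"[:tail] if tail == 2 else "T"
            for k in range(tail):
                pos = positions[len(positions) - tail + k]
                fixed = self._get(pos, comp)
                if fixed is not None and fixed != bases[k]:
                    raise ValidationError(
                        f"{self.pcgs[pcg_idx].name}: incomplete stop "
                        "conflicts with overlap")
                self._set(pos, comp, bases[k])

    def fill_pcgs(self) -> None:
        sense = [c for c in ALL_CODONS if not self.code.is_stop(c)]
        starts = ["ATG", "ATA", "ATT", "GTG"]
        # reserve start codons first so overlapped downstream starts are
        # respected while the upstream gene is being filled
        for idx in range(len(self.pcgs)):
            self.place_codon(idx, 0, starts)
        for idx in range(len(self.pcgs)):
            self.place_terminal(idx)
        for idx in range(len(self.pcgs)):
            positions, _ = self.frames[idx]
            n_codons = len(positions) // 3
            last_full = n_codons - 1 if len(positions) % 3 == 0 else n_codons
            for codon_idx in range(1, last_full):
                self.place_codon(idx, codon_idx, sense)

    def fill_remainder(self) -> None:
        free = [i for i, b in enumerate(self.seq) if b is None]
        bases = np.array(list("ACGT"))
        p = np.array([self.base_probs[b] for b in "ACGT"])
        draws = self.rng.choice(bases, size=len(free), p=p)
        for pos, b in zip(free, draws):
            self.seq[pos] = str(b)

    def tune_composition(self) -> None:
        """Nudge non-coding positions so every base percentage lands within
        the spec tolerance of its target."""
        target = {b: self.spec.composition[i] * self.n / 100.0
                  for i, b in enumerate("ACGT")}
        tol_count = self.spec.composition_tol * self.n / 100.0
        adjustable = [i for i in range(self.n) if i not in self.frame_index]
        self.rng.shuffle(adjustable)
        counts = {b: 0 for b in "ACGT"}
        for b in self.seq:
            counts[b] += 1
        for pos in adjustable:
            over = max(counts, key=lambda b: counts[b] - target[b])
            under = min(counts, key=lambda b: counts[b] - target[b])
            if (counts[over] - target[over] <= tol_count * 0.5
                    and target[under] - counts[under] <= tol_count * 0.5):
                break
            if self.seq[pos] == over:
                self.seq[pos] = under
                counts[over] -= 1
                counts[under] += 1


def generate_genome(spec: GenomeSpec,
                    code: GeneticCode = VERTEBRATE_MITO
                    ) -> tuple[AnnotatedMitogenome, dict]:
    """Realize a :class:`GenomeSpec` into an annotated genome plus a
    ground-truth ledger.  Same spec (same seed) -> identical output."""
    rng = np.random.default_rng(spec.seed)
    builder = _Builder(spec, rng, code)
    builder.fill_pcgs()
    builder.fill_remainder()
    builder.tune_composition()
    sequence = "".join(builder.seq)
    genome = AnnotatedMitogenome(identifier=spec.identifier,
                                 sequence=sequence, circular=True,
                                 features=list(builder.features))
    counts = {b: sequence.count(b) for b in "ACGT"}
    census: dict[str, int] = {}
    for f in builder.features:
        key = f"{f.strand}:{f.feature_class}"
        census[key] = census.get(key, 0) + 1
    last = builder.features[-1]
    ledger = {
        "seed": spec.seed,
        "identifier": spec.identifier,
        "genome_length": builder.n,
        "features": [(f.name, f.feature_class, f.start, f.end, f.strand)
                     for f in builder.features],
        "strand_census": census,
        "base_counts": counts,
        "composition_target": list(spec.composition),
        "control_region": (last.end + 1, builder.n,
                           spec.control_region_length),
        "cds": {f.name: feature_sequence(genome, f)
                for f in builder.features if f.feature_class == "PCG"},
    }
    return genome, ledger


# ---------------------------------------------------------------------------
# planted substitutions

def _single_nt_variants(codon: str, kind: str,
                        code: GeneticCode) -> list[tuple[int, str]]:
    """(position, replacement codon) single-nucleotide changes of the given
    classification that do not create a stop."""
    aa = code.translate(codon)
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if code.is_stop(alt):
                continue
            syn = code.translate(alt) == aa
            if (kind == "syn") == syn:
                out.append((pos, alt))
    return out


def mutate_cds(cds: str, plan: MutationPlan, seed: int,
               code: GeneticCode = VERTEBRATE_MITO,
               eligible_codons: list[int] | None = None
               ) -> tuple[str, list[dict]]:
    """Apply exactly the planned substitutions to an in-frame CDS.

    Each realized change is a single-nucleotide substitution in a distinct
    codon, verified under ``code`` and never creating a stop; the returned
    record lists (codon index, position, old/new codon, classification) for
    oracle checks.  Raises when the plan is infeasible.
    """
    if len(cds) % 3:
        raise ValidationError("CDS length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    n_codons = len(cds) // 3
    pool = list(eligible_codons) if eligible_codons is not None \
        else list(range(n_codons))
    if plan.n_syn + plan.n_nonsyn > len(pool):
        raise ValidationError("plan exceeds the number of eligible codons")
    rng.shuffle(pool)
    todo = ["syn"] * plan.n_syn + ["nonsyn"] * plan.n_nonsyn
    rng.shuffle(todo)
    codons = [cds[3 * i:3 * i + 3] for i in range(n_codons)]
    realized = []
    for kind in todo:
        placed = False
        for j, idx in enumerate(pool):
            variants = _single_nt_variants(codons[idx], kind, code)
            if not variants:
                continue
            pos, alt = variants[rng.integers(len(variants))]
            realized.append({"codon_index": idx, "position": 3 * idx + pos,
                             "from": codons[idx], "to": alt, "kind": kind})
            codons[idx] = alt
            pool.pop(j)
            placed = True
            break
        if not placed:
            raise ValidationError(
                f"infeasible plan: no codon left with a {kind} variant")
    return "".join(codons), realized


def generate_species_pair(spec: GenomeSpec,
                          plans: dict[str, MutationPlan],
                          derived_identifier: str | None = None,
                          code: GeneticCode = VERTEBRATE_MITO
                          ) -> tuple[AnnotatedMitogenome,
                                     AnnotatedMitogenome, dict]:
    """A base genome and a derived genome with planted per-gene divergence.

    ``plans`` maps PCG names to :class:`MutationPlan`; genes without a plan
    stay identical.  Mutated codons avoid the start codon, the terminal
    stop, and any position shared with another protein-coding gene, so the
    planted synonymous/nonsynonymous counts are recovered exactly by
    pairwise NG86 counting on the prepared CDS.
    """
    base, ledger = generate_genome(spec, code)
    seq = list(base.sequence)
    pcg_spans: dict[str, set[int]] = {}
    for f in base.pcgs:
        pcg_spans[f.name] = set(range(f.start - 1, f.end))
    truth: dict[str, dict] = {}
    sub_rng = np.random.default_rng(spec.seed + 1)
    for name, plan in sorted(plans.items()):
        f = base.get(name)
        if f.feature_class != "PCG":
            raise ValidationError(f"{name}: mutation plans apply to PCGs only")
        positions, comp = _reading_positions(f)
        cds_full = feature_sequence(base, f)
        trimmed = len(cds_full) - len(cds_full) % 3
        n_codons = trimmed // 3
        if code.is_stop(cds_full[trimmed - 3:trimmed]):
            n_codons -= 1  # keep the terminal stop intact
        foreign = set().union(*(s for g, s in pcg_spans.items() if g != name)) \
            if len(pcg_spans) > 1 else set()
        eligible = []
        for idx in range(1, n_codons):
            codon_positions = positions[3 * idx:3 * idx + 3]
            if not foreign.intersection(codon_positions):
                eligible.append(idx)
        mutated, realized = mutate_cds(
            cds_full[:3 * n_codons], plan,
            seed=int(sub_rng.integers(2 ** 31)), code=code,
            eligible_codons=eligible)
        for rec in realized:
            off = rec["position"]
            pos = positions[off]
            new_base = rec["to"][off % 3]
            seq[pos] = _COMP[new_base] if comp else new_base
        truth[name] = {"n_syn": plan.n_syn, "n_nonsyn": plan.n_nonsyn,
                       "changes": realized}
    derived = AnnotatedMitogenome(
        identifier=derived_identifier or f"{spec.identifier}_derived",
        sequence="".join(seq), circular=True,
        features=list(base.features))
    pair_ledger = {"base": ledger, "plans": truth}
    return base, derived, pair_ledger


def write_bundle(genome: AnnotatedMitogenome, ledger: dict,
                 outdir: str | Path) -> None:
    """FASTA + feature table + JSON ground truth for one genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, outdir / f"{genome.identifier}.fasta")
    write_feature_table(genome, outdir / f"{genome.identifier}.features.tsv")
    with open(outdir / f"{genome.identifier}.truth.json", "w") as fh:
        json.dump(ledger, fh, indent=2)
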