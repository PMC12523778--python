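"""Pairwise Ka/Ks per gene with Nei-Gojobori (1986) counting.

The screen estimates, for two codon-aligned coding sequences, the number of
synonymous substitutions per synonymous site (Ks) and nonsynonymous
substitutions per nonsynonymous site (Ka).  Ka/Ks > 1 indicates positive
selection, = 1 neutrality, < 1 purifying selection.

Counting follows the classical NG86 scheme:

* **Sites.** Each codon position contributes a synonymous-site fraction
  equal to the number of its three possible single-nucleotide changes that
  are synonymous, divided by 3; changes creating a stop codon are never
  synonymous.  s + n = 3 per codon, and S, N for a sequence pair are the
  averages of the two sequences' totals.
* **Differences.** For a codon pair differing at k positions, all k!
  orderings of the single-nucleotide steps are enumerated; orderings that
  pass through a stop codon are discarded and the synonymous /
  nonsynonymous step counts are averaged over the rest (uniformly over all
  orderings if every one is blocked).
* **Correction.** Proportions pS = Sd/S and pN = Nd/N get the
  Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3); p >= 3/4
  is saturated and the rate undefined.

This matters under the vertebrate mitochondrial code, whose four stops
(TAA, TAG, AGA, AGG) block more pathways than the standard code's three.

Gene preparation mirrors standard mitogenome practice: terminal stop
codons removed, the light-strand ND6 gene taken from the encoded strand
(reverse complement), and the genomic concatenation keeps overlapping
positions (ATP8/ATP6, ND4L/ND4) in both genes so all codons are analysed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from pathlib import Path

import pandas as pd

from .codons import VERTEBRATE_MITO, GeneticCode, coding_sequence
from .model import AnnotatedMitogenome, ValidationError

__all__ = [
    "KaKsResult",
    "ng_site_counts",
    "ng_pair_differences",
    "kaks_pair",
    "prepare_gene_set",
    "per_gene_kaks",
    "jukes_cantor",
]

_BASES = "ACGT"


@dataclass
class KaKsResult:
    """NG86 counts and rates for one gene pair."""

    gene: str
    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    codons_used: int
    pS: float | None = None
    pN: float | None = None
    Ks: float | None = None
    Ka: float | None = None
    ratio: float | None = None
    label: str = "undefined"
    saturated: bool = False


def jukes_cantor(p: float) -> float | None:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); None if saturated."""
    if p < 0:
        raise ValidationError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, table_id: int) -> tuple[float, float]:
    code = GeneticCode.from_ncbi(table_id)
    if code.is_stop(codon):
        raise ValidationError(f"site counts undefined for stop codon {codon}")
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if not code.is_stop(alt) and code.translate(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def ng_site_counts(codon: str,
                   code: GeneticCode = VERTEBRATE_MITO) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon.

    Changes that create stop codons are excluded from the synonymous set
    (they count as nonsynonymous opportunity); s + n = 3 always.
    """
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= set(_BASES):
        raise ValidationError(f"not an unambiguous codon: {codon!r}")
    return _site_counts_cached(codon, code.table_id)


def _step_class(a: str, b: str, code: GeneticCode) -> str:
    """Classify one single-nucleotide codon change as syn or nonsyn."""
    return "syn" if code.translate(a) == code.translate(b) else "nonsyn"


def ng_pair_differences(codon_a: str, codon_b: str,
                        code: GeneticCode = VERTEBRATE_MITO
                        ) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons.

    Enumerates every ordering of the differing positions, drops orderings
    whose intermediate codons are stops, and averages over the remainder;
    if all orderings are blocked, averages uniformly over all of them.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if len(c) != 3 or not set(c) <= set(_BASES):
            raise ValidationError(f"not an unambiguous codon: {c!r}")
        if code.is_stop(c):
            raise ValidationError(f"differences undefined for stop codon {c}")
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return 0.0, 0.0
    open_paths: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        current = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if code.is_stop(nxt):
                blocked = True
            elif not blocked:
                if _step_class(current, nxt, code) == "syn":
                    sd += 1
                else:
                    nd += 1
            current = nxt
        # for the uniform fallback, classify ignoring stop status
        current = a
        sd_all = nd_all = 0
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if code.translate(current) == code.translate(nxt):
                sd_all += 1
            else:
                nd_all += 1
            current = nxt
        all_paths.append((sd_all, nd_all))
        if not blocked:
            open_paths.append((sd, nd))
    paths = open_paths or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _codon_ok(codon: str, code: GeneticCode) -> bool:
    return (len(codon) == 3 and set(codon) <= set(_BASES)
            and not code.is_stop(codon))


def kaks_pair(cds_a: str, cds_b: str,
              code: GeneticCode = VERTEBRATE_MITO,
              gene: str = "", pair: tuple[str, str] = ("a", "b"),
              neutral_tol: float = 0.0) -> KaKsResult:
    """NG86 + Jukes-Cantor Ka/Ks for two codon-aligned sequences.

    Codon columns containing gaps, ambiguity codes or stop codons in either
    sequence are skipped pairwise.  S and N are averaged over the two
    sequences; Sd and Nd are summed over codon pairs.  The selection label
    follows the sign of Ka/Ks - 1 (within ``neutral_tol`` of 1 counts as
    neutral); Ks = 0 or a saturated correction yields "undefined".
    """
    if len(cds_a) != len(cds_b):
        raise ValidationError("sequences must be codon-aligned to equal length")
    if len(cds_a) % 3:
        raise ValidationError("aligned length must be a multiple of 3")
    a, b = cds_a.upper(), cds_b.upper()
    S_a = N_a = S_b = N_b = 0.0
    Sd = Nd = 0.0
    used = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if not (_codon_ok(ca, code) and _codon_ok(cb, code)):
            continue
        used += 1
        sa, na = ng_site_counts(ca, code)
        sb, nb = ng_site_counts(cb, code)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd, nd = ng_pair_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    S = (S_a + S_b) / 2.0
    N = (N_a + N_b) / 2.0
    res = KaKsResult(gene=gene, pair=pair, S=S, N=N, Sd=Sd, Nd=Nd,
                     codons_used=used)
    if used == 0 or S == 0 or N == 0:
        return res
    res.pS = Sd / S
    res.pN = Nd / N
    res.Ks = jukes_cantor(res.pS)
    res.Ka = jukes_cantor(res.pN)
    if res.Ks is None or res.Ka is None:
        res.saturated = res.pS >= 0.75 or res.pN >= 0.75
        return res
    if res.Ks == 0.0:
        return res
    res.ratio = res.Ka / res.Ks
    if res.ratio > 1.0 + neutral_tol:
        res.label = "positive"
    elif res.ratio < 1.0 - neutral_tol:
        res.label = "purifying"
    else:
        res.label = "neutral"
    return res


#: canonical order of the 13 vertebrate mitochondrial PCGs on the genome
PCG_ORDER = ["ND1", "ND2", "COX1", "COX2", "atp8", "atp6", "COX3", "ND3",
             "ND4L", "ND4", "ND5", "ND6", "Cytb"]


def prepare_gene_set(genome: AnnotatedMitogenome,
                     include: list[str] | None = None,
                     code: GeneticCode = VERTEBRATE_MITO,
                     strict: bool = True) -> tuple[dict[str, str], str]:
    """Per-gene prepared CDS and their genomic-order concatenation.

    Each CDS is the encoded-strand sequence (light-strand genes, e.g. ND6,
    reverse complemented) trimmed in frame with the terminal stop removed.
    Overlapping positions belong to every gene containing them, so they
    appear twice in the concatenation — every codon of every gene is kept.
    """
    wanted = include or [p.name for p in genome.pcgs]
    prepared: dict[str, str] = {}
    missing = []
    for name in wanted:
        try:
            pcg = genome.get(name)
        except KeyError:
            missing.append(name)
            continue
        prepared[name] = coding_sequence(genome, pcg, remove_stop=True,
                                         code=code)
    if missing:
        if strict:
            raise ValidationError(
                f"{genome.identifier}: missing PCGs {missing}")
        import warnings
        warnings.warn(f"{genome.identifier}: missing PCGs {missing}, "
                      f"continuing with {len(prepared)} genes")
    concat = "".join(prepared[n] for n in wanted if n in prepared)
    return prepared, concat


def per_gene_kaks(ingroup: AnnotatedMitogenome,
                  reference: AnnotatedMitogenome,
                  alignments: dict[str, tuple[str, str]] | None = None,
                  code: GeneticCode = VERTEBRATE_MITO,
                  include_concatenation: bool = True,
                  neutral_tol: float = 0.0) -> list[KaKsResult]:
    """Ka/Ks for every PCG of a genome pair (plus the 13-gene concatenation).

    ``alignments`` supplies externally produced codon alignments keyed by
    gene name; without it the prepared CDS of each gene must already be
    equal length (true for generator pairs, which are aligned by
    construction).
    """
    genes_a, concat_a = prepare_gene_set(ingroup, code=code, strict=False)
    genes_b, concat_b = prepare_gene_set(reference, code=code, strict=False)
    pair = (ingroup.identifier, reference.identifier)
    results = []
    for name in genes_a:
        if name not in genes_b:
            continue
        if alignments and name in alignments:
            a, b = alignments[name]
        else:
            a, b = genes_a[name], genes_b[name]
        if len(a) != len(b):
            raise ValidationError(
                f"{name}: unaligned sequences of different length; supply "
                "a codon alignment")
        results.append(kaks_pair(a, b, code=code, gene=name, pair=pair,
                                 neutral_tol=neutral_tol))
    if include_concatenation and len(concat_a) == len(concat_b):
        results.append(kaks_pair(concat_a, concat_b, code=code,
                                 gene="concatenated_PCGs", pair=pair,
                                 neutral_tol=neutral_tol))
    return results


def kaks_frame(results: list[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "ingroup": r.pair[0], "reference": r.pair[1],
        "codons_used": r.codons_used, "S": r.S, "N": r.N, "Sd": r.Sd,
        "Nd": r.Nd, "pS": r.pS, "pN": r.pN, "Ks": r.Ks, "Ka": r.Ka,
        "ka_ks": r.ratio, "label": r.label, "saturated": r.saturated,
    } for r in results])


def write_kaks_table(results: list[KaKsResult], path: str | Path) -> None:
    kaks_frame(results).to_csv(path, sep="\t", index=False,
                               float_format="%.6g")
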