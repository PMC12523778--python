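"""Base composition and strand-asymmetry (AT/GC skew) statistics.

Skews follow the usual strand-asymmetry definitions

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed on whichever region is asked for and reported as percentages
(x100) to match the comparative-mitogenomics literature.  Region summaries
are computed on *encoded-strand* sequences: genes annotated on the light
strand are reverse complemented before counting, so their skews describe
the gene as transcribed, not the stored heavy strand.

Percentages and skews are always derived from integer base counts;
rounding happens only in report writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geometry import locate_control_region
from .model import AnnotatedMitogenome, ValidationError, feature_sequence

__all__ = [
    "CompositionSummary",
    "base_composition",
    "skews",
    "region_composition_summary",
    "multi_genome_summary",
    "summarize_composition_rows",
    "composition_frame",
]


@dataclass
class CompositionSummary:
    """Base counts, percentages and skews for one named region."""

    region_name: str
    size_bp: int
    counts: dict[str, int] = field(default_factory=dict)
    pct_A: float = 0.0
    pct_C: float = 0.0
    pct_G: float = 0.0
    pct_T: float = 0.0
    pct_AT: float = 0.0
    pct_GC: float = 0.0
    at_skew: float | None = None  # percent (x100)
    gc_skew: float | None = None


def base_composition(sequence: str,
                     region_name: str = "sequence") -> CompositionSummary:
    """Count A/C/G/T and derive percentages over the unambiguous bases.

    ``size_bp`` reports the raw sequence length; ambiguity codes (N etc.)
    are excluded from both numerator and denominator of the percentages.
    """
    if not sequence:
        raise ValidationError("cannot compute composition of empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    summary = CompositionSummary(region_name=region_name,
                                 size_bp=len(sequence), counts=counts)
    if denom:
        summary.pct_A = 100.0 * counts["A"] / denom
        summary.pct_C = 100.0 * counts["C"] / denom
        summary.pct_G = 100.0 * counts["G"] / denom
        summary.pct_T = 100.0 * counts["T"] / denom
        summary.pct_AT = summary.pct_A + summary.pct_T
        summary.pct_GC = summary.pct_G + summary.pct_C
    return summary


def skews(pct_A: float, pct_C: float, pct_G: float,
          pct_T: float) -> tuple[float, float]:
    """(AT-skew, GC-skew) in percent from base proportions or counts.

    Both formulas are scale-invariant, so raw counts and percentages give
    the same answer.  Raises on a zero denominator.
    """
    at, gc = pct_A + pct_T, pct_G + pct_C
    if at <= 0 or gc <= 0:
        raise ValidationError("skew undefined: A+T and G+C must be positive")
    return 100.0 * (pct_A - pct_T) / at, 100.0 * (pct_G - pct_C) / gc


def _with_skews(summary: CompositionSummary) -> CompositionSummary:
    c = summary.counts
    if c.get("A", 0) + c.get("T", 0) > 0 and c.get("G", 0) + c.get("C", 0) > 0:
        summary.at_skew, summary.gc_skew = skews(
            c["A"], c["C"], c["G"], c["T"])
    return summary


_REGION_SPECS = [
    # (row name, feature class, strand filter or None)
    ("PCGs", "PCG", None),
    ("PCGs(J)", "PCG", "H"),
    ("PCGs(N)", "PCG", "L"),
    ("tRNAs", "tRNA", None),
    ("tRNAs(J)", "tRNA", "H"),
    ("tRNAs(N)", "tRNA", "L"),
    ("rRNAs", "rRNA", None),
]


def region_composition_summary(genome: AnnotatedMitogenome,
                               ) -> list[CompositionSummary]:
    """Composition rows for the whole genome and its canonical sub-regions.

    Sub-region sequences are concatenations of encoded-strand gene
    sequences.  Positions shared by overlapping genes contribute to every
    gene containing them, so the PCG concatenation size equals the plain
    sum of the annotated gene lengths.  A missing control region (no
    trnP/trnF) drops that row rather than failing.
    """
    rows = [_with_skews(base_composition(genome.sequence, "mitogenome"))]
    for name, cls, strand in _REGION_SPECS:
        feats = [f for f in genome.features_of_class(cls)
                 if strand is None or f.strand == strand]
        if not feats:
            continue
        concat = "".join(feature_sequence(genome, f) for f in feats)
        rows.append(_with_skews(base_composition(concat, name)))
    control = next((f for f in genome.features
                    if f.feature_class == "control_region"), None)
    if control is None:
        try:
            control = locate_control_region(genome)
        except ValidationError:
            control = None
    if control is not None:
        seq = feature_sequence(genome, control)
        rows.append(_with_skews(base_composition(seq, "control_region")))
    return rows


def multi_genome_summary(genomes: list[AnnotatedMitogenome]) -> dict:
    """Whole-genome composition rows plus across-genome aggregates."""
    rows = []
    for g in genomes:
        s = _with_skews(base_composition(g.sequence, g.identifier))
        rows.append(s)
    return summarize_composition_rows(rows)


def summarize_composition_rows(rows: list[CompositionSummary]) -> dict:
    """Aggregate statistics over per-genome composition rows.

    Accepts rows built either from sequences or from printed percentage
    tables (see :func:`composition_from_percentages`); skews missing on a
    row are computed from its percentages.
    """
    if not rows:
        raise ValidationError("need at least one genome")
    for r in rows:
        if r.at_skew is None or r.gc_skew is None:
            r.at_skew, r.gc_skew = skews(r.pct_A, r.pct_C, r.pct_G, r.pct_T)
    mean_at = sum(r.pct_AT for r in rows) / len(rows)
    by_at = sorted(rows, key=lambda r: r.at_skew)
    by_gc = sorted(rows, key=lambda r: r.gc_skew)
    return {
        "rows": rows,
        "mean_pct_AT": mean_at,
        "at_skew_min": (by_at[0].region_name, by_at[0].at_skew),
        "at_skew_max": (by_at[-1].region_name, by_at[-1].at_skew),
        "gc_skew_min": (by_gc[0].region_name, by_gc[0].gc_skew),
        "gc_skew_max": (by_gc[-1].region_name, by_gc[-1].gc_skew),
    }


def composition_from_percentages(name: str, size_bp: int, pct_A: float,
                                 pct_C: float, pct_G: float, pct_T: float,
                                 pct_AT: float | None = None,
                                 pct_GC: float | None = None
                                 ) -> CompositionSummary:
    """Build a summary row from printed (possibly rounded) percentages.

    ``pct_AT``/``pct_GC`` may be given explicitly when the source table
    prints them (rounded tables are not always internally consistent);
    otherwise they are the sums of the base percentages.
    """
    s = CompositionSummary(region_name=name, size_bp=size_bp,
                           pct_A=pct_A, pct_C=pct_C, pct_G=pct_G, pct_T=pct_T,
                           pct_AT=pct_AT if pct_AT is not None else pct_A + pct_T,
                           pct_GC=pct_GC if pct_GC is not None else pct_G + pct_C)
    s.at_skew, s.gc_skew = skews(pct_A, pct_C, pct_G, pct_T)
    return s


def composition_frame(rows: list[CompositionSummary],
                      precision: int = 1,
                      skew_sigfigs: int = 3) -> pd.DataFrame:
    """Report-precision DataFrame of composition rows (rounding happens
    here, never upstream)."""
    def _sig(x):
        if x is None:
            return None
        return float(f"%.{skew_sigfigs}g" % x)

    return pd.DataFrame({
        "region": [r.region_name for r in rows],
        "size_bp": [r.size_bp for r in rows],
        "pct_A": [round(r.pct_A, precision) for r in rows],
        "pct_C": [round(r.pct_C, precision) for r in rows],
        "pct_G": [round(r.pct_G, precision) for r in rows],
        "pct_T": [round(r.pct_T, precision) for r in rows],
        "pct_AT": [round(r.pct_AT, precision) for r in rows],
        "pct_GC": [round(r.pct_GC, precision) for r in rows],
        "at_skew": [_sig(r.at_skew) for r in rows],
        "gc_skew": [_sig(r.gc_skew) for r in rows],
    })


def write_composition_table(rows: list[CompositionSummary],
                            path: str | Path, precision: int = 1) -> None:
    composition_frame(rows, precision).to_csv(path, sep="\t", index=False)
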