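"""Independent brute-force oracle for Nei-Gojobori counting.

Written from the definitions, deliberately sharing no code with the
implementation under test: site fractions by direct neighbor enumeration,
pairwise differences by recursive enumeration of every substitution
ordering with stop-codon intermediates discarded.
"""

from itertools import permutations

from Bio.Data import CodonTable

_T2 = CodonTable.unambiguous_dna_by_id[2]


def translate(codon, table=_T2):
    return "*" if codon in table.stop_codons else table.forward_table[codon]


def oracle_sites(codon, table=_T2):
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in table.stop_codons:
                continue
            if translate(alt, table) == translate(codon, table):
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


def _paths(a, b, table):
    diffs = [i for i in range(3) if a[i] != b[i]]
    for order in permutations(diffs):
        steps = []
        cur = a
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in table.stop_codons and nxt != b:
                ok = False
            steps.append((cur, nxt))
            cur = nxt
        yield ok, steps


def oracle_differences(a, b, table=_T2):
    if a == b:
        return 0.0, 0.0
    tallies = []
    fallback = []
    for ok, steps in _paths(a, b, table):
        sd = sum(1 for x, y in steps if translate(x, table) == translate(y, table))
        nd = len(steps) - sd
        fallback.append((sd, nd))
        if ok:
            tallies.append((sd, nd))
    use = tallies or fallback
    return (sum(t[0] for t in use) / len(use),
            sum(t[1] for t in use) / len(use))


def oracle_pair_counts(seq_a, seq_b, table=_T2):
    """(S, N, Sd, Nd) over a codon-aligned pair, skipping stop codons."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if ca in table.stop_codons or cb in table.stop_codons:
            continue
        sa, na = oracle_sites(ca, table)
        sb, nb = oracle_sites(cb, table)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = oracle_differences(ca, cb, table)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd
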