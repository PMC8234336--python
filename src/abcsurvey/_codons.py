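"""Genetic-code tables and codon-level bookkeeping.

Everything downstream of codon arithmetic (the substitution simulator and
the Nei–Gojobori estimator) shares these tables so that "synonymous" means
the same thing on both sides of a parameter-recovery test.
Only the standard nuclear code (NCBI table 1) is built in; the table is a
plain dict so an alternative code can be passed through explicitly.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

NUCLEOTIDES = "ACGT"

# NCBI translation table 1 (standard code); '*' marks stop codons.
STANDARD_CODE: dict[str, str] = {}
_BASES_BY_POS = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(product(_BASES_BY_POS, repeat=3)):
    STANDARD_CODE[_b1 + _b2 + _b3] = _AA_TABLE[_i]

SENSE_CODONS = tuple(c for c, aa in STANDARD_CODE.items() if aa != "*")
STOP_CODONS = frozenset(c for c, aa in STANDARD_CODE.items() if aa == "*")


def translate_codon(codon: str, code: dict[str, str] = STANDARD_CODE) -> str:
    return code[codon]


def translate(cds: str, code: dict[str, str] = STANDARD_CODE) -> str:
    """Translate a CDS (length divisible by 3); a terminal stop is dropped."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = [code[cds[i : i + 3]] for i in range(0, len(cds), 3)]
    if aas and aas[-1] == "*":
        aas.pop()
    if "*" in aas:
        raise ValueError(f"internal stop codon at codon index {aas.index('*')}")
    return "".join(aas)


def split_codons(cds: str) -> list[str]:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def single_nt_neighbors(codon: str):
    """All 9 codons one nucleotide away, with the changed position."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, codon[:pos] + nt + codon[pos + 1 :]


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """NG86 synonymous-site count for one codon.

    Each position contributes the fraction of its 3 possible single-nucleotide
    changes that are synonymous; changes creating a stop codon count as
    nonsynonymous (the common NG86 convention — switch by editing the table,
    not a runtime flag, since every cached quantity depends on it).
    """
    aa = STANDARD_CODE[codon]
    if aa == "*":
        raise ValueError("site counting is undefined for stop codons")
    syn = 0
    for _pos, alt in single_nt_neighbors(codon):
        if STANDARD_CODE[alt] == aa:
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """NG86 (Sd, Nd) between two codons by minimal-pathway averaging.

    All orderings of the differing positions are enumerated; each pathway is a
    chain of single-nucleotide steps and each step is scored synonymous or
    nonsynonymous against the codon it leaves. Pathways passing through a stop
    codon are excluded; if every pathway does, all are kept (the standard
    fallback so that Sd + Nd always equals the number of differing positions).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if STANDARD_CODE[nxt] == "*" and nxt != codon_b:
                through_stop = True
            if STANDARD_CODE[nxt] == STANDARD_CODE[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        fallback.append((sd, nd))
        if not through_stop:
            pathways.append((sd, nd))
    chosen = pathways or fallback
    sd = sum(p[0] for p in chosen) / len(chosen)
    nd = sum(p[1] for p in chosen) / len(chosen)
    return sd, nd


def random_sense_codon(rng) -> str:
    return SENSE_CODONS[rng.integers(len(SENSE_CODONS))]


# Reverse-translation table: amino acid -> tuple of codons.
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in STANDARD_CODE.items():
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] += (_codon,)


def reverse_translate(protein: str, rng) -> str:
    """Pick a random synonymous codon for every residue; appends a stop."""
    codons = []
    for aa in protein:
        choices = CODONS_FOR_AA[aa]
        codons.append(choices[rng.integers(len(choices))])
    stops = tuple(sorted(STOP_CODONS))
    codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)
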