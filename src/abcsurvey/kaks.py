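"""Codon-aware pairwise divergence: Nei–Gojobori Ka/Ks and divergence times.

The estimator follows the classic 1986 counting method: fractional
synonymous-site counts per codon, minimal-pathway averaging of the
differences, Jukes–Cantor correction of both proportions, and the
conventional saturation filter (pairs with Ks > 2 are flagged and excluded
from summaries). Divergence time is the standard molecular-clock conversion
T = Ks / (2λ), reported in million years with λ in substitutions per
synonymous site per year (default 6.5e-9, the rate commonly used for
legume nuclear genes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import _codons
from .align import align_pair
from ._codons import pathway_differences, split_codons, syn_site_fraction, translate

DEFAULT_LAMBDA = 6.5e-9
KS_SATURATION = 2.0


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon columns for a gene pair (gap columns removed)."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    dropped_columns: int

    def __len__(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    omega: float | None  # None when Ks == 0 (ratio undefined)
    saturated: bool  # Ks > 2: multiple hits make Ks unreliable
    codon_columns: int


@dataclass(frozen=True)
class DivergenceEstimate:
    T_mya: float
    lam: float


class SaturationError(ValueError):
    """Raised when a JC-corrected proportion reaches the 3/4 singularity."""


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in _codons.STOP_CODONS:
        return cds[:-3]
    return cds


def codon_align(cds_a: str, cds_b: str) -> CodonAlignment:
    """Align two coding sequences at the protein level, then back-translate.

    Columns containing a gap in either row are dropped entirely; no
    partial-codon scoring. Internal stops are rejected up front (translate
    raises naming the codon index).
    """
    cds_a = _strip_terminal_stop(cds_a.upper())
    cds_b = _strip_terminal_stop(cds_b.upper())
    prot_a = translate(cds_a)
    prot_b = translate(cds_b)
    alignment = align_pair(prot_a, prot_b)
    cod_a = split_codons(cds_a)
    cod_b = split_codons(cds_b)
    out_a: list[str] = []
    out_b: list[str] = []
    dropped = 0
    i = j = 0
    for col_a, col_b in zip(alignment.aligned_a, alignment.aligned_b):
        if col_a != "-" and col_b != "-":
            out_a.append(cod_a[i])
            out_b.append(cod_b[j])
        else:
            dropped += 1
        if col_a != "-":
            i += 1
        if col_b != "-":
            j += 1
    return CodonAlignment(tuple(out_a), tuple(out_b), dropped)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"proportion of differences {p:.4f} >= 3/4; Jukes-Cantor distance undefined"
        )
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori Ka/Ks over retained codon columns.

    Site counts are averaged between the two sequences; differences are
    pathway-averaged per codon pair. S + N = 3 × columns by construction.
    """
    n_cols = len(alignment)
    if n_cols == 0:
        raise ValueError("alignment has no retained codon columns")
    s_a = sum(syn_site_fraction(c) for c in alignment.codons_a)
    s_b = sum(syn_site_fraction(c) for c in alignment.codons_b)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_cols - S
    Sd = Nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    omega = (Ka / Ks) if Ks > 0 else None
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        omega=omega, saturated=Ks > KS_SATURATION, codon_columns=n_cols,
    )


def pair_codons_directly(cds_a: str, cds_b: str) -> CodonAlignment:
    """Codon columns by position, for equal-length indel-free CDS pairs.

    Protein-level alignment becomes unreliable below roughly 50% identity
    (spurious gaps scramble the codon correspondence), so when two CDS are
    known to be co-linear — e.g. duplicates evolved without indels — the
    positional pairing is the faithful one.
    """
    cds_a = _strip_terminal_stop(cds_a.upper())
    cds_b = _strip_terminal_stop(cds_b.upper())
    if len(cds_a) != len(cds_b):
        raise ValueError("direct codon pairing requires equal-length CDS")
    translate(cds_a)
    translate(cds_b)
    return CodonAlignment(tuple(split_codons(cds_a)), tuple(split_codons(cds_b)), 0)


def kaks_pair(cds_a: str, cds_b: str, align: bool = True) -> KaKsResult:
    if align:
        return ng86(codon_align(cds_a, cds_b))
    return ng86(pair_codons_directly(cds_a, cds_b))


def divergence_time(ks: float, lam: float = DEFAULT_LAMBDA) -> DivergenceEstimate:
    """T (MYA) = Ks / (2λ) / 1e6."""
    if ks < 0:
        raise ValueError(f"Ks must be non-negative, got {ks}")
    return DivergenceEstimate(T_mya=ks / (2.0 * lam) / 1e6, lam=lam)


def kaks_table(
    pairs: Iterable[tuple[str, str]],
    cds_store: dict[str, str],
    lam: float = DEFAULT_LAMBDA,
) -> pd.DataFrame:
    """Per-pair Ka/Ks + divergence time; saturated rows flagged `discarded`.

    Discarded rows stay in the table (so the filter is auditable) but are
    excluded from any summary computed with :func:`kaks_summary`.
    """
    rows = []
    for gene_a, gene_b in pairs:
        res = kaks_pair(cds_store[gene_a], cds_store[gene_b])
        t = divergence_time(res.Ks, lam)
        rows.append(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "S": res.S,
                "N": res.N,
                "Sd": res.Sd,
                "Nd": res.Nd,
                "Ka": res.Ka,
                "Ks": res.Ks,
                "omega": res.omega,
                "T_mya": t.T_mya,
                "saturated": res.saturated,
                "discarded": res.saturated,
            }
        )
    return pd.DataFrame(rows)


def kaks_summary(table: pd.DataFrame, by: Sequence[str] = ()) -> pd.DataFrame:
    """Min/max/mean of Ks, Ka and T over non-discarded rows."""
    kept = table.loc[~table["discarded"]]
    if len(by):
        grouped = kept.groupby(list(by))
    else:
        grouped = kept.assign(_all="all").groupby("_all")
    return grouped.agg(
        n_pairs=("Ks", "size"),
        ks_min=("Ks", "min"),
        ks_max=("Ks", "max"),
        ks_mean=("Ks", "mean"),
        ka_mean=("Ka", "mean"),
        t_min_mya=("T_mya", "min"),
        t_max_mya=("T_mya", "max"),
        t_mean_mya=("T_mya", "mean"),
    ).reset_index()
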