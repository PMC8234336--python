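"""Nei-Gojobori Ka/Ks: site counting, pathway averaging, JC correction,
saturation filtering and divergence times, checked against a test-local
exhaustive oracle built directly on Biopython's translation table."""

from __future__ import annotations

import math
from itertools import permutations, product

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from abcsurvey._codons import SENSE_CODONS
from abcsurvey.kaks import (
    CodonAlignment,
    SaturationError,
    codon_align,
    divergence_time,
    kaks_pair,
    kaks_summary,
    kaks_table,
    ng86,
    pair_codons_directly,
)

# ---------------------------------------------------------------------------
# independent oracle (Biopython translation, itertools pathway enumeration)


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_fraction(codon: str) -> float:
    syn = 0
    for pos, nt in product(range(3), "ACGT"):
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if _aa(alt) == _aa(codon):
            syn += 1
    return syn / 3.0


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    kept, fallback = [], []
    for order in permutations(positions):
        cur, sd, nd, through_stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*" and nxt != b:
                through_stop = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        fallback.append((sd, nd))
        if not through_stop:
            kept.append((sd, nd))
    chosen = kept or fallback
    return (
        sum(x[0] for x in chosen) / len(chosen),
        sum(x[1] for x in chosen) / len(chosen),
    )


def test_pathway_counts_match_exhaustive_enumeration_over_all_sense_pairs():
    """Sd/Nd and site fractions agree with brute force for all 61x61 pairs."""
    from abcsurvey._codons import pathway_differences, syn_site_fraction

    for codon in SENSE_CODONS:
        assert syn_site_fraction(codon) == pytest.approx(oracle_syn_fraction(codon))
    for a, b in product(SENSE_CODONS, repeat=2):
        sd, nd = pathway_differences(a, b)
        esd, end_ = oracle_differences(a, b)
        assert sd == pytest.approx(esd), (a, b)
        assert nd == pytest.approx(end_), (a, b)
        # conservation: pathway steps account for every differing position
        assert sd + nd == pytest.approx(sum(x != y for x, y in zip(a, b)))


def test_single_codon_phe_leu_pair_counts_and_distances():
    """TTT vs TTA: S averages to 0.5; the one difference is nonsynonymous."""
    r = ng86(CodonAlignment(("TTT",), ("TTA",), 0))
    assert r.S == pytest.approx(0.5)
    assert r.N == pytest.approx(2.5)
    assert (r.Sd, r.Nd) == (0.0, 1.0)
    assert r.pN == pytest.approx(0.4)
    assert r.Ka == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.4))
    assert r.Ks == 0.0
    assert r.omega is None  # Ks = 0: ratio undefined


def test_three_codon_glycine_pair_synonymous_distance():
    """GGT,GGT,GGT vs GGC,GGT,GGT: S=3, Sd=1, Ks=-0.75*ln(5/9), Ka=0."""
    r = ng86(CodonAlignment(("GGT", "GGT", "GGT"), ("GGC", "GGT", "GGT"), 0))
    assert r.S == pytest.approx(3.0)
    assert r.Sd == pytest.approx(1.0)
    assert r.pS == pytest.approx(1 / 3)
    assert r.Ks == pytest.approx(-0.75 * math.log(5 / 9))
    assert r.Ka == 0.0


def test_identical_sequences_have_zero_distances_and_undefined_omega():
    cds = "ATGGCTAAAGGT"
    r = kaks_pair(cds, cds)
    assert r.Ka == 0.0 and r.Ks == 0.0
    assert r.omega is None
    assert not r.saturated


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_ng86_is_symmetric_and_conserves_sites(seed):
    rng = np.random.default_rng(seed)
    codons_a = tuple(SENSE_CODONS[i] for i in rng.integers(61, size=30))
    codons_b = tuple(SENSE_CODONS[i] for i in rng.integers(61, size=30))
    try:
        r_ab = ng86(CodonAlignment(codons_a, codons_b, 0))
        r_ba = ng86(CodonAlignment(codons_b, codons_a, 0))
    except SaturationError:
        return  # random codons can exceed the JC singularity; nothing to check
    assert r_ab.Ks == pytest.approx(r_ba.Ks)
    assert r_ab.Ka == pytest.approx(r_ba.Ka)
    assert r_ab.S + r_ab.N == pytest.approx(3 * 30)


@given(st.floats(0.001, 0.74), st.floats(0.001, 0.74))
@settings(max_examples=50, deadline=None)
def test_jukes_cantor_distance_is_monotone_in_p(p1, p2):
    from abcsurvey.kaks import _jukes_cantor

    lo, hi = sorted((p1, p2))
    assert _jukes_cantor(lo) <= _jukes_cantor(hi)


def test_jc_saturation_raises_beyond_three_quarters():
    # codon pairs chosen so nearly every nonsynonymous site differs
    cols = (("AAA",) * 20, ("CCC",) * 20)
    with pytest.raises(SaturationError):
        ng86(CodonAlignment(*cols, 0))


# ---------------------------------------------------------------------------
# codon alignment


def test_codon_alignment_of_identical_cds_keeps_all_columns():
    cds = "ATGGCTGGTAAACCTTGA"
    al = codon_align(cds, cds)
    assert al.dropped_columns == 0
    assert len(al) == 5  # terminal stop stripped
    assert al.codons_a == al.codons_b


def test_codon_insertion_drops_exactly_one_column():
    a = "ATGGCTGGTAAACCT"
    b = "ATGGCTGAAGGTAAACCT"  # one extra codon (GAA) inserted
    al = codon_align(a, b)
    assert al.dropped_columns == 1
    assert len(al) == 5


def test_internal_stop_is_rejected_with_codon_index():
    with pytest.raises(ValueError, match="codon index 1"):
        codon_align("ATGTAAGGT", "ATGGCTGGT")


def test_direct_pairing_requires_equal_lengths():
    with pytest.raises(ValueError, match="equal-length"):
        pair_codons_directly("ATGGCT", "ATGGCTAAA")


# ---------------------------------------------------------------------------
# divergence time


def test_divergence_time_endpoints_match_clock_formula():
    """T = Ks/(2 lambda)/1e6 with lambda = 6.5e-9 /site/year."""
    assert divergence_time(0.0).T_mya == 0.0
    assert divergence_time(0.013).T_mya == pytest.approx(1.0)
    assert divergence_time(1.5665).T_mya == pytest.approx(120.5, abs=0.05)
    with pytest.raises(ValueError):
        divergence_time(-0.1)


def test_kaks_table_flags_saturated_pairs_and_excludes_them_from_summary(rng):
    from abcsurvey.simulate import evolve_cds_pair

    anc = "".join(SENSE_CODONS[i] for i in rng.integers(61, size=200))
    mild, *_ = evolve_cds_pair(anc, 0.3, 0.2, rng)
    store = {"anc": anc, "mild": mild, "anc2": anc}
    table = kaks_table([("anc", "mild"), ("anc", "anc2")], store)
    assert len(table) == 2
    assert not table["discarded"].any()
    # simulate extreme divergence to trip the Ks > 2 rule
    hot, *_ = evolve_cds_pair(anc, 1.8, 0.1, rng)
    table2 = kaks_table([("anc", "hot"), ("anc", "mild")], {**store, "hot": hot})
    if table2["saturated"].any():
        kept = kaks_summary(table2)
        assert kept["n_pairs"].iloc[0] == int((~table2["discarded"]).sum())


def test_purifying_selection_keeps_omega_below_one(rng):
    """Pairs simulated at omega=0.2 should estimate omega < 1 almost always."""
    from abcsurvey.simulate import evolve_cds_pair

    below = 0
    n = 100
    for _ in range(n):
        anc = "".join(SENSE_CODONS[i] for i in rng.integers(61, size=300))
        desc, *_ = evolve_cds_pair(anc, 0.5, 0.2, rng)
        r = kaks_pair(anc, desc, align=False)
        if r.omega is not None and r.omega < 1:
            below += 1
    assert below >= 95
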