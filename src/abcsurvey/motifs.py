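"""Conserved-motif and domain-architecture scanning for ABC transporters.

Family membership rests on the nucleotide-binding domain's diagnostic
motifs (Walker A, Walker B, ABC signature, Q-loop, H-loop) plus clusters of
predicted transmembrane helices. The scan is regular-expression based:
Walker A is the classical G-x-x-G-x-G-K-[S/T]; Walker B and the signature
use conventional consensus renderings (hydrophobic set LIVMF, signature
LSGGQ-like). An 'X' in a protein never matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

MOTIF_PATTERNS: dict[str, str] = {
    "walkerA": r"G[^X]{2}G[^X]GK[ST]",
    "walkerB": r"[RK][^X]{3}G[^X]{3}[LIVMF][LIVMF][LIVMF]",
    "abc_signature": r"[LIVMFY]S[SG]G[^X][QRKE]",
    "q_loop": r"Q[^X]{2}[LIVMF]SGG",
    "h_loop": r"H[^X][LIVMF]H",
}

TOPOLOGY_PATTERNS = {
    ("T", "N", "T", "N"): "full_forward",
    ("N", "T", "N", "T"): "full_reverse",
    ("T", "N"): "half_forward",
    ("N", "T"): "half_reverse",
    ("N",): "soluble",
    ("T",): "tmd_only",
}


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 0-based
    end: int  # half-open
    matched: str


@dataclass(frozen=True)
class DomainSegment:
    kind: str  # 'NBD' or 'TMD'
    start: int
    end: int


@dataclass(frozen=True)
class DomainArchitecture:
    segments: tuple[DomainSegment, ...]
    topology: str
    helices: tuple[tuple[int, int], ...]
    motif_hits: tuple[MotifHit, ...]

    @property
    def n_nbd(self) -> int:
        return sum(1 for s in self.segments if s.kind == "NBD")

    @property
    def n_tmd(self) -> int:
        return sum(1 for s in self.segments if s.kind == "TMD")


def scan_motifs(protein: str) -> list[MotifHit]:
    """All non-overlapping occurrences of each motif, leftmost first."""
    protein = protein.upper()
    hits: list[MotifHit] = []
    for name, pattern in MOTIF_PATTERNS.items():
        for m in re.finditer(pattern, protein):
            hits.append(MotifHit(name, m.start(), m.end(), m.group()))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def predict_tm_helices(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    max_len: int = 30,
) -> list[tuple[int, int]]:
    """Transmembrane helices by windowed Kyte-Doolittle hydropathy.

    Maximal runs of window centers whose mean hydropathy reaches the
    threshold become helix segments; runs shorter than ``min_len`` are
    widened symmetrically (membrane-spanning helices need ~15+ residues)
    and runs longer than ``max_len`` are split evenly.
    """
    if window % 2 == 0 or window < 7:
        raise ValueError("window must be odd and >= 7")
    protein = protein.upper()
    n = len(protein)
    if n < window:
        return []
    values = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein]
    half = window // 2
    # rolling mean at each center position
    csum = [0.0]
    for v in values:
        csum.append(csum[-1] + v)
    centers = []
    for c in range(half, n - half):
        mean = (csum[c + half + 1] - csum[c - half]) / window
        if mean >= threshold:
            centers.append(c)
    # group consecutive centers into runs
    runs: list[tuple[int, int]] = []
    for c in centers:
        if runs and c == runs[-1][1]:
            runs[-1] = (runs[-1][0], c + 1)
        else:
            runs.append((c, c + 1))
    helices: list[tuple[int, int]] = []
    for s, e in runs:
        length = e - s
        if length < min_len:
            pad = (min_len - length + 1) // 2
            s = max(0, s - pad)
            e = min(n, s + min_len)
            s = max(0, e - min_len)
            length = e - s
        if length > max_len:
            k = -(-length // max_len)  # ceil
            step = length / k
            for j in range(k):
                helices.append((s + round(j * step), s + round((j + 1) * step)))
        else:
            helices.append((s, e))
    return helices


def call_architecture(
    protein: str,
    nbd_window: int = 250,
    tmd_span: int = 350,
    min_helices: int = 4,
    tm_kwargs: dict | None = None,
) -> DomainArchitecture | None:
    """Domain architecture, or None when no NBD and no TMD is found.

    An NBD is anchored on a Walker A motif with an ABC signature or Walker B
    co-occurring within ``nbd_window`` residues; a TMD is a cluster of at
    least ``min_helices`` predicted helices spanning at most ``tmd_span``
    residues (ABC transporter TMDs carry 4-6 helices). Candidates with at
    least one NBD are family candidates; TMD-only architectures are reported
    but acceptance is deferred to reference-panel comparison (ABCI-style
    members can lack the NBD).
    """
    hits = scan_motifs(protein)
    walker_a = [h for h in hits if h.motif_name == "walkerA"]
    partners = [h for h in hits if h.motif_name in ("abc_signature", "walkerB")]
    nbds: list[DomainSegment] = []
    for wa in walker_a:
        near = [
            p for p in partners
            if abs(p.start - wa.start) <= nbd_window and p.start != wa.start
        ]
        if near:
            lo = min([wa.start] + [p.start for p in near])
            hi = max([wa.end] + [p.end for p in near])
            nbds.append(DomainSegment("NBD", lo, hi))
    # merge overlapping NBD calls (several Walker A copies in one domain)
    nbds.sort(key=lambda s: s.start)
    merged: list[DomainSegment] = []
    for seg in nbds:
        if merged and seg.start <= merged[-1].end:
            merged[-1] = DomainSegment("NBD", merged[-1].start, max(merged[-1].end, seg.end))
        else:
            merged.append(seg)
    nbds = merged

    helices = predict_tm_helices(protein, **(tm_kwargs or {}))
    tmds: list[DomainSegment] = []
    cluster: list[tuple[int, int]] = []
    for helix in helices:
        if cluster and helix[1] - cluster[0][0] > tmd_span:
            if len(cluster) >= min_helices:
                tmds.append(DomainSegment("TMD", cluster[0][0], cluster[-1][1]))
            cluster = []
        cluster.append(helix)
    if len(cluster) >= min_helices:
        tmds.append(DomainSegment("TMD", cluster[0][0], cluster[-1][1]))

    segments = tuple(sorted(nbds + tmds, key=lambda s: s.start))
    if not segments:
        return None
    pattern = tuple("N" if s.kind == "NBD" else "T" for s in segments)
    topology = TOPOLOGY_PATTERNS.get(pattern)
    if topology is None:
        # non-canonical arrangement: classify by content
        if "N" not in pattern:
            topology = "tmd_only"
        elif "T" not in pattern:
            topology = "soluble"
        elif pattern.count("N") >= 2 and pattern.count("T") >= 2:
            topology = "full_forward" if pattern[0] == "T" else "full_reverse"
        else:
            topology = "half_forward" if pattern[0] == "T" else "half_reverse"
    return DomainArchitecture(
        segments=segments,
        topology=topology,
        helices=tuple(helices),
        motif_hits=tuple(hits),
    )
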