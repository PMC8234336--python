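"""Homolog pairs, collinear-block detection, and duplicate-type calls.

The classifier mirrors the MCScanX scheme the field uses for gene-family
surveys: genes anchoring a collinear (syntenic) block are WGD/segmental
duplicates; otherwise a homolog at adjacent gene rank on the same
chromosome makes a tandem pair, within a small rank window a proximal
pair, anywhere else a dispersed duplicate; genes with no homolog at all
are singletons. Distances are gene-rank (ordinal) distances, robust to
intergenic length. Precedence: WGD > tandem > proximal > dispersed.

Blocks are found by dynamic-programming chaining of homolog anchors in
gene-rank coordinates: within a chromosome pair, the longest chain with
strictly monotone ranks on both axes (increasing, or decreasing on the
second axis for inverted blocks) and rank gaps at most ``max_gap`` wins;
chains shorter than ``min_anchors`` are discarded; anchors join at most
one block, best chain first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import align_pair
from .genome import Genome, natural_key

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_TOP_K = 5
DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GAP = 25
DEFAULT_PROXIMAL_WINDOW = 10
DEFAULT_TANDEM_GAP = 1

DUPLICATE_TYPES = ("singleton", "dispersed", "proximal", "tandem", "wgd_segmental")


@dataclass(frozen=True)
class HomologPair:
    gene_a: str  # canonical: gene_a < gene_b
    gene_b: str
    score: float
    identity_pct: float
    rank: int  # rank of this partner among the query's hits (1 = best)


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int


@dataclass(frozen=True)
class CollinearBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    anchors: tuple[Anchor, ...]
    orientation: str  # 'same' or 'inverted'

    @property
    def score(self) -> int:
        return len(self.anchors)


def pairwise_homology(
    proteins: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    top_k: int = DEFAULT_TOP_K,
) -> list[HomologPair]:
    """Best-scoring homolog partners per gene by global alignment.

    All-vs-all; for each gene up to ``top_k`` partners with percent identity
    at least ``min_identity``. Stored symmetrically with gene_a < gene_b.
    """
    ids = sorted(proteins)
    if len(ids) < 2:
        return []
    cache: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            res = align_pair(proteins[a], proteins[b])
            if res.identity_pct >= min_identity:
                cache[(a, b)] = (res.score, res.identity_pct)
    kept: dict[tuple[str, str], HomologPair] = {}
    for query in ids:
        partners = []
        for (a, b), (score, ident) in cache.items():
            if query in (a, b):
                partners.append((a if b == query else b, score, ident))
        partners.sort(key=lambda t: (-t[1], t[0]))
        for rank, (partner, score, ident) in enumerate(partners[:top_k], start=1):
            key = (min(query, partner), max(query, partner))
            prev = kept.get(key)
            if prev is None or rank < prev.rank:
                kept[key] = HomologPair(key[0], key[1], score, ident, rank)
    return sorted(kept.values(), key=lambda p: (p.gene_a, p.gene_b))


def pairs_to_anchors(
    pairs: Iterable[HomologPair],
    genome_a: Genome,
    genome_b: Genome | None = None,
    tandem_gap: int = DEFAULT_TANDEM_GAP,
) -> list[Anchor]:
    """Map homolog pairs to gene-rank coordinates.

    For a self-comparison (genome_b None) the anchor is canonicalized with
    (chrom_a, rank_a) <= (chrom_b, rank_b) and within-tandem-array anchors
    (same chromosome, rank distance <= tandem_gap) are dropped before
    chaining, as is conventional.
    """
    self_compare = genome_b is None
    genome_b = genome_b or genome_a
    anchors = []
    for p in pairs:
        if self_compare:
            ga = genome_a.genes[p.gene_a]
            gb = genome_a.genes[p.gene_b]
        else:
            if p.gene_a in genome_a.genes:
                ga, gb = genome_a.genes[p.gene_a], genome_b.genes[p.gene_b]
            else:
                ga, gb = genome_a.genes[p.gene_b], genome_b.genes[p.gene_a]
        a = (ga.chromosome, ga.gene_rank, ga.gene_id)
        b = (gb.chromosome, gb.gene_rank, gb.gene_id)
        if self_compare:
            if (natural_key(a[0]), a[1]) > (natural_key(b[0]), b[1]):
                a, b = b, a
            if a[0] == b[0] and abs(a[1] - b[1]) <= tandem_gap:
                continue
        anchors.append(Anchor(a[2], b[2], a[0], b[0], a[1], b[1]))
    return anchors


def _best_chain(
    anchors: Sequence[Anchor], max_gap: int, direction: int
) -> list[int]:
    """Longest monotone chain by DP; direction +1 (same) or -1 (inverted)."""
    order = sorted(
        range(len(anchors)),
        key=lambda k: (anchors[k].rank_a, direction * anchors[k].rank_b),
    )
    best_len = [1] * len(anchors)
    prev = [-1] * len(anchors)
    for oi, k in enumerate(order):
        ak = anchors[k]
        for oj in range(oi):
            j = order[oj]
            aj = anchors[j]
            gap_a = ak.rank_a - aj.rank_a
            gap_b = direction * (ak.rank_b - aj.rank_b)
            if 0 < gap_a <= max_gap and 0 < gap_b <= max_gap:
                if best_len[j] + 1 > best_len[k]:
                    best_len[k] = best_len[j] + 1
                    prev[k] = j
    if not anchors:
        return []
    end = max(range(len(anchors)), key=lambda k: best_len[k])
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def detect_collinear_blocks(
    anchors: Sequence[Anchor],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[CollinearBlock]:
    """Greedy best-chain-first extraction of collinear blocks per chromosome pair."""
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: list[CollinearBlock] = []
    block_id = 0
    for (ca, cb), group in sorted(by_pair.items()):
        remaining = list(group)
        while True:
            chain_same = _best_chain(remaining, max_gap, +1)
            chain_inv = _best_chain(remaining, max_gap, -1)
            if len(chain_same) >= len(chain_inv):
                chain, orientation = chain_same, "same"
            else:
                chain, orientation = chain_inv, "inverted"
            if len(chain) < min_anchors:
                break
            chosen = tuple(remaining[i] for i in chain)
            blocks.append(CollinearBlock(block_id, ca, cb, chosen, orientation))
            block_id += 1
            chain_set = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in chain_set]
    return blocks


@dataclass(frozen=True)
class DuplicateCall:
    gene_id: str
    dup_type: str
    evidence: str


def classify_duplicates(
    gene_ids: Iterable[str],
    genome: Genome,
    pairs: Sequence[HomologPair],
    blocks: Sequence[CollinearBlock],
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
    tandem_gap: int = DEFAULT_TANDEM_GAP,
) -> tuple[list[DuplicateCall], dict[str, int]]:
    """One duplicate type per gene, with WGD > tandem > proximal > dispersed
    > singleton precedence; the returned counts partition the gene set."""
    gene_ids = sorted(set(gene_ids))
    for p in pairs:
        for g in (p.gene_a, p.gene_b):
            if g not in genome.genes:
                raise ValueError(f"pair references unknown gene {g}")
    in_block: dict[str, int] = {}
    for block in sorted(blocks, key=lambda b: -b.score):
        for anchor in block.anchors:
            for g in (anchor.gene_a, anchor.gene_b):
                in_block.setdefault(g, block.block_id)
    partners: dict[str, list[str]] = {g: [] for g in gene_ids}
    for p in pairs:
        if p.gene_a in partners:
            partners[p.gene_a].append(p.gene_b)
        if p.gene_b in partners:
            partners[p.gene_b].append(p.gene_a)
    calls: list[DuplicateCall] = []
    counts = {t: 0 for t in DUPLICATE_TYPES}
    for gid in gene_ids:
        g = genome.genes[gid]
        if gid in in_block:
            dup_type, evidence = "wgd_segmental", f"block:{in_block[gid]}"
        else:
            rank_dists = []
            for partner in partners[gid]:
                pg = genome.genes.get(partner)
                if pg is not None and pg.chromosome == g.chromosome:
                    rank_dists.append((abs(pg.gene_rank - g.gene_rank), partner))
            rank_dists.sort()
            if rank_dists and rank_dists[0][0] <= tandem_gap:
                dup_type, evidence = "tandem", f"adjacent:{rank_dists[0][1]}"
            elif rank_dists and rank_dists[0][0] <= proximal_window:
                dup_type, evidence = (
                    "proximal",
                    f"within{rank_dists[0][0]}:{rank_dists[0][1]}",
                )
            elif partners[gid]:
                dup_type, evidence = "dispersed", f"homolog:{partners[gid][0]}"
            else:
                dup_type, evidence = "singleton", ""
        counts[dup_type] += 1
        calls.append(DuplicateCall(gid, dup_type, evidence))
    return calls, counts


def tandem_pair_count(
    calls: Sequence[DuplicateCall],
    genome: Genome,
    pairs: Sequence[HomologPair],
    tandem_gap: int = DEFAULT_TANDEM_GAP,
) -> int:
    """Number of adjacent homolog pairs among tandem-called genes."""
    tandem_genes = {c.gene_id for c in calls if c.dup_type == "tandem"}
    n = 0
    for p in pairs:
        if p.gene_a in tandem_genes and p.gene_b in tandem_genes:
            ga, gb = genome.genes[p.gene_a], genome.genes[p.gene_b]
            if ga.chromosome == gb.chromosome and abs(ga.gene_rank - gb.gene_rank) <= tandem_gap:
                n += 1
    return n


def calls_table(calls: Sequence[DuplicateCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


# ---------------------------------------------------------------------------
# Interspecies synteny


def interspecies_synteny(
    genome_a: Genome,
    genome_b: Genome,
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    family_a: set[str],
    family_b: set[str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    top_k: int = DEFAULT_TOP_K,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> dict:
    """Cross-genome collinear blocks and family ortholog pairs within them.

    Returns blocks, the family pairs inside blocks, and a cardinality
    report (one-to-one / one-to-many / many-to-one) over those pairs.
    """
    cross: list[HomologPair] = []
    ids_a = sorted(proteins_a)
    ids_b = sorted(proteins_b)
    per_query: dict[str, list[tuple[float, float, str]]] = {a: [] for a in ids_a}
    for a in ids_a:
        for b in ids_b:
            res = align_pair(proteins_a[a], proteins_b[b])
            if res.identity_pct >= min_identity:
                per_query[a].append((res.score, res.identity_pct, b))
    for a, hits in per_query.items():
        hits.sort(key=lambda t: (-t[0], t[2]))
        for rank, (score, ident, b) in enumerate(hits[:top_k], start=1):
            cross.append(HomologPair(a, b, score, ident, rank))
    anchors = pairs_to_anchors(cross, genome_a, genome_b)
    blocks = detect_collinear_blocks(anchors, min_anchors, max_gap)
    family_pairs = []
    for block in blocks:
        for anchor in block.anchors:
            if anchor.gene_a in family_a and anchor.gene_b in family_b:
                family_pairs.append((anchor.gene_a, anchor.gene_b, block.block_id))
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for a, b, _ in family_pairs:
        count_a[a] = count_a.get(a, 0) + 1
        count_b[b] = count_b.get(b, 0) + 1
    cardinality = []
    for a, b, block_id in family_pairs:
        if count_a[a] == 1 and count_b[b] == 1:
            kind = "one_to_one"
        elif count_a[a] == 1 and count_b[b] > 1:
            # several genome-A genes anchor the same genome-B gene
            kind = "many_to_one"
        elif count_a[a] > 1 and count_b[b] == 1:
            kind = "one_to_many"
        else:
            kind = "many_to_many"
        cardinality.append(
            {"gene_a": a, "gene_b": b, "block_id": block_id, "cardinality": kind}
        )
    return {
        "blocks": blocks,
        "family_pairs": family_pairs,
        "cardinality": pd.DataFrame(
            cardinality, columns=["gene_a", "gene_b", "block_id", "cardinality"]
        ),
    }
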