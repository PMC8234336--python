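"""Family-member identification, subfamily assignment and naming.

Candidates are proteins whose domain architecture carries at least one
nucleotide-binding domain; TMD-only architectures are kept only when their
nearest labeled reference is an ABCI-style (TMD-only lineage) protein, the
way ALS3-like transporters enter the family despite lacking an NBD.
Subfamilies come from the nearest reference under global-alignment
p-distance, with a neighbor-joining tree over candidates plus references
for context. Final names number members within each subfamily along the
genome (natural chromosome order, then start coordinate).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .align import align_pair
from .genome import Genome, natural_key
from .motifs import DomainArchitecture, call_architecture
from .phylo import TreeNode, neighbor_joining
from .properties import protein_properties
from .simulate import CANONICAL_TOPOLOGY

SUBFAMILIES = tuple(sorted(CANONICAL_TOPOLOGY))  # A..G, I


@dataclass(frozen=True)
class ReferenceProtein:
    ref_id: str
    subfamily: str
    sequence: str


@dataclass(frozen=True)
class SubfamilyAssignment:
    gene_id: str
    subfamily: str
    best_reference: str
    identity_pct: float
    distance: float
    tie: bool  # nearest-reference distance tied; earliest panel entry kept
    topology: str
    topology_consistent: bool
    name: str = ""


class PanelError(ValueError):
    pass


def read_reference_panel(path) -> list[ReferenceProtein]:
    """FASTA with ``subfamily=<tag>`` in the description."""
    panel = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = re.search(r"subfamily=(\w+)", rec.description)
        if not m:
            raise PanelError(f"reference {rec.id} lacks a subfamily= tag")
        panel.append(ReferenceProtein(rec.id, m.group(1), str(rec.seq)))
    return panel


def detect_candidates(
    proteins: dict[str, str],
    panel: list[ReferenceProtein] | None = None,
    tmd_only_min_identity: float = 40.0,
) -> dict[str, DomainArchitecture]:
    """Architecture-validated family candidates.

    Accepts any protein with >= 1 NBD. A TMD-only architecture is accepted
    only when a panel is given and its nearest reference is a TMD-only
    subfamily-I protein at sufficient identity.
    """
    accepted: dict[str, DomainArchitecture] = {}
    for gene_id, seq in proteins.items():
        arch = call_architecture(seq)
        if arch is None:
            continue
        if arch.n_nbd >= 1:
            accepted[gene_id] = arch
        elif panel:
            best = None
            for ref in panel:
                ident = align_pair(seq, ref.sequence).identity_pct
                if best is None or ident > best[1]:
                    best = (ref, ident)
            if (
                best is not None
                and best[1] >= tmd_only_min_identity
                and best[0].subfamily == "I"
            ):
                accepted[gene_id] = arch
    return accepted


def assign_subfamily(
    candidates: dict[str, str],
    panel: list[ReferenceProtein],
    architectures: dict[str, DomainArchitecture] | None = None,
    build_tree: bool = True,
) -> tuple[list[SubfamilyAssignment], TreeNode | None]:
    """Nearest-reference subfamily for each candidate + an NJ tree.

    The tree spans candidates and references on p-distances from global
    pairwise alignment. The topology-consistency flag compares each
    candidate's scanned topology against its subfamily's canonical one.
    """
    if not panel:
        raise PanelError("reference panel is empty")
    covered = {r.subfamily for r in panel}
    missing = set(SUBFAMILIES) - covered
    if missing:
        raise PanelError(f"panel missing subfamilies: {sorted(missing)}")
    architectures = architectures or {}
    assignments: list[SubfamilyAssignment] = []
    cand_ids = sorted(candidates)
    dist_to_refs: dict[str, list[float]] = {}
    for gene_id in cand_ids:
        seq = candidates[gene_id]
        dists = [align_pair(seq, ref.sequence).p_distance for ref in panel]
        dist_to_refs[gene_id] = dists
        best_idx = int(np.argmin(dists))
        best = dists[best_idx]
        tie = sum(1 for x in dists if abs(x - best) < 1e-12) > 1
        ref = panel[best_idx]
        arch = architectures.get(gene_id)
        topology = arch.topology if arch else "unknown"
        canonical = CANONICAL_TOPOLOGY.get(ref.subfamily)
        assignments.append(
            SubfamilyAssignment(
                gene_id=gene_id,
                subfamily=ref.subfamily,
                best_reference=ref.ref_id,
                identity_pct=round(100.0 * (1.0 - best), 2),
                distance=best,
                tie=tie,
                topology=topology,
                topology_consistent=(topology == canonical),
            )
        )
    tree = None
    if build_tree and len(cand_ids) + len(panel) >= 3:
        labels = cand_ids + [r.ref_id for r in panel]
        n = len(labels)
        d = np.zeros((n, n))
        nc = len(cand_ids)
        for i, gid in enumerate(cand_ids):
            for j in range(len(panel)):
                d[i, nc + j] = d[nc + j, i] = dist_to_refs[gid][j]
        for i in range(nc):
            for j in range(i + 1, nc):
                d[i, j] = d[j, i] = align_pair(
                    candidates[cand_ids[i]], candidates[cand_ids[j]]
                ).p_distance
        for i in range(len(panel)):
            for j in range(i + 1, len(panel)):
                d[nc + i, nc + j] = d[nc + j, nc + i] = align_pair(
                    panel[i].sequence, panel[j].sequence
                ).p_distance
        tree = neighbor_joining(d, labels)
    return assignments, tree


def name_members(
    assignments: list[SubfamilyAssignment],
    genome: Genome,
    prefix: str = "fam",
) -> list[SubfamilyAssignment]:
    """Number members within each subfamily by chromosomal position.

    Ordering is (natural chromosome order, start coordinate); names are
    dense 1..n within a subfamily and independent of input order.
    """
    ids = [a.gene_id for a in assignments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in assignments")
    def sort_key(a: SubfamilyAssignment):
        g = genome.genes[a.gene_id]
        return (natural_key(g.chromosome), g.start, g.gene_id)

    named: list[SubfamilyAssignment] = []
    for subfamily in sorted({a.subfamily for a in assignments}):
        members = sorted(
            (a for a in assignments if a.subfamily == subfamily), key=sort_key
        )
        for k, a in enumerate(members, start=1):
            named.append(
                SubfamilyAssignment(
                    **{**a.__dict__, "name": f"{prefix}{subfamily}{k}"}
                )
            )
    named.sort(key=lambda a: a.name)
    return named


def members_table(
    assignments: list[SubfamilyAssignment],
    genome: Genome,
    proteins: dict[str, str],
) -> pd.DataFrame:
    rows = []
    for a in assignments:
        g = genome.genes[a.gene_id]
        props = protein_properties(proteins[a.gene_id])
        rows.append(
            {
                "name": a.name or a.gene_id,
                "gene_id": a.gene_id,
                "subfamily": a.subfamily,
                "chromosome": g.chromosome,
                "start": g.start + 1,  # 1-based for reporting
                "end": g.end,
                "strand": g.strand,
                "topology": a.topology,
                "topology_consistent": a.topology_consistent,
                "length_aa": props.length,
                "mw_kda": round(props.molecular_weight / 1000.0, 2),
                "pi": round(props.isoelectric_point, 2),
                "best_reference": a.best_reference,
                "identity_pct": a.identity_pct,
            }
        )
    return pd.DataFrame(rows)
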