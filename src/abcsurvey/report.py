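"""Survey orchestration and the machine-readable summary report.

`run_survey` wires the stages in dependency order — identification →
structure/chromosome statistics → duplication typing → Ka/Ks and
divergence times → expression classification — and emits a report whose
every percentage recomputes exactly from its counts (audited at build
time). Printed shares use half-up decimal rounding, the convention behind
figures like 69.41% or 0.296% in family-survey papers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import duplication as dup
from . import expression as expr
from .genome import (
    Genome,
    chromosome_distribution,
    read_genome,
    structure_stats,
    structure_summary,
    terminal_share_pct,
)
from .identify import (
    assign_subfamily,
    detect_candidates,
    members_table,
    name_members,
    read_reference_panel,
)
from .kaks import DEFAULT_LAMBDA, kaks_summary, kaks_table


def report_shares(
    counts: Mapping[str, int] | Sequence[int], total: int, decimals: int = 2
) -> dict[str, float] | list[float]:
    """Percentage shares, half-up rounded: share = round(100*count/total)."""
    if total <= 0:
        raise ValueError("total must be positive")

    def one(count: int) -> float:
        if count > total:
            raise ValueError(f"count {count} exceeds total {total}")
        quantum = Decimal(1).scaleb(-decimals)
        return float(
            (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
                quantum, rounding=ROUND_HALF_UP
            )
        )

    if isinstance(counts, Mapping):
        return {k: one(v) for k, v in counts.items()}
    return [one(v) for v in counts]


@dataclass
class SurveyReport:
    member_count: int
    subfamily_counts: dict[str, int]
    subfamily_shares_pct: dict[str, float]
    chromosome_counts: dict[str, int]
    chromosome_shares_pct: dict[str, float]
    terminal_share_pct: float | None
    duplication_counts: dict[str, int]
    duplication_shares_pct: dict[str, float]
    tandem_pair_count: int
    segmental_pair_count: int
    ks_ranges: dict[str, dict[str, float]]
    expression_counts: dict[str, int] | None
    utr_fraction_pct: float
    family_share_of_genome_pct: float | None
    parameters: dict = field(default_factory=dict)

    def audit(self) -> None:
        """Every share must recompute exactly from its counts."""
        checks = [
            (self.subfamily_counts, self.subfamily_shares_pct, 2),
            (self.duplication_counts, self.duplication_shares_pct, 2),
        ]
        for counts, shares, decimals in checks:
            total = sum(counts.values())
            if total:
                recomputed = report_shares(counts, total, decimals)
                if recomputed != shares:
                    raise AssertionError("share table does not recompute from counts")
        if sum(self.subfamily_counts.values()) != self.member_count:
            raise AssertionError("subfamily counts do not sum to member count")
        if sum(self.duplication_counts.values()) != self.member_count:
            raise AssertionError("duplication counts do not sum to member count")

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(asdict(self), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_survey(
    gff3_path,
    protein_path,
    cds_path,
    panel_path,
    tpm_path=None,
    out_dir=None,
    total_annotated_genes: int | None = None,
    terminal_fraction: float = 0.25,
    min_identity: float = dup.DEFAULT_MIN_IDENTITY,
    top_k: int = dup.DEFAULT_TOP_K,
    min_anchors: int = dup.DEFAULT_MIN_ANCHORS,
    max_gap: int = dup.DEFAULT_MAX_GAP,
    proximal_window: int = dup.DEFAULT_PROXIMAL_WINDOW,
    tandem_gap: int = dup.DEFAULT_TANDEM_GAP,
    lam: float = DEFAULT_LAMBDA,
    tau: float = 0.0,
) -> SurveyReport:
    """Run the full survey and return the audited report.

    When ``out_dir`` is given, each stage also writes its TSV output there
    (members, structure stats, chromosome distribution, duplicates, blocks,
    Ka/Ks table, expression profiles, Newick tree, report.json).
    """
    genome = read_genome(gff3_path, protein_path, cds_path)
    panel = read_reference_panel(panel_path)
    proteins = {gid: g.protein for gid, g in genome.genes.items() if g.protein}

    architectures = detect_candidates(proteins, panel)
    candidates = {gid: proteins[gid] for gid in architectures}
    assignments, tree = assign_subfamily(candidates, panel, architectures)
    assignments = name_members(assignments, genome)
    members = members_table(assignments, genome, proteins)
    member_ids = sorted(candidates)
    member_genome = Genome(
        {gid: genome.genes[gid] for gid in member_ids}, genome.chromosome_lengths
    )
    # structure + chromosome statistics over family members (ranks for
    # duplication typing use the FULL gene complement, so rank gaps mean
    # real intervening genes)
    stats = structure_stats(genome.genes[gid] for gid in member_ids)
    struct = structure_summary(stats)
    chrom_dist = chromosome_distribution(member_genome, terminal_fraction)

    pairs = dup.pairwise_homology(candidates, min_identity, top_k)
    anchors = dup.pairs_to_anchors(pairs, genome, tandem_gap=tandem_gap)
    blocks = dup.detect_collinear_blocks(anchors, min_anchors, max_gap)
    calls, dup_counts = dup.classify_duplicates(
        member_ids, genome, pairs, blocks, proximal_window, tandem_gap
    )
    n_tandem_pairs = dup.tandem_pair_count(calls, genome, pairs, tandem_gap)
    block_gene_pairs = {
        (a.gene_a, a.gene_b) for b in blocks for a in b.anchors
    }
    n_segmental_pairs = sum(
        1
        for p in pairs
        if (p.gene_a, p.gene_b) in block_gene_pairs
        or (p.gene_b, p.gene_a) in block_gene_pairs
    )

    cds_store = {gid: genome.genes[gid].cds for gid in member_ids}
    type_by_gene = {c.gene_id: c.dup_type for c in calls}
    kaks_pairs = [(p.gene_a, p.gene_b) for p in pairs]
    kaks = kaks_table(kaks_pairs, cds_store, lam)
    if len(kaks):
        kaks["dup_type"] = [
            type_by_gene.get(a, "") if type_by_gene.get(a) == type_by_gene.get(b)
            else "mixed"
            for a, b in zip(kaks["gene_a"], kaks["gene_b"])
        ]
    ks_ranges: dict[str, dict[str, float]] = {}
    if len(kaks):
        summary = kaks_summary(kaks, by=("dup_type",))
        for row in summary.itertuples():
            ks_ranges[row.dup_type] = {
                "n_pairs": int(row.n_pairs),
                "ks_min": round(float(row.ks_min), 4),
                "ks_max": round(float(row.ks_max), 4),
                "t_min_mya": round(float(row.t_min_mya), 1),
                "t_max_mya": round(float(row.t_max_mya), 1),
                "t_mean_mya": round(float(row.t_mean_mya), 1),
            }

    expression_counts = None
    profiles = None
    if tpm_path is not None:
        matrix = expr.load_tpm(tpm_path)
        profiles, expression_counts = expr.classify_expression(matrix, tau)

    subfamily_counts = {
        s: int((members["subfamily"] == s).sum())
        for s in sorted(members["subfamily"].unique())
    }
    chromosome_counts = dict(
        zip(chrom_dist["chromosome"], chrom_dist["n_genes"].astype(int))
    )
    n_members = len(member_ids)
    report = SurveyReport(
        member_count=n_members,
        subfamily_counts=subfamily_counts,
        subfamily_shares_pct=report_shares(subfamily_counts, n_members, 2),
        chromosome_counts=chromosome_counts,
        chromosome_shares_pct=report_shares(chromosome_counts, n_members, 1),
        terminal_share_pct=terminal_share_pct(chrom_dist),
        duplication_counts=dup_counts,
        duplication_shares_pct=report_shares(dup_counts, n_members, 2),
        tandem_pair_count=n_tandem_pairs,
        segmental_pair_count=n_segmental_pairs,
        ks_ranges=ks_ranges,
        expression_counts=expression_counts,
        utr_fraction_pct=struct.get("utr_fraction_pct", 0.0),
        family_share_of_genome_pct=(
            report_shares({"family": n_members}, total_annotated_genes, 3)["family"]
            if total_annotated_genes
            else None
        ),
        parameters={
            "terminal_fraction": terminal_fraction,
            "min_identity": min_identity,
            "top_k": top_k,
            "min_anchors": min_anchors,
            "max_gap": max_gap,
            "proximal_window": proximal_window,
            "tandem_gap": tandem_gap,
            "lambda": lam,
            "tau": tau,
        },
    )
    report.audit()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        members.to_csv(out / "members.tsv", sep="\t", index=False)
        stats.to_csv(out / "structure_stats.tsv", sep="\t", index=False)
        chrom_dist.to_csv(out / "chromosome_distribution.tsv", sep="\t", index=False)
        dup.calls_table(calls).to_csv(out / "duplicates.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "block_id": b.block_id,
                    "chrom_a": b.chrom_a,
                    "chrom_b": b.chrom_b,
                    "orientation": b.orientation,
                    "n_anchors": b.score,
                    "anchors": ";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors),
                }
                for b in blocks
            ]
        ).to_csv(out / "blocks.tsv", sep="\t", index=False)
        kaks.to_csv(out / "kaks.tsv", sep="\t", index=False)
        if profiles is not None:
            profiles.to_csv(out / "expression_profiles.tsv", sep="\t")
        if tree is not None:
            (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        report.to_json(out / "report.json")
    return report
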