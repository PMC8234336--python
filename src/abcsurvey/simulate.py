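"""Synthetic genomes, reference panels, expression matrices and qPCR tables.

Every downstream stage of the survey has a parameter-recovery test against
data produced here, so the generator carries explicit ground truth:

* gene models with exons/introns/UTRs written as GFF3 + FASTA;
* planted duplications (tandem / proximal / dispersed / segmental) whose
  copies are evolved from a common ancestor at a specified synonymous
  divergence Ks and selection ratio omega = Ka/Ks;
* family genes built around real ABC-transporter architecture (Walker A/B
  and signature motifs in nucleotide-binding domains, hydrophobic
  transmembrane helix clusters) so the identification stage sees authentic
  domain structure, while background genes are random sense codons;
* expression matrices with known ubiquitous / silent / tissue-specific /
  intermediate genes;
* Ct tables following the 2^-ddCt model with Gaussian replicate noise.

All randomness flows from one integer seed through a single numpy
Generator; identical config + seed gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._codons import (
    SENSE_CODONS,
    STANDARD_CODE,
    STOP_CODONS,
    reverse_translate,
    split_codons,
    syn_site_fraction,
    translate,
)
from .genome import GeneModel, Genome

# Canonical domain topology per ABC subfamily (full transporters carry two
# TMD-NBD units, half transporters one; E/F/I members are soluble NBD-only).
CANONICAL_TOPOLOGY: dict[str, str] = {
    "A": "full_forward",
    "B": "full_forward",
    "C": "full_forward",
    "D": "half_forward",
    "E": "soluble",
    "F": "soluble",
    "G": "half_reverse",
    "I": "soluble",
}

DUPLICATION_KINDS = ("tandem", "proximal", "dispersed", "segmental")


class SizingError(ValueError):
    """Chromosome too short for the requested gene complement."""


@dataclass(frozen=True)
class CodonSimParams:
    genetic_code: int = 1
    forbid_stop: bool = True


@dataclass(frozen=True)
class PlantedDuplication:
    family_label: str  # subfamily tag, one of A..G, I
    kind: str  # tandem | proximal | dispersed | segmental
    target_ks: float = 0.3
    target_omega: float = 0.2
    intervening_genes: int = 0  # proximal only; >= 2
    block_size: int = 0  # segmental only; >= 5

    def __post_init__(self):
        if self.kind not in DUPLICATION_KINDS:
            raise ValueError(f"unknown duplication kind {self.kind!r}")
        if self.target_ks < 0 or self.target_omega < 0:
            raise ValueError("target_ks and target_omega must be >= 0")
        if self.kind == "proximal" and self.intervening_genes < 2:
            raise ValueError("proximal events need >= 2 intervening genes")
        if self.kind == "tandem" and self.intervening_genes != 0:
            raise ValueError("tandem events have no intervening genes")
        if self.kind == "segmental" and self.block_size < 5:
            raise ValueError("segmental blocks need >= 5 genes for detection")


@dataclass(frozen=True)
class GenomeSimConfig:
    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    n_background_genes: int = 80
    planted_events: tuple[PlantedDuplication, ...] = ()
    codon_model: CodonSimParams = field(default_factory=CodonSimParams)
    n_no_utr: int = 0  # genes left without UTRs (drawn deterministically)
    seed: int = 0


@dataclass
class SimulatedGenome:
    genome: Genome
    truth: pd.DataFrame  # one row per planted gene
    config: GenomeSimConfig


# ---------------------------------------------------------------------------
# Codon-level evolution


def _site_counts(codons: Sequence[str]) -> tuple[float, float]:
    s = sum(syn_site_fraction(c) for c in codons)
    return s, 3.0 * len(codons) - s


def _pick_change(rng, codons, want_syn, forbid_stop, frozen, max_tries=100_000):
    """Rejection-sample one single-nucleotide change of the requested class.

    Uniform over (codon, position, alternative) triples of that class, which
    matches the NG86 notion of opportunity at each site.
    """
    nts = "ACGT"
    n = len(codons)
    for _ in range(max_tries):
        i = int(rng.integers(n))
        pos = int(rng.integers(3))
        alt = nts[int(rng.integers(4))]
        codon = codons[i]
        if alt == codon[pos]:
            continue
        new_codon = codon[:pos] + alt + codon[pos + 1 :]
        new_aa = STANDARD_CODE[new_codon]
        old_aa = STANDARD_CODE[codon]
        if want_syn:
            if new_aa == old_aa:
                return i, new_codon
        else:
            if new_aa != old_aa and not (forbid_stop and new_aa == "*") and i not in frozen:
                return i, new_codon
    raise RuntimeError("no eligible substitution found (sequence too constrained)")


def evolve_cds_pair(
    ancestor_cds: str,
    target_ks: float,
    target_omega: float,
    seed: int | np.random.Generator,
    params: CodonSimParams = CodonSimParams(),
    frozen_codons: frozenset[int] = frozenset(),
) -> tuple[str, int, int]:
    """Evolve a descendant CDS at specified synonymous density and Ka/Ks.

    The number of synonymous events is Poisson(target_ks x S) and of
    nonsynonymous events Poisson(target_omega x target_ks x N), with S and N
    the NG86 site counts of the ancestor; events land uniformly over the
    current opportunities of their class, so repeat hits and reversions occur
    naturally and the Jukes-Cantor correction of the estimator applies.
    Codon indices in ``frozen_codons`` accept no nonsynonymous change
    (conserved motifs). A terminal stop codon is carried over untouched.

    Returns (descendant_cds, realized_synonymous, realized_nonsynonymous).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cds = ancestor_cds.upper()
    stop = ""
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        stop = cds[-3:]
        cds = cds[:-3]
    codons = split_codons(cds)
    translate(cds)  # validates: divisible by 3, no internal stop
    S, N = _site_counts(codons)
    n_syn = int(rng.poisson(target_ks * S))
    n_non = int(rng.poisson(target_omega * target_ks * N))
    events = np.array(["s"] * n_syn + ["n"] * n_non)
    rng.shuffle(events)
    realized_syn = realized_non = 0
    for ev in events:
        i, new_codon = _pick_change(
            rng, codons, want_syn=(ev == "s"),
            forbid_stop=params.forbid_stop, frozen=frozen_codons,
        )
        codons[i] = new_codon
        if ev == "s":
            realized_syn += 1
        else:
            realized_non += 1
    return "".join(codons) + stop, realized_syn, realized_non


# ---------------------------------------------------------------------------
# Protein architecture templates

_HYDROPHOBIC = "ILVFA"  # strongly positive Kyte-Doolittle values
# broad non-hydrophobic alphabet for fillers/loops: low coincidental identity
# between unrelated proteins, and no accidental transmembrane signal
_POLAR = "ACDEGHKMNPQRSTWY"

# One deterministic sequence template per subfamily; every simulated member
# is a partially mutated copy, so subfamily identity is carried by shared
# template residues (like real subfamily-conserved regions) on top of the
# motifs common to the whole family.
_SUBFAMILY_TEMPLATE_SEED = {
    sub: 7_000 + i for i, sub in enumerate(sorted(CANONICAL_TOPOLOGY))
}
# fraction of template residues redrawn per simulated member: two members of
# one subfamily share ~(1-m)^2 of non-motif residues (~16% + coincidence,
# comfortably below the 40% duplicate-homology threshold, comfortably above
# the ~15% cross-subfamily baseline)
_MEMBER_MUTATION = 0.6


def _draw(rng, alphabet: str, n: int) -> str:
    return "".join(alphabet[int(i)] for i in rng.integers(len(alphabet), size=n))


def _template_regions(subfamily: str) -> list[tuple[str, str]]:
    """(kind, sequence) regions of the subfamily template protein.

    Kinds: 'motif' (invariant, frozen under evolution), 'filler' (polar
    alphabet), 'helix' (hydrophobic alphabet). The NBD carries Walker A,
    the ABC signature and Walker B; a TMD is five 21-residue helices with
    short loops.
    """
    rng = np.random.default_rng(_SUBFAMILY_TEMPLATE_SEED[subfamily])
    topology = CANONICAL_TOPOLOGY[subfamily]
    blocks = {
        "full_forward": ("T", "N", "T", "N"),
        "full_reverse": ("N", "T", "N", "T"),
        "half_forward": ("T", "N"),
        "half_reverse": ("N", "T"),
        "soluble": ("N",),
        "tmd_only": ("T",),
    }[topology]
    regions: list[tuple[str, str]] = [("filler", _draw(rng, _POLAR, 25))]
    for block in blocks:
        if block == "T":
            for _ in range(5):
                regions.append(("helix", _draw(rng, _HYDROPHOBIC, 21)))
                regions.append(("filler", _draw(rng, _POLAR, 9)))
        else:
            regions.extend(
                [
                    ("filler", _draw(rng, _POLAR, 20)),
                    ("motif", "GPSGAGKT"),  # Walker A, G..G.GK[ST]
                    ("filler", _draw(rng, _POLAR, 55)),
                    ("motif", "LSGGQKQR"),  # ABC signature, [LIVMFY]S[SG]G.[QRKE]
                    ("filler", _draw(rng, _POLAR, 25)),
                    # Walker B, [RK].{3}G.{3}[LIVMF]{3}
                    ("motif", "RILLGDEALLV"),
                    ("filler", _draw(rng, _POLAR, 20)),
                ]
            )
        regions.append(("filler", _draw(rng, _POLAR, 25)))
    return regions


def build_family_protein(
    subfamily: str, rng, mutation: float = _MEMBER_MUTATION
) -> tuple[str, list[tuple[int, int]]]:
    """One subfamily member: mutated copy of the subfamily template.

    Returns the sequence and the (start, end) spans of motif residues,
    which the evolver freezes against nonsynonymous change — the in-silico
    analogue of the purifying selection that keeps these motifs diagnostic.
    """
    seq = ""
    motif_spans: list[tuple[int, int]] = []
    for kind, text in _template_regions(subfamily):
        if kind == "motif":
            motif_spans.append((len(seq), len(seq) + len(text)))
            seq += text
            continue
        alphabet = _HYDROPHOBIC if kind == "helix" else _POLAR
        mutated = [
            alphabet[int(rng.integers(len(alphabet)))]
            if rng.random() < mutation
            else aa
            for aa in text
        ]
        seq += "".join(mutated)
    return seq, motif_spans


def build_background_protein(rng, n_codons: int) -> str:
    """Random uniform sense codons; no motif structure, no homology."""
    cds = "".join(SENSE_CODONS[int(i)] for i in rng.integers(len(SENSE_CODONS), size=n_codons))
    return translate(cds)


# ---------------------------------------------------------------------------
# Genome assembly


@dataclass
class _GeneSpec:
    gene_id: str
    protein: str
    cds: str  # includes terminal stop codon
    family_label: str | None = None
    event_id: int | None = None
    true_type: str | None = None
    partner: str | None = None
    target_ks: float | None = None
    target_omega: float | None = None
    realized_syn: int | None = None
    realized_non: int | None = None


def _family_gene(rng, label, gene_id) -> tuple[_GeneSpec, frozenset[int]]:
    protein, motif_spans = build_family_protein(label, rng)
    cds = reverse_translate(protein, rng)
    frozen = frozenset(
        i for s, e in motif_spans for i in range(s, e)
    )
    return _GeneSpec(gene_id, protein, cds, family_label=label), frozen


def _gene_layout(rng, spec: _GeneSpec, cursor: int, with_utr: bool):
    """Lay one gene model onto a chromosome from ``cursor``; returns model end."""
    cds_len = len(spec.cds)
    n_exons = int(rng.integers(1, 9))
    # split the CDS into n_exons non-empty chunks
    if n_exons == 1:
        chunks = [cds_len]
    else:
        cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False))
        chunks = np.diff([0, *cuts, cds_len]).tolist()
    utr5_len = int(rng.integers(60, 300)) if with_utr else 0
    utr3_len = int(rng.integers(60, 300)) if with_utr else 0
    introns = [int(rng.integers(80, 500)) for _ in range(n_exons - 1)]
    strand = "+" if rng.integers(2) else "-"

    start = cursor
    pos = cursor
    exons: list[tuple[int, int]] = []
    cds_segments: list[tuple[int, int]] = []
    utr5: list[tuple[int, int]] = []
    utr3: list[tuple[int, int]] = []
    # Genomic left-to-right; for '-' strand genes the 5' UTR sits on the
    # right end, but segment bookkeeping is symmetric so we lay 5' left and
    # swap labels afterwards for '-' genes.
    for k, chunk in enumerate(chunks):
        exon_start = pos
        if k == 0 and utr5_len:
            utr5.append((pos, pos + utr5_len))
            pos += utr5_len
        cds_segments.append((pos, pos + chunk))
        pos += chunk
        if k == n_exons - 1 and utr3_len:
            utr3.append((pos, pos + utr3_len))
            pos += utr3_len
        exons.append((exon_start, pos))
        if k < n_exons - 1:
            pos += introns[k]
    if strand == "-":
        utr5, utr3 = utr3, utr5
    model = GeneModel(
        gene_id=spec.gene_id,
        chromosome="",  # filled by caller
        strand=strand,
        start=start,
        end=pos,
        exons=tuple(exons),
        cds_segments=tuple(cds_segments),
        utr5_segments=tuple(utr5),
        utr3_segments=tuple(utr3),
        cds=spec.cds,
        protein=spec.protein,
    )
    return model


def generate_genome(config: GenomeSimConfig) -> SimulatedGenome:
    """Build a synthetic annotated genome with planted duplications.

    Raises SizingError when a chromosome cannot hold its assigned genes.
    """
    rng = np.random.default_rng(config.seed)
    params = config.codon_model
    chroms = [f"chr{i+1:02d}" for i in range(config.n_chromosomes)]

    # 1. planted units: ordered lists of gene specs that must stay contiguous
    units_by_chrom: dict[str, list[list[_GeneSpec]]] = {c: [] for c in chroms}
    truth_rows: list[dict] = []

    def record(spec: _GeneSpec, event_id, true_type, partner, event, n_syn, n_non):
        spec.event_id = event_id
        spec.true_type = true_type
        spec.partner = partner
        spec.target_ks = event.target_ks
        spec.target_omega = event.target_omega
        spec.realized_syn = n_syn
        spec.realized_non = n_non

    for ev_idx, event in enumerate(config.planted_events):
        tag = f"ev{ev_idx:02d}"
        if event.kind in ("tandem", "proximal"):
            anc, frozen = _family_gene(rng, event.family_label, f"{tag}_a")
            cds, n_syn, n_non = evolve_cds_pair(
                anc.cds, event.target_ks, event.target_omega, rng, params, frozen
            )
            dup = _GeneSpec(
                f"{tag}_b", translate(cds), cds, family_label=event.family_label
            )
            record(anc, ev_idx, event.kind, dup.gene_id, event, n_syn, n_non)
            record(dup, ev_idx, event.kind, anc.gene_id, event, n_syn, n_non)
            fillers = [
                _GeneSpec(f"{tag}_i{j}", *_background_pair(rng))
                for j in range(event.intervening_genes)
            ]
            unit = [anc, *fillers, dup]
            chrom = chroms[int(rng.integers(len(chroms)))]
            units_by_chrom[chrom].append(unit)
        elif event.kind == "dispersed":
            anc, frozen = _family_gene(rng, event.family_label, f"{tag}_a")
            cds, n_syn, n_non = evolve_cds_pair(
                anc.cds, event.target_ks, event.target_omega, rng, params, frozen
            )
            dup = _GeneSpec(
                f"{tag}_b", translate(cds), cds, family_label=event.family_label
            )
            record(anc, ev_idx, "dispersed", dup.gene_id, event, n_syn, n_non)
            record(dup, ev_idx, "dispersed", anc.gene_id, event, n_syn, n_non)
            if len(chroms) >= 2:
                ca, cb = rng.choice(len(chroms), size=2, replace=False)
                units_by_chrom[chroms[int(ca)]].append([anc])
                units_by_chrom[chroms[int(cb)]].append([dup])
            else:
                # single chromosome: keep the copies far apart by placing them
                # in separate units; rank distance is checked downstream
                units_by_chrom[chroms[0]].append([anc])
                units_by_chrom[chroms[0]].append([dup])
        elif event.kind == "segmental":
            block_a: list[_GeneSpec] = []
            block_b: list[_GeneSpec] = []
            for j in range(event.block_size):
                anc, frozen = _family_gene(rng, event.family_label, f"{tag}_a{j}")
                cds, n_syn, n_non = evolve_cds_pair(
                    anc.cds, event.target_ks, event.target_omega, rng, params, frozen
                )
                dup = _GeneSpec(
                    f"{tag}_b{j}", translate(cds), cds,
                    family_label=event.family_label,
                )
                record(anc, ev_idx, "wgd_segmental", dup.gene_id, event, n_syn, n_non)
                record(dup, ev_idx, "wgd_segmental", anc.gene_id, event, n_syn, n_non)
                block_a.append(anc)
                block_b.append(dup)
            if len(chroms) >= 2:
                ca, cb = rng.choice(len(chroms), size=2, replace=False)
                units_by_chrom[chroms[int(ca)]].append(block_a)
                units_by_chrom[chroms[int(cb)]].append(block_b)
            else:
                units_by_chrom[chroms[0]].append(block_a)
                units_by_chrom[chroms[0]].append(block_b)

    # 2. background genes
    for j in range(config.n_background_genes):
        spec = _GeneSpec(f"bg{j:04d}", *_background_pair(rng))
        chrom = chroms[int(rng.integers(len(chroms)))]
        units_by_chrom[chrom].append([spec])

    # 3. shuffle unit order per chromosome, then lay out coordinates
    genes: dict[str, GeneModel] = {}
    ordered_specs: list[tuple[str, _GeneSpec]] = []
    for chrom in chroms:
        units = units_by_chrom[chrom]
        order = rng.permutation(len(units))
        flat = [spec for k in order for spec in units[int(k)]]
        ordered_specs.extend((chrom, s) for s in flat)

    # choose UTR opt-outs over all genes, deterministically
    all_ids = [s.gene_id for _, s in ordered_specs]
    no_utr: set[str] = set()
    if config.n_no_utr:
        chosen = rng.choice(len(all_ids), size=config.n_no_utr, replace=False)
        no_utr = {all_ids[int(i)] for i in chosen}

    cursors = {c: int(rng.integers(2_000, 10_000)) for c in chroms}
    for chrom, spec in ordered_specs:
        model = _gene_layout(rng, spec, cursors[chrom], spec.gene_id not in no_utr)
        model = GeneModel(**{**model.__dict__, "chromosome": chrom})
        if model.end > config.chrom_length:
            raise SizingError(
                f"{chrom} length {config.chrom_length} exhausted at gene "
                f"{spec.gene_id} (needs {model.end})"
            )
        genes[spec.gene_id] = model
        cursors[chrom] = model.end + int(rng.integers(1_000, 5_000))

    for _, spec in ordered_specs:
        if spec.true_type is not None:
            truth_rows.append(
                {
                    "gene_id": spec.gene_id,
                    "event_id": spec.event_id,
                    "family_label": spec.family_label,
                    "true_type": spec.true_type,
                    "partner": spec.partner,
                    "target_ks": spec.target_ks,
                    "target_omega": spec.target_omega,
                    "realized_syn": spec.realized_syn,
                    "realized_non": spec.realized_non,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "event_id", "family_label", "true_type", "partner",
            "target_ks", "target_omega", "realized_syn", "realized_non",
        ],
    )
    lengths = {c: config.chrom_length for c in chroms}
    return SimulatedGenome(Genome(genes, lengths), truth, config)


def _background_pair(rng) -> tuple[str, str]:
    n_codons = int(rng.integers(120, 400))
    cds = "".join(
        SENSE_CODONS[int(i)] for i in rng.integers(len(SENSE_CODONS), size=n_codons)
    )
    stop = sorted(STOP_CODONS)[int(rng.integers(3))]
    return translate(cds), cds + stop


def write_simulated_genome(sim: SimulatedGenome, out_dir) -> dict[str, Path]:
    from .genome import write_genome

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": out / "annotation.gff3",
        "protein": out / "proteins.fa",
        "cds": out / "cds.fa",
        "truth": out / "truth.tsv",
    }
    write_genome(sim.genome, paths["gff3"], paths["protein"], paths["cds"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Reference panel


def generate_reference_panel(
    seed: int, per_subfamily: int = 2
) -> list[tuple[str, str, str]]:
    """Labeled (id, subfamily, protein) reference proteins covering A..G, I."""
    rng = np.random.default_rng(seed)
    panel = []
    for sub in sorted(CANONICAL_TOPOLOGY):
        for k in range(per_subfamily):
            protein, _ = build_family_protein(sub, rng)
            panel.append((f"ref{sub}{k+1}", sub, protein))
    return panel


def write_reference_panel(panel, path) -> None:
    with open(path, "w") as fh:
        for pid, sub, protein in panel:
            fh.write(f">{pid} subfamily={sub}\n")
            for i in range(0, len(protein), 60):
                fh.write(protein[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Expression matrices


def generate_expression_matrix(
    n_ubiquitous: int,
    n_silent: int,
    n_specific: int,
    n_other: int,
    tissues: Sequence[str],
    seed: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x tissues TPM matrix with known category labels.

    Ubiquitous genes are positive everywhere, silent genes zero everywhere,
    tissue-specific genes positive in exactly one tissue, and "other" genes
    in 2..(T-1) tissues. Values are drawn log-normal, the usual shape of TPM
    distributions.
    """
    if not tissues:
        raise ValueError("tissue list must be non-empty")
    rng = np.random.default_rng(seed)
    n_tissues = len(tissues)
    rows = []
    labels = []
    index = []

    def tpm(n):
        return np.round(np.exp(rng.normal(2.0, 1.0, size=n)), 3)

    counter = 0
    for category, count in (
        ("ubiquitous", n_ubiquitous),
        ("silent", n_silent),
        ("tissue_specific", n_specific),
        ("other", n_other),
    ):
        for _ in range(count):
            counter += 1
            gene = f"gene{counter:04d}"
            values = np.zeros(n_tissues)
            if category == "ubiquitous":
                values = tpm(n_tissues)
            elif category == "tissue_specific":
                t = int(rng.integers(n_tissues))
                values[t] = tpm(1)[0]
            elif category == "other":
                k = int(rng.integers(2, n_tissues))
                which = rng.choice(n_tissues, size=k, replace=False)
                values[which] = tpm(k)
            rows.append(values)
            labels.append(category)
            index.append(gene)
    matrix = pd.DataFrame(rows, index=index, columns=list(tissues))
    matrix.index.name = "gene_id"
    return matrix, pd.Series(labels, index=index, name="category")


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_qpcr_table(
    true_fold_changes: Mapping[str, Mapping[float, float]],
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    reference_gene: str = "beta_tubulin",
    reference_ct: float = 18.0,
) -> pd.DataFrame:
    """Ct table under the 2^-ddCt model.

    For each gene and timepoint, control-condition target Ct is
    ``reference_ct + base_dct + noise`` and treatment Ct subtracts
    log2(fold). Reference-gene rows are emitted for every sample so the
    analysis can normalize each replicate.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    genes = sorted(true_fold_changes)
    timepoints = sorted({t for g in genes for t in true_fold_changes[g]})
    base_dct = {g: round(float(rng.uniform(1.0, 5.0)), 2) for g in genes}

    def noise():
        return float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0

    for timepoint in timepoints:
        for condition in ("control", "treatment"):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": reference_gene,
                        "condition": condition,
                        "timepoint": timepoint,
                        "replicate": rep,
                        "ct": reference_ct + noise(),
                    }
                )
            for gene in genes:
                fold = true_fold_changes[gene].get(timepoint, 1.0)
                shift = -np.log2(fold) if condition == "treatment" else 0.0
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "timepoint": timepoint,
                            "replicate": rep,
                            "ct": reference_ct + base_dct[gene] + shift + noise(),
                        }
                    )
    return pd.DataFrame(rows)
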