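"""Relative qPCR expression: 2^-ddCt fold changes and significance letters.

Per replicate, dCt = Ct_target - Ct_reference; ddCt subtracts the mean
control dCt at the same timepoint; fold change is 2^-ddCt, summarized as
mean +- SD over replicates. Group comparisons use one-way ANOVA followed
by Tukey's HSD, rendered as a compact letter display (groups sharing a
letter do not differ at alpha). Amplification efficiency is fixed at 2,
the assumption built into the 2^-ddCt formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("gene", "condition", "timepoint", "replicate", "ct")


class QpcrInputError(ValueError):
    pass


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    timepoint: float
    mean_fold: float
    sd_fold: float
    replicate_folds: tuple[float, ...]
    letter: str = ""


def load_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise QpcrInputError(f"Ct table missing columns: {sorted(missing)}")
    return table


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str,
    baseline: str = "matched_control",
) -> list[FoldChangeResult]:
    """Fold changes per gene x timepoint under the 2^-ddCt model.

    ``baseline='matched_control'`` normalizes treatment against the control
    series at the same timepoint (the design with an explicit 0 uM control
    arm); ``baseline='time_zero'`` uses the earliest treatment timepoint
    instead.
    """
    ref = records[records["gene"] == reference_gene]
    if ref.empty:
        raise QpcrInputError(f"reference gene {reference_gene!r} absent from table")
    ref_ct = ref.set_index(["condition", "timepoint", "replicate"])["ct"]
    targets = records[records["gene"] != reference_gene]
    dct_rows = []
    for row in targets.itertuples():
        key = (row.condition, row.timepoint, row.replicate)
        if key not in ref_ct.index:
            raise QpcrInputError(
                f"no reference-gene record for sample condition={row.condition}, "
                f"timepoint={row.timepoint}, replicate={row.replicate}"
            )
        dct_rows.append(
            {
                "gene": row.gene,
                "condition": row.condition,
                "timepoint": row.timepoint,
                "replicate": row.replicate,
                "dct": row.ct - float(ref_ct.loc[key]),
            }
        )
    dct = pd.DataFrame(dct_rows)
    results: list[FoldChangeResult] = []
    for gene, gene_rows in dct.groupby("gene", sort=True):
        treat = gene_rows[gene_rows["condition"] == "treatment"]
        control = gene_rows[gene_rows["condition"] == "control"]
        if baseline == "time_zero":
            t0 = treat["timepoint"].min()
            base_by_tp = {
                tp: treat.loc[treat["timepoint"] == t0, "dct"].mean()
                for tp in treat["timepoint"].unique()
            }
        else:
            base_by_tp = {
                tp: control.loc[control["timepoint"] == tp, "dct"].mean()
                for tp in treat["timepoint"].unique()
            }
        for tp in sorted(treat["timepoint"].unique()):
            base = base_by_tp[tp]
            if np.isnan(base):
                raise QpcrInputError(
                    f"no baseline samples for gene {gene!r} at timepoint {tp}"
                )
            folds = tuple(
                2.0 ** -(d - base)
                for d in treat.loc[treat["timepoint"] == tp, "dct"]
            )
            results.append(
                FoldChangeResult(
                    gene=gene,
                    timepoint=float(tp),
                    mean_fold=float(np.mean(folds)),
                    sd_fold=float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0,
                    replicate_folds=folds,
                )
            )
    return results


def _tukey_nonsig_pairs(
    groups: Sequence[Sequence[float]], alpha: float
) -> set[tuple[int, int]]:
    """Index pairs NOT significantly different under Tukey's HSD."""
    k = len(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.var(g) == 0 for g in arrays):
        # degenerate: letters by exact equality of means
        return {
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if float(np.mean(arrays[i])) == float(np.mean(arrays[j]))
        }
    res = stats.tukey_hsd(*arrays)
    return {
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if res.pvalue[i, j] >= alpha
    }


def compact_letter_display(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> list[str]:
    """Letters such that two groups share a letter iff they are not
    significantly different (insert-and-absorb construction).

    Groups are processed in order of decreasing mean, the usual convention
    that gives 'a' to the largest group.
    """
    k = len(groups)
    if k < 2:
        return ["a"] * k
    nonsig = _tukey_nonsig_pairs(groups, alpha)
    sig_pairs = [
        (i, j) for i in range(k) for j in range(i + 1, k) if (i, j) not in nonsig
    ]
    # start with one class holding everything; split it at every significant
    # pair, then absorb classes contained in others
    classes: list[set[int]] = [set(range(k))]
    for i, j in sig_pairs:
        new_classes: list[set[int]] = []
        for cls in classes:
            if i in cls and j in cls:
                new_classes.append(cls - {i})
                new_classes.append(cls - {j})
            else:
                new_classes.append(cls)
        classes = [
            cls
            for idx, cls in enumerate(new_classes)
            if cls
            and not any(
                (cls < other) or (cls == other and idx2 < idx)
                for idx2, other in enumerate(new_classes)
                if idx2 != idx
            )
        ]
    # letter order: classes containing larger means come first
    means = [float(np.mean(np.asarray(g, dtype=float))) for g in groups]
    classes.sort(key=lambda cls: (-max(means[i] for i in cls), sorted(cls)))
    letters = [""] * k
    for letter_idx, cls in enumerate(classes):
        letter = chr(ord("a") + letter_idx)
        for i in cls:
            letters[i] += letter
    return ["".join(sorted(ls)) for ls in letters]


def letter_groups(
    replicate_folds_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact-letter display over named groups (e.g. timepoints)."""
    names = list(replicate_folds_by_group)
    groups = [replicate_folds_by_group[n] for n in names]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two replicates")
    letters = compact_letter_display(groups, alpha)
    return dict(zip(names, letters))


def anova_pvalue(groups: Sequence[Sequence[float]]) -> float:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.var(g) == 0 for g in arrays):
        means = {float(np.mean(g)) for g in arrays}
        return 1.0 if len(means) == 1 else 0.0
    return float(stats.f_oneway(*arrays).pvalue)


def fold_change_table(
    records: pd.DataFrame,
    reference_gene: str,
    alpha: float = 0.05,
    baseline: str = "matched_control",
) -> pd.DataFrame:
    """Fold changes with two letter annotations per row.

    ``letter_across_timepoints`` compares a gene's treatment folds across
    timepoints; ``treatment_vs_control_p`` reports the per-timepoint Welch
    t-test of treatment vs control replicate dCt values. The figure
    convention behind bar letters can mean either comparison, so both are
    emitted.
    """
    results = delta_delta_ct(records, reference_gene, baseline)
    rows = [r.__dict__.copy() for r in results]
    by_gene: dict[str, list[FoldChangeResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    letters: dict[tuple[str, float], str] = {}
    for gene, rs in by_gene.items():
        if len(rs) >= 2 and all(len(r.replicate_folds) >= 2 for r in rs):
            assigned = letter_groups(
                {str(r.timepoint): r.replicate_folds for r in rs}, alpha
            )
            for r in rs:
                letters[(gene, r.timepoint)] = assigned[str(r.timepoint)]
    # treatment vs control per timepoint: control folds renormalized the same way
    ref = records[records["gene"] == reference_gene]
    ref_ct = ref.set_index(["condition", "timepoint", "replicate"])["ct"]
    pvals: dict[tuple[str, float], float] = {}
    targets = records[records["gene"] != reference_gene]
    for (gene, tp), sub in targets.groupby(["gene", "timepoint"]):
        def dcts(condition):
            rows_ = sub[sub["condition"] == condition]
            return [
                row.ct - float(ref_ct.loc[(row.condition, row.timepoint, row.replicate)])
                for row in rows_.itertuples()
            ]
        treat, control = dcts("treatment"), dcts("control")
        if len(treat) >= 2 and len(control) >= 2:
            if np.var(treat) == 0 and np.var(control) == 0:
                p = 1.0 if np.mean(treat) == np.mean(control) else 0.0
            else:
                p = float(stats.ttest_ind(treat, control, equal_var=False).pvalue)
            pvals[(gene, float(tp))] = p
    table = pd.DataFrame(rows).drop(columns=["letter"])
    table["letter_across_timepoints"] = [
        letters.get((r["gene"], r["timepoint"]), "") for r in rows
    ]
    table["treatment_vs_control_p"] = [
        pvals.get((r["gene"], r["timepoint"]), np.nan) for r in rows
    ]
    table["replicate_folds"] = table["replicate_folds"].map(
        lambda fs: ",".join(f"{f:.4f}" for f in fs)
    )
    return table
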