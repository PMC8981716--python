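"""Diagnostic triage of aberrant events and case-table summarization.

After an aberrant event (AE, AS, MAE or an RNA-called variant) is found in a
gene, a deterministic decision flow assigns it one of four statuses:

* ``diagnosed`` — known disease gene, patient phenotype matches, and rare
  variant(s) consistent with the mode of inheritance were found;
* ``VUS-followup`` — known disease gene and phenotype match but no causative
  variant yet (suggests WGS or RNA-variant search);
* ``research-candidate`` — not an established disease gene, but the
  aberration co-occurs with a deleterious rare variant;
* ``unlikely`` — anything else; move on to the next event.

Phenotype match and inheritance consistency are boolean inputs: they encode
the manual comparison of patient phenotype with the disease-gene phenotype
and mode of inheritance, which is outside this package's scope.

The module also ships the transcribed 32-case diagnostic summary table used
as a worked example, and per-sample outlier tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CaseRecord",
    "TriageDecision",
    "triage_event",
    "load_case_table",
    "summarize_cases",
    "per_sample_tally",
]

RNA_DEFECT_CLASSES = ("AE", "AS", "MAE", "Var")

VARIANT_CLASS_VOCAB = {
    "frameshift", "missense", "splice donor", "splice acceptor", "splice region",
    "intronic", "synonymous", "stop", "start loss", "UTR", "promoter",
    "deletion", "MNV", "intergenic",
}


@dataclass
class CaseRecord:
    patient_id: str
    diagnosed_gene: str
    variant_classes: list
    rna_defects: set
    status: str = "diagnosed"

    def __post_init__(self):
        unknown = set(self.variant_classes) - VARIANT_CLASS_VOCAB
        if unknown:
            raise ValueError(f"unknown variant classes: {sorted(unknown)}")
        bad = set(self.rna_defects) - set(RNA_DEFECT_CLASSES)
        if bad:
            raise ValueError(f"unknown RNA defect classes: {sorted(bad)}")
        if self.status == "diagnosed" and not self.rna_defects:
            raise ValueError("diagnosed cases must have at least one RNA defect")


@dataclass
class TriageDecision:
    status: str                       # diagnosed | VUS-followup | research-candidate | unlikely
    rationale: list = field(default_factory=list)


def triage_event(event_gene, *, is_disease_gene, phenotype_match=False,
                 has_consistent_rare_variant=False, has_deleterious_rare_variant=None):
    """Route one aberrant event through the diagnostic decision flow.

    Parameters
    ----------
    event_gene : str
        Gene carrying the aberrant event (for the rationale chain only).
    is_disease_gene : bool
        Gene has an established Mendelian disease association (e.g. OMIM).
    phenotype_match : bool
        Patient phenotype matches the disease-gene phenotype/inheritance.
    has_consistent_rare_variant : bool
        Rare variant(s) consistent with the mode of inheritance were found.
    has_deleterious_rare_variant : bool, optional
        For non-disease genes: a deleterious rare variant supports a novel
        disease-gene hypothesis.  Defaults to ``has_consistent_rare_variant``.
    """
    if has_deleterious_rare_variant is None:
        has_deleterious_rare_variant = has_consistent_rare_variant
    chain = [f"aberrant event in {event_gene}"]
    if is_disease_gene:
        chain.append("known disease gene")
        if phenotype_match:
            chain.append("phenotype and inheritance match")
            if has_consistent_rare_variant:
                chain.append("consistent rare variant(s) found")
                return TriageDecision("diagnosed", chain)
            chain.append("no causative variant found; suggest WGS / RNA variant search")
            return TriageDecision("VUS-followup", chain)
        chain.append("phenotype does not match")
        return TriageDecision("unlikely", chain)
    chain.append("not an established disease gene")
    if has_deleterious_rare_variant:
        chain.append("deleterious rare variant supports novel disease-gene candidacy")
        return TriageDecision("research-candidate", chain)
    chain.append("no supporting variant")
    return TriageDecision("unlikely", chain)


def load_case_table(path=None):
    """Load the transcribed diagnostic case summary (32 diagnosed cases)."""
    if path is None:
        with resources.files("rnadx.data").joinpath("diagnosed_cases.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    records = [
        CaseRecord(
            patient_id=r.patient_id,
            diagnosed_gene=r.diagnosed_gene,
            variant_classes=str(r.variant_classes).split(";"),
            rna_defects=set(str(r.rna_defects).split(",")),
            status=r.status,
        )
        for r in df.itertuples(index=False)
    ]
    return records


def summarize_cases(records, include_rejected=False):
    """Counts per RNA-defect class and a variant-class x defect crosstab.

    A case with several defects counts once in each class; the total number
    of cases is unaffected.  Per-class counts use diagnosed cases only unless
    ``include_rejected``.
    """
    used = [r for r in records if include_rejected or r.status == "diagnosed"]
    class_counts = {c: sum(c in r.rna_defects for r in used) for c in RNA_DEFECT_CLASSES}
    rows = []
    for r in used:
        for vc in r.variant_classes:
            for d in r.rna_defects:
                rows.append((vc, d))
    crosstab = (pd.DataFrame(rows, columns=["variant_class", "rna_defect"])
                .pivot_table(index="variant_class", columns="rna_defect",
                             aggfunc="size", fill_value=0)
                if rows else pd.DataFrame())
    return {
        "n_cases": len(used),
        "class_counts": class_counts,
        "crosstab": crosstab,
    }


def per_sample_tally(calls, annotation=None, disease_list="OMIM"):
    """Per-sample counts of aberrant genes (all modules merged) and medians.

    Parameters
    ----------
    calls : DataFrame with columns sample, gene, module
        One row per (sample, gene, module) significant call.
    annotation : GeneAnnotation, optional
        Supplies disease-gene membership for the stratified counts.

    Returns (per_sample, medians): per-sample counts of distinct aberrant
    genes, total and disease-gene subset, stratified by module; and the
    cohort medians of those counts.
    """
    if len(calls) == 0:
        empty = pd.DataFrame(columns=["n_genes", "n_disease_genes"])
        return empty, pd.Series({"n_genes": 0.0, "n_disease_genes": 0.0})
    calls = calls.copy()
    if annotation is not None:
        members = annotation.gene_lists.get(disease_list, set())
        calls["disease_gene"] = calls["gene"].isin(members)
    else:
        calls["disease_gene"] = False
    per_sample = calls.groupby("sample").agg(
        n_genes=("gene", "nunique"),
        n_disease_genes=("gene", lambda g: calls.loc[g.index].loc[
            calls.loc[g.index, "disease_gene"], "gene"].nunique()),
    )
    if "module" in calls.columns:
        by_module = calls.pivot_table(index="sample", columns="module",
                                      values="gene", aggfunc="nunique", fill_value=0)
        per_sample = per_sample.join(by_module.add_prefix("n_"))
    medians = per_sample[["n_genes", "n_disease_genes"]].median()
    return per_sample, medians
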