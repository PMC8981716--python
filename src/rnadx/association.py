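"""Cohort-level association of outliers with rare variants and gene classes.

Units of analysis are gene-sample pairs.  Each pair carries an outlier class
(underexpression, overexpression or non-outlier; analogously for splicing)
and the consequence group of any rare variant it harbours.  A Fisher exact
test scores each (variant group, outlier class) cell; pairs with rare
variants from several groups are resolved to the group with the lowest
(most associated) p-value.  Per-class variant-group proportions carry
Clopper-Pearson 95% intervals.  Gene-class enrichment is a single-predictor
logistic regression per (gene list, outlier class) with a Haldane-Anscombe
2x2 fallback under complete separation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm

__all__ = [
    "CONSEQUENCE_GROUPS",
    "IMPACT_ORDER",
    "assign_consequence_group",
    "outlier_variant_association",
    "gene_class_enrichment",
    "potential_ptv_flag",
]

#: detailed consequence term -> group (total mapping; unknown terms error)
CONSEQUENCE_GROUPS = {
    "splice acceptor": "splice",
    "splice donor": "splice",
    "splice region": "splice",
    "frameshift": "frameshift",
    "3 prime UTR": "UTR",
    "5 prime UTR": "UTR",
    "start lost": "UTR",
    "downstream": "non-coding",
    "upstream": "non-coding",
    "intron": "non-coding",
    "regulatory region": "non-coding",
    "intergenic": "non-coding",
    "coding": "coding",
    "deletion": "coding",
    "inframe deletion": "coding",
    "insertion": "coding",
    "inframe insertion": "coding",
    "missense": "coding",
    "stop lost": "coding",
    "stop gained": "stop",
    "synonymous": "synonymous",
    "stop retained": "synonymous",
}

#: highest-predicted-impact ranking used when a variant has several transcript
#: consequences; earlier = more severe (VEP-like ordering over our groups)
IMPACT_ORDER = ["stop", "frameshift", "splice", "coding", "UTR", "synonymous", "non-coding"]


def assign_consequence_group(consequence, impact_order=None):
    """Map a consequence term (or several, for multi-transcript variants) to
    its group; multiple consequences resolve to the highest-impact group."""
    order = impact_order or IMPACT_ORDER
    terms = [consequence] if isinstance(consequence, str) else list(consequence)
    groups = []
    for term in terms:
        key = term.strip()
        if key not in CONSEQUENCE_GROUPS:
            raise KeyError(f"unknown consequence term: {key!r}")
        groups.append(CONSEQUENCE_GROUPS[key])
    return min(groups, key=order.index)


def _fisher_tables(units, group):
    """2x2 per outlier class for one variant group; rows: class membership,
    cols: has rare variant of the group."""
    has_g = units["groups"].apply(lambda gs: group in gs)
    out = {}
    for cls in units["outlier_class"].unique():
        if cls == "non-outlier":
            continue
        in_cls = units["outlier_class"] == cls
        out[cls] = np.array([
            [(in_cls & has_g).sum(), (in_cls & ~has_g).sum()],
            [(~in_cls & has_g).sum(), (~in_cls & ~has_g).sum()],
        ])
    return out


def outlier_variant_association(calls, variants, max_outliers_per_sample=20,
                                all_units=None):
    """Associate outlier classes with rare-variant consequence groups.

    Parameters
    ----------
    calls : DataFrame with sample, gene, class (significant outliers only)
    variants : VariantTable of rare variants (pre-filtered), with gene_id
    max_outliers_per_sample : int
        Samples with more outlier genes than this are discarded (their excess
        would swamp the association); the published analysis uses 20 for
        expression and 40 for splicing.
    all_units : DataFrame (sample, gene), optional
        The full universe of tested gene-sample pairs.  Defaults to the cross
        product of samples and genes seen in `variants`.

    Returns (proportions, excluded_samples): proportions is a tidy frame of
    (class, group, n, proportion, ci_low, ci_high, fisher_p).
    """
    per_sample = calls.groupby("sample")["gene"].nunique()
    excluded = sorted(per_sample.index[per_sample > max_outliers_per_sample])
    calls = calls[~calls["sample"].isin(excluded)]

    vt = variants.table
    vt = vt[~vt["sample"].isin(excluded)]
    var_groups = (
        vt.assign(group=[assign_consequence_group(c) for c in vt["consequence"]])
        .groupby(["sample", "gene_id"])["group"].agg(set)
    )

    if all_units is None:
        samples = sorted(set(vt["sample"]) | set(calls["sample"]))
        genes = sorted(set(vt["gene_id"]) | set(calls["gene"]))
        all_units = pd.MultiIndex.from_product([samples, genes], names=["sample", "gene"])
    else:
        all_units = pd.MultiIndex.from_frame(all_units[["sample", "gene"]])

    call_classes = {(s, g): c for s, g, c in zip(calls["sample"], calls["gene"], calls["class"])}
    units = pd.DataFrame({
        "sample": all_units.get_level_values(0),
        "gene": all_units.get_level_values(1),
    })
    units["outlier_class"] = [call_classes.get((s, g), "non-outlier")
                              for s, g in zip(units["sample"], units["gene"])]
    units["groups"] = [var_groups.get((s, g), set())
                       for s, g in zip(units["sample"], units["gene"])]

    groups = sorted({g for gs in units["groups"] for g in gs})
    classes = [c for c in units["outlier_class"].unique() if c != "non-outlier"]

    # Fisher p per (class, group)
    pvals = {}
    for grp in groups:
        for cls, tab in _fisher_tables(units, grp).items():
            pvals[(cls, grp)] = stats.fisher_exact(tab)[1]

    # resolve multi-group units to the lowest-p group for their class
    def resolve(row):
        gs = row["groups"]
        if not gs:
            return None
        cls = row["outlier_class"]
        if cls == "non-outlier":
            return min(sorted(gs))
        return min(sorted(gs), key=lambda g: pvals.get((cls, g), 1.0))

    units["group"] = units.apply(resolve, axis=1)

    rows = []
    for cls in classes:
        in_cls = units[units["outlier_class"] == cls]
        n_cls = len(in_cls)
        for grp in groups:
            n_hit = int((in_cls["group"] == grp).sum())
            if n_cls:
                lo, hi = proportion_confint(n_hit, n_cls, alpha=0.05, method="beta")
                prop = n_hit / n_cls
            else:
                prop, lo, hi = 0.0, 0.0, 0.0
            rows.append((cls, grp, n_hit, n_cls, prop, lo, hi, pvals.get((cls, grp), np.nan)))
    proportions = pd.DataFrame(
        rows, columns=["class", "group", "n", "n_class", "proportion",
                       "ci_low", "ci_high", "fisher_p"])
    return proportions, excluded


def gene_class_enrichment(calls, annotation, classes=None, gene_lists=None,
                          sample_ids=None):
    """Odds ratio and 95% CI per (gene list, outlier class).

    One logistic fit per cell on gene-sample units: response = unit is an
    outlier of the class, predictor = gene belongs to the list.  Under
    complete separation the Haldane-Anscombe-corrected 2x2 odds ratio is
    reported instead, flagged.
    """
    gene_ids = list(annotation.gene_ids)
    lists = gene_lists or sorted(annotation.gene_lists)
    if sample_ids is None:
        sample_ids = sorted(calls["sample"].unique())
    classes = classes or sorted(c for c in calls["class"].unique())

    rows = []
    call_sets = {cls: {(s, g) for s, g, c in zip(calls["sample"], calls["gene"], calls["class"])
                       if c == cls} for cls in classes}
    n_units = len(sample_ids) * len(gene_ids)
    member = {name: annotation.in_list(name, gene_ids) for name in lists}
    for cls in classes:
        y = np.zeros(n_units, dtype=float)
        flat = {(s, g) for (s, g) in call_sets[cls]}
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for (s, g) in flat:
            if g in gene_pos and s in sample_ids:
                y[sample_ids.index(s) * len(gene_ids) + gene_pos[g]] = 1.0
        for name in lists:
            x = np.tile(member[name].astype(float), len(sample_ids))
            if x.sum() == 0:
                rows.append((name, cls, np.nan, np.nan, np.nan, "empty-category"))
                continue
            tab = np.array([
                [((y == 1) & (x == 1)).sum(), ((y == 1) & (x == 0)).sum()],
                [((y == 0) & (x == 1)).sum(), ((y == 0) & (x == 0)).sum()],
            ], dtype=float)
            if (tab == 0).any():
                tab_c = tab + 0.5  # Haldane-Anscombe
                or_ = (tab_c[0, 0] * tab_c[1, 1]) / (tab_c[0, 1] * tab_c[1, 0])
                se = np.sqrt((1 / tab_c).sum())
                rows.append((name, cls, or_, or_ * np.exp(-1.96 * se),
                             or_ * np.exp(1.96 * se), "separation-fallback"))
                continue
            X = sm.add_constant(x)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
            coef, se = fit.params[1], fit.bse[1]
            rows.append((name, cls, np.exp(coef), np.exp(coef - 1.96 * se),
                         np.exp(coef + 1.96 * se), ""))
    return pd.DataFrame(rows, columns=["gene_list", "class", "odds_ratio",
                                       "ci_low", "ci_high", "flag"])


def potential_ptv_flag(variants, annotation, expressed_mask):
    """Potential protein-truncating variants: stop or frameshift consequence,
    at an expressed position, not in the gene's last exon.

    Parameters
    ----------
    variants : VariantTable with an ``exon_index`` column (1-based)
    expressed_mask : mapping (chromosome, position) -> bool or boolean array
    """
    t = variants.table
    groups = np.array([assign_consequence_group(c) for c in t["consequence"]])
    truncating = np.isin(groups, ["stop", "frameshift"])
    if isinstance(expressed_mask, dict):
        expressed = np.array([expressed_mask.get((c, p), False)
                              for c, p in zip(t["chromosome"], t["position"])])
    else:
        expressed = np.asarray(expressed_mask, dtype=bool)
    n_exons = annotation.table["n_exons"].reindex(t["gene_id"]).to_numpy()
    exon_index = t.get("exon_index", pd.Series(np.nan, index=t.index)).to_numpy(dtype=float)
    not_last = exon_index < n_exons
    return truncating & expressed & np.nan_to_num(not_last, nan=False).astype(bool)
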