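"""Fusing binding and expression evidence into regulatory classes.

Genes are grouped by whether the repressor occupies their promoter (bound)
and how their expression responds to its deletion:

* class1 — bound and upregulated in the mutant: direct repression.
* class2 — bound but unchanged: direct targets whose activators are absent
  or saturating under the assay condition.
* class3_up / class3_down — not bound but differentially expressed:
  indirect targets, acting through regulators the repressor controls.
* class4 — bound and downregulated in the mutant: binding supports their
  high wild-type expression.
* none — neither bound nor differentially expressed (or filtered).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .expression import DE_STATUSES
from .errors import ConfigError

REG_CLASSES = ("class1", "class2", "class3_up", "class3_down", "class4", "none")


def assign_regulatory_class(
    bound: bool, de_status: str, rescue_as_de: bool = True
) -> str:
    """Map (bound, DE status) to the four-class regulatory label."""
    if de_status not in DE_STATUSES:
        raise ValueError(f"unknown DE status {de_status!r}")
    if de_status == "filtered":
        return "none"
    if de_status in ("rescued_up", "rescued_down"):
        de_status = de_status.removeprefix("rescued_") if rescue_as_de else "unchanged"
    if de_status == "up":
        return "class1" if bound else "class3_up"
    if de_status == "down":
        return "class4" if bound else "class3_down"
    return "class2" if bound else "none"  # unchanged


def build_regulation_table(
    genes: Iterable[str],
    site_counts: pd.DataFrame,
    de_records: pd.DataFrame,
    rescue_as_de: bool = True,
) -> pd.DataFrame:
    """Master per-gene table of binding evidence, DE status and class.

    ``site_counts`` is the per-promoter site-count frame (gene_id-indexed,
    ``n_sites`` column); genes absent from it are unbound.  ``de_records``
    is gene_id-indexed with log2fc/padj/status; genes absent from it are
    treated as unchanged.
    """
    idx = pd.Index(sorted(genes), name="gene_id")
    n_sites = site_counts["n_sites"].reindex(idx).fillna(0).astype(int)
    de = de_records.reindex(idx)
    status = de["status"].fillna("unchanged") if "status" in de else pd.Series("unchanged", idx)
    out = pd.DataFrame(
        {
            "bound": n_sites > 0,
            "n_sites": n_sites,
            "multi_site": n_sites >= 2,
            "log2fc": de["log2fc"].fillna(0.0) if "log2fc" in de else 0.0,
            "padj": de["padj"].fillna(1.0) if "padj" in de else 1.0,
            "de_status": status,
        },
        index=idx,
    )
    out["reg_class"] = [
        assign_regulatory_class(b, s, rescue_as_de)
        for b, s in zip(out["bound"], out["de_status"])
    ]
    return out


def summarize_regulon(
    records: pd.DataFrame, categories: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Per-category class composition.

    One row per (category label, class) with the gene count and two
    percentages — of the category's classified genes and of the class total
    (the natural denominator is ambiguous, so both are emitted).
    """
    class_totals = records["reg_class"].value_counts()
    label_genes: dict[str, list[str]] = {}
    for gene, labels in categories.items():
        for lab in labels:
            label_genes.setdefault(lab, []).append(gene)
    rows = []
    for lab in sorted(label_genes):
        members = [g for g in label_genes[lab] if g in records.index]
        counts = records.loc[members, "reg_class"].value_counts()
        n_cat = len(members)
        for cls in REG_CLASSES:
            n = int(counts.get(cls, 0))
            rows.append(
                {
                    "category": lab,
                    "reg_class": cls,
                    "n_genes": n,
                    "pct_of_category": 100.0 * n / n_cat if n_cat else 0.0,
                    "pct_of_class": 100.0 * n / class_totals.get(cls, 1)
                    if class_totals.get(cls, 0)
                    else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["category", "reg_class", "n_genes", "pct_of_category", "pct_of_class"]
    )


def enrichment_test(
    selected: Iterable[str], category: Iterable[str], universe: Iterable[str]
) -> float:
    """One-sided hypergeometric enrichment p-value, P(X >= overlap).

    A stand-in for pathway-database enrichment: draws |selected| genes from
    a universe containing |category| successes.
    """
    uni = set(universe)
    if not uni:
        raise ConfigError("empty gene universe")
    sel = set(selected) & uni
    cat = set(category) & uni
    k = len(sel & cat)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, len(uni), len(cat), len(sel)))


def enrichment_table(
    records: pd.DataFrame,
    categories: Mapping[str, Iterable[str]],
    reg_class: str = "class1",
) -> pd.DataFrame:
    """Hypergeometric enrichment of each category in one regulatory class."""
    from .expression import bh_adjust

    universe = list(records.index)
    selected = list(records.index[records["reg_class"] == reg_class])
    label_genes: dict[str, set[str]] = {}
    for gene, labels in categories.items():
        for lab in labels:
            label_genes.setdefault(lab, set()).add(gene)
    rows = []
    for lab in sorted(label_genes):
        cat = label_genes[lab]
        overlap = len(set(selected) & cat & set(universe))
        rows.append(
            {
                "category": lab,
                "reg_class": reg_class,
                "category_size": len(cat & set(universe)),
                "selected_size": len(selected),
                "overlap": overlap,
                "pvalue": enrichment_test(selected, cat, universe),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["category", "reg_class", "category_size", "selected_size", "overlap", "pvalue"],
    )
    if len(df):
        df["padj"] = bh_adjust(df["pvalue"].values)
    else:
        df["padj"] = []
    return df


def tf_regulon_report(records: pd.DataFrame, tf_flags: Mapping[str, bool]) -> pd.DataFrame:
    """TF vs non-TF genes by binding, DE, class membership and multi-site.

    Quantifies whether regulator-encoding genes are disproportionately
    bound (and multiply bound) relative to the rest of the genome.
    """
    flags = pd.Series({g: bool(tf_flags.get(g, False)) for g in records.index})
    de_mask = records["de_status"].isin(["up", "down", "rescued_up", "rescued_down"])
    rows = []
    for group, mask in (("TF", flags), ("non_TF", ~flags)):
        sub = records[mask.values]
        n = len(sub)
        bound = int(sub["bound"].sum())
        de = int(de_mask[mask.values].sum())
        both = int((sub["bound"] & de_mask[mask.values]).sum())
        multi = int(sub["multi_site"].sum())
        row = {
            "group": group,
            "n_genes": n,
            "bound": bound,
            "de": de,
            "bound_and_de": both,
            "under_control": int((sub["reg_class"] != "none").sum()),
            "multi_site": multi,
            "pct_bound": 100.0 * bound / n if n else 0.0,
            "pct_multi_site": 100.0 * multi / n if n else 0.0,
        }
        for cls in REG_CLASSES:
            row[cls] = int((sub["reg_class"] == cls).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
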