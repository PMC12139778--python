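"""Stoichiometry summaries and genotype comparison.

Implements the five-step filtering analysis on classified colocalized
pairs — normalize and classify far-red, normalize and classify green,
then keep only pairs whose green trace is non-rejected AND whose far-red
trace is non-rejected — followed by per-replicate class percentages, the
oligomeric fraction (share of retained pairs with >= 2 far-red steps),
and a nested one-way ANOVA (technical replicates nested in biological
replicates) with Tukey-adjusted pairwise comparisons across genotypes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import REJECTED

__all__ = [
    "ReplicateDesign", "StoichSummary", "run_pipeline", "summarize",
    "compare_groups", "ComparisonResult", "retained",
]

STEP_CLASSES = ("1-step", "2-step", "3-and-higher")
OLIGOMERIC = ("2-step", "3-and-higher")


@dataclass
class ReplicateDesign:
    """Maps field ids onto (genotype, biological, technical) replicates."""

    table: pd.DataFrame  # columns: field_id, genotype, bio_rep, tech_rep

    def __post_init__(self) -> None:
        required = {"field_id", "genotype", "bio_rep", "tech_rep"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns {missing}")
        if self.table["field_id"].duplicated().any():
            raise ValueError("each field must map to exactly one replicate cell")


def retained(green_class: pd.Series, farred_class: pd.Series) -> pd.Series:
    """The filter predicate: green is 1-step AND far-red is not rejected."""
    return (green_class == "1-step") & (farred_class != REJECTED)


def run_pipeline(pairs: pd.DataFrame, green_traces: pd.DataFrame,
                 farred_traces: pd.DataFrame, green_model,
                 farred_model) -> tuple[pd.DataFrame, dict]:
    """Classify colocalized trace pairs and apply the retention filter.

    Five steps, in order: (1) normalize far-red traces; (2) classify
    them; (3) normalize green traces; (4) classify them; (5) retain only
    pairs where a non-rejected green trace accompanies a non-rejected
    far-red trace. Models provide ``classify_traces(raw) -> labels``
    (trained CNNs Z-score internally; the rule-based classifier works on
    raw counts directly).

    ``pairs`` must have columns green_spot_id / farred_spot_id (plus any
    bookkeeping columns, carried through); trace tables have one column
    per spot id, one row per frame. Pairs referencing a missing or
    flagged (all-NaN) trace are excluded as orphans and counted.

    Returns the classified pair table (with green_class, farred_class,
    retained) and a stage-count dict.
    """
    pairs = pairs.copy()
    g_cols = {str(c): c for c in green_traces.columns}
    f_cols = {str(c): c for c in farred_traces.columns}
    ok_g = pairs["green_spot_id"].astype(str).isin(g_cols)
    ok_f = pairs["farred_spot_id"].astype(str).isin(f_cols)
    usable = pairs[ok_g & ok_f].copy()

    def _stack(trace_df, ids, col_map):
        mat = np.stack([trace_df[col_map[str(i)]].to_numpy(dtype=float)
                        for i in ids]) if len(ids) else np.empty((0, 0))
        return mat

    g_mat = _stack(green_traces, usable["green_spot_id"], g_cols)
    f_mat = _stack(farred_traces, usable["farred_spot_id"], f_cols)
    finite = (np.isfinite(g_mat).all(axis=1) & np.isfinite(f_mat).all(axis=1)
              if len(usable) else np.array([], dtype=bool))
    orphaned = int(len(pairs) - int(finite.sum()))
    usable = usable[finite]
    g_mat, f_mat = g_mat[finite], f_mat[finite]

    # steps 1-2: far-red; steps 3-4: green (normalization happens inside
    # each model's classify_traces); step 5: the retention filter
    usable["farred_class"] = (farred_model.classify_traces(f_mat)
                              if len(usable) else [])
    usable["green_class"] = (green_model.classify_traces(g_mat)
                             if len(usable) else [])
    usable["retained"] = retained(usable["green_class"],
                                  usable["farred_class"])
    counts = {
        "pairs_in": int(len(pairs)),
        "orphaned": orphaned,
        "classified": int(len(usable)),
        "retained": int(usable["retained"].sum()),
        "rejected_by_filter": int((~usable["retained"]).sum()),
    }
    return usable.reset_index(drop=True), counts


def _class_percentages(labels: pd.Series) -> dict:
    out = {}
    total = len(labels)
    for c in STEP_CLASSES:
        n = int((labels == c).sum())
        out[f"n_{c}"] = n
        out[f"pct_{c}"] = 100.0 * n / total if total else np.nan
    out["n_total"] = total
    olig = sum(out[f"n_{c}"] for c in OLIGOMERIC)
    out["oligomeric_pct"] = 100.0 * olig / total if total else np.nan
    return out


@dataclass
class StoichSummary:
    """Class percentages at technical, biological and genotype level.

    ``biological`` carries both pooling conventions: ``oligomeric_pct``
    pools technical-replicate counts; ``oligomeric_pct_mean_of_tech``
    averages technical-replicate percentages.
    """

    technical: pd.DataFrame
    biological: pd.DataFrame
    genotype: pd.DataFrame
    excluded_replicates: list = field(default_factory=list)


def summarize(classified_pairs: pd.DataFrame,
              design: ReplicateDesign) -> StoichSummary:
    """Per-replicate far-red class percentages over retained pairs.

    Technical replicates report their own percentages; biological
    replicates pool their technical counts (and also report the mean of
    technical percentages); genotypes report mean +/- SEM of
    biological-replicate oligomeric percentages. Empty replicates are
    flagged and excluded from the means.
    """
    if "field_id" not in classified_pairs.columns:
        raise ValueError("classified pairs need a field_id column")
    kept = classified_pairs[classified_pairs["retained"]].merge(
        design.table, on="field_id", how="left")
    if kept["genotype"].isna().any():
        raise ValueError("some pairs reference fields absent from the design")

    tech_rows, excluded = [], []
    for (gen, bio, tech), grp in kept.groupby(
            ["genotype", "bio_rep", "tech_rep"], sort=True):
        row = {"genotype": gen, "bio_rep": bio, "tech_rep": tech}
        row.update(_class_percentages(grp["farred_class"]))
        tech_rows.append(row)
    # replicate cells present in the design but with no retained pairs
    cells = design.table.groupby(["genotype", "bio_rep", "tech_rep"]).size()
    seen = {(r["genotype"], r["bio_rep"], r["tech_rep"]) for r in tech_rows}
    excluded = [c for c in cells.index if c not in seen]
    technical = pd.DataFrame(tech_rows)

    bio_rows = []
    for (gen, bio), grp in kept.groupby(["genotype", "bio_rep"], sort=True):
        row = {"genotype": gen, "bio_rep": bio}
        row.update(_class_percentages(grp["farred_class"]))
        sub = technical[(technical["genotype"] == gen)
                        & (technical["bio_rep"] == bio)]
        row["oligomeric_pct_mean_of_tech"] = float(
            sub["oligomeric_pct"].mean())
        bio_rows.append(row)
    biological = pd.DataFrame(bio_rows)

    gen_rows = []
    for gen, grp in biological.groupby("genotype", sort=True):
        vals = grp["oligomeric_pct"].to_numpy(dtype=float)
        gen_rows.append({
            "genotype": gen,
            "n_bio_reps": len(vals),
            "oligomeric_pct_mean": float(vals.mean()),
            "oligomeric_pct_sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else np.nan,
        })
    return StoichSummary(technical=technical, biological=biological,
                         genotype=pd.DataFrame(gen_rows),
                         excluded_replicates=excluded)


@dataclass
class ComparisonResult:
    """Nested one-way ANOVA across genotypes plus Tukey HSD pairs."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame


def compare_groups(technical: pd.DataFrame,
                   value: str = "oligomeric_pct") -> ComparisonResult:
    """Nested one-way ANOVA on per-technical-replicate values.

    Genotype is the fixed factor and biological replicate the nested
    error stratum: F = MS(genotype) / MS(bio within genotype). For
    balanced designs this is identical to a one-way ANOVA on
    biological-replicate means. Tukey's HSD runs on the
    biological-replicate means.
    """
    required = {"genotype", "bio_rep", value}
    if not required <= set(technical.columns):
        raise ValueError(f"need columns {required}")
    d = technical.dropna(subset=[value])
    genotypes = sorted(d["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes to compare")
    for g in genotypes:
        if d[d["genotype"] == g]["bio_rep"].nunique() < 2:
            raise ValueError(f"genotype {g!r} has fewer than 2 biological "
                             "replicates")

    grand = d[value].mean()
    ss_a = 0.0      # between genotypes
    ss_b = 0.0      # biological replicates within genotype
    n_bio_total = 0
    for g in genotypes:
        dg = d[d["genotype"] == g]
        ss_a += len(dg) * (dg[value].mean() - grand) ** 2
        for _, db in dg.groupby("bio_rep"):
            ss_b += len(db) * (db[value].mean() - dg[value].mean()) ** 2
            n_bio_total += 1
    df_a = len(genotypes) - 1
    df_b = n_bio_total - len(genotypes)
    if df_b < 1:
        raise ValueError("not enough biological replicates for a nested test")
    ms_a = ss_a / df_a
    ms_b = ss_b / df_b
    if ms_b == 0:
        f_stat = 0.0 if ms_a == 0 else np.inf
    else:
        f_stat = ms_a / ms_b
    p = float(stats.f.sf(f_stat, df_a, df_b)) if np.isfinite(f_stat) else 0.0

    bio_means = (d.groupby(["genotype", "bio_rep"])[value].mean()
                 .reset_index())
    samples = [bio_means[bio_means["genotype"] == g][value].to_numpy()
               for g in genotypes]
    tk = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(genotypes)):
        for j in range(i + 1, len(genotypes)):
            rows.append({"group_a": genotypes[i], "group_b": genotypes[j],
                         "mean_diff": float(np.mean(samples[i])
                                            - np.mean(samples[j])),
                         "p_adj": float(tk.pvalue[i, j])})
    return ComparisonResult(f_statistic=float(f_stat), df_between=df_a,
                            df_within=df_b, p_value=p,
                            tukey=pd.DataFrame(rows))
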