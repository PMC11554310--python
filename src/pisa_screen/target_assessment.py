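"""Known-target bookkeeping: on-target hit rates and target/non-target separation.

Each library compound carries at least one annotated target.  A compound is
"on-target" in a given assay mode if *any* of its annotated targets is a hit
in that mode (multi-target compounds count once); compounds whose targets
were never quantified are excluded from rate denominators.  Combining cell-
and lysate-based screens raises the on-target rate because some targets only
respond in one setting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "read_target_annotations",
    "on_target_table",
    "hit_rate_summary",
    "target_separation_test",
    "ground_truth_recovery",
]


def read_target_annotations(path) -> pd.DataFrame:
    """Read a compound->target table (TSV/CSV; one row per pair).

    Requires columns ``compound_id`` and ``target_protein_id``; an optional
    ``target_class`` column is preserved.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    ann = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("compound_id", "target_protein_id"):
        if col not in ann.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    return ann


def on_target_table(
    hit_tables: dict[str, pd.DataFrame], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-compound on-target status in each mode and combined.

    ``hit_tables`` maps a mode name (e.g. ``"cell"``, ``"lysate"``) to a hit
    table from :func:`pisa_screen.hit_calling.call_hits`.  For every
    annotated compound and mode, records whether any annotated target was
    quantified under that compound and whether any was a hit; ``combined``
    columns take the union over modes.
    """
    compounds = sorted(annotations["compound_id"].unique())
    targets = annotations.groupby("compound_id")["target_protein_id"].agg(set)
    rows = []
    for c in compounds:
        tset = targets[c]
        row: dict[str, object] = {"compound_id": c}
        any_q, any_h = False, False
        for mode, tbl in hit_tables.items():
            sub = tbl[(tbl["treatment_id"] == c) & tbl["protein_id"].isin(tset)]
            quantified = len(sub) > 0
            hit = bool(sub["is_hit"].any()) if quantified else False
            row[f"target_quantified_{mode}"] = quantified
            row[f"on_target_{mode}"] = hit
            any_q |= quantified
            any_h |= hit
        row["target_quantified_combined"] = any_q
        row["on_target_combined"] = any_h
        rows.append(row)
    return pd.DataFrame(rows)


def hit_rate_summary(table: pd.DataFrame) -> pd.DataFrame:
    """On-target hit rates with numerators and denominators.

    Per mode, the denominator is the number of compounds with a quantified
    target in that mode.  The ``combined`` rate is computed over compounds
    whose target was quantified in *every* mode present (the directly
    comparable panel), with the numerator counting a hit in any mode.
    """
    modes = [c.removeprefix("on_target_") for c in table.columns
             if c.startswith("on_target_") and c != "on_target_combined"]
    rows = []
    for mode in modes:
        den = int(table[f"target_quantified_{mode}"].sum())
        num = int(table[f"on_target_{mode}"].sum())
        rows.append({"mode": mode, "n_on_target": num, "n_quantified": den,
                     "rate": num / den if den else np.nan})
    if modes:
        both = table[np.logical_and.reduce(
            [table[f"target_quantified_{m}"] for m in modes])]
        num = int(np.logical_or.reduce(
            [both[f"on_target_{m}"] for m in modes]).sum()) if len(both) else 0
        den = len(both)
        rows.append({"mode": "combined", "n_on_target": num, "n_quantified": den,
                     "rate": num / den if den else np.nan})
    return pd.DataFrame(rows)


def target_separation_test(
    treatment_table: pd.DataFrame,
    annotations: pd.DataFrame,
    exact_below: int = 30,
) -> dict:
    """Two-sided Wilcoxon rank-sum on |mean log2fc|: targets vs non-targets.

    Compares the absolute treatment-level fold changes of annotated
    compound-target pairs against all other compound-protein pairs.  Exact
    enumeration is used below a combined sample size of ``exact_below``,
    otherwise the normal approximation with continuity correction.
    """
    tbl = treatment_table[~treatment_table["is_vehicle"].astype(bool)].dropna(
        subset=["mean_log2fc"])
    key = set(zip(annotations["compound_id"], annotations["target_protein_id"]))
    is_target = [
        (t, p) in key for t, p in zip(tbl["treatment_id"], tbl["protein_id"])
    ]
    is_target = np.asarray(is_target, dtype=bool)
    x = tbl.loc[is_target, "mean_log2fc"].abs().to_numpy()
    y = tbl.loc[~is_target, "mean_log2fc"].abs().to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both target and non-target groups must be non-empty")
    method = "exact" if (len(x) + len(y)) < exact_below else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return {
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "n_target": int(len(x)),
        "n_other": int(len(y)),
        "method": method,
    }


def ground_truth_recovery(
    hit_table: pd.DataFrame,
    ground_truth: pd.DataFrame,
    informative: pd.Series | None = None,
    min_abs_delta_tm: float = 2.0,
) -> dict:
    """Benchmark hit calls against a synthetic screen's injected effects.

    * sensitivity: fraction of applied primary effects with
      |delta Tm| >= ``min_abs_delta_tm`` (restricted to window-informative
      target proteins when ``informative`` is given) that were called hits;
    * false_call_rate: fraction of measured non-effect (protein, compound)
      pairs called hits;
    * log2fc_delta_tm_spearman: Spearman correlation between measured mean
      log2fc and injected delta Tm over quantified applied primary effects.
    """
    tbl = hit_table[~hit_table["is_vehicle"].astype(bool)]
    truth = ground_truth[ground_truth["applied"]] if "applied" in ground_truth else ground_truth
    primary = truth[truth["effect_class"] == "primary"]
    merged = primary.merge(
        tbl, left_on=["compound_id", "protein_id"],
        right_on=["treatment_id", "protein_id"], how="inner",
    )
    eligible = merged[merged["delta_tm"].abs() >= min_abs_delta_tm]
    if informative is not None:
        eligible = eligible[eligible["protein_id"].map(informative).fillna(False)]
    sensitivity = float(eligible["is_hit"].mean()) if len(eligible) else np.nan

    effect_pairs = set(zip(truth["compound_id"], truth["protein_id"]))
    noneffect = tbl[
        [
            (t, p) not in effect_pairs
            for t, p in zip(tbl["treatment_id"], tbl["protein_id"])
        ]
    ]
    false_rate = float(noneffect["is_hit"].mean()) if len(noneffect) else np.nan

    quant = merged.dropna(subset=["mean_log2fc"])
    if len(quant) >= 3:
        rho = float(sps.spearmanr(quant["delta_tm"], quant["mean_log2fc"]).statistic)
    else:
        rho = np.nan
    return {
        "sensitivity": sensitivity,
        "n_eligible_effects": int(len(eligible)),
        "false_call_rate": false_rate,
        "n_noneffect_pairs": int(len(noneffect)),
        "log2fc_delta_tm_spearman": rho,
        "n_quantified_effects": int(len(quant)),
    }
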