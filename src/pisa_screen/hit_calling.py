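"""Replicate fold changes, trimmed-SD z-scores (nSD), and dual-cutoff hits.

Duplicate screen designs leave classical per-treatment tests underpowered,
so significance is called empirically: each treated channel is expressed as
a log2 fold change against the mean of the vehicle channels of its plex, the
spread of a protein's treatment-level fold changes across the whole screen
is summarized by a trimmed standard deviation, and a treatment is a hit only
if *both* replicates exceed the fold-change cutoff and the treatment mean
lies more than ``nsd_cutoff`` trimmed standard deviations from the protein's
(trimmed) mean.  The false-positive behaviour of the cutoffs is measured by
re-labelling pairs of vehicle channels as pseudo-compounds and scoring them
through the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant_io import AbundanceMatrix

__all__ = [
    "compute_log2fc",
    "protein_variability",
    "compute_nsd",
    "call_hits",
    "dmso_false_hit_rate",
    "per_compound_hit_counts",
    "FalseHitRate",
]

DEFAULT_FC_CUTOFF = 0.2
DEFAULT_NSD_CUTOFF = 3.5
DEFAULT_TRIM_FRACTION = 0.1


def _vehicle_pseudo_id(plex_id: str) -> str:
    return f"DMSO::{plex_id}"


def compute_log2fc(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Replicate-level log2 fold changes versus the plex vehicle mean.

    For every protein and channel, log2fc = log2(abundance / mean abundance
    over the vehicle channels of the same plex), missing wherever the
    protein is unquantified in the channel or in all vehicle channels.
    Vehicle channels themselves are kept, re-labelled as one per-plex pseudo
    treatment (``DMSO::<plex>``), so that vehicle variability enters the
    per-protein spread estimate downstream.

    Returns a long table: protein_id, plex_id, channel_id, treatment_id,
    replicate_index, is_vehicle, log2fc.
    """
    ann = matrix.annotations
    vals = matrix.values
    pieces = []
    for plex, cols in ann.groupby("plex_id").groups.items():
        cols = list(cols)
        sub_ann = ann.loc[cols]
        veh_cols = sub_ann.index[sub_ann["is_vehicle"]].tolist()
        if not veh_cols:
            raise ValueError(f"plex {plex!r} has no vehicle channels")
        vmean = vals[veh_cols].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(vals[cols].div(vmean, axis=0))
        fc[~np.isfinite(fc)] = np.nan
        long = fc.stack(future_stack=True).rename("log2fc").reset_index()
        long.columns = ["protein_id", "channel_id", "log2fc"]
        long["plex_id"] = plex
        long["is_vehicle"] = long["channel_id"].map(sub_ann["is_vehicle"]).astype(bool)
        treat = sub_ann["treatment_id"].copy()
        treat[sub_ann["is_vehicle"]] = _vehicle_pseudo_id(str(plex))
        long["treatment_id"] = long["channel_id"].map(treat)
        long["replicate_index"] = long["channel_id"].map(sub_ann["replicate_index"])
        pieces.append(long)
    out = pd.concat(pieces, ignore_index=True)
    return out[
        ["protein_id", "plex_id", "channel_id", "treatment_id",
         "replicate_index", "is_vehicle", "log2fc"]
    ]


def _trimmed_row_stats(m: np.ndarray, trim_fraction: float):
    """Row-wise symmetric-trim mean and SD (population), NaN-aware.

    Trims floor(n * trim_fraction) values from each tail of every row,
    where n is that row's non-missing count.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5); trimming both tails "
                         "by >= 0.5 removes every value")
    n = np.sum(~np.isnan(m), axis=1)
    s = np.sort(m, axis=1)  # NaNs sort last
    k = np.floor(n * trim_fraction).astype(int)
    lo, hi = k, n - k
    x = np.where(np.isnan(s), 0.0, s)
    zeros = np.zeros((m.shape[0], 1))
    c1 = np.concatenate([zeros, np.cumsum(x, axis=1)], axis=1)
    c2 = np.concatenate([zeros, np.cumsum(x * x, axis=1)], axis=1)
    rows = np.arange(m.shape[0])
    cnt = (hi - lo).astype(float)
    ok = cnt > 0
    mean = np.full(m.shape[0], np.nan)
    sd = np.full(m.shape[0], np.nan)
    s1 = c1[rows, hi] - c1[rows, lo]
    s2 = c2[rows, hi] - c2[rows, lo]
    mean[ok] = s1[ok] / cnt[ok]
    var = np.clip(s2[ok] / cnt[ok] - mean[ok] ** 2, 0.0, None)
    sd[ok] = np.sqrt(var)
    return mean, sd, n


def _treatment_means(log2fc: pd.DataFrame) -> pd.DataFrame:
    """Pivot to a proteins x treatments matrix of replicate-averaged log2fc."""
    return log2fc.pivot_table(
        index="protein_id", columns="treatment_id", values="log2fc",
        aggfunc="mean", dropna=False,
    )


def protein_variability(
    log2fc: pd.DataFrame,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    min_treatments: int = 3,
) -> pd.DataFrame:
    """Per-protein trimmed mean/SD of treatment-level log2 fold changes.

    Replicates are averaged first; the pool of treatment-level values spans
    every treatment in the screen, including the per-plex vehicle pseudo
    treatments.  Rows with fewer than ``min_treatments`` values are flagged
    unusable.  Returns a DataFrame indexed by protein with columns
    ``mean_log2fc_all_treatments``, ``trimmed_sd``, ``n_treatments``,
    ``usable``.
    """
    tm = _treatment_means(log2fc)
    mean, sd, n = _trimmed_row_stats(tm.to_numpy(dtype=float), trim_fraction)
    out = pd.DataFrame(
        {
            "mean_log2fc_all_treatments": mean,
            "trimmed_sd": sd,
            "n_treatments": n,
            "usable": n >= min_treatments,
        },
        index=tm.index,
    )
    return out


def compute_nsd(log2fc: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level table with the nSD z-score filled in.

    nsd = (treatment mean log2fc - protein trimmed mean) / protein trimmed
    SD; missing when the protein's stats are unusable or its trimmed SD is
    zero (constant proteins can never be hits).

    Returns one row per (protein, treatment): mean_log2fc, n_replicates,
    min_abs_log2fc, rep1_log2fc, rep2_log2fc, nsd, is_vehicle.
    """
    df = log2fc.copy()
    df["abs_log2fc"] = df["log2fc"].abs()
    g = df.groupby(["protein_id", "treatment_id"], sort=True)
    table = g.agg(
        mean_log2fc=("log2fc", "mean"),
        n_replicates=("log2fc", "count"),
        min_abs_log2fc=("abs_log2fc", "min"),
        is_vehicle=("is_vehicle", "first"),
    ).reset_index()
    reps = df[df["replicate_index"].isin([1, 2])].pivot_table(
        index=["protein_id", "treatment_id"], columns="replicate_index",
        values="log2fc", aggfunc="first", dropna=False,
    )
    reps.columns = [f"rep{int(c)}_log2fc" for c in reps.columns]
    table = table.merge(reps.reset_index(), on=["protein_id", "treatment_id"], how="left")
    for col in ("rep1_log2fc", "rep2_log2fc"):
        if col not in table.columns:
            table[col] = np.nan

    st = stats.reindex(table["protein_id"])
    center = st["mean_log2fc_all_treatments"].to_numpy()
    sd = st["trimmed_sd"].to_numpy()
    usable = st["usable"].to_numpy(dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        nsd = (table["mean_log2fc"].to_numpy() - center) / sd
    nsd[~usable | (sd == 0) | ~np.isfinite(nsd)] = np.nan
    table["nsd"] = nsd
    return table


def call_hits(
    log2fc: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    nsd_cutoff: float = DEFAULT_NSD_CUTOFF,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Dual-cutoff hit calls on the replicate log2fc table.

    A (protein, treatment) is a hit iff every replicate satisfies
    |log2fc| >= fc_cutoff (both-replicate rule; treatments with a missing
    replicate are ineligible) and |nSD| >= nsd_cutoff.  Cutoffs are applied
    inclusively.  Direction is ``stabilized`` for hits with positive mean
    log2fc, ``destabilized`` for negative.
    """
    if stats is None:
        stats = protein_variability(log2fc, trim_fraction=trim_fraction)
    table = compute_nsd(log2fc, stats)
    fc_ok = (table["min_abs_log2fc"] >= fc_cutoff) & (table["n_replicates"] >= 2)
    nsd_ok = table["nsd"].abs() >= nsd_cutoff
    table["is_hit"] = (fc_ok & nsd_ok).fillna(False).astype(bool)
    direction = np.where(
        table["is_hit"] & (table["mean_log2fc"] > 0), "stabilized",
        np.where(table["is_hit"] & (table["mean_log2fc"] < 0), "destabilized", "none"),
    )
    table["direction"] = direction
    return table


@dataclass
class FalseHitRate:
    """Vehicle-derived false-hit rate (n_DMSO-hits) and its bookkeeping."""

    rate: float
    n_hits: int
    n_measurements: int
    per_plex: pd.DataFrame


def dmso_false_hit_rate(
    matrix: AbundanceMatrix,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    nsd_cutoff: float = DEFAULT_NSD_CUTOFF,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> FalseHitRate:
    """Estimate the false-hit rate from vehicle channels.

    Within each plex, disjoint pairs of vehicle channels are re-labelled as
    duplicate pseudo-compounds, one pair per plex per round, and scored
    against the remaining vehicle channels through the full hit-calling
    pipeline (normalized input assumed).  The rate is the number of
    (protein, pseudo-compound) hits divided by the number of fully measured
    (protein, pseudo-compound) pairs across all rounds.  Requires at least
    four vehicle channels per plex so each held-out pair leaves a two-channel
    reference.
    """
    ann = matrix.annotations
    pairs_by_plex: dict[str, list[tuple[str, str]]] = {}
    for plex, cols in ann.groupby("plex_id").groups.items():
        veh = [c for c in cols if ann.loc[c, "is_vehicle"]]
        if len(veh) < 4:
            raise ValueError(
                f"plex {plex!r} has {len(veh)} vehicle channels; >= 4 are needed "
                "to hold out a pseudo-compound pair"
            )
        pairs_by_plex[str(plex)] = [
            (veh[i], veh[i + 1]) for i in range(0, len(veh) - 1, 2)
        ]
    n_rounds = max(len(p) for p in pairs_by_plex.values())

    total_hits = 0
    total_meas = 0
    plex_rows: dict[str, list[int]] = {p: [0, 0] for p in pairs_by_plex}
    for r in range(n_rounds):
        new_ann = ann.copy()
        pseudo_ids = {}
        for plex, pairs in pairs_by_plex.items():
            if r >= len(pairs):
                continue
            a, b = pairs[r]
            tid = f"pseudoDMSO::{plex}::round{r + 1}"
            pseudo_ids[tid] = plex
            new_ann.loc[[a, b], "treatment_id"] = tid
            new_ann.loc[[a, b], "is_vehicle"] = False
            new_ann.loc[a, "replicate_index"] = 1
            new_ann.loc[b, "replicate_index"] = 2
        relabeled = AbundanceMatrix(matrix.values, new_ann)
        hits = call_hits(
            compute_log2fc(relabeled), fc_cutoff=fc_cutoff,
            nsd_cutoff=nsd_cutoff, trim_fraction=trim_fraction,
        )
        sub = hits[hits["treatment_id"].isin(pseudo_ids)]
        measured = sub[sub["n_replicates"] >= 2]
        total_hits += int(measured["is_hit"].sum())
        total_meas += len(measured)
        by_t = measured.groupby("treatment_id")["is_hit"].agg(["sum", "count"])
        for tid, row in by_t.iterrows():
            plex_rows[pseudo_ids[tid]][0] += int(row["sum"])
            plex_rows[pseudo_ids[tid]][1] += int(row["count"])

    per_plex = pd.DataFrame(
        [
            {"plex_id": p, "n_hits": h, "n_measurements": m,
             "rate": (h / m if m else np.nan)}
            for p, (h, m) in sorted(plex_rows.items())
        ]
    )
    rate = total_hits / total_meas if total_meas else np.nan
    return FalseHitRate(rate=rate, n_hits=total_hits, n_measurements=total_meas,
                        per_plex=per_plex)


def per_compound_hit_counts(hit_table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-compound stabilized/destabilized hit counts and the screen median.

    Vehicle pseudo-treatments are excluded.  Compounds with no hits are kept
    with zero counts so the median reflects the full compound panel.
    """
    tbl = hit_table[~hit_table["is_vehicle"].astype(bool)]
    compounds = sorted(tbl["treatment_id"].unique())
    if not compounds:
        return (
            pd.DataFrame(columns=["treatment_id", "n_stabilized", "n_destabilized", "n_total"]),
            0.0,
        )
    hits = tbl[tbl["is_hit"]]
    stab = hits[hits["direction"] == "stabilized"].groupby("treatment_id").size()
    destab = hits[hits["direction"] == "destabilized"].groupby("treatment_id").size()
    counts = pd.DataFrame({"treatment_id": compounds})
    counts["n_stabilized"] = counts["treatment_id"].map(stab).fillna(0).astype(int)
    counts["n_destabilized"] = counts["treatment_id"].map(destab).fillna(0).astype(int)
    counts["n_total"] = counts["n_stabilized"] + counts["n_destabilized"]
    return counts, float(counts["n_total"].median())
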