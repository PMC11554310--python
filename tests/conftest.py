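import numpy as np
import pandas as pd
import pytest

from pisa_screen.quant_io import AbundanceMatrix


def make_matrix(values: dict, treatments: dict, plex_id: str = "plex1") -> AbundanceMatrix:
    """Build a single-plex AbundanceMatrix from plain dicts.

    ``values`` maps protein_id -> list of abundances (one per channel);
    ``treatments`` maps channel_id -> (treatment_id, replicate_index,
    is_vehicle), in column order.
    """
    channels = list(treatments)
    vals = pd.DataFrame.from_dict(values, orient="index", columns=channels)
    vals.index.name = "protein_id"
    ann = pd.DataFrame(
        [
            {
                "channel_id": ch,
                "plex_id": plex_id,
                "treatment_id": t,
                "replicate_index": r,
                "is_vehicle": v,
            }
            for ch, (t, r, v) in treatments.items()
        ]
    ).set_index("channel_id")
    return AbundanceMatrix(vals, ann)


@pytest.fixture
def tiny_matrix() -> AbundanceMatrix:
    """3 proteins x 4 channels: one compound in duplicate + two vehicles."""
    return make_matrix(
        values={
            "P1": [2.0, 2.0, 1.0, 1.0],
            "P2": [1.0, 1.0, 1.0, 1.0],
            "P3": [0.5, 0.5, 1.0, 1.0],
        },
        treatments={
            "c1": ("drugA", 1, False),
            "c2": ("drugA", 2, False),
            "v1": ("DMSO", 1, True),
            "v2": ("DMSO", 2, True),
        },
    )


def spearman_brute(a, b):
    """Independent Spearman oracle: average ranks then Pearson, pairwise-complete."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[mask], b[mask]

    def avg_rank(x):
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x), dtype=float)
        ranks[order] = np.arange(1, len(x) + 1)
        for v in np.unique(x):
            sel = x == v
            ranks[sel] = ranks[sel].mean()
        return ranks

    ra, rb = avg_rank(a), avg_rank(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    return np.nan if denom == 0 else float((ra @ rb) / denom)


def trimmed_stats_brute(values, trim_fraction):
    """Independent trimmed mean/SD oracle: sort, slice floor(n*trim) per tail."""
    x = np.sort(np.asarray([v for v in values if not np.isnan(v)], dtype=float))
    k = int(np.floor(len(x) * trim_fraction))
    kept = x[k: len(x) - k]
    return float(np.mean(kept)), float(np.std(kept))
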