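"""Reading, validation, and normalization of protein abundance matrices.

The on-disk format is a wide delimited matrix (first column ``protein_id``,
one column per TMT channel) plus a separate sample-annotation table keyed by
channel id.  The delimiter is chosen by extension (``.csv`` -> comma,
anything else -> tab).  Missing quantifications stay missing throughout; no
imputation is performed anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VEHICLE_TREATMENT",
    "AbundanceMatrix",
    "read_matrix",
    "write_matrix",
    "normalize_channel_sums",
]

#: Reserved treatment id for vehicle (DMSO) control channels.
VEHICLE_TREATMENT = "DMSO"

ANNOTATION_COLUMNS = ["channel_id", "plex_id", "treatment_id", "replicate_index", "is_vehicle"]
OPTIONAL_ANNOTATION_COLUMNS = ["dose", "mode"]


def _delimiter(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class AbundanceMatrix:
    """Proteins x channels soluble-abundance matrix with channel annotations.

    Attributes
    ----------
    values : pandas.DataFrame
        Non-negative abundances, indexed by unique protein ids, one column
        per channel id.  NaN marks a missing quantification.
    annotations : pandas.DataFrame
        One row per channel, indexed by ``channel_id``, with columns
        ``plex_id``, ``treatment_id``, ``replicate_index``, ``is_vehicle``
        and optionally ``dose`` and ``mode``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals, ann = self.values, self.annotations
        if vals.index.duplicated().any():
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups[:5]}")
        if ann.index.name != "channel_id":
            if "channel_id" in ann.columns:
                ann = ann.set_index("channel_id")
                self.annotations = ann
            else:
                raise ValueError("annotations must be keyed by channel_id")
        if ann.index.duplicated().any():
            raise ValueError("duplicate channel ids in annotations")
        missing_ann = [c for c in vals.columns if c not in ann.index]
        if missing_ann:
            raise ValueError(f"matrix columns absent from annotations: {missing_ann}")
        extra_ann = [c for c in ann.index if c not in vals.columns]
        if extra_ann:
            raise ValueError(f"annotated channels absent from matrix: {extra_ann}")
        for col in ("plex_id", "treatment_id", "is_vehicle"):
            if col not in ann.columns:
                raise ValueError(f"annotation column {col!r} is required")
        if (vals.to_numpy(dtype=float) < 0).any():
            raise ValueError("abundances must be non-negative")
        # every plex needs at least two vehicle channels to define a reference
        veh = ann.groupby("plex_id")["is_vehicle"].sum()
        short = veh[veh < 2]
        if len(short):
            raise ValueError(
                f"plexes with fewer than two vehicle channels: {short.index.tolist()}"
            )
        # align annotation order to matrix columns
        aligned = ann.loc[list(vals.columns)]
        aligned.index.name = "channel_id"
        self.annotations = aligned

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def plexes(self) -> list[str]:
        return list(dict.fromkeys(self.annotations["plex_id"]))


def read_matrix(matrix_path: str | Path, annotation_path: str | Path) -> AbundanceMatrix:
    """Read and validate a matrix + annotation pair from disk."""
    vals = pd.read_csv(matrix_path, sep=_delimiter(matrix_path), index_col="protein_id")
    vals = vals.astype(float)
    ann = pd.read_csv(annotation_path, sep=_delimiter(annotation_path))
    if "channel_id" not in ann.columns:
        raise ValueError("annotation table must have a channel_id column")
    ann["channel_id"] = ann["channel_id"].astype(str)
    ann = ann.set_index("channel_id")
    if "is_vehicle" in ann.columns:
        ann["is_vehicle"] = ann["is_vehicle"].astype(bool)
    vals.columns = vals.columns.astype(str)
    return AbundanceMatrix(vals, ann)


def write_matrix(matrix: AbundanceMatrix, matrix_path: str | Path, annotation_path: str | Path) -> None:
    """Write a matrix + annotation pair; round-trips through :func:`read_matrix`."""
    matrix.values.rename_axis("protein_id").to_csv(
        matrix_path, sep=_delimiter(matrix_path), float_format="%.12g"
    )
    matrix.annotations.rename_axis("channel_id").to_csv(
        annotation_path, sep=_delimiter(annotation_path), float_format="%.12g"
    )


def normalize_channel_sums(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Equalize summed protein quantities across the channels of each plex.

    Within each plex, the column sums are computed over the proteins
    quantified in *all* channels of that plex (so missingness cannot bias the
    scale factors), and every channel is rescaled so those sums equal the
    plex-wide mean of the original sums.  Within-channel ratios between
    proteins are unchanged and the operation is idempotent.
    """
    vals = matrix.values.copy()
    ann = matrix.annotations
    for plex, cols in ann.groupby("plex_id").groups.items():
        cols = list(cols)
        block = vals[cols]
        complete = block.dropna()
        sums = complete.sum(axis=0)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0].tolist()
            raise ValueError(f"plex {plex!r} has all-zero/empty channels: {bad}")
        factors = sums.mean() / sums
        vals[cols] = block * factors
    return AbundanceMatrix(vals, ann.copy())
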