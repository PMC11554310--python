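"""Synthetic PISA screens with known ground truth.

The generator produces protein x TMT-channel abundance matrices from first
principles: each protein carries a two-state melting curve, each channel is
one pooled thermal-window sample, compound treatments shift the melting
temperature of their targets, and measurement noise plus per-channel loading
differences are applied multiplicatively.  Because every injected effect is
recorded in a ground-truth table, the whole downstream pipeline
(normalization, hit calling, target assessment, correlation networks) can be
benchmarked without any external data.

Defaults model the screening conditions used throughout: live-cell screens
with a 48-58 deg C window pooled from 10 temperatures, 16-channel plexes with
duplicate treatments, and 4 (cell) or 2 (lysate) vehicle channels per plex.
Secondary effects (indirect thermal-stability changes, e.g. from lost
phosphorylation) are flagged ``secondary`` and are suppressed in lysate mode,
where cellular signaling is disrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import PlexLayout, design_layout
from .melting import MeltingCurveParams, _soluble_fraction_matrix, window_grid
from .quant_io import AbundanceMatrix

__all__ = [
    "CompoundEffect",
    "ScreenDesign",
    "NoiseModel",
    "sample_proteome",
    "window_informative",
    "generate_screen",
    "default_effects",
    "simulate_screen",
    "simulate_null_screen",
    "simulate_planted_complex",
    "write_ground_truth",
]

# Default measurement noise: ~5% CV is typical protein-level precision for
# summed TMT reporter quantification after signal-to-noise filtering.
DEFAULT_MEASUREMENT_CV = 0.05
# Channel loading imbalance before normalization.
DEFAULT_LOADING_CV = 0.10


@dataclass(frozen=True)
class CompoundEffect:
    """A compound-induced melting-temperature shift on one protein.

    ``delta_tm`` is signed: positive for stabilization (soluble abundance
    increases over the window, positive log2FC), negative for
    destabilization.  ``effect_class`` is ``"primary"`` for direct ligand
    binding and ``"secondary"`` for indirect effects, which act in cell mode
    only.
    """

    compound_id: str
    protein_id: str
    delta_tm: float
    effect_class: str = "primary"

    def __post_init__(self) -> None:
        if self.effect_class not in ("primary", "secondary"):
            raise ValueError(f"effect_class must be primary|secondary, got {self.effect_class}")


@dataclass
class ScreenDesign:
    """Geometry and thermal protocol of a multiplexed PISA screen."""

    compounds: list[str]
    replicates_per_compound: int = 2
    plex_size: int = 16
    vehicle_channels_per_plex: int | None = None
    window_low: float = 48.0
    window_high: float = 58.0
    n_temperatures: int = 10
    mode: str = "cell"

    def __post_init__(self) -> None:
        if self.mode not in ("cell", "lysate"):
            raise ValueError(f"mode must be cell|lysate, got {self.mode}")
        if self.vehicle_channels_per_plex is None:
            # 6 compounds x 2 + 4 vehicle per 16-plex in cell mode;
            # 7 compounds x 2 + 2 vehicle per 16-plex in lysate mode.
            self.vehicle_channels_per_plex = 4 if self.mode == "cell" else 2

    def layout(self) -> PlexLayout:
        return design_layout(
            n_compounds=len(self.compounds),
            replicates=self.replicates_per_compound,
            plex_size=self.plex_size,
            vehicle_per_plex=self.vehicle_channels_per_plex,
            compound_ids=list(self.compounds),
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal measurement noise and channel loading.

    Both CVs are coefficients of variation of median-one log-normal factors;
    setting both to zero reproduces the noise-free expected matrix exactly.
    """

    measurement_cv: float = DEFAULT_MEASUREMENT_CV
    loading_cv: float = DEFAULT_LOADING_CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_cv < 0 or self.loading_cv < 0:
            raise ValueError("noise CVs must be non-negative")


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def sample_proteome(
    n_proteins: int,
    tm_mean: float = 50.0,
    tm_sd: float = 4.0,
    slope_range: tuple[float, float] = (1.0, 3.0),
    plateau_range: tuple[float, float] = (0.0, 0.15),
    seed: int = 0,
) -> pd.DataFrame:
    """Sample per-protein melting-curve parameters.

    Melting temperatures are normal around 50 deg C so the 48-58 deg C
    window covers the back half of most melting curves; transition slopes
    and non-denaturing plateaus are uniform over modest ranges.  Returns a
    DataFrame with columns ``protein_id, tm, slope, plateau``; reproducible
    for a fixed seed.
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(max(n_proteins, 1))))
    ids = [f"P{str(i + 1).zfill(width)}" for i in range(n_proteins)]
    return pd.DataFrame(
        {
            "protein_id": ids,
            "tm": rng.normal(tm_mean, tm_sd, n_proteins),
            "slope": rng.uniform(*slope_range, n_proteins),
            "plateau": rng.uniform(*plateau_range, n_proteins),
        }
    )


def _pooled_solubility(proteome: pd.DataFrame, temps: np.ndarray,
                       tm_shift: np.ndarray | float = 0.0) -> np.ndarray:
    tm = proteome["tm"].to_numpy() + tm_shift
    return _soluble_fraction_matrix(
        tm, proteome["slope"].to_numpy(), proteome["plateau"].to_numpy(), temps
    )


def window_informative(
    proteome: pd.DataFrame,
    window_low: float = 48.0,
    window_high: float = 58.0,
    n_temperatures: int = 10,
    bounds: tuple[float, float] = (0.05, 0.95),
) -> pd.Series:
    """Boolean mask of proteins whose pooled solubility is window-informative.

    A protein with S_M very near 0 or 1 melts entirely outside the window and
    cannot report a Tm shift; the informative band is S_M in (0.05, 0.95).
    """
    temps = window_grid(window_low, window_high, n_temperatures)
    sm = _pooled_solubility(proteome, temps)
    lo, hi = bounds
    return pd.Series((sm > lo) & (sm < hi), index=proteome["protein_id"].to_numpy(),
                     name="window_informative")


def generate_screen(
    design: ScreenDesign,
    proteome: pd.DataFrame,
    effects: list[CompoundEffect],
    noise: NoiseModel,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Simulate one screen; returns the abundance matrix and ground truth.

    Per channel, abundance(protein) = loading_factor x S_M(curve shifted by
    the channel's treatment effects) x exp(measurement noise).  Lysate mode
    drops ``secondary`` effects.  The ground-truth table lists every
    (compound, protein, delta_tm, effect_class) with an ``applied`` flag
    showing whether the effect was active in this mode.
    """
    known = set(design.compounds)
    prot_ids = proteome["protein_id"].tolist()
    prot_index = {p: i for i, p in enumerate(prot_ids)}
    for e in effects:
        if e.compound_id not in known:
            raise ValueError(f"effect references unknown compound {e.compound_id!r}")
        if e.protein_id not in prot_index:
            raise ValueError(f"effect references unknown protein {e.protein_id!r}")

    layout = design.layout()
    temps = window_grid(design.window_low, design.window_high, design.n_temperatures)
    base_sm = _pooled_solubility(proteome, temps)

    # melting curves shifted per compound, only for affected proteins
    active: dict[str, dict[int, float]] = {}
    for e in effects:
        if design.mode == "lysate" and e.effect_class == "secondary":
            continue
        active.setdefault(e.compound_id, {})
        active[e.compound_id][prot_index[e.protein_id]] = (
            active[e.compound_id].get(prot_index[e.protein_id], 0.0) + e.delta_tm
        )

    rng = np.random.default_rng(noise.seed)
    load_rng, meas_rng = rng.spawn(2)
    n_ch = len(layout.channels)
    n_prot = len(prot_ids)
    sig_load = _lognormal_sigma(noise.loading_cv)
    sig_meas = _lognormal_sigma(noise.measurement_cv)
    loading = np.exp(load_rng.normal(0.0, sig_load, n_ch)) if sig_load > 0 else np.ones(n_ch)
    meas = (
        np.exp(meas_rng.normal(0.0, sig_meas, (n_prot, n_ch)))
        if sig_meas > 0
        else np.ones((n_prot, n_ch))
    )

    values = np.empty((n_prot, n_ch))
    shifted_cache: dict[str, np.ndarray] = {}
    for j, row in enumerate(layout.channels.itertuples(index=False)):
        col = base_sm
        if row.treatment_id in active:
            if row.treatment_id not in shifted_cache:
                col = base_sm.copy()
                idx = np.fromiter(active[row.treatment_id].keys(), dtype=int)
                shifts = np.fromiter(active[row.treatment_id].values(), dtype=float)
                sub = proteome.iloc[idx]
                col[idx] = _soluble_fraction_matrix(
                    sub["tm"].to_numpy() + shifts,
                    sub["slope"].to_numpy(),
                    sub["plateau"].to_numpy(),
                    temps,
                )
                shifted_cache[row.treatment_id] = col
            col = shifted_cache[row.treatment_id]
        values[:, j] = loading[j] * col
    values *= meas

    vals = pd.DataFrame(values, index=pd.Index(prot_ids, name="protein_id"),
                        columns=layout.channels["channel_id"].tolist())
    ann = layout.channels.set_index("channel_id").copy()
    ann["mode"] = design.mode
    matrix = AbundanceMatrix(vals, ann)

    truth = pd.DataFrame(
        [
            {
                "compound_id": e.compound_id,
                "protein_id": e.protein_id,
                "delta_tm": e.delta_tm,
                "effect_class": e.effect_class,
                "applied": not (design.mode == "lysate" and e.effect_class == "secondary"),
            }
            for e in effects
        ],
        columns=["compound_id", "protein_id", "delta_tm", "effect_class", "applied"],
    )
    return matrix, truth


def default_effects(
    compounds: list[str],
    proteome: pd.DataFrame,
    seed: int = 0,
    stabilize_fraction: float = 2.0 / 3.0,
    delta_tm_range: tuple[float, float] = (1.0, 8.0),
    secondary_fraction: float = 0.2,
    secondary_delta_tm_range: tuple[float, float] = (1.0, 4.0),
) -> list[CompoundEffect]:
    """One primary target per compound, plus occasional secondary effects.

    Each compound engages one randomly chosen protein with a signed Tm shift
    whose magnitude is uniform over ``delta_tm_range`` (saturating doses
    shift targets by roughly 1-8 deg C); stabilization is twice as common as
    destabilization, matching the prevalence of positive shifts among known
    target engagements.  A ``secondary_fraction`` of compounds additionally
    perturb one unrelated protein (cell mode only).
    """
    rng = np.random.default_rng(seed)
    prot_ids = proteome["protein_id"].to_numpy()
    effects: list[CompoundEffect] = []
    for c in compounds:
        target = str(rng.choice(prot_ids))
        sign = 1.0 if rng.random() < stabilize_fraction else -1.0
        mag = rng.uniform(*delta_tm_range)
        effects.append(CompoundEffect(c, target, sign * mag, "primary"))
        if rng.random() < secondary_fraction:
            other = str(rng.choice(prot_ids))
            s_sign = 1.0 if rng.random() < 0.5 else -1.0
            s_mag = rng.uniform(*secondary_delta_tm_range)
            effects.append(CompoundEffect(c, other, s_sign * s_mag, "secondary"))
    return effects


def simulate_screen(
    n_compounds: int = 50,
    n_proteins: int = 5000,
    mode: str = "cell",
    seed: int = 0,
    noise: NoiseModel | None = None,
    effects: list[CompoundEffect] | None = None,
    **effect_kwargs,
) -> tuple[AbundanceMatrix, pd.DataFrame, ScreenDesign, pd.DataFrame]:
    """Convenience wrapper: proteome + effects + screen in one call.

    Derives independent substreams from ``seed`` for the proteome, the
    effect assignment, and the noise so that any stage can be regenerated
    alone.  Returns (matrix, ground_truth, design, proteome).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    prot_seed, eff_seed, noise_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    proteome = sample_proteome(n_proteins, seed=prot_seed)
    width = len(str(n_compounds))
    compounds = [f"cmpd{str(i + 1).zfill(width)}" for i in range(n_compounds)]
    design = ScreenDesign(compounds=compounds, mode=mode)
    if effects is None:
        effects = default_effects(compounds, proteome, seed=eff_seed, **effect_kwargs)
    if noise is None:
        noise = NoiseModel(seed=noise_seed)
    else:
        noise = NoiseModel(noise.measurement_cv, noise.loading_cv, noise_seed)
    matrix, truth = generate_screen(design, proteome, effects, noise)
    return matrix, truth, design, proteome


def simulate_null_screen(
    n_compounds: int = 96,
    n_proteins: int = 6800,
    mode: str = "cell",
    seed: int = 0,
    noise: NoiseModel | None = None,
) -> tuple[AbundanceMatrix, ScreenDesign]:
    """A screen with default noise and no compound effects at all.

    Used to calibrate and check the vehicle-derived false-hit rate: every
    apparent hit on a null screen is a false positive.
    """
    matrix, _, design, _ = simulate_screen(
        n_compounds=n_compounds, n_proteins=n_proteins, mode=mode, seed=seed,
        noise=noise, effects=[],
    )
    return matrix, design


def simulate_planted_complex(
    seed: int = 0,
    n_members: int = 3,
    n_background: int = 200,
    n_compounds: int = 24,
    n_shared_compounds: int = 6,
    member_scale_range: tuple[float, float] = (0.8, 1.2),
    shared_delta_tm_range: tuple[float, float] = (2.0, 6.0),
    noise: NoiseModel | None = None,
) -> tuple[AbundanceMatrix, ScreenDesign, list[str], pd.DataFrame]:
    """Screen with a planted co-responding protein complex.

    ``n_members`` proteins share a response profile: the same
    ``n_shared_compounds`` compounds shift all of them, with per-member
    magnitudes scaled by a factor drawn once per member.  This mimics
    paralogous kinases or complex subunits whose solubility profiles
    correlate across a compound library.  Returns (matrix, design,
    member_protein_ids, proteome).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    prot_seed, eff_seed, noise_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    rng = np.random.default_rng(eff_seed)
    proteome = sample_proteome(n_members + n_background, seed=prot_seed)
    # make planted members cleanly window-informative so shifts register
    informative = window_informative(proteome)
    info_idx = np.flatnonzero(informative.to_numpy())
    member_idx = rng.choice(info_idx, size=n_members, replace=False)
    members = proteome["protein_id"].iloc[member_idx].tolist()

    width = len(str(n_compounds))
    compounds = [f"cmpd{str(i + 1).zfill(width)}" for i in range(n_compounds)]
    shared = rng.choice(compounds, size=n_shared_compounds, replace=False)
    scales = rng.uniform(*member_scale_range, size=n_members)
    effects = []
    for c in shared:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mag = rng.uniform(*shared_delta_tm_range)
        for m, s in zip(members, scales):
            effects.append(CompoundEffect(str(c), m, sign * mag * s, "primary"))

    design = ScreenDesign(compounds=compounds, mode="cell")
    if noise is None:
        noise = NoiseModel(seed=noise_seed)
    else:
        noise = NoiseModel(noise.measurement_cv, noise.loading_cv, noise_seed)
    matrix, _ = generate_screen(design, proteome, effects, noise)
    return matrix, design, members, proteome


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth effect table as TSV."""
    truth.to_csv(path, sep="\t", index=False, float_format="%.12g")
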