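"""Synthetic data generators with recorded ground truth.

Everything is produced directly on the log2 scale; ``raw_scale`` exports
2**x matrices for exercising the log2 transform.  Missingness is cellwise
MNAR: the probability that a cell is censored is a decreasing logistic
function of its (pre-censoring) abundance, with the logistic midpoint
calibrated by bisection so the realized missing fraction hits the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import NEGATIVE, POSITIVE
from .targeted_qc import TransitionSet

__all__ = [
    "SimConfig",
    "PanelConfig",
    "GroundTruth",
    "generate_group_quant",
    "apply_mnar_missingness",
    "generate_marker_panel",
    "generate_paired_sites",
    "generate_transition_runs",
    "raw_scale",
]

LAYERS = ("peptide", "protein", "transcript")


@dataclass(frozen=True)
class SimConfig:
    """Two-group log2 quantitation matrix layout."""

    n_features: int
    n_pos: int
    n_neg: int
    n_true: int = 0
    effect_size: float = 0.0
    baseline_mean: float = 25.0
    feature_sd: float = 2.0
    noise_sd: float = 1.0
    missing_target: float = 0.0
    mnar_steepness: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_features, self.n_pos, self.n_neg, self.n_true) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_true > self.n_features:
            raise ValueError("n_true cannot exceed n_features")
        if not 0 <= self.missing_target < 1:
            raise ValueError("missing_target must be in [0, 1)")
        if self.mnar_steepness <= 0:
            raise ValueError("mnar_steepness must be positive")


@dataclass(frozen=True)
class PanelConfig:
    """Multi-layer marker panel layout (peptide/protein/transcript)."""

    markers: tuple[str, ...]
    layers: tuple[str, ...] = ("protein",)
    peptides_per_marker: int = 1
    layer_correlation: float = 1.0
    informative_markers: frozenset[str] = frozenset()
    effect_size: float = 0.0
    n_pos: int = 10
    n_neg: int = 10
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(
            self, "informative_markers", frozenset(self.informative_markers)
        )
        if not self.layers:
            raise ValueError("at least one layer required")
        unknown = set(self.layers) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")
        if not self.informative_markers <= set(self.markers):
            raise ValueError("informative_markers must be a subset of markers")
        if not 0 <= self.layer_correlation <= 1:
            raise ValueError("layer_correlation must be in [0, 1]")
        if self.peptides_per_marker < 1:
            raise ValueError("peptides_per_marker must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted simulation truth used by recovery tests.

    ``true_differential`` maps feature id -> direction (+1 up in the
    positive group, -1 down); ``informative_variables`` lists panel
    variable ids carrying signal; ``emt_shifts`` maps gene -> signed log2
    shift applied in the tumor site.
    """

    true_differential: Mapping[str, int] = field(default_factory=dict)
    informative_variables: frozenset[str] = frozenset()
    emt_shifts: Mapping[str, float] = field(default_factory=dict)


def _sample_ids(n_pos: int, n_neg: int) -> tuple[list[str], dict[str, str]]:
    pos = [f"pos{i + 1:02d}" for i in range(n_pos)]
    neg = [f"neg{i + 1:02d}" for i in range(n_neg)]
    labels = {s: POSITIVE for s in pos} | {s: NEGATIVE for s in neg}
    return pos + neg, labels


def group_labels(table: pd.DataFrame) -> dict[str, str]:
    """Recover the group mapping from generated sample ids."""
    out = {}
    for s in table.columns:
        if s.startswith("pos"):
            out[s] = POSITIVE
        elif s.startswith("neg"):
            out[s] = NEGATIVE
        else:
            raise ValueError(f"sample id {s!r} does not encode a group")
    return out


def generate_group_quant(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Complete (no-missing) two-group log2 matrix with planted effects.

    Planted features receive a signed mean shift of ``effect_size`` in the
    positive group; directions are drawn at random and recorded in the
    returned ground truth.
    """
    rng = np.random.default_rng(config.seed)
    feature_ids = [f"F{i + 1:05d}" for i in range(config.n_features)]
    samples, _ = _sample_ids(config.n_pos, config.n_neg)

    mu = rng.normal(config.baseline_mean, config.feature_sd, size=config.n_features)
    values = mu[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_features, config.n_pos + config.n_neg)
    )

    planted_idx = rng.choice(config.n_features, size=config.n_true, replace=False)
    directions = rng.choice([-1, 1], size=config.n_true)
    values[planted_idx[:, None], np.arange(config.n_pos)[None, :]] += (
        directions[:, None] * config.effect_size
    )

    table = pd.DataFrame(values, index=feature_ids, columns=samples)
    table.index.name = "feature_id"
    truth = GroundTruth(
        true_differential={
            feature_ids[i]: int(d) for i, d in zip(planted_idx, directions)
        }
    )
    return table, truth


def apply_mnar_missingness(
    table: pd.DataFrame,
    missing_target: float,
    mnar_steepness: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Censor cells with probability decreasing logistically in abundance.

    The logistic midpoint is found by bisection so the expected missing
    fraction equals ``missing_target``; realized fractions land within
    Bernoulli sampling noise of the target.
    """
    if not 0 <= missing_target < 1:
        raise ValueError("missing_target must be in [0, 1)")
    if mnar_steepness <= 0:
        raise ValueError("mnar_steepness must be positive")
    if table.isna().any().any():
        raise ValueError("input table must be complete")
    if missing_target == 0:
        return table.copy()

    x = table.to_numpy(dtype=float)

    def mean_prob(mid: float) -> float:
        return float(expit(-mnar_steepness * (x - mid)).mean())

    lo, hi = x.min() - 60.0 / mnar_steepness, x.max() + 60.0 / mnar_steepness
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < missing_target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)

    rng = np.random.default_rng(seed)
    mask = rng.random(x.shape) < expit(-mnar_steepness * (x - mid))
    out = table.copy()
    out.values[mask] = np.nan
    return out


def _panel_variable_ids(config: PanelConfig) -> list[tuple[str, str]]:
    """(marker, variable_id) pairs in deterministic marker/layer order."""
    suffix = {"protein": ["protein"], "transcript": ["rna"]}
    out = []
    for marker in config.markers:
        for layer in config.layers:
            if layer == "peptide":
                for i in range(config.peptides_per_marker):
                    out.append((marker, f"{marker}|pep{i + 1}"))
            else:
                out.append((marker, f"{marker}|{suffix[layer][0]}"))
    return out


def generate_marker_panel(config: PanelConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Multi-layer marker panel sharing one latent factor per marker.

    Each variable is sqrt(rho) * latent + sqrt(1-rho) * noise, so any two
    layers of the same marker correlate at rho.  Informative markers carry
    ``effect_size`` (in latent-sd units) on the latent factor in the
    positive group.
    """
    rng = np.random.default_rng(config.seed)
    samples, _ = _sample_ids(config.n_pos, config.n_neg)
    n_samples = len(samples)
    variables = _panel_variable_ids(config)

    rho = config.layer_correlation
    latent = {m: rng.normal(size=n_samples) for m in config.markers}
    for m in config.informative_markers:
        latent[m][: config.n_pos] += config.effect_size

    rows = []
    for marker, _vid in variables:
        noise = rng.normal(size=n_samples)
        rows.append(np.sqrt(rho) * latent[marker] + np.sqrt(1.0 - rho) * noise)

    table = pd.DataFrame(
        np.vstack(rows), index=[vid for _, vid in variables], columns=samples
    )
    table.index.name = "feature_id"
    informative = frozenset(
        vid for marker, vid in variables if marker in config.informative_markers
    )
    return table, GroundTruth(informative_variables=informative)


def generate_paired_sites(
    n_pairs: int,
    n_features: int,
    emt_signature: Mapping[str, str],
    shift: float,
    seed: int = 0,
    baseline_mean: float = 25.0,
    pair_sd: float = 0.5,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired tumor/node matrices with opposite-signed class shifts.

    Mes genes get +``shift`` in the tumor table and Epi genes +``shift``
    in the node table; per-(feature, pair) latent offsets make columns
    genuinely paired.
    """
    if not emt_signature:
        raise ValueError("emt_signature must be nonempty")
    genes = list(emt_signature)
    if n_features < len(genes):
        raise ValueError("n_features smaller than signature")
    rng = np.random.default_rng(seed)
    fillers = [f"F{i + 1:05d}" for i in range(n_features - len(genes))]
    feature_ids = genes + fillers
    pairs = [f"pair{i + 1:02d}" for i in range(n_pairs)]

    mu = rng.normal(baseline_mean, 1.0, size=n_features)
    shared = rng.normal(0.0, pair_sd, size=(n_features, n_pairs))
    tumor = (
        mu[:, None]
        + shared
        + rng.normal(0.0, noise_sd, size=(n_features, n_pairs))
    )
    node = (
        mu[:, None]
        + shared
        + rng.normal(0.0, noise_sd, size=(n_features, n_pairs))
    )

    emt_shifts: dict[str, float] = {}
    for i, gene in enumerate(genes):
        cls = emt_signature[gene]
        if cls == "Mes":
            tumor[i, :] += shift
            emt_shifts[gene] = float(shift)
        elif cls == "Epi":
            node[i, :] += shift
            emt_shifts[gene] = float(-shift)
        else:
            raise ValueError(f"signature class must be Epi or Mes, got {cls!r}")

    tumor_df = pd.DataFrame(tumor, index=feature_ids, columns=pairs)
    node_df = pd.DataFrame(node, index=feature_ids, columns=pairs)
    tumor_df.index.name = node_df.index.name = "feature_id"
    return tumor_df, node_df, GroundTruth(emt_shifts=emt_shifts)


def generate_transition_runs(
    n_peptides: int,
    n_transitions: int,
    heavy_spike: float = 1e5,
    light_heavy_ratio: float = 1.0,
    distortion: float = 0.0,
    include_blank: bool = False,
    blank_residual: float = 0.0,
    seed: int = 0,
) -> list[TransitionSet]:
    """Skyline-style transition runs with a planted light/heavy ratio.

    Light areas are the heavy pattern times ``light_heavy_ratio`` times a
    per-transition multiplicative lognormal distortion; with distortion 0
    the two channels are exactly proportional (rdotp 1).  When
    ``include_blank`` is set a blank run per peptide carries
    ``blank_residual`` fraction of the preceding heavy signal.
    """
    if n_transitions < 3:
        raise ValueError("at least 3 transitions required")
    rng = np.random.default_rng(seed)
    runs: list[TransitionSet] = []
    for p in range(n_peptides):
        pep = f"PEP{p + 1:03d}"
        tids = tuple(f"y{i + 3}" for i in range(n_transitions))
        heavy = heavy_spike * rng.uniform(0.2, 1.0, size=n_transitions)
        noise = np.exp(rng.normal(0.0, distortion, size=n_transitions)) if distortion > 0 else 1.0
        light = heavy * light_heavy_ratio * noise
        runs.append(
            TransitionSet(
                run_id="matrix01",
                peptide_id=pep,
                transition_ids=tids,
                light_areas=tuple(float(v) for v in light),
                heavy_areas=tuple(float(v) for v in heavy),
                library_intensities=tuple(float(v) for v in heavy),
            )
        )
        if include_blank:
            runs.append(
                TransitionSet(
                    run_id="blank01",
                    peptide_id=pep,
                    transition_ids=tids,
                    light_areas=tuple(0.0 for _ in tids),
                    heavy_areas=tuple(float(v * blank_residual) for v in heavy),
                    library_intensities=tuple(float(v) for v in heavy),
                )
            )
    return runs


def raw_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Export a log2 table on the raw intensity scale (2**x)."""
    return np.power(2.0, table)
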