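"""Synthetic data generators with known ground truth.

Three generators emulate the data modalities the estimator consumes:

* single-cell ZINB counts whose activity-dependent target module is driven by
  a latent per-cell activity in [0, 1], with cell-type / dataset / depth
  nuisance structure and stimulated vs unstimulated groups;
* electrophysiology feature tables in which a few features (membrane time
  constant, input resistance, threshold current) carry activity signal of
  known sign among pure-noise features;
* spatial spot tables mixing neuronal and non-neuronal class signatures in
  region-specific proportions, with a planted regional activity shift.

Ground truth (latent activity, per-gene effect sizes, informative flags,
regional shifts and densities) is always returned alongside the data and is
never consumed by the estimator itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "SpatialConfig",
    "SpatialDataset",
    "simulate_activity",
    "simulate_counts",
    "simulate_dataset",
    "simulate_ephys",
    "simulate_spatial",
]


@dataclass
class SimConfig:
    """Parameters of the single-cell generator.

    Activity follows Beta(2, 8) for unstimulated and Beta(8, 2) for stimulated
    cells — clearly separated but overlapping groups. Sequencing depth is
    log-normal around 8000 counts so most cells fall inside the [5000, 50000]
    QC band. Informative genes respond with log-fold coefficient
    `effect_size`; every gene also receives Normal(0, 0.3) cell-type and
    dataset offsets, the nuisance structure the auxiliary decoder inputs must
    absorb.
    """

    n_cells: int = 5000
    n_genes: int = 500
    n_targets: int = 22
    n_informative_nontargets: int = 0
    cell_types: dict = field(default_factory=lambda: {"glut": 0.6, "gaba": 0.4})
    datasets: dict = field(default_factory=lambda: {"ds1": 1.0, "ds2": 0.7})
    group_fraction_stimulated: float = 0.5
    activity_params: dict = field(
        default_factory=lambda: {"unstim": (2.0, 8.0), "stim": (8.0, 2.0)}
    )
    effect_size: float = 1.5
    target_baseline_rate: float = 5e-4
    informative_nontarget_rate: float | None = None  # defaults to target rate
    dispersion: float = 10.0
    dropout: float = 0.05
    depth_meanlog: float = float(np.log(8000))
    depth_sdlog: float = 0.4
    type_effect_sd: float = 0.3
    dataset_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name, (a, b) in self.activity_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta shapes for group '{name}' must be > 0")
        if not 0 <= self.group_fraction_stimulated <= 1:
            raise ValueError("group_fraction_stimulated must lie in [0, 1]")
        if abs(sum(self.cell_types.values()) - 1) > 1e-8:
            raise ValueError("cell type proportions must sum to 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    activity: np.ndarray  # per-cell latent activity in [0, 1]
    informative_flags: np.ndarray  # per-gene bool
    effect_sizes: np.ndarray  # per-gene log-fold coefficient (0 if uninformative)
    type_effects: pd.DataFrame  # genes x cell types, log offsets
    dataset_effects: pd.DataFrame  # genes x datasets, log offsets


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    metadata: pd.DataFrame
    truth: SyntheticTruth


def _gene_ids(config: SimConfig) -> list:
    """Target genes borrow the packaged activity-dependent symbols when they
    fit; remaining genes get generic identifiers."""
    from .targets import TARGET_GENES

    ids = []
    for i in range(config.n_targets):
        ids.append(TARGET_GENES[i] if i < len(TARGET_GENES) else f"TGT{i:04d}")
    for i in range(config.n_informative_nontargets):
        ids.append(f"INF{i:04d}")
    for i in range(config.n_genes - config.n_targets - config.n_informative_nontargets):
        ids.append(f"G{i:05d}")
    return ids


def simulate_activity(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw per-cell latent activity and stimulation-group labels.

    Returns (activity, groups) with groups in {'stim', 'unstim'}.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_cells
    n_stim = int(round(config.group_fraction_stimulated * n))
    groups = np.array(["unstim"] * (n - n_stim) + ["stim"] * n_stim)
    rng.shuffle(groups)
    a = np.empty(n)
    for g, (alpha, beta) in config.activity_params.items():
        idx = groups == g
        a[idx] = rng.beta(alpha, beta, idx.sum())
    return a, groups


def simulate_counts(activity: np.ndarray, groups: np.ndarray, config: SimConfig,
                    rng: np.random.Generator | None = None) -> SyntheticDataset:
    """Generate ZINB counts driven by latent activity.

    Gene g in cell i has mean mu = s_i * p_g * exp(beta_g * a_i + gamma_{g,t}
    + delta_{g,d}); a negative-binomial draw with dispersion theta is then
    zeroed with probability pi (structural dropout).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    a = np.asarray(activity, dtype=float)
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("activity values must lie in [0, 1]")
    n = len(a)
    G = config.n_genes
    n_info = config.n_targets + config.n_informative_nontargets
    gene_ids = _gene_ids(config)

    beta = np.zeros(G)
    beta[:n_info] = config.effect_size
    p = rng.lognormal(np.log(1.0 / G), 0.5, G)
    p[: config.n_targets] = config.target_baseline_rate
    if config.n_informative_nontargets:
        rate = (
            config.informative_nontarget_rate
            if config.informative_nontarget_rate is not None
            else config.target_baseline_rate
        )
        p[config.n_targets: n_info] = rate

    types = rng.choice(
        list(config.cell_types), n, p=list(config.cell_types.values())
    )
    ds_labels = list(config.datasets)
    ds = rng.choice(ds_labels, n)
    depth_mult = np.array([config.datasets[d] for d in ds])
    s = rng.lognormal(config.depth_meanlog, config.depth_sdlog, n) * depth_mult

    gamma = pd.DataFrame(
        rng.normal(0, config.type_effect_sd, (G, len(config.cell_types))),
        index=gene_ids, columns=list(config.cell_types),
    )
    delta = pd.DataFrame(
        rng.normal(0, config.dataset_effect_sd, (G, len(ds_labels))),
        index=gene_ids, columns=ds_labels,
    )

    type_idx = pd.Categorical(types, categories=list(config.cell_types)).codes
    ds_idx = pd.Categorical(ds, categories=ds_labels).codes
    log_mu = (
        np.log(p)[:, None]
        + beta[:, None] * a[None, :]
        + gamma.to_numpy()[:, type_idx]
        + delta.to_numpy()[:, ds_idx]
        + np.log(s)[None, :]
    )
    mu = np.exp(log_mu)
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError("non-finite ZINB mean encountered")
    theta = config.dispersion
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam)
    if config.dropout > 0:
        counts *= rng.random(counts.shape) >= config.dropout

    cell_ids = [f"cell{i:06d}" for i in range(n)]
    metadata = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "species": "mouse",
            "cell_class": types,
            "subclass": [f"{t}_{d}" for t, d in zip(types, ds)],
            "dataset": ds,
            "group": groups,
            "total_counts": counts.sum(axis=0),
        }
    ).set_index("cell_id")
    truth = SyntheticTruth(
        activity=a,
        informative_flags=beta > 0,
        effect_sizes=beta,
        type_effects=gamma,
        dataset_effects=delta,
    )
    return SyntheticDataset(CountMatrix(counts, gene_ids, cell_ids), metadata, truth)


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Activity draw + count generation under one seed."""
    rng = np.random.default_rng(config.seed)
    a, groups = simulate_activity(config, rng)
    return simulate_counts(a, groups, config, rng)


# ---------------------------------------------------------------------------
# Electrophysiology
# ---------------------------------------------------------------------------

EPHYS_EFFECTS = {
    "tau": -0.154,
    "input_resistance": 0.088,
    "threshold_current": -0.080,
}


def simulate_ephys(activity: np.ndarray, effects: dict | None = None,
                   n_noise_features: int = 12, noise_sd: float = 0.5,
                   type_offset_sd: float = 0.1, n_types: int = 4,
                   seed: int = 0) -> pd.DataFrame:
    """Electrophysiology feature table with planted activity effects.

    The informative features carry the field's characteristic signs — more
    active neurons show shorter membrane time constant (tau), higher input
    resistance, and lower threshold (rheobase) current. Noise features are
    pure Gaussian. Per-cell neuron-type offsets add nuisance structure that
    must be regressed out before modeling.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(activity, dtype=float)
    n = len(a)
    # effects are planted on the standardized-activity scale (SD units), so
    # their magnitudes are comparable to standardized regression coefficients
    az = (a - a.mean()) / a.std() if a.std() > 0 else a - a.mean()
    effects = EPHYS_EFFECTS if effects is None else effects
    types = rng.integers(0, n_types, n)
    df = pd.DataFrame(index=[f"cell{i:06d}" for i in range(n)])
    for name, beta in effects.items():
        offs = rng.normal(0, type_offset_sd, n_types)
        df[name] = beta * az + offs[types] + rng.normal(0, noise_sd, n)
    for j in range(n_noise_features):
        df[f"ephys_noise_{j:02d}"] = rng.normal(0, max(noise_sd, 1e-12), n)
    df["neuron_type"] = [f"type{t}" for t in types]
    return df


# ---------------------------------------------------------------------------
# Spatial spots
# ---------------------------------------------------------------------------


@dataclass
class SpatialConfig:
    """Region-structured spatial generator: each region has a neuron density
    (fraction of the spot mixture drawn from neuronal class signatures) and a
    group-specific activity shift applied to spots of the 'trained' group."""

    regions: dict = field(
        default_factory=lambda: {
            "regionA": {"density": 0.7, "shift": 0.15},
            "regionB": {"density": 0.5, "shift": 0.0},
            "regionC": {"density": 0.3, "shift": 0.0},
        }
    )
    n_donors_per_group: int = 3
    spots_per_donor_region: int = 30
    n_genes: int = 150
    depth: float = 3000.0
    base_activity: float = 0.3
    donor_sd: float = 0.03
    noise_sd: float = 0.05
    density_jitter_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if len(self.regions) < 2:
            raise ValueError("need at least 2 regions")
        if self.n_donors_per_group < 2:
            raise ValueError("need at least 2 donors per group (mixed model)")


@dataclass
class SpatialDataset:
    counts: CountMatrix
    spots: pd.DataFrame  # spot_id, region, donor, group, x, y
    signatures: pd.DataFrame  # genes x {gaba, glut, nonneuronal} expected profiles
    truth: pd.DataFrame  # per-spot activity + neuronal fraction; region attrs


def class_signatures(n_genes: int, rng: np.random.Generator) -> pd.DataFrame:
    """Three class-average expression profiles with marker-gene blocks."""
    base = rng.lognormal(0.0, 0.4, (n_genes, 3))
    block = n_genes // 5
    base[:block, 0] *= 8.0  # GABAergic markers
    base[block: 2 * block, 1] *= 8.0  # glutamatergic markers
    base[2 * block: 3 * block, 2] *= 8.0  # non-neuronal markers
    sig = pd.DataFrame(
        base,
        index=[f"SG{i:04d}" for i in range(n_genes)],
        columns=["gaba", "glut", "nonneuronal"],
    )
    return sig / sig.sum(axis=0)


def simulate_spatial(config: SpatialConfig) -> SpatialDataset:
    """Generate spots mixing class signatures by regional neuron density, with
    a planted per-region activity shift between groups."""
    rng = np.random.default_rng(config.seed)
    sig = class_signatures(config.n_genes, rng)
    rows = []
    truth_rows = []
    cols = []
    for group in ("HC", "trained"):
        for d in range(config.n_donors_per_group):
            donor = f"{group}_donor{d}"
            donor_off = rng.normal(0, config.donor_sd)
            for region, attrs in config.regions.items():
                for k in range(config.spots_per_donor_region):
                    frac = np.clip(
                        attrs["density"] + rng.normal(0, config.density_jitter_sd),
                        0.02, 0.98,
                    )
                    mix = (
                        0.4 * frac * sig["gaba"].to_numpy()
                        + 0.6 * frac * sig["glut"].to_numpy()
                        + (1 - frac) * sig["nonneuronal"].to_numpy()
                    )
                    counts = rng.poisson(config.depth * mix / mix.sum())
                    act = (
                        config.base_activity
                        + (attrs["shift"] if group == "trained" else 0.0)
                        + donor_off
                        + rng.normal(0, config.noise_sd)
                    )
                    spot_id = f"{donor}_{region}_s{k:03d}"
                    rows.append(
                        (spot_id, region, donor, group,
                         rng.uniform(0, 10), rng.uniform(0, 10))
                    )
                    truth_rows.append(
                        (spot_id, float(np.clip(act, 0, 1)), frac,
                         attrs["density"], attrs["shift"])
                    )
                    cols.append(counts)
    spots = pd.DataFrame(
        rows, columns=["spot_id", "region", "donor", "group", "x", "y"]
    ).set_index("spot_id")
    truth = pd.DataFrame(
        truth_rows,
        columns=["spot_id", "activity", "neuronal_fraction",
                 "region_density", "region_shift"],
    ).set_index("spot_id")
    counts = CountMatrix(
        np.column_stack(cols), sig.index.tolist(), spots.index.tolist()
    )
    return SpatialDataset(counts, spots, sig, truth)
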