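"""Synthetic data with planted ground truth for every pipeline stage.

The study's animal recordings and sequencing data are not bundled here;
instead this module generates inputs carrying the statistical structure the
analysis assumes — negative-binomial counts with library-size variation,
batch shifts, planted differentially expressed genes, planted co-expression
modules whose latent scores drive trait values, planted outlier samples,
ERG waveforms with oscillatory-potential bursts at known times, and flicker
trials with a known dilation step — so every stage can be tested against a
recorded ground truth.

All randomness flows from ``numpy.random.default_rng`` seeded from the
config, so a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .erg import Waveform
from .hemodynamics import CaliberTrace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_counts",
    "gen_trait_table",
    "gen_erg_waveform",
    "gen_flicker_trial",
    "gen_marker_atlas",
]

LN2 = np.log(2.0)


@dataclass
class SimulationConfig:
    """Parameters of the bulk RNA-seq simulation.

    ``dispersion`` is the negative-binomial dispersion ``alpha`` in the
    parameterization ``Var = mu + alpha * mu^2`` (alpha = 0 recovers
    Poisson). ``module_spec`` lists planted co-expression modules as
    ``(size, loading, trait_corr)``: each module shares a per-sample latent
    factor, gene log2-expression picks it up with weight ``loading``, and
    the matching trait is built to correlate ``trait_corr`` with the latent
    score. ``batch_sd`` is the SD of per-gene log2 batch shifts.
    ``outlier_shift`` scales whole-sample displacement in units of the
    per-gene within-group log2 spread, along a random gene direction, so
    outliers are visible in PCA space but not in any single gene.
    """

    seed: int = 0
    n_samples_per_group: int = 10
    groups: tuple[str, ...] = ("Ctrl+Veh", "DM+Veh", "DM+Cont", "DM+Wash")
    n_genes: int = 2000
    n_batches: int = 2
    batch_sd: float = 0.3
    n_de_genes: int = 100
    de_lfc: float = 1.0
    de_group: str | None = None  # defaults to groups[1]
    dispersion: float = 0.05
    module_spec: tuple[tuple[int, float, float], ...] = (
        (150, 0.8, 0.6),
        (120, 0.8, 0.0),
        (100, 0.7, 0.0),
    )
    n_outlier_samples: int = 1
    outlier_shift: float = 6.0
    base_mean_log_mu: float = 4.5
    base_mean_log_sd: float = 1.5
    libsize_log_sd: float = 0.15

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0 or not self.groups:
            raise ValueError("dimensions must be positive and groups non-empty")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if sum(m[0] for m in self.module_spec) + self.n_de_genes > self.n_genes:
            raise ValueError("module sizes plus DE genes exceed n_genes")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        for size, loading, corr in self.module_spec:
            if not -1 <= corr <= 1:
                raise ValueError("trait correlation coefficients must lie in [-1, 1]")
            if size < 2:
                raise ValueError("module size must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside generated data."""

    de_gene_ids: set = field(default_factory=set)
    de_lfc_by_gene: dict = field(default_factory=dict)
    module_membership: dict = field(default_factory=dict)  # gene -> module label
    latent_scores: pd.DataFrame | None = None  # module x sample
    trait_corr: dict = field(default_factory=dict)  # module label -> requested r
    outlier_sample_ids: set = field(default_factory=set)
    planted_dilation_percent: dict = field(default_factory=dict)  # trial id -> %
    planted_op_times_ms: dict = field(default_factory=dict)  # waveform id -> list

    def to_json(self, path: str | Path) -> None:
        d = {
            "de_gene_ids": sorted(self.de_gene_ids),
            "de_lfc_by_gene": self.de_lfc_by_gene,
            "module_membership": self.module_membership,
            "latent_scores": None
            if self.latent_scores is None
            else self.latent_scores.to_dict(orient="split"),
            "trait_corr": self.trait_corr,
            "outlier_sample_ids": sorted(self.outlier_sample_ids),
            "planted_dilation_percent": self.planted_dilation_percent,
            "planted_op_times_ms": self.planted_op_times_ms,
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with Var = mu + alpha*mu^2 (gamma-Poisson mixture; alpha=0 -> Poisson)."""
    if alpha == 0:
        return rng.poisson(mu)
    # numpy's parameterization: n = 1/alpha successes, p = n/(n+mu)
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mu))


def gen_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a gene x sample count matrix with planted structure.

    Returns ``(counts, metadata, ground_truth)``: integer counts (genes as
    rows), per-sample metadata (condition, batch), and the planted truth.

    Construction, per gene g and sample j, on the log2 scale::

        log2 mu_gj = log2(base_g) + lfc_g * [j in DE group]
                     + loading_m * z_mj * [g in module m]
                     + batch_shift_gb + log2(libsize_j) + outlier_shift_gj

    then ``counts ~ NB(mu, alpha)``. Base means are log-normal
    (heavy-tailed); batch shifts are N(0, batch_sd) per (gene, batch) with
    batch 0 as reference; the outlier displacement is
    ``outlier_shift * sigma_g * v_g`` with v ~ N(0,1), sigma_g the NB noise
    SD of gene g on the log2 scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    samples, conditions, batches = [], [], []
    for gi, grp in enumerate(config.groups):
        for k in range(config.n_samples_per_group):
            samples.append(f"s{gi * config.n_samples_per_group + k:03d}")
            conditions.append(grp)
            batches.append(f"b{k % config.n_batches}")
    n_s = len(samples)
    meta = pd.DataFrame({"condition": conditions, "batch": batches}, index=samples)

    truth = GroundTruth()

    base = np.exp(rng.normal(config.base_mean_log_mu, config.base_mean_log_sd, config.n_genes))
    log2mu = np.log2(base)[:, None] + np.zeros((config.n_genes, n_s))

    # planted DE genes occupy the first indices; module genes follow, so the
    # two plantings do not interact
    de_idx = np.arange(config.n_de_genes)
    de_group = config.de_group or config.groups[1]
    if de_group not in config.groups:
        raise ValueError(f"unknown DE group {de_group!r}")
    in_de_group = np.array([c == de_group for c in conditions])
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    for i, s in zip(de_idx, signs):
        lfc = s * config.de_lfc
        log2mu[i, in_de_group] += lfc
        truth.de_gene_ids.add(genes[i])
        truth.de_lfc_by_gene[genes[i]] = float(lfc)

    # planted co-expression modules: shared latent factor per module
    module_labels = [f"M{m + 1}" for m in range(len(config.module_spec))]
    latent = {}
    pos = config.n_de_genes
    cond_arr = np.array(conditions)
    for label, (size, loading, corr) in zip(module_labels, config.module_spec):
        z = rng.standard_normal(n_s)
        # module factors model inter-individual (trait-like) variation:
        # center within each condition group so planted co-expression does
        # not masquerade as a treatment effect
        for grp in config.groups:
            sel = cond_arr == grp
            z[sel] -= z[sel].mean()
        z = z / z.std()
        latent[label] = z
        idx = np.arange(pos, pos + size)
        pos += size
        # keep module genes well-expressed so biological covariance, not
        # counting noise, dominates their correlation structure
        base[idx] = np.maximum(base[idx], 50.0)
        log2mu[idx] = np.log2(base[idx])[:, None] + loading * z[None, :]
        for i in idx:
            truth.module_membership[genes[i]] = label
        truth.trait_corr[label] = float(corr)
    truth.latent_scores = pd.DataFrame(latent, index=samples).T

    # batch shifts (batch 0 is reference)
    if config.n_batches > 1:
        shift = rng.normal(0.0, config.batch_sd, (config.n_genes, config.n_batches))
        shift[:, 0] = 0.0
        b_idx = np.array([int(b[1:]) for b in batches])
        log2mu += shift[:, b_idx]

    # library size factors
    libsize = np.exp(rng.normal(0.0, config.libsize_log_sd, n_s))
    log2mu += np.log2(libsize)[None, :]

    # whole-sample outliers displaced along a random gene direction
    if config.n_outlier_samples > 0:
        out_j = rng.choice(n_s, size=config.n_outlier_samples, replace=False)
        mu_clean = 2.0**log2mu
        sigma_g = np.sqrt(
            (1.0 / np.maximum(mu_clean.mean(axis=1), 1e-9) + config.dispersion)
        ) / LN2
        for j in out_j:
            v = rng.standard_normal(config.n_genes)
            log2mu[:, j] += config.outlier_shift * sigma_g * v
            truth.outlier_sample_ids.add(samples[j])

    mu = 2.0**log2mu
    counts = _nb_draw(rng, mu, config.dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples, dtype=np.int64)
    return counts_df, meta, truth


def gen_trait_table(
    config: SimulationConfig,
    truth: GroundTruth,
    trait_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample trait values tied to planted module latent scores.

    Each module with requested correlation ``r`` gets one trait::

        trait = r * z + sqrt(1 - r^2) * noise

    with z the standardized latent score and independent standard-normal
    noise, so the expected sample correlation is r. Modules with r = 0 get
    pure-noise traits. ``trait_names`` can map module labels to trait
    column names (e.g. ``{"M1": "op2_implicit_ms"}``).
    """
    if truth.latent_scores is None:
        raise ValueError("ground truth carries no latent scores; run gen_counts first")
    rng = np.random.default_rng(config.seed + 1_000_003)
    samples = list(truth.latent_scores.columns)
    cols = {}
    for label in truth.latent_scores.index:
        r = truth.trait_corr.get(label, 0.0)
        z = truth.latent_scores.loc[label].to_numpy()
        noise = rng.standard_normal(len(samples))
        trait = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * noise
        name = (trait_names or {}).get(label, f"trait_{label}")
        cols[name] = trait
    return pd.DataFrame(cols, index=samples)


# ---------------------------------------------------------------------------
# ERG waveforms


def _gamma_wave(t: np.ndarray, peak_s: float, shape: float = 4.0) -> np.ndarray:
    """Smooth unimodal template peaking at peak_s (low-frequency by design)."""
    tau = peak_s / shape
    x = np.where(t > 0, t / tau, 0.0)
    w = x**shape * np.exp(shape - x)
    return np.where(t > 0, w / w.max() if w.max() > 0 else w, 0.0)


def gen_erg_waveform(
    op_times_ms: list[float],
    op_amplitudes: list[float],
    seed: int = 0,
    rate: float = 4000.0,
    duration_s: float = 0.30,
    pre_stim_s: float = 0.05,
    noise_uv: float = 1.0,
    a_amp: float = 100.0,
    b_amp: float = 200.0,
    op_freq_hz: float = 140.0,
    burst_sd_ms: float = 1.5,
) -> Waveform:
    """Synthesize a dark-adapted ERG trace with known OP timing.

    The slow component is a difference of gamma-shaped waves (a-wave trough
    near 15 ms, b-wave peak near 60 ms; spectral content well below the
    75 Hz OP passband). Gaussian-windowed cosine bursts at ``op_freq_hz``
    are centered at ``op_times_ms`` after stimulus onset with the given
    peak amplitudes, plus white noise of SD ``noise_uv``.
    """
    if len(op_times_ms) != len(op_amplitudes):
        raise ValueError("op_times_ms and op_amplitudes must align")
    if any(t <= 0 for t in op_times_ms):
        raise ValueError("OP times must be positive (ms after onset)")
    if sorted(op_times_ms) != list(op_times_ms):
        raise ValueError("OP times must be strictly increasing")
    post_s = duration_s - pre_stim_s
    if any(t / 1000.0 >= post_s for t in op_times_ms):
        raise ValueError("OP time beyond record length")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    onset = int(round(pre_stim_s * rate))
    t = (np.arange(n) - onset) / rate  # seconds relative to onset

    slow = -a_amp * _gamma_wave(t, 0.015, shape=6.0) + b_amp * _gamma_wave(t, 0.060, shape=8.0)
    x = slow.copy()
    sd = burst_sd_ms / 1000.0
    for t0_ms, amp in zip(op_times_ms, op_amplitudes):
        t0 = t0_ms / 1000.0
        env = np.exp(-0.5 * ((t - t0) / sd) ** 2)
        x += amp * env * np.cos(2 * np.pi * op_freq_hz * (t - t0))
    if noise_uv > 0:
        x += rng.normal(0.0, noise_uv, n)
    return Waveform(x, rate=rate, onset_index=onset, flash_intensity=-3.0)


# ---------------------------------------------------------------------------
# Flicker trials


def _planted_width(t: np.ndarray, baseline_px: float, dilation_percent: float) -> np.ndarray:
    """Vessel width over a 35 s trial: baseline, 1 s ramp to dilated during
    the 10-25 s flicker epoch, 1 s ramp back."""
    dilated = baseline_px * (1.0 + dilation_percent / 100.0)
    w = np.full_like(t, baseline_px, dtype=float)
    ramp_up = (t >= 10.0) & (t < 11.0)
    w[ramp_up] = baseline_px + (dilated - baseline_px) * (t[ramp_up] - 10.0)
    w[(t >= 11.0) & (t < 25.0)] = dilated
    ramp_dn = (t >= 25.0) & (t < 26.0)
    w[ramp_dn] = dilated - (dilated - baseline_px) * (t[ramp_dn] - 25.0)
    return w


def gen_flicker_trial(
    baseline_px: float,
    dilation_percent: float,
    seed: int = 0,
    frame_rate: float = 8.0,
    duration_s: float = 35.0,
    noise_px: float = 0.3,
    as_stack: bool = False,
    image_height: int = 48,
    image_width: int = 64,
    noise_intensity: float = 0.05,
    drift_amplitude: float = 0.03,
    vessel_class: str = "arteriole",
    trial_id: str = "t0",
) -> tuple[object, GroundTruth]:
    """Simulate one functional-hyperemia trial with a planted dilation.

    With ``as_stack=False`` (fast path) returns a :class:`CaliberTrace`
    whose widths are the planted profile plus N(0, noise_px) jitter. With
    ``as_stack=True`` returns a (n_frames, H, W) float image stack showing
    the vessel as a horizontal bright band of the planted width (soft
    half-pixel edges), with additive noise and a slow multiplicative
    intensity drift. Both paths share the same ground truth.
    """
    if baseline_px <= 0:
        raise ValueError("baseline_px must be positive")
    if dilation_percent <= -100:
        raise ValueError("dilation_percent must exceed -100")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    width = _planted_width(t, baseline_px, dilation_percent)

    truth = GroundTruth()
    truth.planted_dilation_percent[trial_id] = float(dilation_percent)

    if not as_stack:
        noisy = np.maximum(width + rng.normal(0.0, noise_px, n_frames), 0.0)
        trace = CaliberTrace(noisy, t, vessel_id=trial_id, vessel_class=vessel_class)
        return trace, truth

    rows = np.arange(image_height)[:, None]
    center = image_height / 2.0
    stack = np.empty((n_frames, image_height, image_width))
    drift = 1.0 + drift_amplitude * np.sin(2 * np.pi * t / duration_s)
    edge_scale = 0.75  # px; logistic edge softness of the vessel wall
    for j in range(n_frames):
        half = width[j] / 2.0
        d = np.abs(rows - center)
        # smooth vessel cross-section: logistic roll-off at the wall, so the
        # half-intensity crossing tracks the true caliber continuously
        profile = 1.0 / (1.0 + np.exp((d - half) / edge_scale))
        frame = 0.1 + 0.9 * profile * drift[j]
        stack[j] = frame + rng.normal(0.0, noise_intensity, (image_height, image_width))
    return stack, truth


# ---------------------------------------------------------------------------
# Marker atlas


def gen_marker_atlas(
    classes: list[str],
    genes_per_class: int = 30,
    seed: int = 0,
    shared_fraction: float = 0.0,
    nonsig_fraction: float = 0.0,
) -> pd.DataFrame:
    """Synthetic cell-type marker table (gene, class, log2FC, padj).

    A ``shared_fraction`` of each class's genes is duplicated into the next
    class (exercising the unique-within-class filter) and a
    ``nonsig_fraction`` fails the significance thresholds (padj >= 0.05 or
    log2FC <= 0.25).
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    n_shared = int(round(shared_fraction * genes_per_class))
    n_nonsig = int(round(nonsig_fraction * genes_per_class))
    for ci, cls in enumerate(classes):
        for gi in range(genes_per_class):
            gene = f"{cls}_marker{gi:03d}"
            sig = gi >= n_nonsig
            lfc = float(rng.uniform(0.5, 3.0)) if sig else float(rng.uniform(0.0, 0.2))
            padj = float(rng.uniform(1e-8, 0.04)) if sig else float(rng.uniform(0.06, 1.0))
            rows.append({"gene": gene, "class": cls, "log2FC": lfc, "padj": padj})
            if sig and gi < n_nonsig + n_shared:
                other = classes[(ci + 1) % len(classes)]
                rows.append(
                    {
                        "gene": gene,
                        "class": other,
                        "log2FC": float(rng.uniform(0.5, 3.0)),
                        "padj": float(rng.uniform(1e-8, 0.04)),
                    }
                )
    return pd.DataFrame(rows)
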