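"""Synthetic study inputs with the statistical structure the pipeline assumes.

Generators for every input the transport-effect analysis consumes:

* **Accelerometer traces** — carrier transports are gravity plus a
  walker's fundamental-plus-harmonics oscillation (ground frequency near
  4 Hz, amplitudes below 2.4 g, ~5.5 min); pneumatic-tube transports are
  gravity plus baseline noise plus Poisson-timed biexponential shock
  pulses with heavy-tailed amplitudes and random 3D orientation (~2.4
  min, on average 116 shocks above 2.5 g), sampled at 25 Hz and per-axis
  clipped at +/- 16 g, as a low-rate hobby-board accelerometer would.
* **Nanoparticle size distributions** — unimodal right-skewed (binned
  lognormal) densities in 10-1000 nm, peaking around 70-130 nm, with
  multiplicative bin noise.
* **Proteome tables** — log-normal peptide intensities composed of
  protein base + peptide offset + donor effect + replicate noise, split
  over two injections, with logistic intensity-dependent missingness
  (MNAR), planted transport-differential proteins and planted
  metric-correlated proteins; the truth record lists every planted
  membership and effect.
* **Blood counts** — per-donor cell counts and hemoglobin within
  physiological ranges, with a configurable erythrocyte-hemoglobin
  correlation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .accelerometry import AccelTrace
from .annotation import AnnotationRecord
from .particles import SizeDistribution
from .quant import PeptideMatrix

__all__ = [
    "CarrierParams",
    "PtsParams",
    "ParticleParams",
    "ProteomeParams",
    "BloodCountParams",
    "SyntheticConfig",
    "gen_accel_trace",
    "gen_size_distribution",
    "gen_proteome",
    "gen_blood_counts",
]

SAMPLE_RATE_HZ = 25.0
CLIP_G = 16.0


@dataclass(frozen=True)
class CarrierParams:
    """Walker-transport trace parameters (oscillation-dominated)."""

    duration_min: float = 5.5
    ground_frequency_hz: float = 4.0
    fundamental_amp_g: float = 0.4
    harmonic_amp_g: float = 0.15  # first harmonic (2x fundamental)
    phase_noise_sd: float = 0.05  # radians per sample (random-walk phase)
    noise_sd_g: float = 0.05


@dataclass(frozen=True)
class PtsParams:
    """Pneumatic-tube trace parameters (shock-dominated)."""

    duration_min: float = 2.4
    expected_shocks: float = 116.0  # above the 2.5 g threshold
    shock_min_g: float = 2.6
    pareto_shape: float = 1.5
    shock_max_g: float = 20.0  # vector amplitude cap (axes still clip at 16)
    decay_s: float = 0.10
    rise_s: float = 0.02
    noise_sd_g: float = 0.15


@dataclass(frozen=True)
class ParticleParams:
    """Binned lognormal size-distribution parameters for one group."""

    mode_nm: float = 100.0
    geometric_sd: float = 1.5
    total_concentration: float = 6e12  # particles/mL, AUC target
    bin_width_nm: float = 10.0
    noise_cv: float = 0.02  # multiplicative bin noise (dilution-averaged curves are smooth)
    dilution_factor: float = 1000.0


@dataclass(frozen=True)
class ProteomeParams:
    """Synthetic peptide-intensity study layout and noise model."""

    n_donors: int = 12
    plasma_types: Tuple[str, ...] = ("PFP", "PPP")
    n_proteins: int = 400
    peptides_per_protein: int = 4
    base_mean_log2: float = 23.0
    base_sd_log2: float = 2.0
    peptide_sd_log2: float = 1.0
    donor_sd_log2: float = 0.3
    replicate_sd_log2: float = 0.25
    missing_mid_log2: float = 20.0  # intensity of 50% missingness
    missing_scale_log2: float = 0.8
    n_planted_differential: int = 10
    planted_effect_log2: float = 3.0  # shift in PTS
    n_planted_correlated: int = 10
    correlated_slope: float = 0.8  # log2 units per SD of the metric
    correlated_noise_sd: float = 0.2


@dataclass(frozen=True)
class BloodCountParams:
    """Physiological ranges (min, max) per analyte; counts in 10^9/L
    (10^12/L for erythrocytes), hemoglobin in g/L."""

    ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "Ec": (3.9, 5.8),
            "Lc": (4.0, 10.0),
            "Ly": (1.0, 3.5),
            "Mc": (0.2, 0.8),
            "Gc": (1.8, 7.0),
            "Tc": (150.0, 400.0),
            "HGB": (120.0, 170.0),
        }
    )
    ec_hgb_correlation: float = 0.9


@dataclass(frozen=True)
class SyntheticConfig:
    """One bundle of generator settings for a full synthetic study."""

    seed: int = 0
    carrier: CarrierParams = CarrierParams()
    pts: PtsParams = PtsParams()
    particles_c: ParticleParams = ParticleParams(mode_nm=84.0, geometric_sd=1.35, total_concentration=6e12)
    particles_pts: ParticleParams = ParticleParams(mode_nm=116.0, geometric_sd=1.6, total_concentration=8e12)
    proteome: ProteomeParams = ProteomeParams()
    blood: BloodCountParams = BloodCountParams()


def gen_accel_trace(
    mode: str,
    config: Optional[SyntheticConfig] = None,
    seed: int = 0,
) -> AccelTrace:
    """One synthetic 3-axis transport trace (``mode`` = ``"C"`` or ``"PTS"``).

    Carrier traces carry the gait oscillation on a tilted gravity
    baseline; pneumatic-tube traces carry Poisson-timed biexponential
    shocks with random 3D orientation. Axes are clipped at +/- 16 g.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    if mode == "C":
        p = config.carrier
        n = int(round(p.duration_min * 60 * SAMPLE_RATE_HZ))
        t = np.arange(n) / SAMPLE_RATE_HZ
        phase = 2 * np.pi * p.ground_frequency_hz * t + np.cumsum(
            rng.normal(0.0, p.phase_noise_sd, n)
        )
        osc = p.fundamental_amp_g * np.sin(phase) + p.harmonic_amp_g * np.sin(
            2 * phase + rng.uniform(0, 2 * np.pi)
        )
        # the oscillation acts mostly vertically; small projections sideways
        direction = np.array([0.15, 0.1, 1.0])
        direction = direction / np.linalg.norm(direction)
        sig = osc[:, None] * direction[None, :]
        sig += rng.normal(0.0, p.noise_sd_g, (n, 3))
    elif mode == "PTS":
        p = config.pts
        n = int(round(p.duration_min * 60 * SAMPLE_RATE_HZ))
        t = np.arange(n) / SAMPLE_RATE_HZ
        sig = rng.normal(0.0, p.noise_sd_g, (n, 3))
        n_shocks = rng.poisson(p.expected_shocks)
        starts = np.sort(rng.integers(0, n, n_shocks))
        # truncated Pareto vector amplitudes: maxima reach near the clip
        u = rng.uniform(0, 1, n_shocks)
        xm, a, cap = p.shock_min_g, p.pareto_shape, p.shock_max_g
        cdf_cap = 1.0 - (xm / cap) ** a
        amps = xm / (1.0 - u * cdf_cap) ** (1.0 / a)
        width = int(np.ceil(5 * p.decay_s * SAMPLE_RATE_HZ))
        tau_pulse = np.arange(width + 1) / SAMPLE_RATE_HZ
        shape = np.exp(-tau_pulse / p.decay_s) - np.exp(-tau_pulse / p.rise_s)
        shape = shape / shape.max()  # sampled peak equals the drawn amplitude
        for s0, amp in zip(starts, amps):
            direction = rng.normal(0, 1, 3)
            direction /= np.linalg.norm(direction)
            end = min(s0 + width + 1, n)
            sig[s0:end] += amp * shape[: end - s0, None] * direction[None, :]
    else:
        raise ValueError("mode must be 'C' or 'PTS'")
    gravity = np.array([0.0, 0.0, 1.0])
    sig = sig + gravity[None, :]
    sig = np.clip(sig, -CLIP_G, CLIP_G)
    return AccelTrace(
        timestamps=t,
        ax=sig[:, 0],
        ay=sig[:, 1],
        az=sig[:, 2],
        sample_rate=SAMPLE_RATE_HZ,
        clip_limit=CLIP_G,
    )


def gen_size_distribution(params: ParticleParams, seed: int = 0) -> SizeDistribution:
    """One binned nanoparticle size distribution (lognormal density scaled
    to the configured total concentration, plus multiplicative bin noise)."""
    rng = np.random.default_rng(seed)
    bins = np.arange(10.0, 1000.0 + params.bin_width_nm / 2, params.bin_width_nm)
    sigma = np.log(params.geometric_sd)
    mu = np.log(params.mode_nm) + sigma**2  # lognormal mode = exp(mu - sigma^2)
    density = np.exp(-((np.log(bins) - mu) ** 2) / (2 * sigma**2)) / bins
    density = density / np.trapezoid(density, bins) * params.total_concentration
    if params.noise_cv > 0:
        density = density * rng.lognormal(0.0, params.noise_cv, bins.size)
    return SizeDistribution(
        bin_centers=bins, concentration=density, dilution_factor=params.dilution_factor
    )


def _default_metrics(n_donors: int, rng: np.random.Generator) -> pd.DataFrame:
    """Per-donor, per-transport TK/RMS/VDV values in the two regimes (the
    pneumatic tube roughly an order of magnitude above the carrier)."""
    rows = []
    for d in range(n_donors):
        donor = f"D{d:02d}"
        rows.append(
            {
                "donor": donor,
                "transport": "C",
                "TK": rng.uniform(0.008, 0.032),
                "RMS": rng.uniform(0.15, 0.4),
                "VDV": rng.uniform(1.0, 2.5),
            }
        )
        rows.append(
            {
                "donor": donor,
                "transport": "PTS",
                "TK": rng.uniform(0.1, 0.5),
                "RMS": rng.uniform(1.0, 3.0),
                "VDV": rng.uniform(8.0, 25.0),
            }
        )
    return pd.DataFrame(rows).set_index(["donor", "transport"])


_LOCATION_POOL = [
    ("cell membrane", True),
    ("cytoplasm", False),
    ("mitochondrion", False),
    ("nucleus", False),
    ("secreted", False),
    ("cell surface", False),
    ("extracellular matrix", False),
]


def _gen_annotation(
    proteins: Sequence[str], genes: Mapping[str, str], rng: np.random.Generator
) -> Dict[str, AnnotationRecord]:
    records = {}
    for pid in proteins:
        loc, tm = _LOCATION_POOL[rng.integers(0, len(_LOCATION_POOL))]
        keywords = []
        if loc == "secreted":
            keywords.append(
                ["coagulation", "complement", "immunoglobulin", "lipid transport", "transport"][
                    rng.integers(0, 5)
                ]
            )
        records[pid] = AnnotationRecord(
            protein_id=pid,
            gene_name=genes[pid],
            has_transmembrane=tm,
            subcellular_locations=frozenset({loc}),
            keywords=frozenset(keywords),
            platelet_set=bool(rng.uniform() < 0.3),
            exosome_go=bool(rng.uniform() < 0.1),
        )
    return records


def gen_proteome(
    params: Optional[ProteomeParams] = None, seed: int = 0
) -> Tuple[PeptideMatrix, Dict[str, AnnotationRecord], Dict]:
    """A synthetic peptide-intensity study with planted effects.

    Returns the peptide matrix (columns: donor x plasma x transport x
    replicate x injection, linear intensities with MNAR missingness), an
    annotation table, and a truth record listing planted differential
    proteins (shifted by the configured log2 effect in the pneumatic-tube
    samples), planted metric-correlated proteins (intensity linear in the
    donor's VDV value plus noise), the per-donor transport metrics used,
    and the missingness model.
    """
    p = params or ProteomeParams()
    rng = np.random.default_rng(seed)
    donors = [f"D{d:02d}" for d in range(p.n_donors)]
    metrics = _default_metrics(p.n_donors, rng)
    proteins = [f"P{i:04d}" for i in range(p.n_proteins)]
    genes = {pid: f"G{i:04d}" for i, pid in enumerate(proteins)}
    planted_diff = proteins[: p.n_planted_differential]
    planted_corr = proteins[
        p.n_planted_differential : p.n_planted_differential + p.n_planted_correlated
    ]
    base = rng.normal(p.base_mean_log2, p.base_sd_log2, p.n_proteins)
    pep_ids, pep_protein = [], []
    pep_offsets = []
    for i, pid in enumerate(proteins):
        for k in range(p.peptides_per_protein):
            pep_ids.append(f"{pid}_pep{k}")
            pep_protein.append(pid)
            pep_offsets.append(rng.normal(0.0, p.peptide_sd_log2))
    pep_offsets = np.asarray(pep_offsets)
    pep_base = base[np.repeat(np.arange(p.n_proteins), p.peptides_per_protein)]
    donor_effect = rng.normal(0.0, p.donor_sd_log2, (p.n_donors, p.n_proteins))
    diff_idx = np.arange(p.n_planted_differential)
    corr_idx = np.arange(
        p.n_planted_differential, p.n_planted_differential + p.n_planted_correlated
    )
    vdv = metrics["VDV"]
    vdv_z = (vdv - vdv.mean()) / vdv.std(ddof=0)
    columns = []
    data = []
    n_missing_expected = 0.0
    n_cells = 0
    for di, donor in enumerate(donors):
        for plasma in p.plasma_types:
            for transport in ("C", "PTS"):
                for rep in ("r1", "r2", "r3"):
                    rep_shift = rng.normal(0.0, p.replicate_sd_log2, p.n_proteins)
                    prot_log2 = base + rep_shift + donor_effect[di]
                    if transport == "PTS":
                        prot_log2[diff_idx] += p.planted_effect_log2
                    prot_log2[corr_idx] += p.correlated_slope * vdv_z.loc[
                        (donor, transport)
                    ] + rng.normal(0.0, p.correlated_noise_sd, corr_idx.size)
                    pep_log2 = (
                        pep_base
                        + pep_offsets
                        + (prot_log2 - base)[
                            np.repeat(np.arange(p.n_proteins), p.peptides_per_protein)
                        ]
                    )
                    linear = np.power(2.0, pep_log2)
                    frac1 = rng.beta(50, 50, linear.size)  # injection split ~ half
                    for inj, frac in (("i1", frac1), ("i2", 1.0 - frac1)):
                        vals = linear * frac
                        x = np.log2(np.maximum(vals, 1e-300))
                        p_miss = 1.0 / (
                            1.0
                            + np.exp((x - p.missing_mid_log2) / p.missing_scale_log2)
                        )
                        miss = rng.uniform(size=vals.size) < p_miss
                        vals = np.where(miss, np.nan, vals)
                        n_missing_expected += p_miss.sum()
                        n_cells += vals.size
                        columns.append((donor, plasma, transport, rep, inj))
                        data.append(vals)
    intens = pd.DataFrame(
        np.column_stack(data),
        index=pep_ids,
        columns=pd.MultiIndex.from_tuples(
            columns, names=["donor", "plasma", "transport", "replicate", "injection"]
        ),
    )
    matrix = PeptideMatrix(
        intensities=intens, protein_of=pd.Series(pep_protein, index=pep_ids)
    )
    records = _gen_annotation(proteins, genes, rng)
    truth = {
        "planted_differential": {pid: p.planted_effect_log2 for pid in planted_diff},
        "planted_correlated": {pid: ("VDV", p.correlated_slope) for pid in planted_corr},
        "gene_of": genes,
        "metrics": metrics,
        "expected_missing_fraction": n_missing_expected / n_cells,
        "missing_model": {
            "mid_log2": p.missing_mid_log2,
            "scale_log2": p.missing_scale_log2,
        },
    }
    return matrix, records, truth


def gen_blood_counts(
    params: Optional[BloodCountParams] = None, n_donors: int = 12, seed: int = 0
) -> pd.DataFrame:
    """Per-donor blood counts within the configured physiological ranges.

    Values are drawn through a Gaussian copula so the erythrocyte count
    and hemoglobin share the configured correlation; all marginals stay
    inside their ranges.
    """
    p = params or BloodCountParams()
    rng = np.random.default_rng(seed)
    names = list(p.ranges)
    k = len(names)
    corr = np.eye(k)
    i_ec, i_hgb = names.index("Ec"), names.index("HGB")
    corr[i_ec, i_hgb] = corr[i_hgb, i_ec] = p.ec_hgb_correlation
    z = rng.multivariate_normal(np.zeros(k), corr, size=n_donors, method="cholesky")
    from scipy.stats import norm

    u = norm.cdf(z)
    data = {}
    for j, name in enumerate(names):
        lo, hi = p.ranges[name]
        data[name] = lo + u[:, j] * (hi - lo)
    return pd.DataFrame(data, index=[f"D{d:02d}" for d in range(n_donors)])
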