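"""Synthetic Sed-seq data with known ground truth.

Generates transcriptomes, true proportion-in-supernatant (pSup) surfaces,
negative-binomial fraction count tables, and spike-in polysome TPM tables.
Every downstream stage of the package (mixing-ratio estimation, condensation
scores, biophysical model fits, translation metrics) can be exercised against
the ground truth produced here.

The count model mirrors the measurement process of sedimentation
fractionation followed by RNA-seq: a transcript of true abundance ``alpha``
and true supernatant proportion ``p`` contributes expected counts

    E[T] = s_T * alpha,   E[S] = s_S * alpha * p,   E[P] = s_P * alpha * (1 - p)

where ``s_T, s_S, s_P`` are fraction-specific sequencing depth factors.
Conservation of mass holds in expectation with mixing ratios
``a_S = s_T / s_S`` and ``a_P = s_T / s_P``:  E[T] = a_S E[S] + a_P E[P].
Counts are negative-binomial with variance ``m + m^2 / phi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SyntheticTruth",
    "generate_transcriptome",
    "simulate_true_psup",
    "simulate_sedseq_counts",
    "simulate_polysome_tpm",
    "simulate_study",
]

LENGTH_MIN = 100
LENGTH_MAX = 20_000
PSUP_CLIP = (0.001, 0.999)


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated fractionation condition.

    ``table`` has one row per gene: ``gene_id``, ``abundance`` (expression
    units), ``true_psup`` in (0,1).  Scalars record the fraction depth
    factors, NB dispersion and the master seed.
    """

    table: pd.DataFrame
    s_T: float = 1.0
    s_S: float = 1.0
    s_P: float = 1.0
    phi: float = 50.0
    seed: int = 0
    n_clipped: int = 0

    @property
    def a_S(self) -> float:
        """Implied supernatant mixing ratio s_T / s_S."""
        return self.s_T / self.s_S

    @property
    def a_P(self) -> float:
        """Implied pellet mixing ratio s_T / s_P."""
        return self.s_T / self.s_P


def generate_transcriptome(
    n_genes: int,
    length_logmean: float = float(np.log(1500.0)),
    length_logsd: float = 0.5,
    frac_induced: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic transcript annotation table.

    Total lengths (CDS + UTRs) are log-normal, truncated to
    [100, 20000] nt.  ``floor(frac_induced * n_genes)`` genes are flagged as
    stress-induced and assigned to the "Hsf1" or "Msn2/4" regulon;
    the rest carry regulon "none".

    Returns a DataFrame with columns ``gene_id, length_total, utr5_len,
    utr3_len, regulon, induced``.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if not 0.0 <= frac_induced <= 1.0:
        raise ValueError(f"frac_induced must be in [0, 1], got {frac_induced}")
    rng = np.random.default_rng(seed)
    length = np.exp(rng.normal(length_logmean, length_logsd, size=n_genes))
    length = np.clip(np.round(length), LENGTH_MIN, LENGTH_MAX).astype(int)
    # UTR lengths roughly matching yeast medians (~50 nt 5', ~120 nt 3')
    utr5 = np.exp(rng.normal(np.log(50.0), 0.6, size=n_genes))
    utr3 = np.exp(rng.normal(np.log(120.0), 0.6, size=n_genes))
    utr5 = np.clip(np.round(utr5), 10, None).astype(int)
    utr3 = np.clip(np.round(utr3), 10, None).astype(int)
    # keep room for a minimal CDS
    over = utr5 + utr3 + 3 > length
    if over.any():
        scale = (length[over] - 3) / (utr5[over] + utr3[over])
        utr5[over] = np.maximum(1, np.floor(utr5[over] * scale)).astype(int)
        utr3[over] = np.maximum(1, np.floor(utr3[over] * scale)).astype(int)

    n_induced = int(np.floor(frac_induced * n_genes))
    induced = np.zeros(n_genes, dtype=bool)
    idx = rng.choice(n_genes, size=n_induced, replace=False)
    induced[idx] = True
    regulon = np.where(
        induced, np.where(rng.random(n_genes) < 0.7, "Hsf1", "Msn2/4"), "none"
    )
    width = len(str(n_genes))
    gene_id = np.array([f"YSIM{i:0{width}d}" for i in range(n_genes)])
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "length_total": length,
            "utr5_len": utr5,
            "utr3_len": utr3,
            "regulon": regulon,
            "induced": induced,
        }
    )


def _sedimented_fraction(
    length: np.ndarray,
    beta: float,
    x: float,
    mu: float,
    nu: float,
    exponent_sign: int,
) -> np.ndarray:
    return beta * length**x * np.exp(exponent_sign * (mu + nu * length))


def simulate_true_psup(
    annotation: pd.DataFrame,
    beta: float = 1e-4,
    x: float = 1.0,
    mu: float = 0.0,
    nu: float = 0.0,
    sigma_g: float = 0.25,
    delta_e: float = 0.0,
    seed: int = 0,
    exponent_sign: int = 1,
    abundance_logmean: float = float(np.log(50.0)),
    abundance_logsd: float = 1.0,
    induction_log2fc: float = 0.0,
    depth_factors: tuple[float, float, float] = (1.0, 1.0, 1.0),
    phi: float = 50.0,
    gene_offsets: np.ndarray | None = None,
) -> SyntheticTruth:
    """Build per-gene true pSup from the length-dependence model.

    The sedimented fraction of a transcript of length L is
    ``f = beta * L^x * exp(sign * (mu + nu*L))`` and ``pSup = 1 - f``,
    clipped to [0.001, 0.999] and then jittered on the log-odds scale by
    Normal(0, sigma_g).  Genes flagged ``induced`` receive an extra
    ``delta_e`` on the log-odds scale (escape from condensation) and an
    abundance multiplier ``2**induction_log2fc``.

    ``gene_offsets`` injects a fixed per-gene log-odds offset (used by
    :func:`simulate_study` to share gene effects across conditions); when
    given it replaces the Normal(0, sigma_g) draw.
    """
    if beta <= 0 or x <= 0:
        raise ValueError("beta and x must be positive")
    if exponent_sign not in (1, -1):
        raise ValueError("exponent_sign must be +1 or -1")
    rng = np.random.default_rng(seed)
    L = annotation["length_total"].to_numpy(dtype=float)
    n = L.size
    f = _sedimented_fraction(L, beta, x, mu, nu, exponent_sign)
    n_over = int((f > 1.0).sum())
    if n_over > 0.5 * n:
        warnings.warn(
            f"sedimented fraction exceeds 1 for {n_over}/{n} genes before "
            "clipping; parameters drive near-total pelleting",
            stacklevel=2,
        )
    p = np.clip(1.0 - f, *PSUP_CLIP)
    lop = logit(p)
    if gene_offsets is None:
        gene_offsets = rng.normal(0.0, sigma_g, size=n) if sigma_g > 0 else np.zeros(n)
    lop = lop + gene_offsets
    induced = annotation["induced"].to_numpy(dtype=bool)
    lop = lop + delta_e * induced
    p = np.clip(expit(lop), *PSUP_CLIP)

    alpha = np.exp(rng.normal(abundance_logmean, abundance_logsd, size=n))
    alpha = alpha * np.where(induced, 2.0**induction_log2fc, 1.0)
    table = pd.DataFrame(
        {
            "gene_id": annotation["gene_id"].to_numpy(),
            "abundance": alpha,
            "true_psup": p,
        }
    )
    s_T, s_S, s_P = depth_factors
    if min(s_T, s_S, s_P) <= 0:
        raise ValueError("depth factors must be positive")
    return SyntheticTruth(
        table=table, s_T=s_T, s_S=s_S, s_P=s_P, phi=phi, seed=seed,
        n_clipped=n_over,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean m, size phi): variance m + m^2/phi."""
    mean = np.asarray(mean, dtype=float)
    p = phi / (phi + mean)
    return rng.negative_binomial(phi, np.clip(p, 1e-12, 1.0))


def simulate_sedseq_counts(
    truth: SyntheticTruth,
    annotation: pd.DataFrame,
    mean_total_count: float = 500.0,
    seed: int = 0,
    condition: str = "sim",
    replicate: int = 1,
) -> pd.DataFrame:
    """Draw NB fraction counts from a :class:`SyntheticTruth`.

    Counts are scaled so the Total fraction averages ``mean_total_count``
    per gene.  Returns a long-format table with columns
    ``gene_id, condition, replicate, fraction, counts``
    (fraction in {Total, Sup, Pellet}); ``attrs['a_S']``/``attrs['a_P']``
    carry the true mixing ratios for test assertions.
    """
    if truth.phi <= 0:
        raise ValueError(f"phi must be positive, got {truth.phi}")
    rng = np.random.default_rng(seed)
    alpha = truth.table["abundance"].to_numpy()
    p = truth.table["true_psup"].to_numpy()
    c = mean_total_count / (truth.s_T * alpha.mean())
    t = _nb_draw(rng, truth.s_T * alpha * c, truth.phi)
    s = _nb_draw(rng, truth.s_S * alpha * p * c, truth.phi)
    pel = _nb_draw(rng, truth.s_P * alpha * (1.0 - p) * c, truth.phi)
    gene_id = truth.table["gene_id"].to_numpy()
    frames = []
    for frac, vals in (("Total", t), ("Sup", s), ("Pellet", pel)):
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "condition": condition,
                    "replicate": replicate,
                    "fraction": frac,
                    "counts": vals,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["a_S"] = truth.a_S
    out.attrs["a_P"] = truth.a_P
    out.attrs["seed"] = seed
    return out


def simulate_polysome_tpm(
    annotation: pd.DataFrame,
    occupancy: np.ndarray,
    n_spikes: int = 20,
    spike_abundance: float = 200.0,
    fraction_scales: dict[str, float] | None = None,
    phi: float = 100.0,
    seed: int = 0,
    abundance_logmean: float = float(np.log(50.0)),
    abundance_logsd: float = 1.0,
    depth: float = 2e6,
) -> pd.DataFrame:
    """Simulate spike-in polysome-seq TPM tables (Total/Free/Bound).

    Per-gene bound abundance is ``alpha * occ`` and free abundance
    ``alpha * (1 - occ)``; each fraction is multiplied by an arbitrary
    scale (emulating unequal input material), NB-noised at the count level
    and converted to TPM.  ``n_spikes`` spike-in transcripts share one true
    abundance across fractions, anchoring cross-fraction normalization.

    Returns a long table ``gene_id, fraction, tpm, est_counts, is_spike``.
    """
    if n_spikes < 1:
        raise ValueError(f"n_spikes must be >= 1, got {n_spikes}")
    occupancy = np.asarray(occupancy, dtype=float)
    if ((occupancy < 0) | (occupancy > 1)).any():
        raise ValueError("occupancies must lie in [0, 1]")
    if fraction_scales is None:
        fraction_scales = {"Total": 1.0, "Free": 1.0, "Bound": 1.0}
    rng = np.random.default_rng(seed)
    n = len(annotation)
    alpha = np.exp(rng.normal(abundance_logmean, abundance_logsd, size=n))
    gene_len = annotation["length_total"].to_numpy(dtype=float)
    spike_len = np.full(n_spikes, 1000.0)
    spike_ids = np.array([f"SPIKE{i:03d}" for i in range(n_spikes)])

    per_fraction_abund = {
        "Total": alpha,
        "Free": alpha * (1.0 - occupancy),
        "Bound": alpha * occupancy,
    }
    frames = []
    for frac, scale in fraction_scales.items():
        abund = np.concatenate([per_fraction_abund[frac], np.full(n_spikes, spike_abundance)])
        lengths = np.concatenate([gene_len, spike_len])
        mean_counts = scale * abund
        mean_counts = mean_counts * (depth / max(mean_counts.sum(), 1e-12))
        counts = _nb_draw(rng, mean_counts, phi)
        dens = counts / lengths
        tpm = 1e6 * dens / max(dens.sum(), 1e-12)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": np.concatenate([annotation["gene_id"].to_numpy(), spike_ids]),
                    "fraction": frac,
                    "tpm": tpm,
                    "est_counts": counts,
                    "is_spike": np.concatenate(
                        [np.zeros(n, dtype=bool), np.ones(n_spikes, dtype=bool)]
                    ),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = seed
    return out


def simulate_study(
    annotation: pd.DataFrame,
    beta: float = 1e-4,
    x: float = 1.0,
    mu: float = 0.7,
    nu: float = 2e-4,
    sigma_g: float = 0.25,
    delta_e: float = 1.0,
    induction_log2fc: float = 2.0,
    exponent_sign: int = 1,
    depth_factors_control: tuple[float, float, float] = (1.0, 1.0 / 1.5, 1.0 / 3.0),
    depth_factors_stress: tuple[float, float, float] = (1.0, 1.0 / 1.5, 1.0 / 3.0),
    phi: float = 50.0,
    mean_total_count: float = 500.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> dict:
    """Simulate a paired control/stress Sed-seq study.

    Gene-level log-odds offsets (scatter around the length trend) are drawn
    once and shared between conditions, emulating condition-persistent gene
    effects; the stress condition additionally applies the condensation
    multiplier ``exp(sign*(mu + nu*L))`` and the escape offset ``delta_e``
    to induced genes.  Counts are drawn independently per replicate.

    Returns a dict with keys ``truth_control``, ``truth_stress`` (each a
    :class:`SyntheticTruth`) and ``counts`` (one long table covering both
    conditions and all replicates).
    """
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, sigma_g, size=len(annotation)) if sigma_g > 0 else None
    seed_c, seed_s = rng.integers(0, 2**31 - 1, size=2)
    truth_c = simulate_true_psup(
        annotation, beta=beta, x=x, mu=0.0, nu=0.0, sigma_g=sigma_g,
        delta_e=0.0, seed=int(seed_c), exponent_sign=exponent_sign,
        depth_factors=depth_factors_control, phi=phi, gene_offsets=offsets,
    )
    truth_s = simulate_true_psup(
        annotation, beta=beta, x=x, mu=mu, nu=nu, sigma_g=sigma_g,
        delta_e=delta_e, seed=int(seed_s), exponent_sign=exponent_sign,
        induction_log2fc=induction_log2fc,
        depth_factors=depth_factors_stress, phi=phi, gene_offsets=offsets,
    )
    frames = []
    for cond, truth in (("control", truth_c), ("stress", truth_s)):
        for rep in range(1, n_replicates + 1):
            cseed = int(rng.integers(0, 2**31 - 1))
            frames.append(
                simulate_sedseq_counts(
                    truth, annotation, mean_total_count=mean_total_count,
                    seed=cseed, condition=cond, replicate=rep,
                )
            )
    counts = pd.concat(frames, ignore_index=True)
    counts.attrs["seed"] = seed
    return {"truth_control": truth_c, "truth_stress": truth_s, "counts": counts}
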