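"""Length-controlled condensation statistics: dSed, eSed, sedScore.

Transcript sedimentation depends strongly on length even without stress,
so raw pSup differences confound length with condensation state.  All
scores here work on the log-odds scale, lopSup = log(p / (1 - p)), and
control for length in one of two ways:

* a sliding window in log-length (width = a fraction of the full
  log-length range) giving a per-gene windowed mean mu(L, T) and SD
  sigma(L, T), plus the global residual SD sigma(control);
* fixed-size length bins (100 genes) for the within-bin Z-score
  rSed / sedScore.

Scores:

    dSed(x, T) = [lopSup(x, control) - lopSup(x, T)] / sigma(control)
    eSed(x, T) = [(lopSup(x, T) - mu(L, T))
                  - (lopSup(x, control) - mu(L, control))] / sigma(control)

dSed > 0 means more sedimentation (condensation) under treatment; eSed > 0
means the transcript sediments less than transcripts of similar length
(escape).  rSed is the per-replicate within-bin Z of lopSup averaged over
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "LengthProfile",
    "log_odds",
    "inverse_log_odds",
    "average_replicates",
    "windowed_length_stats",
    "delta_sed",
    "escape_sed",
    "sed_score",
]


def log_odds(p):
    """Natural-log odds log(p/(1-p)); inverse of :func:`inverse_log_odds`."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = logit(p)
    return float(out) if out.ndim == 0 else out


def inverse_log_odds(x):
    x = np.asarray(x, dtype=float)
    out = expit(x)
    return float(out) if out.ndim == 0 else out


@dataclass
class LengthProfile:
    """Windowed length statistics of lopSup for one condition.

    ``table`` has per-gene columns gene_id, log_length, lopsup, mu
    (windowed mean), sigma (windowed SD, NaN for singleton windows);
    ``sigma_global`` is the SD of (lopsup - mu) over all genes;
    ``n_undefined_sigma`` counts singleton windows.
    """

    table: pd.DataFrame
    sigma_global: float
    window_fraction: float
    n_undefined_sigma: int = 0


def average_replicates(psup_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates: mean lopsup per gene, psup = expit(mean lopsup)."""
    if "replicate" not in psup_table.columns or psup_table["replicate"].nunique() <= 1:
        return psup_table.copy()
    keys = ["gene_id"] + (["condition"] if "condition" in psup_table.columns else [])
    agg = psup_table.groupby(keys, as_index=False)["lopsup"].mean()
    agg["psup"] = expit(agg["lopsup"])
    return agg


def windowed_length_stats(
    psup_table: pd.DataFrame,
    annotation: pd.DataFrame,
    window_fraction: float = 0.02,
) -> LengthProfile:
    """Windowed mean/SD of lopSup along log transcript length.

    For each gene with log-length l, the window is
    [l - w/2, l + w/2] with w = window_fraction * (max log L - min log L);
    mu is the mean lopsup of all genes inside (including the focal gene),
    sigma the within-window SD.  Windows are truncated at the data range.
    Replicates are averaged on the log-odds scale first.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    tab = average_replicates(psup_table)
    tab = tab.merge(annotation[["gene_id", "length_total"]], on="gene_id")
    tab = tab.dropna(subset=["lopsup"])
    if tab["length_total"].nunique() < 2:
        raise ValueError("need >= 2 genes with distinct lengths")
    tab = tab.sort_values(["length_total", "gene_id"], kind="stable").reset_index(drop=True)
    ll = np.log(tab["length_total"].to_numpy(dtype=float))
    lop = tab["lopsup"].to_numpy(dtype=float)
    w = window_fraction * (ll.max() - ll.min())
    lo = np.searchsorted(ll, ll - w / 2, side="left")
    hi = np.searchsorted(ll, ll + w / 2, side="right")
    csum = np.concatenate([[0.0], np.cumsum(lop)])
    csum2 = np.concatenate([[0.0], np.cumsum(lop * lop)])
    n = (hi - lo).astype(float)
    mu = (csum[hi] - csum[lo]) / n
    with np.errstate(invalid="ignore"):
        var = (csum2[hi] - csum2[lo] - n * mu**2) / (n - 1)
    sigma = np.sqrt(np.maximum(var, 0.0))
    sigma[n < 2] = np.nan
    n_undef = int((n < 2).sum())
    if n_undef:
        warnings.warn(
            f"windowed SD undefined for {n_undef} genes (singleton windows)",
            stacklevel=2,
        )
    resid = lop - mu
    sigma_global = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    out = pd.DataFrame(
        {
            "gene_id": tab["gene_id"].to_numpy(),
            "log_length": ll,
            "lopsup": lop,
            "mu": mu,
            "sigma": sigma,
        }
    )
    return LengthProfile(
        table=out,
        sigma_global=sigma_global,
        window_fraction=window_fraction,
        n_undefined_sigma=n_undef,
    )


def _aligned_lopsup(control: pd.DataFrame, treatment: pd.DataFrame) -> pd.DataFrame:
    c = average_replicates(control)[["gene_id", "lopsup"]].rename(columns={"lopsup": "lop_c"})
    t = average_replicates(treatment)[["gene_id", "lopsup"]].rename(columns={"lopsup": "lop_t"})
    merged = c.merge(t, on="gene_id").dropna()
    if merged.empty:
        raise ValueError("control and treatment share no scored genes")
    return merged


def delta_sed(
    control: pd.DataFrame,
    treatment: pd.DataFrame,
    profile_control: LengthProfile,
) -> pd.DataFrame:
    """Differential sedimentation in units of the control residual SD.

    dSed = (lopSup_control - lopSup_treatment) / sigma(control); positive
    values mean the transcript sediments more (condenses) under treatment.
    """
    if not profile_control.sigma_global > 0:
        raise ValueError("degenerate control: sigma(control) = 0")
    merged = _aligned_lopsup(control, treatment)
    merged["delta_sed"] = (merged["lop_c"] - merged["lop_t"]) / profile_control.sigma_global
    return merged[["gene_id", "delta_sed"]]


def escape_sed(
    control: pd.DataFrame,
    treatment: pd.DataFrame,
    profile_control: LengthProfile,
    profile_treatment: LengthProfile,
) -> pd.DataFrame:
    """Escape score: treatment shift relative to similar-length transcripts.

    eSed = [(lopSup_T - mu(L,T)) - (lopSup_control - mu(L,control))]
           / sigma(control); eSed > 0 = escapes condensation.
    """
    if profile_control.window_fraction != profile_treatment.window_fraction:
        raise ValueError("profiles computed with different window fractions")
    if not profile_control.sigma_global > 0:
        raise ValueError("degenerate control: sigma(control) = 0")
    pc = profile_control.table[["gene_id", "mu"]].rename(columns={"mu": "mu_c"})
    pt = profile_treatment.table[["gene_id", "mu"]].rename(columns={"mu": "mu_t"})
    merged = _aligned_lopsup(control, treatment).merge(pc, on="gene_id").merge(pt, on="gene_id")
    merged["e_sed"] = (
        (merged["lop_t"] - merged["mu_t"]) - (merged["lop_c"] - merged["mu_c"])
    ) / profile_control.sigma_global
    return merged[["gene_id", "e_sed"]]


def sed_score(
    psup_table: pd.DataFrame,
    annotation: pd.DataFrame,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Within-length-bin Z-score of sedimentation (rSed / sedScore).

    Per replicate, genes are sorted by total transcript length (ties broken
    by gene_id), partitioned into consecutive bins of ``bin_size``; a final
    partial bin is merged into the preceding one.  Each gene's Z-score is
    its lopSup deviation from the bin mean in units of the bin SD (ddof=1),
    with the sign flipped so that r_sed > 0 means the transcript sediments
    *more* than transcripts of similar length (a translationally blocked
    transcript like HAC1 scores high).  The reported r_sed is the mean of
    per-replicate Z-scores.  Bins with zero SD yield z = 0 (no deviation
    possible) and are counted in ``attrs['n_zero_sd_bins']``.
    """
    if "replicate" in psup_table.columns:
        reps = list(psup_table.groupby("replicate"))
    else:
        reps = [(1, psup_table)]
    n_genes = psup_table["gene_id"].nunique()
    if n_genes < bin_size:
        raise ValueError(f"need >= bin_size={bin_size} genes, got {n_genes}")
    zero_sd_bins = 0
    per_rep = []
    for rep, tab in reps:
        tab = tab.merge(annotation[["gene_id", "length_total"]], on="gene_id")
        tab = tab.dropna(subset=["lopsup"])
        tab = tab.sort_values(["length_total", "gene_id"], kind="stable").reset_index(drop=True)
        n = len(tab)
        n_bins = max(n // bin_size, 1)
        bin_idx = np.minimum(np.arange(n) // bin_size, n_bins - 1)
        lop = tab["lopsup"].to_numpy(dtype=float)
        z = np.empty(n)
        for b in range(n_bins):
            sel = bin_idx == b
            vals = lop[sel]
            sd = vals.std(ddof=1) if sel.sum() > 1 else 0.0
            # guard against floating-point dust from the mean subtraction
            if sd <= 1e-12 * max(1.0, float(np.abs(vals).max())):
                zero_sd_bins += 1
                z[sel] = 0.0
            else:
                z[sel] = -(vals - vals.mean()) / sd
        per_rep.append(
            pd.DataFrame({"gene_id": tab["gene_id"].to_numpy(), f"z_rep{rep}": z})
        )
    if zero_sd_bins:
        warnings.warn(
            f"{zero_sd_bins} length bins had zero within-bin SD; their genes "
            "get z = 0",
            stacklevel=2,
        )
    out = per_rep[0]
    for extra in per_rep[1:]:
        out = out.merge(extra, on="gene_id", how="outer")
    zcols = [c for c in out.columns if c.startswith("z_rep")]
    out["r_sed"] = out[zcols].mean(axis=1)
    out.attrs["n_zero_sd_bins"] = zero_sd_bins
    return out
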