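"""Spike-in-normalized translation metrics from polysome fractionation.

Polysome-seq separates free mRNPs from ribosome-bound material; with a
known spike-in added to every fraction, absolute comparisons across
fractions become possible:

* ribosome occupancy = bound / (bound + free), the fraction of a
  transcript's molecules carrying at least one ribosome, after dividing
  each fraction's abundances by its median spike-in abundance;
* ribosome association = TPM_bound / TPM_total, a relative measure robust
  to condensed RNA pelleting out of the gradient in stressed samples;
* sucrose-cushion occupancy = pellet fraction without EDTA minus pellet
  fraction with EDTA (EDTA dissolves ribosomes, so EDTA-resistant
  pelleting reflects condensates, not polysomes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "normalize_to_spikein",
    "ribosome_occupancy",
    "ribosome_association",
    "occupancy_from_cushion",
]


def normalize_to_spikein(
    tpm_table: pd.DataFrame, min_spike_counts: float = 100.0
) -> pd.DataFrame:
    """Divide each fraction's abundances by its median spike-in abundance.

    ``tpm_table`` is long format: gene_id, fraction, tpm, est_counts,
    is_spike.  Spikes qualify with est_counts > ``min_spike_counts``.
    Returns gene rows only, with a ``norm_abundance`` column.
    """
    req = {"gene_id", "fraction", "tpm", "est_counts", "is_spike"}
    if not req.issubset(tpm_table.columns):
        raise ValueError(f"tpm table must have columns {sorted(req)}")
    out = []
    for frac, grp in tpm_table.groupby("fraction", sort=True):
        spikes = grp[grp["is_spike"] & (grp["est_counts"] > min_spike_counts)]
        if spikes.empty:
            raise ValueError(
                f"no spike-in transcript exceeds {min_spike_counts} counts "
                f"in fraction {frac!r}"
            )
        med = float(spikes["tpm"].median())
        genes = grp[~grp["is_spike"]].copy()
        genes["norm_abundance"] = genes["tpm"] / med
        out.append(genes)
    return pd.concat(out, ignore_index=True)


def ribosome_occupancy(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-gene occupancy = bound / (bound + free) from normalized abundances.

    ``normalized`` is the output of :func:`normalize_to_spikein` and must
    contain fractions 'Bound' and 'Free'.  Genes absent from a fraction or
    with zero abundance in both get NA.
    """
    wide = normalized.pivot_table(
        index="gene_id", columns="fraction", values="norm_abundance", aggfunc="first"
    )
    for col in ("Bound", "Free"):
        if col not in wide.columns:
            raise ValueError(f"normalized table is missing fraction '{col}'")
    b = wide["Bound"].to_numpy(dtype=float)
    f = wide["Free"].to_numpy(dtype=float)
    den = b + f
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = np.where(den > 0, b / np.where(den > 0, den, 1.0), np.nan)
    return pd.DataFrame({"gene_id": wide.index.to_numpy(), "occupancy": occ})


def ribosome_association(tpm_bound: pd.DataFrame, tpm_total: pd.DataFrame) -> pd.DataFrame:
    """Per-gene association = TPM_bound / TPM_total (no upper bound).

    Inputs are two tables with gene_id and tpm columns; genes with zero
    total TPM get NA.
    """
    b = tpm_bound[["gene_id", "tpm"]].rename(columns={"tpm": "tpm_bound"})
    t = tpm_total[["gene_id", "tpm"]].rename(columns={"tpm": "tpm_total"})
    merged = b.merge(t, on="gene_id")
    with np.errstate(invalid="ignore", divide="ignore"):
        assoc = np.where(
            merged["tpm_total"] > 0,
            merged["tpm_bound"] / merged["tpm_total"].replace(0, np.nan),
            np.nan,
        )
    return pd.DataFrame({"gene_id": merged["gene_id"].to_numpy(), "association": assoc})


def occupancy_from_cushion(
    psed_no_edta: float, psed_edta: float, renormalize: bool = False
) -> float:
    """Ribosome occupancy from sucrose-cushion pelleting with/without EDTA.

    EDTA dissolves polysomes but not condensates, so the EDTA-resistant
    pellet fraction is background.  Default: occupancy =
    pSed(-EDTA) - pSed(+EDTA), floored at 0.  With ``renormalize``,
    the difference is scaled by 1/(1 - pSed(+EDTA)), i.e. the occupancy
    among the EDTA-releasable pool.
    """
    for name, v in (("psed_no_edta", psed_no_edta), ("psed_edta", psed_edta)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    diff = max(psed_no_edta - psed_edta, 0.0)
    if not renormalize:
        return diff
    if psed_edta == 1.0:
        raise ValueError("pSed(+EDTA) = 1: renormalized occupancy undefined")
    return diff / (1.0 - psed_edta)
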