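"""Sex-linked contig classification from depth-GC residuals and heterozygosity.

In a female of a ZW species the Z chromosome is hemizygous: Z-derived
contigs sequence at about half the autosomal depth and carry essentially
no heterozygous sites. Raw depth alone is confounded by the strong
dependence of sequencing depth on GC content, so classification works on
the residual of a robust regression of log2(median depth) on GC: a fully
hemizygous contig sits ~1 log2 unit (a factor of 2) below the autosomal
expectation at the same GC.

A contig is called Z-linked when its residual falls at or below
``residual_cut`` (default -0.5 log2, midway between the diploid and
haploid states) *and* its heterozygosity is at or below ``het_cut`` (or it
has no SNPs at all); autosomal when the residual is above the cut and
heterozygosity is clearly non-zero; ambiguous otherwise. When a
conspecific male sample is available, the female:male normalized depth
ratio (expectation 0.5 on Z, 1.0 on autosomes) provides an independent
check.
"""
from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DepthGCFit",
    "fit_depth_gc",
    "classify_contigs",
    "sex_depth_ratio",
    "PROFILE_COLUMNS",
]

PROFILE_COLUMNS = ["contig", "length", "gc", "median_depth", "n_snp", "het"]

AUTOSOMAL = "autosomal"
Z_LINKED = "Z_linked"
AMBIGUOUS = "ambiguous"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class DepthGCFit:
    intercept: float
    slope: float
    residual_log2: pd.Series  # indexed by contig id

    def predict_log2_depth(self, gc) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(gc, dtype=float)


def fit_depth_gc(profiles: pd.DataFrame, min_contigs: int = 20) -> DepthGCFit:
    """Robust, length-weighted linear fit of log2(median depth) on GC.

    Uses Huber M-estimation so that a minority of hemizygous contigs does
    not drag the autosomal trend down; rows are weighted by sqrt(contig
    length) since longer contigs have more stable median depths. Contigs
    with zero depth are excluded from the fit (their residual is -inf).
    """
    df = profiles[profiles["median_depth"] > 0]
    if len(df) < min_contigs:
        raise ValueError(f"need >= {min_contigs} contigs with positive depth, got {len(df)}")
    gc = df["gc"].to_numpy(dtype=float)
    if np.std(gc) < 1e-4:
        raise ValueError("degenerate GC spread; depth-GC trend is unidentifiable")
    y = np.log2(df["median_depth"].to_numpy(dtype=float))
    w = np.sqrt(df["length"].to_numpy(dtype=float))
    # sqrt-weight trick: scale response and both design columns by sqrt(w)
    exog = np.column_stack([w, gc * w])
    fit = sm.RLM(y * w, exog, M=sm.robust.norms.HuberT()).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])

    all_gc = profiles["gc"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        all_log2 = np.log2(profiles["median_depth"].to_numpy(dtype=float))
    residual = pd.Series(
        all_log2 - (intercept + slope * all_gc),
        index=profiles["contig"].to_numpy(),
        name="residual_log2",
    )
    return DepthGCFit(intercept, slope, residual)


def classify_contigs(
    profiles: pd.DataFrame,
    fit: DepthGCFit | pd.Series,
    residual_cut: float = -0.5,
    het_cut: float = 1e-3,
    min_len: int = 30_000,
) -> tuple[pd.DataFrame, dict]:
    """Assign each contig to autosomal / Z_linked / ambiguous / excluded.

    Contigs shorter than ``min_len`` are excluded outright (median depth is
    unstable there). The summary reports how many Z candidates carry zero
    SNPs — in a true hemizygous set this fraction is high, the residual
    heterozygosity being mostly caller noise.
    """
    residual = fit.residual_log2 if isinstance(fit, DepthGCFit) else fit
    df = profiles.copy()
    df["residual_log2"] = df["contig"].map(residual)

    classes = []
    for row in df.itertuples(index=False):
        if row.length < min_len:
            classes.append(EXCLUDED)
        elif row.residual_log2 <= residual_cut and (row.het <= het_cut or row.n_snp == 0):
            classes.append(Z_LINKED)
        elif row.residual_log2 > residual_cut and row.het > het_cut:
            classes.append(AUTOSOMAL)
        else:
            classes.append(AMBIGUOUS)
    df["sex_class"] = classes

    z = df[df["sex_class"] == Z_LINKED]
    n_z = len(z)
    n_z_zero_snp = int((z["n_snp"] == 0).sum())
    summary = {
        "n_contigs": len(df),
        "n_z_linked": n_z,
        "n_z_zero_snp": n_z_zero_snp,
        "zero_snp_fraction": n_z_zero_snp / n_z if n_z else float("nan"),
        "z_linked_bp": int(z["length"].sum()),
        "mean_z_het": float(z["het"].mean()) if n_z else float("nan"),
    }
    return df, summary


def sex_depth_ratio(
    female_profiles: pd.DataFrame,
    male_profiles: pd.DataFrame,
    ratio_cut: float = 0.65,
    autosomal_contigs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-contig female:male normalized depth ratio.

    Each sample's depth is normalized by its median depth over
    ``autosomal_contigs`` (over all contigs when not given; the median is
    dominated by autosomes). For a ZW female vs a ZZ male the expected
    ratio is 0.5 on Z-linked contigs and 1.0 on autosomes; contigs at or
    below ``ratio_cut`` are flagged Z.
    """
    f = female_profiles.set_index("contig")["median_depth"]
    m = male_profiles.set_index("contig")["median_depth"]
    missing = set(f.index) ^ set(m.index)
    if missing:
        raise ValueError(f"contigs missing from one sample: {sorted(missing)[:5]} ...")
    norm_ids = list(autosomal_contigs) if autosomal_contigs is not None else list(f.index)
    f_norm = float(f.loc[norm_ids].median())
    m_norm = float(m.loc[norm_ids].median())
    if f_norm <= 0 or m_norm <= 0:
        raise ValueError("non-positive normalization depth")
    ratio = (f / f_norm) / (m / m_norm)
    out = pd.DataFrame(
        {
            "contig": f.index,
            "female_depth": f.to_numpy(),
            "male_depth": m.to_numpy(),
            "fm_ratio": ratio.to_numpy(),
        }
    )
    out["z_flagged"] = out["fm_ratio"] <= ratio_cut
    return out
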