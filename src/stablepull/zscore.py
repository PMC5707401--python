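"""Asymmetric z-score normalization and stable-interactor calling.

In a pulldown where differentially labeled cells are mixed before lysis,
only pre-existing stable bait interactions retain a high heavy/light
SILAC ratio; everything that exchanges or forms in the lysate equalizes
toward ratio 1.  The resulting log2-ratio distribution is a broad
background mode near 0 with a positive tail of genuine interactors, so a
single symmetric scale estimate would be inflated by the signal itself.
The normalization used here is therefore *asymmetric*: the distribution
center is estimated once, and separate robust scales are fitted for the
upper and lower half via the median-to-quartile distances,

    s_up = (q3 - median) / 0.6745,     s_lo = (median - q1) / 0.6745,

0.6745 being the third quartile of the standard normal, so that each
half-IQR maps to one standard deviation under normality.  A protein's
z-score is its centered log2 ratio divided by the scale of the side it
falls on.  Proteins with mean z >= 2 across replicates (detected in at
least two) are called interactors; in the triple-label protocol the
RNase-effect channel is normalized the same way and a z <= -1 marks an
interaction as RNA-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import QuantTable

__all__ = [
    "NormalizationParams",
    "call_interactors",
    "classify_rnase",
    "fit_asymmetric_z",
    "log2_transform",
    "rnase_z_scores",
    "z_score",
]

#: third quartile of the standard normal distribution
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class NormalizationParams:
    """Fitted parameters of the asymmetric z-score for one replicate."""

    center: float
    s_up: float
    s_lo: float
    q1: float
    q3: float
    median: float
    scheme: str = "iqr"          # "iqr" | "positive"
    center_stat: str = "mean"    # "mean" | "median"
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "center_stat": self.center_stat,
            "center": float(self.center),
            "s_up": float(self.s_up),
            "s_lo": float(self.s_lo),
            "q1": float(self.q1),
            "q3": float(self.q3),
            "median": float(self.median),
            "n": int(self.n),
        }


def log2_transform(ratios) -> np.ndarray:
    """Elementwise log2 of SILAC ratios; NaN passes through.

    Raises ``ValueError`` naming the offending positions for ratios <= 0.
    """
    arr = np.asarray(ratios, dtype=float)
    bad = np.where(np.isfinite(arr) & (arr <= 0))[0]
    if bad.size:
        raise ValueError(
            f"non-positive ratios at positions {bad.tolist()}; "
            "SILAC ratios must be > 0")
    with np.errstate(invalid="ignore"):
        return np.log2(arr)


def fit_asymmetric_z(log2_ratios, *, scheme: str = "iqr",
                     center_stat: str = "mean",
                     min_n: int = 8) -> NormalizationParams:
    """Fit normalization parameters on one replicate's log2 ratios.

    scheme "iqr" (default): center (mean or median) plus side scales from
    the median-to-quartile distances over 0.6745.  scheme "positive":
    center and a single symmetric scale from the mean and standard
    deviation of the strictly positive log2 ratios.

    Quartiles use linear interpolation.  Degenerate distributions (zero
    scale on either side) are rejected.
    """
    x = np.asarray(log2_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise ValueError(
            f"need >= {min_n} finite log2 ratios to fit normalization, "
            f"got {x.size}")
    if center_stat not in ("mean", "median"):
        raise ValueError(f"unknown center_stat {center_stat!r}")

    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    if scheme == "iqr":
        center = float(np.mean(x)) if center_stat == "mean" else float(med)
        s_up = (q3 - med) / _Z75
        s_lo = (med - q1) / _Z75
    elif scheme == "positive":
        pos = x[x > 0]
        if pos.size < 2:
            raise ValueError("scheme 'positive' needs >= 2 positive values")
        center = float(np.mean(pos))
        s_up = s_lo = float(np.std(pos, ddof=1))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if not (s_up > 0 and s_lo > 0):
        raise ValueError(
            "degenerate log2-ratio distribution: zero scale on one side "
            f"(s_up={s_up:.4g}, s_lo={s_lo:.4g})")
    return NormalizationParams(center=float(center), s_up=float(s_up),
                               s_lo=float(s_lo), q1=float(q1), q3=float(q3),
                               median=float(med), scheme=scheme,
                               center_stat=center_stat, n=int(x.size))


def z_score(x, params: NormalizationParams) -> np.ndarray:
    """Asymmetric z-score: deviation over the scale of its side.

    z = (x - c)/s_up for x >= c, else (x - c)/s_lo.  Continuous at the
    center and strictly increasing in x.
    """
    arr = np.asarray(x, dtype=float)
    dev = arr - params.center
    scale = np.where(dev >= 0, params.s_up, params.s_lo)
    out = dev / scale
    return out if out.shape else float(out)


def _replicate_z_frame(table: QuantTable, *, ratio_col: str = "ratio_hl",
                       scheme: str = "iqr", center_stat: str = "mean",
                       min_n: int = 8,
                       ) -> tuple[pd.DataFrame, NormalizationParams]:
    df = table.data
    present = df[df[ratio_col].notna()]
    logr = log2_transform(present[ratio_col].to_numpy())
    params = fit_asymmetric_z(logr, scheme=scheme, center_stat=center_stat,
                              min_n=min_n)
    z = z_score(logr, params)
    out = pd.DataFrame({
        "protein_group_id": present["protein_group_id"].to_numpy(),
        "gene_name": present["gene_name"].to_numpy(),
        "z": z,
        "intensity": present["intensity"].to_numpy(dtype=float),
    })
    return out, params


def call_interactors(tables: list[QuantTable], *, z_cut: float = 2.0,
                     min_reps: int = 2, scheme: str = "iqr",
                     center_stat: str = "mean", min_n: int = 8,
                     ) -> tuple[pd.DataFrame, dict[str, NormalizationParams]]:
    """Normalize each replicate independently and call interactors.

    Each replicate's log2 ratios are z-scored with its own fitted
    parameters; a protein's mean z is taken over the replicates in which
    it was detected (post-filter), and it must be detected in at least
    ``min_reps`` replicates to be evaluated.  The call is boundary
    inclusive: mean z >= ``z_cut``.

    Returns a frame sorted by mean z (descending, ties broken by mean
    intensity then ID) with columns ``protein_group_id``, ``gene_name``,
    per-replicate ``z_<replicate_id>``, ``n_reps``, ``mean_z``,
    ``mean_log10_intensity`` and ``is_interactor``, plus the per-replicate
    normalization parameters.
    """
    if min_reps > len(tables):
        raise ValueError(
            f"min_reps={min_reps} exceeds the number of replicates "
            f"({len(tables)})")

    frames = []
    params_by_rep: dict[str, NormalizationParams] = {}
    for t in tables:
        zf, params = _replicate_z_frame(t, scheme=scheme,
                                        center_stat=center_stat, min_n=min_n)
        zf["replicate_id"] = t.replicate_id
        params_by_rep[t.replicate_id] = params
        frames.append(zf)
    long = pd.concat(frames, ignore_index=True)

    with np.errstate(divide="ignore"):
        long["log10_intensity"] = np.where(
            long["intensity"] > 0, np.log10(long["intensity"]), np.nan)

    grouped = long.groupby("protein_group_id", sort=False)
    summary = grouped.agg(
        gene_name=("gene_name", "first"),
        n_reps=("z", "size"),
        mean_z=("z", "mean"),
        mean_log10_intensity=("log10_intensity", "mean"),
    ).reset_index()

    wide = long.pivot_table(index="protein_group_id", columns="replicate_id",
                            values="z", aggfunc="first")
    wide.columns = [f"z_{c}" for c in wide.columns]
    summary = summary.merge(wide, left_on="protein_group_id",
                            right_index=True, how="left")

    summary = summary[summary["n_reps"] >= min_reps].copy()
    summary["is_interactor"] = summary["mean_z"] >= z_cut
    summary = summary.sort_values(
        by=["mean_z", "mean_log10_intensity", "protein_group_id"],
        ascending=[False, False, True], kind="mergesort",
    ).reset_index(drop=True)
    return summary, params_by_rep


def rnase_z_scores(tables: list[QuantTable], *, scheme: str = "iqr",
                   center_stat: str = "mean", min_n: int = 8) -> pd.Series:
    """Mean asymmetric z of the RNase-effect channel, per protein.

    Each conventional-protocol replicate's RNase/bait ratios are log2
    transformed and normalized with the same asymmetric scheme as the
    bait/control channel; the mean over detected replicates is returned,
    indexed by protein group ID.
    """
    frames = []
    for t in tables:
        if t.data["ratio_rnase"].notna().sum() == 0:
            continue
        zf, _ = _replicate_z_frame(t, ratio_col="ratio_rnase", scheme=scheme,
                                   center_stat=center_stat, min_n=min_n)
        frames.append(zf[["protein_group_id", "z"]])
    if not frames:
        return pd.Series(dtype=float, name="rnase_z")
    long = pd.concat(frames, ignore_index=True)
    out = long.groupby("protein_group_id")["z"].mean()
    out.name = "rnase_z"
    return out


def classify_rnase(calls: pd.DataFrame, rnase_z: pd.Series, *,
                   z_cut: float = -1.0) -> pd.DataFrame:
    """Attach an RNA-dependence class to each call.

    RNase-channel z <= ``z_cut`` (default -1, boundary inclusive) marks
    the interaction as lost upon RNase digestion, hence RNA-dependent;
    z > ``z_cut`` is RNA-independent; proteins without an RNase channel
    measurement are ``not_applicable``.
    """
    out = calls.copy()
    z = out["protein_group_id"].map(rnase_z)
    out["rnase_z"] = z
    out["rna_class"] = np.select(
        [z.isna(), z <= z_cut],
        ["not_applicable", "rna_dependent"],
        default="rna_independent",
    )
    return out
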