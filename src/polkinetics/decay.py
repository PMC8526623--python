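"""SLAM-seq mRNA half-life estimation and the transcript-buffering statistic.

During a uridine chase after 4sU labeling, a gene's T->C conversion rate
decays as ``r(t) = r0 * 2**(-t / T)`` with half-life ``T``.  Taking natural
logs linearizes the decay, ``ln r = a - k t`` with ``T = ln2 / k``, and a
robust (Huber M-estimator) linear fit over all replicate points gives a
half-life per gene and condition that is insensitive to outlier replicates.

Transcript buffering is scored per gene as the difference between the
steady-state (RNA-seq) and nascent (PRO-seq) log2 fold changes: positive
values mean mRNA levels changed more than production, i.e. a stability
change.

Conversion tables are tidy DataFrames with columns
``gene_id, condition, replicate, timepoint_h, conversion_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

CONVERSION_COLUMNS = ["gene_id", "condition", "replicate", "timepoint_h",
                      "conversion_rate"]

HUBER_T = 1.345
IRLS_TOL = 1e-8
IRLS_MAXITER = 50
K_MIN = 1e-12  # per hour; slopes below this are numerically zero


@dataclass
class HalfLife:
    gene_id: str
    condition: str
    decay_k: float          # per hour
    half_life: float        # hours; NaN when k <= 0
    intercept: float        # fitted ln conversion rate at t = 0
    n_points: int
    converged: bool


def filter_conversion_genes(table: pd.DataFrame, min_detected_reps: int = 3
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep genes whose conversion rates behave like a clean decay.

    A gene survives when, in every condition: (i) at least
    ``min_detected_reps`` replicates have conversion > 0 at every timepoint,
    (ii) the median conversion at t = 0 is positive, and (iii) the median
    conversion is non-increasing across ordered timepoints.  Returns
    ``(filtered table, reasons)`` with one reason row per removed gene.
    """
    reasons = []
    keep_genes = []
    for gene, g in table.groupby("gene_id", sort=True):
        reason = None
        for cond, gc in g.groupby("condition"):
            detected = (gc[gc["conversion_rate"] > 0]
                        .groupby("timepoint_h")["replicate"].nunique())
            tps = sorted(gc["timepoint_h"].unique())
            if detected.reindex(tps, fill_value=0).min() < min_detected_reps:
                reason = "undetected"
                break
            med = gc.groupby("timepoint_h")["conversion_rate"].median()
            med = med.loc[tps]
            if med.iloc[0] <= 0:
                reason = "zero_at_t0"
                break
            if (np.diff(med.to_numpy()) > 0).any():
                reason = "non_monotonic"
                break
        if reason is None:
            keep_genes.append(gene)
        else:
            reasons.append((gene, reason))
    filtered = table[table["gene_id"].isin(keep_genes)].reset_index(drop=True)
    return filtered, pd.DataFrame(reasons, columns=["gene_id", "reason"])


def fit_decay_robust(timepoints_h, conversion_rates,
                     gene_id: str = "", condition: str = "") -> HalfLife:
    """Fit ``ln r = a - k t`` by IRLS with Huber weights (c = 1.345, MAD
    scale); ``half_life = ln2 / k`` for k > 0, else NaN.

    Requires >= 3 points spanning >= 2 distinct timepoints and strictly
    positive conversion rates.  Exactly log-linear input (zero residuals,
    where the MAD scale degenerates) returns the exact least-squares line.
    """
    t = np.asarray(timepoints_h, dtype=np.float64)
    r = np.asarray(conversion_rates, dtype=np.float64)
    if t.size < 3:
        raise ValueError("at least 3 points required")
    if np.unique(t).size < 2:
        raise ValueError("at least 2 distinct timepoints required")
    if (r <= 0).any():
        raise ValueError("conversion rates must be > 0 (filter first)")
    y = np.log(r)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    scale = max(1.0, float(np.abs(y).max()))
    if np.abs(resid).max() <= 1e-12 * scale:
        a, slope = beta
        converged = True
    else:
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T)).fit(
            scale_est="mad", conv="coefs", tol=IRLS_TOL,
            maxiter=IRLS_MAXITER)
        a, slope = res.params
        converged = bool(getattr(res, "converged", True))
    k = -float(slope)
    if abs(k) < K_MIN:
        k = 0.0
    half_life = np.log(2) / k if k > 0 else float("nan")
    return HalfLife(gene_id=gene_id, condition=condition, decay_k=k,
                    half_life=half_life, intercept=float(a),
                    n_points=int(t.size), converged=converged)


def half_life_table(table: pd.DataFrame, per_replicate: bool = False
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One robust decay fit per (gene, condition), pooling all replicates.

    With ``per_replicate=True`` each replicate is fit separately and the
    per-replicate half-lives averaged (median).  Returns ``(fits, summary)``;
    the summary gives the per-condition median half-life over genes whose
    half-life is defined (k > 0) in every condition.
    """
    rows = []
    for (gene, cond), g in table.groupby(["gene_id", "condition"], sort=True):
        try:
            if per_replicate:
                fits = [fit_decay_robust(gr["timepoint_h"],
                                         gr["conversion_rate"], gene, cond)
                        for _, gr in g.groupby("replicate")]
                ks = np.array([f.decay_k for f in fits])
                k = float(np.median(ks))
                hl = np.log(2) / k if k > 0 else float("nan")
                rows.append((gene, cond, k, hl,
                             float(np.median([f.intercept for f in fits])),
                             int(len(g)), all(f.converged for f in fits), None))
            else:
                f = fit_decay_robust(g["timepoint_h"], g["conversion_rate"],
                                     gene, cond)
                rows.append((gene, cond, f.decay_k, f.half_life, f.intercept,
                             f.n_points, f.converged, None))
        except ValueError as exc:
            rows.append((gene, cond, float("nan"), float("nan"), float("nan"),
                         int(len(g)), False, str(exc)))
    fits = pd.DataFrame(rows, columns=["gene_id", "condition", "decay_k",
                                       "half_life", "intercept", "n_points",
                                       "converged", "error"])
    defined = fits[fits["half_life"].notna()]
    n_cond = fits["condition"].nunique()
    shared = (defined.groupby("gene_id")["condition"].nunique() == n_cond)
    shared_genes = shared[shared].index
    summary = (defined[defined["gene_id"].isin(shared_genes)]
               .groupby("condition")["half_life"].median()
               .reset_index(name="median_half_life_h"))
    summary["n_genes"] = len(shared_genes)
    return fits, summary


def spike_scaled_l2fc(counts: pd.DataFrame, size_factors: pd.Series,
                      numerator_samples, denominator_samples,
                      pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log2 fold change of spike-scaled mean counts.

    ``counts`` is genes x samples; each sample column is multiplied by its
    size factor, samples are averaged within each group, and
    ``log2((mean_num + pc) / (mean_den + pc))`` is returned.
    """
    scaled = counts.mul(size_factors, axis=1)
    num = scaled[list(numerator_samples)].mean(axis=1)
    den = scaled[list(denominator_samples)].mean(axis=1)
    return np.log2((num + pseudocount) / (den + pseudocount))


def buffering_statistic(l2fc_rna: pd.Series, l2fc_pro: pd.Series
                        ) -> tuple[pd.DataFrame, dict]:
    """Per-gene difference of RNA-seq and PRO-seq log2 fold changes.

    ``delta = l2fc_rna - l2fc_pro``; genes missing (or non-finite) in either
    input are dropped and counted.  The summary reports the median delta and
    the fraction of positive deltas -- a positive skew indicates stability
    changes buffered away from transcription.
    """
    joined = pd.DataFrame({"l2fc_rna": l2fc_rna, "l2fc_pro": l2fc_pro})
    finite = joined.notna().all(axis=1) & np.isfinite(joined).all(axis=1)
    n_dropped = int((~finite).sum())
    kept = joined[finite]
    scores = pd.DataFrame({
        "gene_id": kept.index,
        "delta": (kept["l2fc_rna"] - kept["l2fc_pro"]).to_numpy()})
    summary = {"median_delta": float(scores["delta"].median()),
               "fraction_positive": float((scores["delta"] > 0).mean()),
               "n_genes": int(len(scores)), "n_dropped": n_dropped}
    return scores, summary


def read_conversion_table(path) -> pd.DataFrame:
    """Read a SLAMdunk-style conversion-rate TSV, validating schema and
    ranges; parse failures report the offending line number."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CONVERSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"conversion table missing columns: {sorted(missing)}")
    for col in ("timepoint_h", "conversion_rate"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"malformed value in column {col!r} at line {bad[0] + 2}")
        df[col] = coerced
    if ((df["conversion_rate"] < 0) | (df["conversion_rate"] > 1)).any():
        bad = df.index[(df["conversion_rate"] < 0) |
                       (df["conversion_rate"] > 1)][0]
        raise ValueError(f"conversion rate outside [0, 1] at line {bad + 2}")
    return df
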