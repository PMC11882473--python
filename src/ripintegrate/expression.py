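"""Negative-binomial differential expression and small assay formulas.

The screen is a minimal NB Wald test: median-of-ratios library size factors,
per-gene method-of-moments dispersion on normalised counts (variance =
mu + alpha * mu^2, alpha floored at 1e-8), group means, and a Wald statistic
on the log2 fold-change whose standard error comes from the NB variance of
each group mean.  With three replicates per group the dispersion estimate is
noisy, so the statistic is referred to a t distribution with n1 + n2 - 2
degrees of freedom rather than a normal; this keeps the type-I error of the
screen near its nominal level at the study's sample size.  No dispersion
shrinkage, outlier refitting or fold-change moderation is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CountMatrix

DISPERSION_FLOOR = 1e-8
FC_PSEUDO = 0.5  # Laplace pseudo-count on normalised group means for reporting


@dataclass(frozen=True)
class DesignSpec:
    """Two-group design: sample -> group map with a named reference group."""

    groups: dict[str, str]
    reference: str

    def __post_init__(self) -> None:
        levels = set(self.groups.values())
        if len(levels) != 2:
            raise ValueError(f"design must have exactly 2 groups, got {sorted(levels)}")
        if self.reference not in levels:
            raise ValueError(f"reference group {self.reference!r} not in design")
        for level in levels:
            n = sum(1 for g in self.groups.values() if g == level)
            if n < 2:
                raise ValueError(f"group {level!r} has {n} sample(s); need >= 2")

    @property
    def treatment(self) -> str:
        return next(g for g in set(self.groups.values()) if g != self.reference)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @classmethod
    def from_tsv(cls, path: str, reference: str | None = None) -> "DesignSpec":
        df = pd.read_csv(path, sep="\t")
        groups = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        if reference is None:
            reference = df.iloc[0, 1]
        return cls(groups, str(reference))


def size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Ratios are taken over genes with a nonzero count in every sample,
    against the per-gene geometric mean across samples.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "consider a pseudo-reference fallback"
        )
    sub = mat[all_pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    log_factors = np.median(ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns)


@dataclass
class DegResult:
    gene: str
    base_mean: float
    log2fc: float
    p_value: float
    fdr: float = float("nan")
    status: str = "ns"


def nb_test(cm: CountMatrix, design: DesignSpec) -> pd.DataFrame:
    """Per-gene NB Wald screen of treatment vs reference.

    Returns a DataFrame indexed by gene with columns baseMean, log2FC
    (positive = up in treatment), p, FDR and status (filled by
    :func:`classify_degs`; initialised to 'ns').
    """
    from .integration import bh_fdr

    missing = [s for s in design.groups if s not in cm.counts.columns]
    if missing:
        raise ValueError(f"design samples absent from counts: {missing}")
    sf = size_factors(cm)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    cols = list(cm.counts.columns)
    idx_ref = [cols.index(s) for s in design.samples_of(design.reference)]
    idx_trt = [cols.index(s) for s in design.samples_of(design.treatment)]
    a = norm[:, idx_ref]
    b = norm[:, idx_trt]
    n1, n2 = a.shape[1], b.shape[1]
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    base_mean = norm.mean(axis=1)
    # pooled within-group variance, method-of-moments dispersion
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mu = np.where(base_mean > 0, base_mean, 1.0)
    alpha = np.maximum((pooled_var - mu) / mu**2, DISPERSION_FLOOR)
    # Wald on log2FC: Var(log mean_i) ~ (1/mu_i + alpha) / n_i
    m1p = m1 + FC_PSEUDO
    m2p = m2 + FC_PSEUDO
    log2fc = np.log2(m2p) - np.log2(m1p)
    se_ln = np.sqrt((1.0 / m1p + alpha) / n1 + (1.0 / m2p + alpha) / n2)
    se = se_ln / math.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    all_zero = (cm.counts.to_numpy() == 0).all(axis=1)
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "p": p,
            "FDR": bh_fdr(p),
            "status": "ns",
        },
        index=cm.counts.index,
    )
    out.index.name = "gene"
    return out


def classify_degs(
    results: pd.DataFrame,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    p_threshold: float = 0.05,
    use_fdr: bool = False,
) -> tuple[set[str], set[str]]:
    """Split genes into up/down sets by fold-change and significance cut-offs.

    ``fc_up``/``fc_down`` are linear fold-changes (treatment / reference);
    significance uses raw p by default or BH-FDR when ``use_fdr``.
    Mutates ``results['status']`` in place.
    """
    if results.empty:
        raise ValueError("empty result table")
    if fc_up <= 1 or fc_down >= 1:
        raise ValueError("need fc_up > 1 and fc_down < 1")
    fc = np.power(2.0, results["log2FC"].to_numpy())
    sig = (results["FDR"] if use_fdr else results["p"]).to_numpy() < p_threshold
    up_mask = sig & (fc > fc_up)
    down_mask = sig & (fc < fc_down)
    results["status"] = np.where(up_mask, "up", np.where(down_mask, "down", "ns"))
    genes = results.index
    return set(genes[up_mask]), set(genes[down_mask])


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method, normalised to a reference gene."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def proliferation_rate(od_exp: float, od_control: float, od_blank: float) -> float:
    """CCK-8 proliferation rate in percent:
    (OD_exp - OD_blank) / (OD_control - OD_blank) * 100."""
    if od_control <= od_blank:
        raise ValueError("control OD must exceed blank OD")
    return (od_exp - od_blank) / (od_control - od_blank) * 100.0
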