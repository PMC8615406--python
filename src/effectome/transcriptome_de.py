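"""Negative-binomial differential expression for the 2x2 induction design.

The design crosses strain (WT vs a ttsI insertion mutant) with inducer
(genistein vs DMSO vehicle). Two contrasts classify each gene:

* TtsI dependence — WT+genistein over ttsI_mutant+genistein;
* genistein induction — WT+genistein over WT+DMSO.

The test is a deliberately transparent negative-binomial Wald test:
median-of-ratios size factors, a per-gene method-of-moments dispersion
pooled within conditions, a delta-method standard error for the log fold
change, and a Student-t reference with the residual degrees of freedom of
the dispersion estimate (the small-sample analogue of the normal Wald
reference; with many samples the two coincide). Multiplicity is controlled
by Benjamini–Hochberg over all tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
DEFAULT_PRIOR_DF = 30.0

CONDITIONS = [("WT", "genistein"), ("WT", "DMSO"),
              ("ttsI_mutant", "genistein"), ("ttsI_mutant", "DMSO")]


def condition_label(strain: str, inducer: str) -> str:
    return f"{strain}:{inducer}"


def _validate(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("empty count matrix")
    if (counts.values < 0).any():
        raise ValueError("count matrix has negative entries")
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    factor_j = median over genes (restricted to genes with a positive
    geometric mean, i.e. nonzero in every sample) of count_gj / geomean_g.
    """
    _validate(counts)
    mat = counts.values.astype(float)
    positive = np.all(mat > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; cannot normalize")
    sub = mat[positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(counts: pd.DataFrame, factors: pd.Series,
                        design: pd.DataFrame,
                        floor: float = DISPERSION_FLOOR,
                        prior_df: float = 0.0) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within each condition, alpha_c = (s_c^2 − m̄_c) / m̄_c^2 on that
    condition's own mean (so a real between-condition effect never inflates
    the estimate); the per-gene estimate is the df-weighted average across
    conditions, floored at ``floor``. A Poisson-like or constant gene lands
    on the floor.

    With ``prior_df`` > 0 the raw per-gene estimates are shrunk toward
    their across-gene mean with that many pseudo-degrees of freedom
    (alpha~ = (df*alpha_g + prior_df*alpha_bar) / (df + prior_df)), the
    standard moderation for designs with very few replicates, where the
    per-gene moment estimate alone is too noisy to give a calibrated Wald
    test. The returned Series carries ``attrs['residual_df']`` and
    ``attrs['prior_df']`` for the test's t reference.
    """
    norm = counts.values / factors.reindex(counts.columns).values
    labels = design.set_index("sample_id").loc[counts.columns]
    cond = (labels["strain"] + ":" + labels["inducer"]).values
    uniq = pd.unique(cond)
    df = 0
    weighted = np.zeros(norm.shape[0])
    for c in uniq:
        mask = cond == c
        n_c = int(mask.sum())
        if n_c < 2:
            continue
        m_c = norm[:, mask].mean(axis=1)
        s2_c = norm[:, mask].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_c = (s2_c - m_c) / np.square(m_c)
        a_c = np.where(np.isfinite(a_c), a_c, 0.0)
        weighted += (n_c - 1) * a_c
        df += n_c - 1
    if df <= 0:
        raise ValueError("need replicate samples to estimate dispersion")
    raw = weighted / df
    if prior_df > 0:
        target = float(np.mean(np.maximum(raw, 0.0)))
        raw = (df * raw + prior_df * target) / (df + prior_df)
    alpha = pd.Series(np.maximum(floor, raw), index=counts.index,
                      name="dispersion")
    alpha.attrs["residual_df"] = df
    alpha.attrs["prior_df"] = float(prior_df)
    return alpha


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    numerator: tuple[str, str]     # (strain, inducer)
    denominator: tuple[str, str]

    def label(self) -> str:
        return (f"{condition_label(*self.numerator)}_vs_"
                f"{condition_label(*self.denominator)}").replace(":", ".")


def nb_wald_test(counts: pd.DataFrame, design: pd.DataFrame,
                 contrast: Contrast,
                 factors: pd.Series | None = None,
                 dispersion: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene log2 fold change, SE, Wald statistic, p and BH-adjusted p.

    Condition means are fitted on normalized counts with a pseudocount of
    0.5 (keeps the log ratio finite for zero-mean conditions); the SE is the
    NB delta-method SE of the log ratio, var(log m) ≈ (1/m + alpha)/n per
    condition, with the moderated dispersion estimate (prior_df pseudo-
    degrees of freedom toward the across-gene mean) unless a dispersion
    Series is supplied. p-values are two-sided from a Student-t reference
    at the total (residual + prior) degrees of freedom of that estimate.
    """
    _validate(counts)
    needed = {"sample_id", "strain", "inducer"}
    if not needed.issubset(design.columns):
        raise ValueError(f"design table must have columns {sorted(needed)}")
    labels = design.set_index("sample_id").loc[counts.columns]
    cond = labels["strain"] + ":" + labels["inducer"]
    num_label = condition_label(*contrast.numerator)
    den_label = condition_label(*contrast.denominator)
    for lab in (num_label, den_label):
        n_in = int((cond == lab).sum())
        if n_in == 0:
            raise ValueError(f"condition {lab!r} absent from design")
        if n_in < 2:
            raise ValueError(f"condition {lab!r} has fewer than 2 replicates")

    if factors is None:
        factors = size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors, design,
                                         prior_df=DEFAULT_PRIOR_DF)

    norm = counts.values / factors.reindex(counts.columns).values
    num_mask = (cond == num_label).values
    den_mask = (cond == den_label).values
    n1, n2 = int(num_mask.sum()), int(den_mask.sum())
    # zero / near-zero condition means are floored at the pseudocount so the
    # log ratio stays finite without perturbing well-measured genes
    m1 = np.maximum(norm[:, num_mask].mean(axis=1), PSEUDOCOUNT)
    m2 = np.maximum(norm[:, den_mask].mean(axis=1), PSEUDOCOUNT)
    alpha = dispersion.reindex(counts.index).values

    log2fc = np.log2(m1 / m2)
    se = np.sqrt((1.0 / m1 + alpha) / n1 + (1.0 / m2 + alpha) / n2) / np.log(2)
    stat = log2fc / se
    df = (dispersion.attrs.get("residual_df", norm.shape[1] - cond.nunique())
          + dispersion.attrs.get("prior_df", 0.0))
    pval = 2.0 * stats.t.sf(np.abs(stat), df=df)
    padj = multipletests(pval, method="fdr_bh")[1]

    return pd.DataFrame({
        "gene_id": counts.index,
        "baseMean": norm.mean(axis=1),
        "log2FC": log2fc,
        "SE": se,
        "stat": stat,
        "p": pval,
        "padj": padj,
    }).set_index("gene_id")


# ---------------------------------------------------------------------------
# regulation classification
# ---------------------------------------------------------------------------

def classify_regulation(ttsI_contrast: pd.DataFrame,
                        genistein_contrast: pd.DataFrame,
                        fc_min: float = 2.0, p_max: float = 0.01,
                        use_adjusted: bool = True) -> pd.DataFrame:
    """Flag genes as TtsI-dependent and/or genistein-induced.

    ``ttsI_contrast`` is WT+genistein vs ttsI_mutant+genistein;
    ``genistein_contrast`` is WT+genistein vs WT+DMSO. A gene passes a
    contrast when its fold change is >= ``fc_min`` (with positive sign) and
    its (BH-adjusted by default) p-value is < ``p_max``. ``near_miss``
    flags genes that clear one cutoff in a contrast but not the other —
    effect size without significance or vice versa.
    """
    if not ttsI_contrast.index.equals(genistein_contrast.index):
        a, b = set(ttsI_contrast.index), set(genistein_contrast.index)
        raise ValueError(
            f"contrasts cover different gene sets "
            f"({len(a - b)} only in first, {len(b - a)} only in second)")
    pcol = "padj" if use_adjusted else "p"
    lfc_min = np.log2(fc_min)

    def passes(tbl):
        fc_ok = tbl["log2FC"] >= lfc_min
        p_ok = tbl[pcol] < p_max
        return fc_ok & p_ok, fc_ok ^ p_ok

    ttsI_dep, ttsI_near = passes(ttsI_contrast)
    gen_ind, gen_near = passes(genistein_contrast)
    both = ttsI_dep & gen_ind
    return pd.DataFrame({
        "ttsI_dependent": ttsI_dep,
        "genistein_induced": gen_ind,
        "ttsI_dependent_genistein_induction": both,
        "near_miss": (ttsI_near | gen_near) & ~both,
    }, index=ttsI_contrast.index)
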