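"""Multi-environment trial statistics: variance components, h2, GCV, correlation.

The two-way random model for a line i grown in environment j, replicate k is

    y_ijk = mu + g_i + e_j + r(e)_jk + (ge)_ij + eps_ijk

with genotype, environment, replication-within-environment and genotype x
environment all random.  Variance components are solved by the method of
moments from the expected mean squares of the balanced ANOVA (replicates
nested in environments; mild imbalance is absorbed by using cell means with
the average cell size):

    MS_error = s2
    MS_GE    = s2 + r s2_gt
    MS_G     = s2 + r s2_gt + r t s2_g

Heritability (broad sense, on an entry-mean basis):

    single environment:  h2 = s2_g / (s2_g + s2/r)
    combined:            h2 = s2_g / (s2_g + s2_gt/t + s2/(t r))

GCV% = 100 * sqrt(s2_g) / phenotypic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iokit import PhenotypeTable

__all__ = [
    "VarianceComponents",
    "TraitSummary",
    "estimate_components",
    "heritability",
    "trait_summary",
    "trait_correlation",
]


@dataclass
class VarianceComponents:
    """Method-of-moments variance components of the two-way random model.

    Negative solutions are truncated to zero and flagged in ``truncated``.
    ``t`` is the number of environments, ``r`` the replicates per environment;
    the mean squares and p-values of the genotype and GxE F-tests are kept for
    reporting.
    """

    sigma2_g: float
    sigma2_gt: float
    sigma2_e: float
    t: int
    r: float
    truncated: tuple[str, ...] = ()
    p_genotype: float = float("nan")
    p_gxe: float = float("nan")


@dataclass
class TraitSummary:
    trait: str
    n: int
    mean: float
    minimum: float
    maximum: float
    gcv_percent: float
    h2_percent: float
    histogram_midpoints: np.ndarray
    histogram_counts: np.ndarray
    components: VarianceComponents


def _trait_frame(pheno: PhenotypeTable, trait: str) -> pd.DataFrame:
    df = pheno.data
    df = df[(df["trait"] == trait) & df["value"].notna()]
    if df.empty:
        raise ValueError(f"no data for trait {trait!r}")
    return df


def estimate_components(pheno: PhenotypeTable, trait: str) -> VarianceComponents:
    """Solve the variance components for one trait by expected mean squares.

    Requires at least 2 genotypes and a design where residual error is
    separable (>= 2 replicates, or >= 2 environments with replication).  For
    single-environment data sigma2_gt is fixed at 0.
    """
    df = _trait_frame(pheno, trait)
    envs = sorted(df["environment"].unique())
    genos = sorted(df["accession"].unique())
    t, n = len(envs), len(genos)
    if n < 2:
        raise ValueError("need >= 2 genotypes")
    reps_per_env = df.groupby(["environment", "accession"])["value"].size()
    r = float(reps_per_env.mean())
    if r < 2 and t < 2:
        raise ValueError("residual error inseparable: need >= 2 replicates or environments")

    grand = df["value"].mean()
    cell = df.groupby(["accession", "environment"])["value"].mean().unstack()
    cell = cell.reindex(index=genos, columns=envs)
    g_mean = cell.mean(axis=1)
    e_mean = cell.mean(axis=0)

    ss_g = r * t * float(((g_mean - grand) ** 2).sum())
    df_g = n - 1
    interaction = cell.sub(g_mean, axis=0).sub(e_mean, axis=1) + grand
    ss_ge = r * float((interaction**2).sum().sum())
    df_ge = (n - 1) * (t - 1)

    # residual: plot values around their cell mean, with replicate-in-env
    # block effects removed
    merged = df.merge(
        cell.stack().rename("cell_mean"),
        left_on=["accession", "environment"],
        right_index=True,
    )
    rep_mean = df.groupby(["environment", "replicate"])["value"].mean()
    env_mean_map = df.groupby("environment")["value"].mean()
    merged = merged.merge(
        rep_mean.rename("rep_mean"), left_on=["environment", "replicate"], right_index=True
    )
    merged["env_mean"] = merged["environment"].map(env_mean_map)
    resid = merged["value"] - merged["cell_mean"] - (merged["rep_mean"] - merged["env_mean"])
    n_rep_terms = df.groupby("environment")["replicate"].nunique().sum() - t
    df_err = len(df) - n * t - int(n_rep_terms)
    ss_err = float((resid**2).sum())

    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_err = ss_err / df_err
    truncated: list[str] = []
    if t >= 2:
        ms_ge = ss_ge / df_ge
        ms_g = ss_g / df_g
        s2_gt = (ms_ge - ms_err) / r
        s2_g = (ms_g - ms_ge) / (r * t)
        # degenerate noiseless data: an exactly-zero denominator MS means the
        # tested term is absent, not infinitely significant
        p_ge = float(stats.f.sf(ms_ge / ms_err, df_ge, df_err)) if ms_err > 0 else (1.0 if ms_ge == 0 else 0.0)
        # genotype tested against the GxE mean square (random model)
        p_g = float(stats.f.sf(ms_g / ms_ge, df_g, df_ge)) if ms_ge > 0 else (1.0 if ms_g == 0 else 0.0)
    else:
        ms_g = ss_g / df_g
        s2_gt = 0.0
        s2_g = (ms_g - ms_err) / r
        p_ge = float("nan")
        p_g = float(stats.f.sf(ms_g / ms_err, df_g, df_err)) if ms_err > 0 else (1.0 if ms_g == 0 else 0.0)
    if s2_gt < 0:
        s2_gt = 0.0
        truncated.append("sigma2_gt")
    if s2_g < 0:
        s2_g = 0.0
        truncated.append("sigma2_g")
    return VarianceComponents(
        sigma2_g=s2_g,
        sigma2_gt=s2_gt,
        sigma2_e=ms_err,
        t=t,
        r=r,
        truncated=tuple(truncated),
        p_genotype=p_g,
        p_gxe=p_ge,
    )


def heritability(vc: VarianceComponents, combined: bool = True) -> float:
    """Entry-mean heritability from the components.

    ``combined=True`` uses h2 = s2_g/(s2_g + s2_gt/t + s2/(t r)); otherwise
    the single-environment form h2 = s2_g/(s2_g + s2/r).
    """
    if vc.sigma2_g == 0 and vc.sigma2_gt == 0 and vc.sigma2_e == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    if combined:
        denom = vc.sigma2_g + vc.sigma2_gt / vc.t + vc.sigma2_e / (vc.t * vc.r)
    else:
        denom = vc.sigma2_g + vc.sigma2_e / vc.r
    return vc.sigma2_g / denom


def trait_summary(pheno: PhenotypeTable, trait: str, bin_width: float = 1.0) -> TraitSummary:
    """Descriptive statistics plus GCV% and h2% for one trait.

    The histogram is binned at midpoints ``bin_width`` apart, anchored at a
    multiple of the width.
    """
    df = _trait_frame(pheno, trait)
    values = df["value"].to_numpy()
    mean = float(values.mean())
    if mean == 0:
        raise ValueError("phenotypic mean is zero; GCV undefined")
    vc = estimate_components(pheno, trait)
    gcv = 100.0 * np.sqrt(vc.sigma2_g) / mean
    try:
        h2 = 100.0 * heritability(vc, combined=vc.t > 1)
    except ValueError:  # constant trait: h2 undefined, GCV still 0
        h2 = float("nan")

    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2
    return TraitSummary(
        trait=trait,
        n=len(values),
        mean=mean,
        minimum=float(values.min()),
        maximum=float(values.max()),
        gcv_percent=float(gcv),
        h2_percent=float(h2),
        histogram_midpoints=mids,
        histogram_counts=counts,
        components=vc,
    )


def trait_correlation(
    pheno: PhenotypeTable, trait_a: str, trait_b: str
) -> tuple[float, float]:
    """Pearson correlation of accession means between two traits.

    Returns (r, two-sided p).  Requires >= 3 shared accessions and non-zero
    variance in both traits.
    """
    ma = pheno.accession_means(trait_a)
    mb = pheno.accession_means(trait_b)
    shared = ma.index.intersection(mb.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared accessions")
    a = ma.loc[shared].to_numpy()
    b = mb.loc[shared].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a trait; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
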