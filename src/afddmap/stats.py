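"""Marker and phenotype statistics for confirming a mapped recessive locus.

Goodness-of-fit chi-squares for segregation ratios, parental-allele
segregation-distortion tests within phenotype groups, phenotype-frequency
tables by genotype class, and least-squares regression of ordinal growth
scores on genotype-class indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "GofResult",
    "DistortionResult",
    "RegressionResult",
    "gof_chi_square",
    "allele_distortion_test",
    "phenotype_frequency_table",
    "phenotype_score_regression",
]


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p: float
    observed: tuple[int, ...]
    expected: tuple[float, ...]


@dataclass(frozen=True)
class DistortionResult:
    """Outcome of one parental-allele distortion test.

    ``informative`` is False when the parent transmits a single allele to all
    offspring (a marker-homozygous parent cannot show distortion); ``result``
    is then None.
    """

    informative: bool
    result: GofResult | None
    n_excluded: int = 0
    reason: str = ""


def gof_chi_square(
    observed: Sequence[int], expected_ratio: Sequence[float]
) -> GofResult:
    """Pearson goodness-of-fit test against an expected ratio.

    No continuity correction is applied (e.g. observed (76, 132, 67) against
    1:2:1 gives chi2 = 1.029, p = 0.5978); df = k - 1.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.ndim != 1 or len(obs) != len(ratio):
        raise ValueError("observed and expected_ratio must have equal length")
    if (obs < 0).any() or obs.sum() <= 0:
        raise ValueError("observed counts must be non-negative with positive total")
    if (ratio <= 0).any():
        raise ValueError("expected_ratio entries must be positive")
    expected = obs.sum() * ratio / ratio.sum()
    chi2, p = sps.chisquare(obs, f_exp=expected)
    return GofResult(
        float(chi2), len(obs) - 1, float(p),
        tuple(int(x) for x in obs), tuple(float(x) for x in expected),
    )


def allele_distortion_test(
    alleles: Sequence, expected_ratio: Sequence[float] = (1.0, 1.0)
) -> DistortionResult:
    """Test transmitted parental alleles against the expected (default 1:1) ratio.

    ``alleles`` holds the allele each offspring in the phenotype group
    received from one parent (any two distinct values; NaN/None entries are
    excluded and tallied).  If only one allele value is observed the parent is
    reported as uninformative instead of tested.
    """
    s = pd.Series(list(alleles))
    n_excluded = int(s.isna().sum())
    s = s.dropna()
    values = sorted(s.unique().tolist())
    if len(values) > 2:
        raise ValueError(f"more than two allele values observed: {values}")
    if len(values) < 2:
        return DistortionResult(
            informative=False, result=None, n_excluded=n_excluded,
            reason="uninformative parent (single transmitted allele)",
        )
    counts = [int((s == v).sum()) for v in values]
    return DistortionResult(
        informative=True,
        result=gof_chi_square(counts, expected_ratio),
        n_excluded=n_excluded,
    )


def phenotype_frequency_table(
    individuals: pd.DataFrame,
    rounds: Sequence[int] | None = None,
    exclude_recombinants: bool = True,
) -> pd.DataFrame:
    """Std2 frequency per suppressor-genotype class and evaluation round.

    Uses the simulator truth columns (``co_genotype``, ``locus*_genotype``,
    ``score_r*``).  Only dominant-allele carriers enter the table (the
    recessive suppression is undetectable in coco individuals); rows are the
    genotype classes at the suppressor loci, e.g. the six classes of a
    two-locus cross with one parent homozygous at locus 2.  Recombinants
    between the dominant locus and suppressor locus 1 are excluded by default
    (flag column ``dom_locus1_recombinant``); individuals with a missing
    genotype are excluded, with the count kept in the result's
    ``attrs["n_excluded_missing_genotype"]``.
    """
    df = individuals.copy()
    if rounds is None:
        rounds = sorted(
            int(c.split("score_r")[1]) for c in df.columns if c.startswith("score_r")
        )
    locus_cols = sorted(c for c in df.columns if c.endswith("_genotype")
                        and c.startswith("locus"))
    if not locus_cols:
        raise ValueError("no locus*_genotype columns found")
    carriers = df[df["co_genotype"].isin(["CoCo", "Coco"])].copy()
    if exclude_recombinants and "dom_locus1_recombinant" in carriers:
        carriers = carriers[~carriers["dom_locus1_recombinant"]]
    missing = carriers[locus_cols].isna().any(axis=1)
    n_missing = int(missing.sum())
    carriers = carriers[~missing]
    rows = []
    for cls, sub in carriers.groupby(locus_cols, sort=True):
        if isinstance(cls, str):
            cls = (cls,)
        row = {"genotype_class": " ".join(cls), "n": len(sub)}
        for t in rounds:
            std2 = (sub[f"score_r{t}"] >= 3).sum()
            row[f"n_std2_r{t}"] = int(std2)
            row[f"freq_std2_r{t}"] = round(float(std2 / len(sub)), 4) if len(sub) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_excluded_missing_genotype"] = n_missing
    return out


@dataclass(frozen=True)
class RegressionResult:
    r2: float
    model_p: float
    n: int


def phenotype_score_regression(
    scores: Sequence[float],
    *genotypes: Sequence,
) -> RegressionResult:
    """Least-squares fit of growth-habit scores on genotype-class indicators.

    One or two genotype factors are coded as categorical indicators; returns
    the coefficient of determination and the overall-F p value.  A nested
    two-locus fit on the same individuals never has lower r2 than either
    single-locus fit.
    """
    if not genotypes or len(genotypes) > 2:
        raise ValueError("one or two genotype factors required")
    data = pd.DataFrame({"score": np.asarray(scores, dtype=float)})
    terms = []
    for i, g in enumerate(genotypes):
        col = f"g{i + 1}"
        data[col] = pd.Series(list(g)).astype(str).to_numpy()
        terms.append(f"C({col})")
    data = data.dropna()
    if len(data) < 10:
        raise ValueError("need at least 10 complete observations")
    for i in range(len(genotypes)):
        if data[f"g{i + 1}"].nunique() < 2:
            raise ValueError(f"genotype factor {i + 1} has a single class; fit undefined")
    fit = smf.ols("score ~ " + " + ".join(terms), data=data).fit()
    return RegressionResult(float(fit.rsquared), float(fit.f_pvalue), int(len(data)))
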