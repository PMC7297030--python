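"""Expected pool allele frequencies for phase-resolved marker segregation types.

In an outcrossing biparental F1 population, a biallelic SNV marker segregates
according to the (phase-resolved) genotype configuration of the two parents.
Writing V for the variant allele (relative to the reference genome) and R for
the reference allele, each parent is an ordered allele pair whose *first*
allele rides the haplotype carrying the recessive allele of the trait locus
the marker is linked to.  Twelve such derivatives exist once at least one
parent is heterozygous; five of them produce a positive allele-frequency
directional difference (AFDD) between the recessive-phenotype pool and the
dominant-phenotype pool and are therefore informative for mapping a recessive
trait.  They carry the conventional names

====  ==============  ==========================
name  configuration   outcrossing marker notation
====  ==============  ==========================
A     (V|R, V|R)      <hk x hk>, variant in coupling in both parents
B     (V|R, V|V)      <lm x ll>, pollen parent variant-homozygous
C     (V|V, V|R)      <nn x np>, seed parent variant-homozygous
D     (V|R, R|R)      <lm x mm>, pollen parent reference-homozygous
E     (R|R, V|R)      <pp x np>, seed parent reference-homozygous
====  ==============  ==========================

All expectations are computed with exact rational arithmetic under complete
marker-locus linkage, for a recessive trait controlled by one locus or by two
unlinked loci (the trait expressed only when homozygous recessive at every
locus; both parents heterozygous at each modelled locus).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "VARIANT",
    "REFERENCE",
    "MarkerSegregation",
    "RecessiveModel",
    "PoolExpectation",
    "TypeFilterWindow",
    "ALL_DERIVATIVES",
    "enumerate_offspring",
    "expected_pool_af",
    "informative_filter_windows",
    "expectation_table",
]

VARIANT = "V"
REFERENCE = "R"

#: phenotype classes used throughout
RECESSIVE = "recessive"
DOMINANT = "dominant"

_NAMED_TYPES: dict[tuple[tuple[str, str], tuple[str, str]], str] = {
    (("V", "R"), ("V", "R")): "A",
    (("V", "R"), ("V", "V")): "B",
    (("V", "V"), ("V", "R")): "C",
    (("V", "R"), ("R", "R")): "D",
    (("R", "R"), ("V", "R")): "E",
}


class ConfigurationError(ValueError):
    """Raised for invalid segregation or model configurations."""


@dataclass(frozen=True)
class MarkerSegregation:
    """Phase-resolved marker configuration of the two parents.

    Parameters
    ----------
    seed_parent, pollen_parent
        Ordered allele pairs drawn from ``{"V", "R"}``.  The first allele of
        each pair is the one on the haplotype carrying the recessive trait
        allele of that parent.
    """

    seed_parent: tuple[str, str]
    pollen_parent: tuple[str, str]

    def __post_init__(self) -> None:
        for pair in (self.seed_parent, self.pollen_parent):
            if len(pair) != 2 or any(a not in (VARIANT, REFERENCE) for a in pair):
                raise ConfigurationError(
                    f"parent allele pair must be two alleles from {{V, R}}, got {pair!r}"
                )

    @property
    def label(self) -> str:
        """Named type ``A``-``E``, or ``"other"``."""
        return _NAMED_TYPES.get((self.seed_parent, self.pollen_parent), "other")

    @classmethod
    def from_label(cls, label: str) -> "MarkerSegregation":
        for key, name in _NAMED_TYPES.items():
            if name == label:
                return cls(*key)
        raise ConfigurationError(f"unknown segregation type label {label!r}")

    def key(self) -> str:
        """Compact string key, e.g. ``"VRxVR"`` for type A."""
        return "".join(self.seed_parent) + "x" + "".join(self.pollen_parent)


def _all_derivatives() -> tuple[MarkerSegregation, ...]:
    pairs = [("V", "R"), ("R", "V"), ("V", "V"), ("R", "R")]
    het = {("V", "R"), ("R", "V")}
    out = []
    for seed, pollen in product(pairs, pairs):
        if seed in het or pollen in het:  # both-homozygous pairs do not segregate
            out.append(MarkerSegregation(seed, pollen))
    return tuple(out)


#: the 12 phase-resolved segregating derivatives of <hk x hk>, <lm x ll>, <nn x np>
ALL_DERIVATIVES: tuple[MarkerSegregation, ...] = _all_derivatives()


@dataclass(frozen=True)
class RecessiveModel:
    """Number of unlinked recessive loci required for trait expression.

    The marker is completely linked to locus 1; under ``n_loci = 2`` a second,
    unlinked locus segregates with both parents heterozygous, and the trait is
    expressed only in offspring homozygous recessive at both loci.
    """

    n_loci: int = 1

    def __post_init__(self) -> None:
        if self.n_loci not in (1, 2):
            raise ConfigurationError(f"n_loci must be 1 or 2, got {self.n_loci}")


@dataclass(frozen=True)
class PoolExpectation:
    """Expected pool variant allele frequencies, in percent (exact rationals).

    ``afdd`` is the allele-frequency directional difference
    ``af_recessive_pool - af_dominant_pool`` in percentage points; a marker is
    informative for mapping the recessive trait only when it is positive.
    """

    af_recessive_pool: Fraction
    af_dominant_pool: Fraction
    afdd: Fraction
    informative: bool


def _gametes(pair: tuple[str, str], n_loci: int):
    """Enumerate (marker allele, trait alleles...) gametes with probabilities.

    Locus 1 is completely linked to the marker: haplotype 0 carries the
    recessive allele (coded 1) together with the first marker allele.
    """
    for hap in (0, 1):
        marker = pair[hap]
        locus1 = 1 if hap == 0 else 0
        if n_loci == 1:
            yield (marker, (locus1,)), Fraction(1, 2)
        else:
            for locus2 in (1, 0):
                yield (marker, (locus1, locus2)), Fraction(1, 4)


def enumerate_offspring(
    seg: MarkerSegregation, model: RecessiveModel
) -> dict[tuple[str, str], Fraction]:
    """Exact offspring distribution over (marker genotype, phenotype class).

    Returns a mapping ``{(genotype, class): probability}`` where ``genotype``
    is the unordered marker genotype (``"VV"``, ``"VR"`` or ``"RR"``) and
    ``class`` is ``"recessive"`` (homozygous recessive at every trait locus)
    or ``"dominant"``.  Probabilities are exact and sum to one.
    """
    if not isinstance(model, RecessiveModel):
        model = RecessiveModel(model)
    dist: dict[tuple[str, str], Fraction] = {}
    for (m_s, t_s), p_s in _gametes(seg.seed_parent, model.n_loci):
        for (m_p, t_p), p_p in _gametes(seg.pollen_parent, model.n_loci):
            genotype = "".join(sorted(m_s + m_p, reverse=True))  # V before R
            recessive = all(a + b == 2 for a, b in zip(t_s, t_p))
            klass = RECESSIVE if recessive else DOMINANT
            key = (genotype, klass)
            dist[key] = dist.get(key, Fraction(0)) + p_s * p_p
    return dist


def _variant_dose(genotype: str) -> int:
    return genotype.count(VARIANT)


def expected_pool_af(
    seg: MarkerSegregation, model: RecessiveModel | int = RecessiveModel(1)
) -> PoolExpectation:
    """Closed-form expected variant AF in the two phenotype pools, percent.

    The recessive pool collects offspring homozygous recessive at all trait
    loci; the dominant pool collects everyone else.  Under complete linkage the
    recessive pool is fixed for the first (recessive-linked) marker allele of
    each parent, while the dominant pool frequency follows from subtracting the
    recessive class from the Mendelian total.
    """
    if not isinstance(model, RecessiveModel):
        model = RecessiveModel(model)
    vs0, vs1 = (1 if a == VARIANT else 0 for a in seg.seed_parent)
    vp0, vp1 = (1 if a == VARIANT else 0 for a in seg.pollen_parent)
    q = Fraction(1, 4) ** model.n_loci  # P(recessive class)

    af_rec = Fraction(vs0 + vp0, 2)
    # E[variant dose] over all offspring, and its recessive-class share
    e_total = Fraction(vs0 + vs1 + vp0 + vp1, 2)
    e_rec = (vs0 + vp0) * q
    af_dom = (e_total - e_rec) / (2 * (1 - q))

    af_rec_pct = 100 * af_rec
    af_dom_pct = 100 * af_dom
    afdd = af_rec_pct - af_dom_pct
    return PoolExpectation(af_rec_pct, af_dom_pct, afdd, informative=afdd > 0)


def pool_af_from_enumeration(
    seg: MarkerSegregation, model: RecessiveModel | int
) -> PoolExpectation:
    """Pool AFs recomputed from the full offspring enumeration (cross-check route)."""
    if not isinstance(model, RecessiveModel):
        model = RecessiveModel(model)
    dist = enumerate_offspring(seg, model)
    totals = {RECESSIVE: Fraction(0), DOMINANT: Fraction(0)}
    doses = {RECESSIVE: Fraction(0), DOMINANT: Fraction(0)}
    for (genotype, klass), p in dist.items():
        totals[klass] += p
        doses[klass] += p * _variant_dose(genotype)
    af_rec = 100 * doses[RECESSIVE] / (2 * totals[RECESSIVE])
    af_dom = 100 * doses[DOMINANT] / (2 * totals[DOMINANT])
    afdd = af_rec - af_dom
    return PoolExpectation(af_rec, af_dom, afdd, informative=afdd > 0)


# ---------------------------------------------------------------------------
# informative-SNV filter windows


@dataclass(frozen=True)
class TypeFilterWindow:
    """AF / AFDD acceptance window for one set of informative types.

    Bounds are the published decimal constants (percent scale), not recomputed
    from the underlying fractions.  ``afdd_max_inclusive`` distinguishes the
    half-open B/C upper bound (< 43.3, so that no SNV satisfies both the A and
    the B/C window) from the closed D/E bound.
    """

    type_set: str  # "A", "B/C" or "D/E"
    source_group: str  # zygosity group the window draws from
    af_recessive_min: float
    af_recessive_max: float
    afdd_min: float
    afdd_max: float
    afdd_max_inclusive: bool = True

    def contains(self, af_recessive: float, afdd: float) -> bool:
        if not (self.af_recessive_min <= af_recessive <= self.af_recessive_max):
            return False
        if afdd < self.afdd_min:
            return False
        if self.afdd_max_inclusive:
            return afdd <= self.afdd_max
        return afdd < self.afdd_max


_WINDOW_A = TypeFilterWindow("A", "Ho-R/He-D", 85.0, 100.0, 43.3, float("inf"))
_WINDOW_BC = TypeFilterWindow("B/C", "Ho-R/He-D", 85.0, 100.0, 16.7, 43.3,
                              afdd_max_inclusive=False)
_WINDOW_DE = TypeFilterWindow("D/E", "He-R/He-D", 35.0, 65.0, 16.7, 43.3)


def informative_filter_windows(
    models: Iterable[RecessiveModel | int] = (1, 2)
) -> list[TypeFilterWindow]:
    """The three published filter windows (A; B/C; D/E).

    The bounds are fixed constants chosen to bracket the expected values under
    both the one- and two-recessive-gene models (e.g. the A window AFDD floor
    43.3 covers the expectations 66.7 and 53.3); they are returned unchanged
    for any non-empty subset of models.
    """
    models = [m if isinstance(m, RecessiveModel) else RecessiveModel(m) for m in models]
    if not models:
        raise ConfigurationError("at least one recessive model is required")
    return [_WINDOW_A, _WINDOW_BC, _WINDOW_DE]


def expectation_table(models: Iterable[RecessiveModel | int] = (1, 2)) -> pd.DataFrame:
    """All 12 derivatives x models with expected pool AFs and AFDD.

    Columns: seed_pair, pollen_pair, label, n_loci, af_recessive, af_dominant,
    afdd (floats, percent scale) and informative.
    """
    models = [m if isinstance(m, RecessiveModel) else RecessiveModel(m) for m in models]
    if not models:
        raise ConfigurationError("at least one recessive model is required")
    rows = []
    for seg in ALL_DERIVATIVES:
        for model in models:
            exp = expected_pool_af(seg, model)
            rows.append(
                {
                    "seed_pair": "|".join(seg.seed_parent),
                    "pollen_pair": "|".join(seg.pollen_parent),
                    "label": seg.label,
                    "n_loci": model.n_loci,
                    "af_recessive": float(exp.af_recessive_pool),
                    "af_dominant": float(exp.af_dominant_pool),
                    "afdd": float(exp.afdd),
                    "informative": exp.informative,
                }
            )
    return pd.DataFrame(rows)
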