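"""Seeded forward simulation of an outcrossing F1 pooled-sequencing experiment.

The generator emulates the statistical structure the AFDDD mapping method
assumes: a biparental cross between two parents heterozygous at a dominant
growth-habit locus (Co-like), one or two recessive suppressor loci whose joint
homozygosity suppresses the dominant phenotype with incomplete, age-dependent
penetrance, SNV markers of all twelve phase-resolved segregation-type
derivatives scattered along the genome, recombination under the Haldane (no
interference) model, phenotype-based pooling, and pooled short-read allele
counts (Poisson depth, binomial allele sampling with a symmetric substitution
error).

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children, so identical (config, seed) pairs give
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .segregation import ALL_DERIVATIVES

__all__ = [
    "GenomeSpec",
    "CrossConfig",
    "Population",
    "SimulationResult",
    "ConfigError",
    "PoolingError",
    "simulate_cross",
    "assign_phenotypes",
    "build_pools",
    "simulate_pool_reads",
    "simulate_experiment",
    "DEFAULT_MIXTURE",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


class PoolingError(RuntimeError):
    """Not enough individuals of a phenotype class to fill a pool."""


_DERIVATIVE_KEYS = tuple(seg.key() for seg in ALL_DERIVATIVES)
_NONSEG_KEY = "VVxVV"  # homozygous-variant in both parents: segregation <qq x qq>

#: default mixture: uniform over the 12 segregating derivatives plus a
#: non-segregating homozygous-variant class (reference-homozygous sites carry
#: no variant allele and are never emitted)
DEFAULT_MIXTURE: dict[str, float] = {_NONSEG_KEY: 0.10}
DEFAULT_MIXTURE.update({k: 0.075 for k in _DERIVATIVE_KEYS})

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class GenomeSpec:
    """Synthetic genome layout.

    ``snv_density`` is the expected number of segregating SNV sites per bp;
    ``seg_type_mixture`` gives the probability of each phase-resolved
    derivative (keys like ``"VRxVR"``) plus the non-segregating ``"VVxVV"``
    class, and must sum to one.
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000),
        ("chr2", 30_000_000),
        ("chr3", 30_000_000),
        ("chr4", 30_000_000),
        ("chr5", 30_000_000),
    )
    snv_density: float = 1.0e-4
    seg_type_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )

    def validate(self) -> None:
        if not self.chromosomes:
            raise ConfigError("genome.chromosomes: at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigError(f"genome.chromosomes: length of {name} must be > 0")
        if self.snv_density <= 0:
            raise ConfigError("genome.snv_density: must be > 0")
        allowed = set(_DERIVATIVE_KEYS) | {_NONSEG_KEY}
        bad = set(self.seg_type_mixture) - allowed
        if bad:
            raise ConfigError(f"genome.seg_type_mixture: unknown keys {sorted(bad)}")
        total = sum(self.seg_type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"genome.seg_type_mixture: weights sum to {total}, not 1")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated cross and sequencing experiment.

    Defaults mirror the mapping study's design: 275 F1 offspring from two
    parents heterozygous at the dominant locus, a recessive suppressor locus
    heterozygous in both parents plus a second, unlinked one homozygous
    recessive in the seed parent and heterozygous in the pollen parent,
    penetrance falling with age (0.867, 0.667, 0.448 per evaluation round),
    pools of 16 recessive-phenotype and 18 dominant-phenotype Co-carriers,
    and mean mapped depths of 22.5x / 34.6x.
    """

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    dominant_locus: tuple[str, int] = ("chr1", 28_000_000)
    #: haplotype phase of the dominant allele relative to suppressor locus 1:
    #: "coupling" puts it on the recessive-linked haplotype of that parent
    dominant_phase: tuple[str, str] = ("coupling", "repulsion")
    suppressor_loci: tuple[tuple[str, int], ...] = (
        ("chr1", 26_500_000),
        ("chr2", 14_500_000),
    )
    #: per-locus (seed, pollen) genotypes, "Rr" heterozygous / "rr" recessive-hom
    suppressor_genotypes: tuple[tuple[str, str], ...] = (("Rr", "Rr"), ("rr", "Rr"))
    n_offspring: int = 275
    recomb_rate: float = 5.0  # cM per Mb
    penetrance: tuple[float, ...] = (0.867, 0.667, 0.448)
    leak: float = 0.03  # per-round Std2 rate among non-qualifying Co-carriers
    standard_subscore_p: float = 0.5  # P(score 4 vs 3), and P(1 vs 2)
    pool_sizes: tuple[int, int] = (16, 18)  # (recessive pool, dominant pool)
    pool_round: int = 0
    depth_means: tuple[float, float] = (22.5, 34.6)  # (recessive, dominant)
    seq_error: float = 0.002

    def validate(self) -> None:
        self.genome.validate()
        lengths = self.genome.lengths
        for label, (chrom, pos) in [("dominant_locus", self.dominant_locus)] + [
            (f"suppressor_loci[{i}]", locus)
            for i, locus in enumerate(self.suppressor_loci)
        ]:
            if chrom not in lengths:
                raise ConfigError(f"{label}: unknown chromosome {chrom!r}")
            if not (1 <= pos <= lengths[chrom]):
                raise ConfigError(f"{label}: position {pos} outside {chrom}")
        if not 1 <= len(self.suppressor_loci) <= 2:
            raise ConfigError("suppressor_loci: one or two loci required")
        if len(self.suppressor_genotypes) != len(self.suppressor_loci):
            raise ConfigError("suppressor_genotypes: one (seed, pollen) pair per locus")
        for i, pair in enumerate(self.suppressor_genotypes):
            for g in pair:
                if g not in ("Rr", "rr", "RR"):
                    raise ConfigError(
                        f"suppressor_genotypes[{i}]: genotypes must be Rr, rr or RR"
                    )
        if self.suppressor_genotypes[0] != ("Rr", "Rr"):
            raise ConfigError(
                "suppressor_genotypes[0]: locus 1 must be heterozygous in both parents"
            )
        for p in self.dominant_phase:
            if p not in ("coupling", "repulsion"):
                raise ConfigError("dominant_phase: entries must be coupling/repulsion")
        if self.n_offspring <= 0:
            raise ConfigError("n_offspring: must be > 0")
        if self.recomb_rate < 0:
            raise ConfigError("recomb_rate: must be >= 0")
        if not self.penetrance:
            raise ConfigError("penetrance: at least one evaluation round required")
        for t, p in enumerate(self.penetrance):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"penetrance[{t}]: must be in [0, 1]")
        if not 0.0 <= self.leak <= 1.0:
            raise ConfigError("leak: must be in [0, 1]")
        if not 0.0 <= self.standard_subscore_p <= 1.0:
            raise ConfigError("standard_subscore_p: must be in [0, 1]")
        if any(s <= 0 for s in self.pool_sizes):
            raise ConfigError("pool_sizes: must be positive")
        if not 0 <= self.pool_round < len(self.penetrance):
            raise ConfigError("pool_round: outside the penetrance schedule")
        if any(d <= 0 for d in self.depth_means):
            raise ConfigError("depth_means: must be > 0")
        if not 0.0 <= self.seq_error < 1.0:
            raise ConfigError("seq_error: must be in [0, 1)")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genome": {
                "chromosomes": [list(c) for c in self.genome.chromosomes],
                "snv_density": self.genome.snv_density,
                "seg_type_mixture": dict(self.genome.seg_type_mixture),
            },
            "dominant_locus": list(self.dominant_locus),
            "dominant_phase": list(self.dominant_phase),
            "suppressor_loci": [list(l) for l in self.suppressor_loci],
            "suppressor_genotypes": [list(g) for g in self.suppressor_genotypes],
            "n_offspring": self.n_offspring,
            "recomb_rate": self.recomb_rate,
            "penetrance": list(self.penetrance),
            "leak": self.leak,
            "standard_subscore_p": self.standard_subscore_p,
            "pool_sizes": list(self.pool_sizes),
            "pool_round": self.pool_round,
            "depth_means": list(self.depth_means),
            "seq_error": self.seq_error,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CrossConfig":
        data = dict(data)
        kwargs = {}
        if "genome" in data:
            g = dict(data.pop("genome"))
            if "chromosomes" in g:
                g["chromosomes"] = tuple((str(n), int(l)) for n, l in g["chromosomes"])
            kwargs["genome"] = GenomeSpec(**g)
        for key in (
            "dominant_locus", "dominant_phase", "pool_sizes", "depth_means",
            "penetrance",
        ):
            if key in data:
                data[key] = tuple(data.pop(key))
        for key in ("suppressor_loci", "suppressor_genotypes"):
            if key in data:
                data[key] = tuple(tuple(x) for x in data.pop(key))
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        kwargs.update(data)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "CrossConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# genome construction


@dataclass
class _ChromData:
    positions: np.ndarray       # all loci (markers + trait loci), 1-based, sorted
    is_marker: np.ndarray       # bool mask
    ref: np.ndarray             # marker ref base ("" at trait loci)
    alt: np.ndarray
    derivative: np.ndarray      # mixture key per locus ("" at trait loci)
    seed_hap: np.ndarray        # (2, L) uint8 parental haplotype alleles
    pollen_hap: np.ndarray


@dataclass
class Population:
    """A simulated F1 population with full genotype and phenotype truth."""

    config: CrossConfig
    chrom_data: dict[str, _ChromData]
    alleles: dict[str, np.ndarray]  # chrom -> (n, 2, L) uint8; gamete 0 = seed
    origins: dict[str, np.ndarray]  # parental haplotype of origin, same shape
    individuals: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.individuals)

    def locus_index(self, chrom: str, pos: int) -> int:
        data = self.chrom_data[chrom]
        idx = int(np.searchsorted(data.positions, pos))
        if idx >= len(data.positions) or data.positions[idx] != pos:
            raise KeyError(f"no locus at {chrom}:{pos}")
        return idx

    def transmitted_alleles(self, chrom: str, pos: int) -> pd.DataFrame:
        """Per-offspring alleles received from each parent at one locus."""
        idx = self.locus_index(chrom, pos)
        arr = self.alleles[chrom]
        return pd.DataFrame(
            {
                "id": self.individuals["id"].to_numpy(),
                "seed_allele": arr[:, 0, idx],
                "pollen_allele": arr[:, 1, idx],
            }
        )


def _parent_pairs_for_derivative(key: str) -> tuple[np.ndarray, np.ndarray]:
    seed, pollen = key.split("x")
    to_int = lambda s: np.array([1 if a == "V" else 0 for a in s], dtype=np.uint8)
    return to_int(seed), to_int(pollen)


def _build_chromosomes(config: CrossConfig, rng: np.random.Generator):
    """Draw marker sites, assign derivatives, and lay out parental haplotypes."""
    mixture_keys = sorted(config.genome.seg_type_mixture)
    weights = np.array([config.genome.seg_type_mixture[k] for k in mixture_keys])
    weights = weights / weights.sum()

    trait_loci: dict[str, list[tuple[int, str, int]]] = {}
    # locus spec: (pos, kind, index); kind "dom" or "sup"
    dom_chrom, dom_pos = config.dominant_locus
    trait_loci.setdefault(dom_chrom, []).append((dom_pos, "dom", 0))
    for i, (chrom, pos) in enumerate(config.suppressor_loci):
        trait_loci.setdefault(chrom, []).append((pos, "sup", i))

    chrom_data: dict[str, _ChromData] = {}
    for chrom, length in config.genome.chromosomes:
        n_sites = rng.poisson(config.genome.snv_density * length)
        pos = np.unique(rng.integers(1, length + 1, size=n_sites))
        special = {p for p, _, _ in trait_loci.get(chrom, [])}
        pos = pos[~np.isin(pos, sorted(special))]
        n_sites = len(pos)

        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        derivative = rng.choice(mixture_keys, size=n_sites, p=weights)

        # merge trait loci into the locus sequence
        extra = sorted(trait_loci.get(chrom, []))
        all_pos = np.concatenate([pos, np.array([p for p, _, _ in extra], dtype=np.int64)])
        order = np.argsort(all_pos, kind="stable")
        L = len(all_pos)
        positions = all_pos[order].astype(np.int64)
        is_marker = np.concatenate(
            [np.ones(n_sites, bool), np.zeros(len(extra), bool)]
        )[order]
        ref = np.concatenate([_BASES[ref_idx], np.array([""] * len(extra))])[order]
        alt = np.concatenate([_BASES[alt_idx], np.array([""] * len(extra))])[order]
        deriv = np.concatenate([derivative, np.array([""] * len(extra))])[order]

        seed_hap = np.zeros((2, L), dtype=np.uint8)
        pollen_hap = np.zeros((2, L), dtype=np.uint8)
        marker_idx = np.flatnonzero(is_marker)
        for j, key in zip(marker_idx, deriv[marker_idx]):
            s, p = _parent_pairs_for_derivative(key)
            seed_hap[:, j] = s
            pollen_hap[:, j] = p
        for pos_t, kind, index in extra:
            j = int(np.searchsorted(positions, pos_t))
            if kind == "dom":
                for hap_arr, phase in (
                    (seed_hap, config.dominant_phase[0]),
                    (pollen_hap, config.dominant_phase[1]),
                ):
                    hap = 0 if phase == "coupling" else 1
                    hap_arr[hap, j] = 1
            else:
                for hap_arr, gt in (
                    (seed_hap, config.suppressor_genotypes[index][0]),
                    (pollen_hap, config.suppressor_genotypes[index][1]),
                ):
                    if gt == "rr":
                        hap_arr[:, j] = 1
                    elif gt == "Rr":
                        hap_arr[0, j] = 1  # recessive allele rides haplotype 0
        chrom_data[chrom] = _ChromData(
            positions, is_marker, ref, alt, deriv, seed_hap, pollen_hap
        )
    return chrom_data


def _gamete_origins(
    positions: np.ndarray, recomb_rate: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Haplotype-of-origin matrix (n, L) for n meioses along one chromosome.

    Crossovers follow the Haldane model: no interference, recombination
    fraction between adjacent loci ``(1 - exp(-2 d)) / 2`` for map distance
    ``d`` Morgans (``recomb_rate`` cM/Mb converts as ``d = rate * bp / 1e8``).
    """
    L = len(positions)
    starts = rng.integers(0, 2, size=n, dtype=np.uint8)
    if L <= 1:
        return starts[:, None].copy() if L else np.zeros((n, 0), dtype=np.uint8)
    d = np.diff(positions) * (recomb_rate / 1e8)
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    switches = rng.random((n, L - 1)) < r
    origins = np.empty((n, L), dtype=np.uint8)
    origins[:, 0] = starts
    origins[:, 1:] = (starts[:, None] + np.cumsum(switches, axis=1)) % 2
    return origins


_DOM_GT = {0: "coco", 1: "Coco", 2: "CoCo"}
_SUP_GT = {0: "RR", 1: "Rr", 2: "rr"}


def simulate_cross(config: CrossConfig, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> Population:
    """Simulate the F1 population: genomes, gametes and trait genotypes.

    Each offspring receives one recombinant gamete per parent.  Phenotypes are
    left unassigned; see :func:`assign_phenotypes`.
    """
    config.validate()
    if rng is None:
        ss = np.random.SeedSequence(seed, spawn_key=(0,))
        genome_rng, meiosis_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    else:
        genome_rng = meiosis_rng = rng
    chrom_data = _build_chromosomes(config, genome_rng)

    n = config.n_offspring
    alleles: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    for chrom, data in chrom_data.items():
        L = len(data.positions)
        out_a = np.empty((n, 2, L), dtype=np.uint8)
        out_o = np.empty((n, 2, L), dtype=np.uint8)
        for g, hap in ((0, data.seed_hap), (1, data.pollen_hap)):
            org = _gamete_origins(data.positions, config.recomb_rate, n, meiosis_rng)
            out_o[:, g, :] = org
            out_a[:, g, :] = hap[org, np.arange(L)]
        alleles[chrom] = out_a
        origins[chrom] = out_o

    individuals = pd.DataFrame({"id": [f"F1_{i:04d}" for i in range(n)]})
    dom_chrom, dom_pos = config.dominant_locus
    pop = Population(config, chrom_data, alleles, origins, individuals)
    j_dom = pop.locus_index(dom_chrom, dom_pos)
    dose = alleles[dom_chrom][:, :, j_dom].sum(axis=1)
    individuals["co_genotype"] = [_DOM_GT[d] for d in dose]
    qualifying = np.ones(n, dtype=bool)
    for i, (chrom, pos) in enumerate(config.suppressor_loci):
        j = pop.locus_index(chrom, pos)
        dose_i = alleles[chrom][:, :, j].sum(axis=1)
        individuals[f"locus{i + 1}_genotype"] = [_SUP_GT[d] for d in dose_i]
        individuals[f"seed_allele_locus{i + 1}"] = alleles[chrom][:, 0, j]
        individuals[f"pollen_allele_locus{i + 1}"] = alleles[chrom][:, 1, j]
        qualifying &= dose_i == 2
    individuals["qualifying"] = qualifying

    # recombinant between the dominant locus and suppressor locus 1 (same chrom)
    sup1_chrom, sup1_pos = config.suppressor_loci[0]
    if sup1_chrom == dom_chrom:
        j1 = pop.locus_index(sup1_chrom, sup1_pos)
        o = origins[dom_chrom]
        recomb = (o[:, 0, j_dom] != o[:, 0, j1]) | (o[:, 1, j_dom] != o[:, 1, j1])
    else:
        recomb = np.zeros(n, dtype=bool)
    individuals["dom_locus1_recombinant"] = recomb
    return pop


def assign_phenotypes(population: Population, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> Population:
    """Fill per-round phenotype scores (1 C, 2 CL, 3 SL, 4 S) in place.

    Offspring without the dominant allele are always standard (Std1).
    Dominant-allele carriers that are homozygous recessive at every suppressor
    locus express the suppressed standard phenotype (Std2) in round ``t`` with
    probability ``penetrance[t]``; other carriers with the small ``leak``
    probability.  A single latent uniform per individual makes expression
    persistent: with a non-increasing schedule, individuals revert from
    standard to the dominant phenotype as rounds progress, never the reverse.
    """
    config = population.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    ind = population.individuals
    n = len(ind)
    carrier = (ind["co_genotype"] != "coco").to_numpy()
    qualifying = ind["qualifying"].to_numpy()
    u = rng.random(n)
    for t, pen in enumerate(config.penetrance):
        threshold = np.where(qualifying, pen, config.leak)
        std2 = carrier & (u < threshold)
        standard = std2 | ~carrier
        sub = rng.random(n) < config.standard_subscore_p
        score = np.where(standard, np.where(sub, 4, 3), np.where(sub, 1, 2))
        ind[f"score_r{t}"] = score.astype(np.int64)
    return population


def build_pools(
    population: Population,
    round_index: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the (recessive-phenotype, dominant-phenotype) pools.

    Both pools contain only dominant-allele carriers: the recessive pool draws
    from Std2 individuals (standard score but Co-carrying), the dominant pool
    from columnar-scored carriers.  Sampling is uniform without replacement.

    Returns the two arrays of row indices into ``population.individuals``.
    """
    config = population.config
    if round_index is None:
        round_index = config.pool_round
    col = f"score_r{round_index}"
    if col not in population.individuals:
        raise ConfigError(f"pool_round: phenotypes for round {round_index} not assigned")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    ind = population.individuals
    carrier = (ind["co_genotype"] != "coco").to_numpy()
    standard = (ind[col] >= 3).to_numpy()
    std2 = np.flatnonzero(carrier & standard)
    columnar = np.flatnonzero(carrier & ~standard)
    n_rec, n_dom = config.pool_sizes
    if len(std2) < n_rec:
        raise PoolingError(
            f"recessive pool needs {n_rec} Std2 individuals but only "
            f"{len(std2)} are available in round {round_index}"
        )
    if len(columnar) < n_dom:
        raise PoolingError(
            f"dominant pool needs {n_dom} columnar individuals but only "
            f"{len(columnar)} are available in round {round_index}"
        )
    rec = np.sort(rng.choice(std2, size=n_rec, replace=False))
    dom = np.sort(rng.choice(columnar, size=n_dom, replace=False))
    return rec, dom


def simulate_pool_reads(
    population: Population,
    pool_indices: np.ndarray,
    depth_mean: float,
    seq_error: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pooled sequencing allele counts at every marker site.

    Per site the true pool variant frequency is ``f = variant alleles /
    (2 * pool size)``; read depth is Poisson with the given mean and the
    variant-read count binomial with success probability
    ``f (1 - e) + (1 - f) e / 3`` for substitution error rate ``e`` (an
    erroneous base turns into each of the three other bases equally often).
    """
    config = population.config
    if seq_error is None:
        seq_error = config.seq_error
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    pool_indices = np.asarray(pool_indices)
    n_pool = len(pool_indices)
    if n_pool == 0:
        raise ConfigError("pool_sizes: pool must be non-empty")
    frames = []
    for chrom, _length in config.genome.chromosomes:
        data = population.chrom_data[chrom]
        m = data.is_marker
        counts = population.alleles[chrom][pool_indices][:, :, m].sum(axis=(0, 1))
        f = counts / (2.0 * n_pool)
        depth = rng.poisson(depth_mean, size=len(f))
        p = f * (1.0 - seq_error) + (1.0 - f) * seq_error / 3.0
        alt = rng.binomial(depth, p)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(depth > 0, 100.0 * alt / np.maximum(depth, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": data.positions[m],
                    "ref": data.ref[m],
                    "alt": data.alt[m],
                    "depth": depth,
                    "alt_count": alt,
                    "af": af,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimulationResult:
    """Bundle of one full simulated pooled-sequencing experiment."""

    config: CrossConfig
    seed: int | None
    population: Population
    recessive_pool: np.ndarray
    dominant_pool: np.ndarray
    recessive_reads: pd.DataFrame
    dominant_reads: pd.DataFrame

    @property
    def truth_loci(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": self.config.dominant_locus[0],
                "pos": self.config.dominant_locus[1],
                "name": "dominant_locus",
            }
        ]
        for i, (chrom, pos) in enumerate(self.config.suppressor_loci):
            rows.append({"chrom": chrom, "pos": pos, "name": f"suppressor{i + 1}"})
        return pd.DataFrame(rows)


def simulate_experiment(config: CrossConfig | None = None,
                        seed: int | None = None) -> SimulationResult:
    """Run the full generator: cross, phenotypes, pools and pooled reads."""
    if config is None:
        config = CrossConfig()
    pop = simulate_cross(config, seed=seed)
    assign_phenotypes(pop, seed=seed)
    rec_idx, dom_idx = build_pools(pop, seed=seed)
    ss = np.random.SeedSequence(seed, spawn_key=(3,))
    rng_rec, rng_dom = (np.random.default_rng(c) for c in ss.spawn(2))
    rec_reads = simulate_pool_reads(
        pop, rec_idx, config.depth_means[0], rng=rng_rec
    )
    dom_reads = simulate_pool_reads(
        pop, dom_idx, config.depth_means[1], rng=rng_dom
    )
    return SimulationResult(config, seed, pop, rec_idx, dom_idx, rec_reads, dom_reads)
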