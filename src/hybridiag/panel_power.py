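"""Exact and Monte-Carlo classification probabilities for pedigree classes.

A panel of L fully diagnostic, unlinked nuclear loci misclassifies advanced
hybrids at a rate set by Mendelian segregation: a first backcross (BC1) is
heterozygous at each locus independently with probability 1/2, so it looks
like an F1 with probability (1/2)^L and like a pure parent with probability
(1/2)^L — at the three-locus design, 1/8 each.  This module computes those
category probabilities exactly from the per-locus genotype law of a pedigree,
and by Monte Carlo through the simulator, and tabulates how detection power
grows with panel size.

Genotypes are represented in species space (sorted pairs of species ids),
which is exact for fully diagnostic loci where allele codes and species are
in bijection at every locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .classifier import Category, ClassifierPolicy, DEFAULT_POLICY, classify_dataset
from .cross_simulator import CrossSpec, SimulationConfig, simulate_dataset
from .errors import SimulationError
from .panel_model import MarkerPanel

Genotype = tuple[str, str]  # sorted species pair


@dataclass(frozen=True)
class LocusGenotypeDistribution:
    """Exact per-locus genotype law of a pedigree, in species space."""

    probs: Mapping[Genotype, float]

    def __post_init__(self):
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-12 or any(p < 0 for p in self.probs.values()):
            raise SimulationError(f"genotype law does not sum to 1 (sum={total})")

    def __getitem__(self, genotype: Genotype) -> float:
        return self.probs.get(tuple(sorted(genotype)), 0.0)

    def heterozygous_mass(self) -> float:
        return sum(p for g, p in self.probs.items() if g[0] != g[1])


@dataclass(frozen=True)
class CategoryDistribution:
    """Probabilities that an individual of a pedigree class is called
    pure (per species), F1 or post-F1 by the classifier."""

    p_pure: Mapping[str, float]
    p_f1: float
    p_postf1: float

    def __post_init__(self):
        total = sum(self.p_pure.values()) + self.p_f1 + self.p_postf1
        entries = list(self.p_pure.values()) + [self.p_f1, self.p_postf1]
        if abs(total - 1.0) > 1e-12 or any(not 0 <= p <= 1 for p in entries):
            raise SimulationError(f"category masses invalid (sum={total})")

    @property
    def p_pure_total(self) -> float:
        return sum(self.p_pure.values())


@dataclass(frozen=True)
class MCCategoryDistribution(CategoryDistribution):
    """Monte-Carlo estimate with 95% Wilson score intervals per entry."""

    n_reps: int = 0
    ci_pure: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    ci_f1: tuple[float, float] = (0.0, 1.0)
    ci_postf1: tuple[float, float] = (0.0, 1.0)


def _allele_law(spec: CrossSpec) -> dict[str, float]:
    """Law of the single allele a random gamete of this pedigree carries."""
    law: dict[str, float] = {}
    for (a, b), p in locus_distribution_raw(spec).items():
        law[a] = law.get(a, 0.0) + p / 2
        law[b] = law.get(b, 0.0) + p / 2
    return law


def locus_distribution_raw(spec: CrossSpec) -> dict[Genotype, float]:
    if spec.is_leaf:
        return {(spec.species, spec.species): 1.0}  # type: ignore
    dam = _allele_law(spec.dam)  # type: ignore
    sire = _allele_law(spec.sire)  # type: ignore
    out: dict[Genotype, float] = {}
    for a, pa in dam.items():
        for b, pb in sire.items():
            g = tuple(sorted((a, b)))
            out[g] = out.get(g, 0.0) + pa * pb
    return out


def locus_distribution(spec: CrossSpec, panel: MarkerPanel) -> LocusGenotypeDistribution:
    """Exact genotype law at any (fully diagnostic) nuclear locus.

    Computed recursively: a leaf is homozygous with certainty; a cross pairs
    one allele from each parent's gamete law, where a parent passes each of
    its two alleles with probability 1/2.
    """
    spec.validate(panel)
    return LocusGenotypeDistribution(locus_distribution_raw(spec))


def category_distribution(spec: CrossSpec, panel: MarkerPanel,
                          policy: ClassifierPolicy = DEFAULT_POLICY,
                          n_loci: int | None = None) -> CategoryDistribution:
    """Exact classification probabilities for individuals of one pedigree.

    With per-locus law q over L exchangeable loci: an individual is called
    pure for species s iff homozygous (s,s) at every locus, q[(s,s)]^L; F1
    iff heterozygous for the same species pair everywhere, sum over pairs of
    q[pair]^L; all remaining mass (combined patterns, all-homozygous
    discordant, multi-pair heterozygous) is post-F1.  With no missing data
    the unresolved category has probability zero for any policy.
    """
    q = locus_distribution(spec, panel)
    L = len(panel.nuclear_loci) if n_loci is None else int(n_loci)
    if L < 1:
        raise SimulationError("panel must have at least one nuclear locus")
    p_pure = {}
    for sp in panel.species_ids:
        p = q[(sp, sp)] ** L
        if p > 0:
            p_pure[sp] = p
    p_f1 = sum(q.probs[g] ** L for g in q.probs if g[0] != g[1])
    p_postf1 = 1.0 - sum(p_pure.values()) - p_f1
    return CategoryDistribution(p_pure=p_pure, p_f1=p_f1,
                                p_postf1=max(p_postf1, 0.0))


def mc_category_distribution(spec: CrossSpec, panel: MarkerPanel,
                             policy: ClassifierPolicy = DEFAULT_POLICY,
                             n_reps: int = 10_000,
                             seed: int = 0) -> MCCategoryDistribution:
    """Monte-Carlo classification frequencies with 95% Wilson intervals.

    Simulates ``n_reps`` independent individuals of the pedigree through the
    cross simulator (no genotyping error or missingness), classifies them,
    and tabulates category frequencies.  Deterministic given ``seed``.
    """
    from statsmodels.stats.proportion import proportion_confint

    if n_reps < 1:
        raise SimulationError("n_reps must be >= 1")
    ds = simulate_dataset(SimulationConfig(
        panel=panel, composition=[(spec, n_reps)], seed=seed))
    counts = {"f1": 0, "postf1": 0}
    pure_counts: dict[str, int] = {}
    for _, cls in classify_dataset(ds, policy):
        if cls.category is Category.PURE:
            pure_counts[cls.genetic_species] = \
                pure_counts.get(cls.genetic_species, 0) + 1
        elif cls.category is Category.F1_HYBRID:
            counts["f1"] += 1
        elif cls.category is Category.POST_F1_HYBRID:
            counts["postf1"] += 1

    def wilson(k: int) -> tuple[float, float]:
        lo, hi = proportion_confint(k, n_reps, alpha=0.05, method="wilson")
        return float(lo), float(hi)

    return MCCategoryDistribution(
        p_pure={sp: k / n_reps for sp, k in pure_counts.items()},
        p_f1=counts["f1"] / n_reps,
        p_postf1=counts["postf1"] / n_reps,
        n_reps=n_reps,
        ci_pure={sp: wilson(k) for sp, k in pure_counts.items()},
        ci_f1=wilson(counts["f1"]),
        ci_postf1=wilson(counts["postf1"]),
    )


def detection_curve(spec: CrossSpec, panel: MarkerPanel,
                    policy: ClassifierPolicy = DEFAULT_POLICY,
                    L_values: Sequence[int] = tuple(range(1, 11))) -> pd.DataFrame:
    """Post-F1 detection probability as a function of panel size L.

    Evaluates the exact category distribution on panels of L exchangeable
    diagnostic loci.  A single locus can never show the combined
    homozygous+heterozygous pattern, so detection power is 0 at L=1 and is
    nondecreasing in L for segregating pedigrees such as BC1 and F2.
    """
    rows = []
    for L in L_values:
        if L < 1:
            raise SimulationError("L values must be positive integers")
        dist = category_distribution(spec, panel, policy, n_loci=L)
        row: dict[str, float] = {"L": L}
        for sp in panel.species_ids:
            row[f"p_pure_{sp}"] = dist.p_pure.get(sp, 0.0)
        row["p_f1"] = dist.p_f1
        row["p_postf1"] = dist.p_postf1
        rows.append(row)
    return pd.DataFrame(rows)
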