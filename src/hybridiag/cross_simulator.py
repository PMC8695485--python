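"""Mendelian cross simulator over species-diagnostic marker panels.

Pedigrees are described by :class:`CrossSpec`, a recursive structure whose
leaves are pure species and whose internal nodes are dam x sire crosses
(dam first).  Simulation follows Mendelian transmission at unlinked,
mutation-free nuclear loci — at each locus a parent passes one of its two
alleles with probability 1/2, independently across loci — and strict
maternal transmission of the mitochondrial allele.  Each cross node draws
fresh, independent parent individuals for every offspring (no shared
broodstock).

An optional genotyping-error model replaces a locus call, with a given
probability, by a uniformly random valid genotype at that locus (a whole-lane
miscall, the simplest one-parameter corruption for multiplex band readouts);
missingness is applied independently per locus afterwards.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np

from .errors import SimulationError
from .genotype_io import Dataset, GenotypeCall, SampleRecord
from .panel_model import MITOCHONDRIAL, MarkerPanel, default_catfish_panel


@dataclass(frozen=True)
class CrossSpec:
    """A pedigree: either a pure-species leaf or a dam x sire cross."""

    species: str | None = None
    dam: "CrossSpec | None" = None
    sire: "CrossSpec | None" = None
    label: str = ""

    def __post_init__(self):
        is_leaf = self.species is not None
        is_cross = self.dam is not None and self.sire is not None
        if is_leaf == is_cross:
            raise SimulationError(
                "CrossSpec must be either a species leaf or a dam x sire cross")

    @staticmethod
    def leaf(species: str, label: str = "") -> "CrossSpec":
        return CrossSpec(species=species, label=label or species)

    @staticmethod
    def cross(dam: "CrossSpec", sire: "CrossSpec", label: str = "") -> "CrossSpec":
        return CrossSpec(dam=dam, sire=sire,
                         label=label or f"({dam.label} x {sire.label})")

    @property
    def is_leaf(self) -> bool:
        return self.species is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.species]  # type: ignore
        return self.dam.leaves() + self.sire.leaves()  # type: ignore

    def maternal_leaf(self) -> str:
        """Species of the strictly-maternal (dam-of-dam-of-...) lineage."""
        node = self
        while not node.is_leaf:
            node = node.dam  # type: ignore
        return node.species  # type: ignore

    def notation(self) -> str:
        if self.is_leaf:
            return self.species  # type: ignore
        d = self.dam.notation()  # type: ignore
        s = self.sire.notation()  # type: ignore
        d = f"({d})" if not self.dam.is_leaf else d  # type: ignore
        s = f"({s})" if not self.sire.is_leaf else s  # type: ignore
        return f"{d} x {s}"

    def validate(self, panel: MarkerPanel) -> None:
        bad = [sp for sp in self.leaves() if sp not in panel.species_ids]
        if bad:
            raise SimulationError(f"cross leaves {bad!r} not in panel species")


_TOKEN = re.compile(r"\s*(\(|\)|x\b|[^\s()]+)")


def parse_cross(text: str) -> CrossSpec:
    """Parse the small recursive cross notation, dam listed first.

    Examples: ``Pret``, ``Pret x Pcor``, ``(Pret x Pcor) x Pret``.
    """
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_expr() -> CrossSpec:
        nonlocal pos
        left = parse_atom()
        if peek() == "x":
            pos += 1
            right = parse_expr()
            return CrossSpec.cross(left, right)
        return left

    def parse_atom() -> CrossSpec:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise SimulationError(f"unexpected end of cross notation in {text!r}")
        if tok == "(":
            pos += 1
            inner = parse_expr()
            if peek() != ")":
                raise SimulationError(f"unbalanced parentheses in {text!r}")
            pos += 1
            return inner
        if tok in (")", "x"):
            raise SimulationError(f"unexpected {tok!r} in cross notation {text!r}")
        pos += 1
        return CrossSpec.leaf(tok)

    spec = parse_expr()
    if pos != len(tokens):
        raise SimulationError(f"trailing tokens in cross notation {text!r}")
    return spec


@dataclass(frozen=True)
class SimulationConfig:
    """Composition and noise model for one simulated dataset.

    ``composition`` pairs each cross with the number of individuals to draw;
    ``seed`` is mandatory (one RNG stream per dataset).  Error and missing
    rates are per-locus probabilities in [0, 1].  ``morph_label_policy``
    maps a cross label to the species id stamped as the morphological label
    (unlabelled crosses get an unknown morphological species).
    """

    panel: MarkerPanel
    composition: Sequence[tuple[CrossSpec, int]]
    seed: int
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    morph_label_policy: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for rate, name in ((self.genotyping_error_rate, "genotyping_error_rate"),
                           (self.missing_rate, "missing_rate")):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {rate}")
        if not self.composition:
            raise SimulationError("composition must be non-empty")
        for spec, count in self.composition:
            if count < 0:
                raise SimulationError(f"negative count for cross {spec.label!r}")
            spec.validate(self.panel)


def simulate_gamete(parent_genotype: Mapping[str, GenotypeCall],
                    panel: MarkerPanel,
                    rng: np.random.Generator) -> dict[str, str]:
    """Draw one haploid gamete: one allele per nuclear locus, chosen 1/2:1/2.

    Loci assort independently (unlinked markers).  Requires a complete
    parental genotype at every nuclear locus.
    """
    gamete: dict[str, str] = {}
    for locus in panel.nuclear_loci:
        call = parent_genotype.get(locus.name)
        if call is None or call.missing:
            raise SimulationError(
                f"parent genotype missing at nuclear locus {locus.name!r}")
        gamete[locus.name] = call.alleles[int(rng.integers(2))]
    return gamete


def _simulate_calls(spec: CrossSpec, panel: MarkerPanel,
                    rng: np.random.Generator) -> dict[str, GenotypeCall]:
    mito = panel.mitochondrial_locus
    if spec.is_leaf:
        sp = spec.species
        calls = {}
        for locus in panel.nuclear_loci:
            a = locus.diagnostic_allele[sp]
            calls[locus.name] = GenotypeCall.nuclear(locus.name, a, a)
        if mito is not None:
            calls[mito.name] = GenotypeCall.mito(mito.name,
                                                 mito.diagnostic_allele[sp])
        return calls
    dam_calls = _simulate_calls(spec.dam, panel, rng)  # type: ignore
    sire_calls = _simulate_calls(spec.sire, panel, rng)  # type: ignore
    egg = simulate_gamete(dam_calls, panel, rng)
    sperm = simulate_gamete(sire_calls, panel, rng)
    calls = {name: GenotypeCall.nuclear(name, egg[name], sperm[name])
             for name in egg}
    if mito is not None:
        calls[mito.name] = dam_calls[mito.name]  # strict maternal transmission
    return calls


def simulate_individual(spec: CrossSpec, panel: MarkerPanel,
                        rng: np.random.Generator,
                        sample_id: str = "sim_0001", source: str = "sim",
                        morph_species: str | None = None) -> SampleRecord:
    """Simulate one individual from a pedigree, drawing fresh parents."""
    spec.validate(panel)
    return SampleRecord(sample_id=sample_id, source=source,
                        morph_species=morph_species,
                        calls=_simulate_calls(spec, panel, rng))


def _random_genotype(locus, rng: np.random.Generator) -> GenotypeCall:
    codes = sorted(locus.allele_codes)
    if locus.kind == MITOCHONDRIAL:
        return GenotypeCall.mito(locus.name, codes[int(rng.integers(len(codes)))])
    pairs = list(combinations_with_replacement(codes, 2))
    a1, a2 = pairs[int(rng.integers(len(pairs)))]
    return GenotypeCall.nuclear(locus.name, a1, a2)


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Simulate a full dataset: composition, then error, then missingness.

    Deterministic given the seed; sample ids are ``<label>_<i>`` counters.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    samples: list[SampleRecord] = []
    for spec, count in config.composition:
        label = spec.label or spec.notation()
        morph = config.morph_label_policy.get(label)
        for i in range(count):
            calls = _simulate_calls(spec, panel, rng)
            for locus in panel.loci:
                if config.genotyping_error_rate > 0 and \
                        rng.random() < config.genotyping_error_rate:
                    calls[locus.name] = _random_genotype(locus, rng)
                if config.missing_rate > 0 and rng.random() < config.missing_rate:
                    calls[locus.name] = GenotypeCall.make_missing(locus.name)
            samples.append(SampleRecord(
                sample_id=f"{label}_{i + 1:04d}", source=label,
                morph_species=morph, calls=calls))
    return Dataset(panel, samples)


# ---------------------------------------------------------------------------
# Deterministic 84-sample reference fixture

def _pure_calls(panel: MarkerPanel, sp: str) -> dict[str, GenotypeCall]:
    calls = {}
    for locus in panel.nuclear_loci:
        a = locus.diagnostic_allele[sp]
        calls[locus.name] = GenotypeCall.nuclear(locus.name, a, a)
    mito = panel.mitochondrial_locus
    calls[mito.name] = GenotypeCall.mito(mito.name, mito.diagnostic_allele[sp])
    return calls


def _f1_calls(panel: MarkerPanel, dam: str, sire: str) -> dict[str, GenotypeCall]:
    calls = {}
    for locus in panel.nuclear_loci:
        calls[locus.name] = GenotypeCall.nuclear(
            locus.name, locus.diagnostic_allele[dam], locus.diagnostic_allele[sire])
    mito = panel.mitochondrial_locus
    calls[mito.name] = GenotypeCall.mito(mito.name, mito.diagnostic_allele[dam])
    return calls


def _postf1_calls(panel: MarkerPanel, hom_sp: str,
                  other_sp: str) -> dict[str, GenotypeCall]:
    # canonical post-F1 vector: homozygous at the first nuclear locus,
    # heterozygous at the rest (which advanced cross produced a real post-F1
    # sample is unknowable from these markers; this choice is arbitrary)
    calls = {}
    for j, locus in enumerate(panel.nuclear_loci):
        if j == 0:
            a = locus.diagnostic_allele[hom_sp]
            calls[locus.name] = GenotypeCall.nuclear(locus.name, a, a)
        else:
            calls[locus.name] = GenotypeCall.nuclear(
                locus.name, locus.diagnostic_allele[hom_sp],
                locus.diagnostic_allele[other_sp])
    mito = panel.mitochondrial_locus
    calls[mito.name] = GenotypeCall.mito(mito.name, mito.diagnostic_allele[hom_sp])
    return calls


def make_table2_fixture(panel: MarkerPanel | None = None) -> Dataset:
    """Deterministic 84-sample dataset matching the published survey.

    Five research institutions (A-E) supplied catfish lots morphologically
    labelled as pure species; genetic diagnosis found per-institution
    category counts pure/F1/post-F1 of A: 49/0/0 (*P. reticulatum*),
    B: 3/1/1 (*P. reticulatum*), C: 0/0/6 (*P. corruscans*), D: 1/1/13
    (*P. corruscans*), E: 9/0/0 (*L. marmoratus*).  Genotype vectors are
    canonical per category; the raw per-sample genotypes were not published.
    """
    if panel is None:
        panel = default_catfish_panel()
    for sp in ("Pcor", "Pret", "Lmar"):
        if sp not in panel.species_ids:
            raise SimulationError(
                f"the reference fixture needs species {sp!r} in the panel")
    if len(panel.nuclear_loci) < 2 or panel.mitochondrial_locus is None:
        raise SimulationError(
            "the reference fixture needs >=2 nuclear loci and a mitochondrial locus")

    groups = [  # (institution, morph label, n_pure, n_f1, n_postf1, other parent)
        ("A", "Pret", 49, 0, 0, "Pcor"),
        ("B", "Pret", 3, 1, 1, "Pcor"),
        ("C", "Pcor", 0, 0, 6, "Pret"),
        ("D", "Pcor", 1, 1, 13, "Pret"),
        ("E", "Lmar", 9, 0, 0, "Pcor"),
    ]
    samples: list[SampleRecord] = []
    for inst, morph, n_pure, n_f1, n_post, other in groups:
        k = 0
        for _ in range(n_pure):
            k += 1
            samples.append(SampleRecord(f"{inst}_{k:03d}", inst, morph,
                                        _pure_calls(panel, morph)))
        for _ in range(n_f1):
            k += 1
            samples.append(SampleRecord(f"{inst}_{k:03d}", inst, morph,
                                        _f1_calls(panel, morph, other)))
        for _ in range(n_post):
            k += 1
            samples.append(SampleRecord(f"{inst}_{k:03d}", inst, morph,
                                        _postf1_calls(panel, morph, other)))
    return Dataset(panel, samples)
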