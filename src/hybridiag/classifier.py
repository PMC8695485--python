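"""Genotype-pattern classification of individuals into pure / F1 / post-F1.

The rule, applied to the typed (non-missing) nuclear loci of a fully
diagnostic panel:

* **pure species** — every locus homozygous, all for the same species;
* **F1 hybrid** — every locus heterozygous for the same species pair
  (a first-generation cross is heterozygous everywhere with certainty);
* **post-F1 hybrid** — a combination of homozygous and heterozygous loci
  (F2, backcross or later generation).

Patterns outside the three clauses are resolved deterministically:
all-homozygous but for different species across loci is post-F1 with flag
``all_hom_discordant`` (under diagnostic unlinked loci it cannot arise
without hybrid ancestry); all-heterozygous spanning different species pairs
is post-F1 with flag ``multispecies_ancestry`` (impossible for an F1 of two
species).  Purity is defined genetically: an individual homozygous for a
species other than its morphological label is PURE for the genetic species
with ``label_concordant = "no"``.

The mitochondrial locus identifies the maternal species only; it never
influences the category.  A conflict between a pure/F1 nuclear profile and
the maternal species is recorded as flag ``cytonuclear_discordance``.
Classification is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import GenotypeTableError
from .genotype_io import Dataset, GenotypeCall, SampleRecord
from .panel_model import MarkerPanel

FLAG_ALL_HOM_DISCORDANT = "all_hom_discordant"
FLAG_MULTISPECIES = "multispecies_ancestry"
FLAG_CYTONUCLEAR = "cytonuclear_discordance"


class Category(str, Enum):
    PURE = "PURE"
    F1_HYBRID = "F1_HYBRID"
    POST_F1_HYBRID = "POST_F1_HYBRID"
    UNRESOLVED = "UNRESOLVED"

    @property
    def is_hybrid(self) -> bool:
        return self in (Category.F1_HYBRID, Category.POST_F1_HYBRID)


@dataclass(frozen=True)
class ClassifierPolicy:
    """Tunable evidence threshold for the classifier.

    ``min_typed_nuclear_loci``: minimum number of non-missing nuclear loci
    required to classify; below it the sample is UNRESOLVED.  Loci with
    missing calls are simply dropped before applying the rule.
    """

    min_typed_nuclear_loci: int = 1

    def __post_init__(self):
        if self.min_typed_nuclear_loci < 1:
            raise ValueError("min_typed_nuclear_loci must be >= 1")


DEFAULT_POLICY = ClassifierPolicy()


@dataclass(frozen=True)
class Classification:
    """Outcome of classifying one individual.

    ``genetic_species`` is set iff category is PURE; ``species_pair`` is the
    unordered pair of parental species for hybrid categories when it is
    unambiguous (exactly two species observed across loci).
    ``label_concordant`` is "yes"/"no" only for PURE samples with a known
    morphological label, otherwise "unknown".
    """

    category: Category
    genetic_species: str | None = None
    species_pair: tuple[str, str] | None = None
    maternal_species: str | None = None
    label_concordant: str = "unknown"
    flags: tuple[str, ...] = ()


def assign_maternal_lineage(sample: SampleRecord, panel: MarkerPanel) -> str | None:
    """Species whose diagnostic mitochondrial allele the sample carries.

    Returns None when the mitochondrial call is missing (or the panel has no
    mitochondrial locus); raises if the call's allele code is not diagnostic
    for any panel species.
    """
    mito = panel.mitochondrial_locus
    if mito is None:
        return None
    call = sample.call(mito.name)
    if call.missing:
        return None
    code = call.alleles[0]
    sp = mito.species_of_allele(code)
    if sp is None:
        raise GenotypeTableError(
            f"sample {sample.sample_id!r}: mitochondrial allele code {code!r} "
            f"is not diagnostic for any panel species")
    return sp


def _locus_state(call: GenotypeCall, locus) -> tuple[str, frozenset[str]]:
    """("hom"|"het", species set) for a typed nuclear call."""
    species = []
    for code in call.alleles:
        sp = locus.species_of_allele(code)
        if sp is None:
            raise GenotypeTableError(
                f"allele code {code!r} at locus {locus.name!r} is not diagnostic "
                f"for any panel species")
        species.append(sp)
    kind = "hom" if call.is_homozygous else "het"
    return kind, frozenset(species)


def classify_individual(sample: SampleRecord, panel: MarkerPanel,
                        policy: ClassifierPolicy = DEFAULT_POLICY) -> Classification:
    """Apply the genotype-pattern rule to one individual."""
    maternal = assign_maternal_lineage(sample, panel)

    typed = []
    for locus in panel.nuclear_loci:
        call = sample.call(locus.name)
        if not call.missing:
            typed.append(_locus_state(call, locus))

    if len(typed) < policy.min_typed_nuclear_loci:
        return Classification(Category.UNRESOLVED, maternal_species=maternal)

    kinds = [k for k, _ in typed]
    all_species = frozenset().union(*(s for _, s in typed))
    flags: list[str] = []
    pair: tuple[str, str] | None = (tuple(sorted(all_species))  # type: ignore
                                    if len(all_species) == 2 else None)

    if all(k == "hom" for k in kinds):
        if len(all_species) == 1:
            sp = next(iter(all_species))
            if maternal is not None and maternal != sp:
                flags.append(FLAG_CYTONUCLEAR)
            if sample.morph_species is None:
                concordant = "unknown"
            else:
                concordant = "yes" if sample.morph_species == sp else "no"
            return Classification(Category.PURE, genetic_species=sp,
                                  maternal_species=maternal,
                                  label_concordant=concordant,
                                  flags=tuple(flags))
        # all homozygous, discordant across loci: only possible with hybrid
        # ancestry under fully diagnostic unlinked markers
        flags.append(FLAG_ALL_HOM_DISCORDANT)
        if len(all_species) > 2:
            flags.append(FLAG_MULTISPECIES)
        return Classification(Category.POST_F1_HYBRID, species_pair=pair,
                              maternal_species=maternal, flags=tuple(flags))

    if all(k == "het" for k in kinds):
        pairs = {s for _, s in typed}
        if len(pairs) == 1:
            p = tuple(sorted(next(iter(pairs))))
            if maternal is not None and maternal not in p:
                flags.append(FLAG_CYTONUCLEAR)
            return Classification(Category.F1_HYBRID, species_pair=p,  # type: ignore
                                  maternal_species=maternal, flags=tuple(flags))
        flags.append(FLAG_MULTISPECIES)
        return Classification(Category.POST_F1_HYBRID, species_pair=None,
                              maternal_species=maternal, flags=tuple(flags))

    # combined homozygous and heterozygous loci
    if len(all_species) > 2:
        flags.append(FLAG_MULTISPECIES)
    return Classification(Category.POST_F1_HYBRID, species_pair=pair,
                          maternal_species=maternal, flags=tuple(flags))


def classify_dataset(dataset: Dataset,
                     policy: ClassifierPolicy = DEFAULT_POLICY
                     ) -> list[tuple[SampleRecord, Classification]]:
    """Classify every sample, preserving dataset order."""
    return [(rec, classify_individual(rec, dataset.panel, policy))
            for rec in dataset.samples]


# ---------------------------------------------------------------------------
# Classification table I/O (the `classify` CLI output; `report` input)

CLASSIFICATION_COLUMNS = ["sample_id", "source", "morph_species", "category",
                          "genetic_species", "species_pair", "maternal_species",
                          "label_concordant", "flags"]


def classification_row(rec: SampleRecord, cls: Classification) -> list[str]:
    return [
        rec.sample_id,
        rec.source,
        rec.morph_species if rec.morph_species is not None else "?",
        cls.category.value,
        cls.genetic_species or "",
        "/".join(cls.species_pair) if cls.species_pair else "",
        cls.maternal_species or "",
        cls.label_concordant,
        ";".join(cls.flags),
    ]


def write_classification_table(classified, path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CLASSIFICATION_COLUMNS)
        for rec, cls in classified:
            writer.writerow(classification_row(rec, cls))
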