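"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (literal
application of the three category clauses; exhaustive enumeration of
genotype spaces) and never call the package's classifier or exact-power
code paths they are checking.
"""

from __future__ import annotations

from itertools import product
from math import prod

from hybridiag.genotype_io import GenotypeCall, SampleRecord

# One locus state is ("hom"|"het", frozenset of species carried).
State = tuple[str, frozenset]


def literal_classify(states: list[State]) -> tuple[str, str | None]:
    """The three diagnosis clauses applied literally to typed nuclear loci.

    Fixed edge policies: all-homozygous for different species -> post-F1;
    all-heterozygous spanning different species pairs -> post-F1.  Returns
    (category name, pure species or None).
    """
    if not states:
        return "UNRESOLVED", None
    kinds = {k for k, _ in states}
    if kinds == {"hom"}:
        species = set().union(*(s for _, s in states))
        if len(species) == 1:
            return "PURE", next(iter(species))
        return "POST_F1_HYBRID", None
    if kinds == {"het"}:
        pairs = {s for _, s in states}
        if len(pairs) == 1:
            return "F1_HYBRID", None
        return "POST_F1_HYBRID", None
    return "POST_F1_HYBRID", None


def all_nuclear_genotypes(species_ids) -> list[tuple[str, str]]:
    """Every unordered genotype over the species' diagnostic alleles."""
    out = []
    for i, a in enumerate(species_ids):
        for b in species_ids[i:]:
            out.append((a, b))
    return out


def genotype_state(genotype: tuple[str, str]) -> State:
    a, b = genotype
    return ("hom" if a == b else "het", frozenset({a, b}))


def record_from_vector(panel, vector, sample_id="v", source="enum",
                       morph=None, mito=None) -> SampleRecord:
    """Build a SampleRecord carrying one genotype per nuclear locus.

    ``vector`` pairs with panel.nuclear_loci positionally; species ids are
    translated to each locus's allele codes.
    """
    calls = {}
    for locus, (a, b) in zip(panel.nuclear_loci, vector):
        calls[locus.name] = GenotypeCall.nuclear(
            locus.name, locus.diagnostic_allele[a], locus.diagnostic_allele[b])
    ml = panel.mitochondrial_locus
    if ml is not None and mito is not None:
        calls[ml.name] = GenotypeCall.mito(ml.name, ml.diagnostic_allele[mito])
    return SampleRecord(sample_id, source, morph, calls)


def enumerate_category_distribution(locus_law: dict, L: int) -> dict:
    """Exact category probabilities by full enumeration of the L-locus space.

    ``locus_law`` maps sorted species-pair genotypes to probabilities (the
    same per-locus law at every locus).  Enumerates all |law|^L weighted
    genotype vectors and classifies each with the literal rule.
    """
    out = {"p_pure": {}, "p_f1": 0.0, "p_postf1": 0.0}
    for combo in product(locus_law.items(), repeat=L):
        weight = prod(p for _, p in combo)
        states = [genotype_state(g) for g, _ in combo]
        category, sp = literal_classify(states)
        if category == "PURE":
            out["p_pure"][sp] = out["p_pure"].get(sp, 0.0) + weight
        elif category == "F1_HYBRID":
            out["p_f1"] += weight
        else:
            out["p_postf1"] += weight
    return out
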