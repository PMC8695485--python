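import numpy as np
import pytest
from scipy import stats

from hybridiag.classifier import Category, classify_dataset, classify_individual
from hybridiag.cross_simulator import (CrossSpec, SimulationConfig,
                                       make_table2_fixture, parse_cross,
                                       simulate_dataset, simulate_gamete,
                                       simulate_individual)
from hybridiag.errors import SimulationError
from hybridiag.genotype_io import GenotypeCall, write_genotype_table

BC1 = CrossSpec.cross(CrossSpec.cross(CrossSpec.leaf("Pret"),
                                      CrossSpec.leaf("Pcor")),
                      CrossSpec.leaf("Pret"), label="BC1_Pret")


def test_leaf_individual_is_homozygous_everywhere(panel):
    rng = np.random.default_rng(0)
    rec = simulate_individual(CrossSpec.leaf("Pret"), panel, rng)
    for locus in panel.nuclear_loci:
        assert rec.calls[locus.name] == GenotypeCall.nuclear(locus.name,
                                                             "Pret", "Pret")
    assert rec.calls["16S"] == GenotypeCall.mito("16S", "Pret")


def test_f1_is_heterozygous_everywhere_with_dam_mitochondria(panel):
    rng = np.random.default_rng(1)
    f1 = CrossSpec.cross(CrossSpec.leaf("Pret"), CrossSpec.leaf("Pcor"))
    for _ in range(20):
        rec = simulate_individual(f1, panel, rng)
        for locus in panel.nuclear_loci:
            assert rec.calls[locus.name].is_heterozygous
        assert rec.calls["16S"].alleles == ("Pret",)  # dam side, always


def test_gamete_from_homozygote_is_forced(panel):
    rng = np.random.default_rng(2)
    parent = {l.name: GenotypeCall.nuclear(l.name, "Pret", "Pret")
              for l in panel.nuclear_loci}
    for _ in range(10):
        assert set(simulate_gamete(parent, panel, rng).values()) == {"Pret"}


def test_gamete_missing_parent_call_raises(panel):
    rng = np.random.default_rng(2)
    parent = {l.name: GenotypeCall.make_missing(l.name)
              for l in panel.nuclear_loci}
    with pytest.raises(SimulationError, match="missing"):
        simulate_gamete(parent, panel, rng)


def test_gamete_segregation_is_binomial_half(panel):
    """A heterozygote passes each allele ~1/2; 10,000 draws, 3 SE band."""
    rng = np.random.default_rng(42)
    parent = {l.name: GenotypeCall.nuclear(l.name, "Pcor", "Pret")
              for l in panel.nuclear_loci}
    n = 10_000
    k = sum(simulate_gamete(parent, panel, rng)["RAG2"] == "Pcor"
            for _ in range(n))
    se = (0.25 / n) ** 0.5
    assert abs(k / n - 0.5) < 3 * se


def test_two_locus_gametes_assort_independently(panel):
    """Joint law over two heterozygous loci is uniform on 4 combinations."""
    rng = np.random.default_rng(7)
    parent = {l.name: GenotypeCall.nuclear(l.name, "Pcor", "Pret")
              for l in panel.nuclear_loci}
    counts = {}
    n = 8000
    for _ in range(n):
        g = simulate_gamete(parent, panel, rng)
        key = (g["RAG2"], g["EF1a"])
        counts[key] = counts.get(key, 0) + 1
    assert len(counts) == 4
    chi2 = stats.chisquare(list(counts.values()))
    assert chi2.pvalue > 1e-3


@pytest.mark.parametrize("notation,maternal", [
    ("Pret", "Pret"),
    ("Pret x Pcor", "Pret"),
    ("(Pret x Pcor) x Pret", "Pret"),
    ("Pcor x (Pret x Pcor)", "Pcor"),
    ("((Pret x Pcor) x Pret) x Lmar", "Pret"),
])
def test_strict_maternal_mitochondrial_transmission(panel, notation, maternal):
    spec = parse_cross(notation)
    assert spec.maternal_leaf() == maternal
    rng = np.random.default_rng(11)
    for _ in range(10):
        rec = simulate_individual(spec, panel, rng)
        assert rec.calls["16S"].alleles == (maternal,)


def test_parse_cross_structure_and_notation_round_trip():
    spec = parse_cross("(Pret x Pcor) x Pret")
    assert not spec.is_leaf
    assert spec.dam.dam.species == "Pret"
    assert spec.dam.sire.species == "Pcor"
    assert spec.sire.species == "Pret"
    assert parse_cross(spec.notation()) == spec


@pytest.mark.parametrize("bad", ["", "x Pret", "(Pret x", "Pret Pcor"])
def test_parse_cross_rejects_malformed(bad):
    with pytest.raises(SimulationError):
        parse_cross(bad)


def test_unknown_leaf_species_rejected(panel):
    with pytest.raises(SimulationError, match="Xenops"):
        simulate_individual(CrossSpec.leaf("Xenops"), panel,
                            np.random.default_rng(0))


def test_pure_composition_classifies_all_pure(panel):
    config = SimulationConfig(panel=panel,
                              composition=[(CrossSpec.leaf("Pret"), 49)],
                              seed=5)
    ds = simulate_dataset(config)
    assert len(ds) == 49
    assert all(cls.category is Category.PURE and cls.genetic_species == "Pret"
               for _, cls in classify_dataset(ds))


def test_same_seed_gives_byte_identical_datasets(tmp_path, panel):
    config = SimulationConfig(
        panel=panel, composition=[(BC1, 30), (CrossSpec.leaf("Lmar"), 5)],
        seed=123, genotyping_error_rate=0.1, missing_rate=0.05)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_genotype_table(simulate_dataset(config), p1)
    write_genotype_table(simulate_dataset(config), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_all_missing_rate_yields_unresolved(panel):
    config = SimulationConfig(panel=panel,
                              composition=[(BC1, 10)], seed=9, missing_rate=1.0)
    ds = simulate_dataset(config)
    assert all(cls.category is Category.UNRESOLVED
               for _, cls in classify_dataset(ds))


def test_error_model_produces_valid_panel_genotypes(panel):
    # a corrupted call is still a valid genotype; Dataset construction validates
    config = SimulationConfig(panel=panel, composition=[(BC1, 200)], seed=13,
                              genotyping_error_rate=1.0)
    ds = simulate_dataset(config)
    assert len(ds) == 200


def test_morph_label_policy_stamps_labels(panel):
    config = SimulationConfig(
        panel=panel, composition=[(CrossSpec.leaf("Pret", label="lotA"), 3)],
        seed=1, morph_label_policy={"lotA": "Pret"})
    ds = simulate_dataset(config)
    assert all(s.morph_species == "Pret" for s in ds.samples)
    assert [s.sample_id for s in ds.samples] == \
        ["lotA_0001", "lotA_0002", "lotA_0003"]


def test_invalid_rates_and_empty_composition_rejected(panel):
    with pytest.raises(SimulationError):
        SimulationConfig(panel=panel, composition=[], seed=0)
    with pytest.raises(SimulationError):
        SimulationConfig(panel=panel, composition=[(BC1, 1)], seed=0,
                         missing_rate=1.5)


def test_bc1_classification_fractions_match_enumeration(panel):
    """BC1 at 3 loci: 1/8 looks F1, 1/8 looks pure, 3/4 detected post-F1."""
    config = SimulationConfig(panel=panel, composition=[(BC1, 4000)], seed=77)
    counts = {c: 0 for c in Category}
    for _, cls in classify_dataset(simulate_dataset(config)):
        counts[cls.category] += 1
    n = 4000
    for category, p in [(Category.F1_HYBRID, 0.125), (Category.PURE, 0.125),
                        (Category.POST_F1_HYBRID, 0.75)]:
        se = (p * (1 - p) / n) ** 0.5
        assert abs(counts[category] / n - p) < 3 * se


# ---------------------------------------------------------------------------
# Reference fixture

def test_table2_fixture_shape(table2):
    assert len(table2) == 84
    by_source = {}
    for s in table2.samples:
        by_source[s.source] = by_source.get(s.source, 0) + 1
    assert by_source == {"A": 49, "B": 5, "C": 6, "D": 15, "E": 9}


def test_table2_fixture_institution_subsets(table2):
    def categories(inst):
        sub = table2.subset(lambda s: s.source == inst)
        return [cls.category for _, cls in classify_dataset(sub)]

    c = categories("C")
    assert len(c) == 6 and all(x is Category.POST_F1_HYBRID for x in c)
    e = categories("E")
    assert len(e) == 9 and all(x is Category.PURE for x in e)
    sub_e = table2.subset(lambda s: s.source == "E")
    assert all(cls.genetic_species == "Lmar"
               for _, cls in classify_dataset(sub_e))


def test_table2_fixture_is_deterministic(tmp_path):
    p1, p2 = tmp_path / "f1.csv", tmp_path / "f2.csv"
    write_genotype_table(make_table2_fixture(), p1)
    write_genotype_table(make_table2_fixture(), p2)
    assert p1.read_bytes() == p2.read_bytes()
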