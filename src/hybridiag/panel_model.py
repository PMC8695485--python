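"""Marker panels: species, species-diagnostic loci, and their validation.

A *species-diagnostic* locus carries a distinct fixed allele in each species,
so a heterozygote at any such locus directly reveals mixed ancestry.  A
:class:`MarkerPanel` bundles the species under study with a set of diagnostic
nuclear loci (codominant; both alleles observable) and at most one
mitochondrial locus used for maternal-lineage assignment.

Panels are treated as immutable: every classification is reproducible against
a frozen panel, and edits should construct a new panel.  Allele codes are
arbitrary strings matched exactly and case-sensitively; by convention they
equal the species id they diagnose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

from .errors import PanelError

NUCLEAR = "nuclear"
MITOCHONDRIAL = "mitochondrial"
_KINDS = (NUCLEAR, MITOCHONDRIAL)


@dataclass(frozen=True)
class Species:
    """One species in a panel.

    ``id`` is the short unique code used everywhere else (e.g. ``"Pcor"``);
    ``display_name`` is free text for reports.
    """

    id: str
    display_name: str = ""


@dataclass(frozen=True)
class Locus:
    """A marker locus with one diagnostic allele per species.

    Parameters
    ----------
    name
        Short unique locus code (e.g. ``"RAG2"``).
    kind
        ``"nuclear"`` (diploid, codominant) or ``"mitochondrial"``
        (haploid, maternally inherited).
    diagnostic_allele
        Map species id -> allele code; must cover every panel species with
        pairwise-distinct codes for the locus to be fully diagnostic.
    band_sizes
        Optional map species id -> expected amplicon length in bp, used only
        by gel band decoding.  Left unset when no sizes are published.
    """

    name: str
    kind: str
    diagnostic_allele: Mapping[str, str]
    band_sizes: Mapping[str, int] | None = None

    @property
    def allele_codes(self) -> frozenset[str]:
        return frozenset(self.diagnostic_allele.values())

    def species_of_allele(self, code: str) -> str | None:
        """Species diagnosed by ``code`` at this locus, or None."""
        for sp, allele in self.diagnostic_allele.items():
            if allele == code:
                return sp
        return None


@dataclass(frozen=True)
class MarkerPanel:
    """A frozen set of species and diagnostic loci.

    Must contain at least two species, at least one nuclear locus and at
    most one mitochondrial locus (see :func:`validate_panel`).
    """

    species: tuple[Species, ...]
    loci: tuple[Locus, ...]
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "loci", tuple(self.loci))

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(sp.id for sp in self.species)

    @property
    def nuclear_loci(self) -> tuple[Locus, ...]:
        return tuple(l for l in self.loci if l.kind == NUCLEAR)

    @property
    def mitochondrial_locus(self) -> Locus | None:
        for l in self.loci:
            if l.kind == MITOCHONDRIAL:
                return l
        return None

    def get_locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise PanelError(f"no locus named {name!r} in panel {self.name!r}")


@dataclass(frozen=True)
class Violation:
    """One panel-invariant violation, with enough context to locate it."""

    code: str
    message: str
    locus: str | None = None
    species: str | None = None


def validate_panel(panel: MarkerPanel) -> list[Violation]:
    """Check every panel invariant; an empty list means the panel is valid.

    Violations are returned as data, never raised: a report of *all*
    problems at once is more useful than failing at the first.
    """
    out: list[Violation] = []
    ids = [sp.id for sp in panel.species]

    if len(ids) < 2:
        out.append(Violation("too_few_species", "a panel needs at least 2 species"))
    for sp in panel.species:
        if not sp.id or any(c.isspace() for c in sp.id):
            out.append(Violation("bad_species_id",
                                 f"species id {sp.id!r} is empty or contains whitespace",
                                 species=sp.id))
    for sid in set(ids):
        if ids.count(sid) > 1:
            out.append(Violation("duplicate_species", f"species id {sid!r} repeated",
                                 species=sid))

    names = [l.name for l in panel.loci]
    for name in set(names):
        if names.count(name) > 1:
            out.append(Violation("duplicate_locus", f"locus name {name!r} repeated",
                                 locus=name))
    n_mito = sum(1 for l in panel.loci if l.kind == MITOCHONDRIAL)
    if n_mito > 1:
        out.append(Violation("multiple_mitochondrial_loci",
                             f"panel has {n_mito} mitochondrial loci; at most 1 allowed"))
    if not any(l.kind == NUCLEAR for l in panel.loci):
        out.append(Violation("no_nuclear_locus", "panel has no nuclear locus"))

    for locus in panel.loci:
        if locus.kind not in _KINDS:
            out.append(Violation("bad_locus_kind",
                                 f"locus {locus.name!r} has unknown kind {locus.kind!r}",
                                 locus=locus.name))
        missing = [sid for sid in ids if sid not in locus.diagnostic_allele]
        for sid in missing:
            out.append(Violation("missing_diagnostic_allele",
                                 f"locus {locus.name!r} lacks a diagnostic allele "
                                 f"for species {sid!r}",
                                 locus=locus.name, species=sid))
        codes = [locus.diagnostic_allele[s] for s in ids if s in locus.diagnostic_allele]
        if len(set(codes)) != len(codes):
            out.append(Violation("non_diagnostic_locus",
                                 f"locus {locus.name!r} has identical allele codes for "
                                 f"different species (not fully diagnostic)",
                                 locus=locus.name))
        if locus.band_sizes is not None:
            sizes = list(locus.band_sizes.values())
            if any((not isinstance(s, int)) or s <= 0 for s in sizes):
                out.append(Violation("bad_band_size",
                                     f"locus {locus.name!r} has a non-positive band size",
                                     locus=locus.name))
            if len(set(sizes)) != len(sizes):
                out.append(Violation("indistinct_band_sizes",
                                     f"locus {locus.name!r} has identical expected band "
                                     f"sizes for different species",
                                     locus=locus.name))
    return out


def default_catfish_panel() -> MarkerPanel:
    """The 3-species Neotropical catfish panel: 3 nuclear loci + 1 mitochondrial.

    Species are *Pseudoplatystoma corruscans* (pintado), *P. reticulatum*
    (cachara) and *Leiarius marmoratus* (jundia); nuclear loci are RAG2,
    EF1a and beta-globin, with the 16S rRNA gene as the maternal marker.
    Allele codes equal species ids; expected band sizes are not set (not
    published for this assay).  The panel assumes all three loci are
    diagnostic for every pairwise species contrast.
    """
    species = (
        Species("Pcor", "Pseudoplatystoma corruscans (pintado)"),
        Species("Pret", "Pseudoplatystoma reticulatum (cachara)"),
        Species("Lmar", "Leiarius marmoratus (jundia)"),
    )
    ids = {sp.id: sp.id for sp in species}
    loci = (
        Locus("RAG2", NUCLEAR, dict(ids)),
        Locus("EF1a", NUCLEAR, dict(ids)),
        Locus("glob", NUCLEAR, dict(ids)),
        Locus("16S", MITOCHONDRIAL, dict(ids)),
    )
    return MarkerPanel(species=species, loci=loci, name="catfish-3sp")


# ---------------------------------------------------------------------------
# Panel config file (YAML dialect); writer emits exactly what the reader reads.

def panel_to_dict(panel: MarkerPanel) -> dict:
    d: dict = {
        "name": panel.name,
        "species": [{"id": sp.id, "display_name": sp.display_name}
                    for sp in panel.species],
        "loci": [],
    }
    for locus in panel.loci:
        entry: dict = {
            "name": locus.name,
            "kind": locus.kind,
            "alleles": {sid: locus.diagnostic_allele[sid]
                        for sid in panel.species_ids
                        if sid in locus.diagnostic_allele},
        }
        if locus.band_sizes is not None:
            entry["band_sizes"] = dict(locus.band_sizes)
        d["loci"].append(entry)
    return d


def panel_from_dict(d: Mapping) -> MarkerPanel:
    try:
        species = tuple(Species(s["id"], s.get("display_name", ""))
                        for s in d["species"])
        loci = tuple(
            Locus(l["name"], l["kind"], dict(l["alleles"]),
                  dict(l["band_sizes"]) if "band_sizes" in l else None)
            for l in d["loci"])
    except (KeyError, TypeError) as exc:
        raise PanelError(f"malformed panel config: {exc!r}") from exc
    return MarkerPanel(species=species, loci=loci, name=d.get("name", ""))


def read_panel(path) -> MarkerPanel:
    """Read a panel config (YAML) from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise PanelError(f"panel config {path} is not a mapping")
    return panel_from_dict(data)


def write_panel(panel: MarkerPanel, path) -> None:
    """Write ``panel`` as a YAML config; round-trips exactly through read_panel."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(panel_to_dict(panel), fh, sort_keys=False,
                       default_flow_style=False, allow_unicode=True)
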