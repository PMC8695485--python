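"""Genotype tables and gel band decoding.

The on-disk format is a plain UTF-8 CSV with header
``sample_id,source,morph_species,<locus>_a1,<locus>_a2,...,<mito locus>``:
two allele-code columns per nuclear locus (order not meaningful; the writer
emits them sorted) and a single column for the mitochondrial locus.  The
missing token is ``?``, also used for an unknown morphological species label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import BandDecodeError, GenotypeTableError
from .panel_model import MITOCHONDRIAL, NUCLEAR, Locus, MarkerPanel

MISSING_TOKEN = "?"


@dataclass(frozen=True)
class GenotypeCall:
    """One genotype call at one locus.

    ``alleles`` is a sorted tuple of two codes for a nuclear call, one code
    for a mitochondrial call, and empty when ``missing``.
    """

    locus: str
    alleles: tuple[str, ...]
    missing: bool = False

    @staticmethod
    def nuclear(locus: str, a1: str, a2: str) -> "GenotypeCall":
        return GenotypeCall(locus, tuple(sorted((a1, a2))))

    @staticmethod
    def mito(locus: str, allele: str) -> "GenotypeCall":
        return GenotypeCall(locus, (allele,))

    @staticmethod
    def make_missing(locus: str) -> "GenotypeCall":
        return GenotypeCall(locus, (), missing=True)

    @property
    def is_heterozygous(self) -> bool:
        return (not self.missing) and len(self.alleles) == 2 \
            and self.alleles[0] != self.alleles[1]

    @property
    def is_homozygous(self) -> bool:
        return (not self.missing) and len(self.alleles) == 2 \
            and self.alleles[0] == self.alleles[1]


@dataclass(frozen=True)
class SampleRecord:
    """One individual: identifying labels plus per-locus genotype calls.

    ``morph_species`` is the morphological (phenotypic) species label the
    individual arrived with, or None when unknown; it never influences the
    genetic classification, only the concordance check.
    """

    sample_id: str
    source: str
    morph_species: str | None
    calls: Mapping[str, GenotypeCall]

    def call(self, locus: str) -> GenotypeCall:
        return self.calls.get(locus, GenotypeCall.make_missing(locus))


@dataclass
class Dataset:
    """An ordered collection of samples typed on one panel."""

    panel: MarkerPanel
    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self):
        validate_samples(self.samples, self.panel)

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, predicate) -> "Dataset":
        return Dataset(self.panel, [s for s in self.samples if predicate(s)])

    def to_dataframe(self):
        """Genotype table as a pandas DataFrame (same columns as the CSV)."""
        import pandas as pd

        cols = _header(self.panel)
        return pd.DataFrame([_row(s, self.panel) for s in self.samples],
                            columns=cols)


def validate_samples(samples: Sequence[SampleRecord], panel: MarkerPanel) -> None:
    """Raise GenotypeTableError on duplicate ids, unknown loci or allele codes."""
    seen: set[str] = set()
    locus_by_name = {l.name: l for l in panel.loci}
    for rec in samples:
        if rec.sample_id in seen:
            raise GenotypeTableError(f"duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)
        if rec.morph_species is not None and rec.morph_species not in panel.species_ids:
            raise GenotypeTableError(
                f"sample {rec.sample_id!r}: morphological species "
                f"{rec.morph_species!r} not in panel")
        for name, call in rec.calls.items():
            locus = locus_by_name.get(name)
            if locus is None:
                raise GenotypeTableError(
                    f"sample {rec.sample_id!r}: call references unknown locus {name!r}")
            if call.missing:
                continue
            want = 1 if locus.kind == MITOCHONDRIAL else 2
            if len(call.alleles) != want:
                raise GenotypeTableError(
                    f"sample {rec.sample_id!r}, locus {name!r}: expected {want} "
                    f"allele(s), got {len(call.alleles)}")
            for code in call.alleles:
                if code not in locus.allele_codes:
                    raise GenotypeTableError(
                        f"sample {rec.sample_id!r}, locus {name!r}: allele code "
                        f"{code!r} is not in the panel")


def _header(panel: MarkerPanel) -> list[str]:
    cols = ["sample_id", "source", "morph_species"]
    for locus in panel.nuclear_loci:
        cols += [f"{locus.name}_a1", f"{locus.name}_a2"]
    mito = panel.mitochondrial_locus
    if mito is not None:
        cols.append(mito.name)
    return cols


def _row(rec: SampleRecord, panel: MarkerPanel) -> list[str]:
    row = [rec.sample_id, rec.source,
           rec.morph_species if rec.morph_species is not None else MISSING_TOKEN]
    for locus in panel.nuclear_loci:
        call = rec.call(locus.name)
        if call.missing:
            row += [MISSING_TOKEN, MISSING_TOKEN]
        else:
            row += list(call.alleles)  # already sorted
    mito = panel.mitochondrial_locus
    if mito is not None:
        call = rec.call(mito.name)
        row.append(MISSING_TOKEN if call.missing else call.alleles[0])
    return row


def read_genotype_table(path, panel: MarkerPanel) -> Dataset:
    """Read a genotype CSV into a Dataset, preserving row order.

    The header must contain exactly the columns implied by the panel;
    unknown or missing columns are a named error.  Cells equal to the
    missing token ``?`` (or empty) become missing calls; a nuclear locus
    with either allele cell missing is treated as wholly missing.
    """
    expected = _header(panel)
    samples: list[SampleRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeTableError("empty file: no header", line=1)
        except csv.Error as exc:
            raise GenotypeTableError(f"malformed CSV: {exc}", line=1)
        unknown = [c for c in header if c not in expected]
        if unknown:
            raise GenotypeTableError(f"unknown column(s) {unknown!r}", line=1)
        absent = [c for c in expected if c not in header]
        if absent:
            raise GenotypeTableError(f"missing column(s) {absent!r}", line=1)
        idx = {c: header.index(c) for c in expected}

        mito = panel.mitochondrial_locus
        for lineno, row in enumerate(reader, start=2):
            try:
                if len(row) != len(header):
                    raise GenotypeTableError(
                        f"expected {len(header)} fields, got {len(row)}", line=lineno)
                get = lambda c: row[idx[c]].strip()
                morph = get("morph_species")
                calls: dict[str, GenotypeCall] = {}
                for locus in panel.nuclear_loci:
                    a1, a2 = get(f"{locus.name}_a1"), get(f"{locus.name}_a2")
                    if MISSING_TOKEN in (a1, a2) or "" in (a1, a2):
                        calls[locus.name] = GenotypeCall.make_missing(locus.name)
                    else:
                        calls[locus.name] = GenotypeCall.nuclear(locus.name, a1, a2)
                if mito is not None:
                    m = get(mito.name)
                    calls[mito.name] = (GenotypeCall.make_missing(mito.name)
                                        if m in (MISSING_TOKEN, "")
                                        else GenotypeCall.mito(mito.name, m))
                samples.append(SampleRecord(
                    sample_id=get("sample_id"),
                    source=get("source"),
                    morph_species=None if morph in (MISSING_TOKEN, "") else morph,
                    calls=calls))
            except csv.Error as exc:
                raise GenotypeTableError(f"malformed CSV: {exc}", line=lineno)
    try:
        return Dataset(panel, samples)
    except GenotypeTableError:
        raise


def write_genotype_table(dataset: Dataset, path) -> None:
    """Write a Dataset as CSV; byte-stable and an exact read round-trip."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_header(dataset.panel))
        for rec in dataset.samples:
            writer.writerow(_row(rec, dataset.panel))


# ---------------------------------------------------------------------------
# Gel band decoding

@dataclass(frozen=True)
class BandObservation:
    """Observed amplicon band lengths (bp) at one locus on a gel lane."""

    locus: str
    sizes: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "sizes", tuple(self.sizes))


def decode_band_pattern(observations: Iterable[BandObservation],
                        panel: MarkerPanel,
                        tolerance_bp: int = 0) -> dict[str, GenotypeCall]:
    """Decode observed band sizes into genotype calls.

    Each observed size must match exactly one species' expected band at its
    locus within ``tolerance_bp``; one matched band at a nuclear locus is a
    homozygote, two distinct matches a heterozygote, and a mitochondrial
    locus must show exactly one band.  Ambiguous or unmatchable sizes raise
    BandDecodeError.  The default tolerance is 0 bp: slack is opt-in.
    """
    if tolerance_bp < 0:
        raise BandDecodeError("tolerance_bp must be nonnegative")
    out: dict[str, GenotypeCall] = {}
    for obs in observations:
        locus = panel.get_locus(obs.locus)
        if locus.band_sizes is None:
            raise BandDecodeError(
                f"locus {obs.locus!r} has no expected band sizes in the panel")
        if any(s <= 0 for s in obs.sizes):
            raise BandDecodeError(f"locus {obs.locus!r}: band sizes must be positive")
        n_max = 1 if locus.kind == MITOCHONDRIAL else 2
        if len(obs.sizes) == 0:
            raise BandDecodeError(f"locus {obs.locus!r}: no bands observed")
        if len(obs.sizes) > n_max:
            raise BandDecodeError(
                f"locus {obs.locus!r}: {len(obs.sizes)} bands observed, "
                f"at most {n_max} allowed")
        matched: list[str] = []
        for size in sorted(obs.sizes):
            hits = [sp for sp, exp in locus.band_sizes.items()
                    if abs(size - exp) <= tolerance_bp]
            if len(hits) != 1:
                raise BandDecodeError(
                    f"locus {obs.locus!r}: band of {size} bp matches "
                    f"{len(hits)} expected bands within +/-{tolerance_bp} bp")
            matched.append(locus.diagnostic_allele[hits[0]])
        if locus.kind == MITOCHONDRIAL:
            out[obs.locus] = GenotypeCall.mito(obs.locus, matched[0])
        elif len(matched) == 1:
            out[obs.locus] = GenotypeCall.nuclear(obs.locus, matched[0], matched[0])
        else:
            if matched[0] == matched[1]:
                raise BandDecodeError(
                    f"locus {obs.locus!r}: two bands decode to the same allele "
                    f"{matched[0]!r}")
            out[obs.locus] = GenotypeCall.nuclear(obs.locus, matched[0], matched[1])
    return out
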