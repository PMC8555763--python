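"""Sequence- vs length-level STR allele handling and allele frequencies.

MPS resolves isoalleles: sequence-distinct variants that share a repeat
length and are invisible to capillary electrophoresis. Alleles are
represented as plain strings: a length allele is its repeat number
("14", "9.3"), a sequence allele appends an opaque isoallele tag in
brackets ("14[t2]"). Statistics depend only on allele distinctness, so
the tag is never parsed beyond being stripped when collapsing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

from .io_formats import (
    AlleleFrequencyTable,
    GenotypeTable,
    LocusSpec,
    ValidationError,
)

_TAG_RE = re.compile(r"^(?P<length>[^\[\]]+)(\[(?P<tag>[^\[\]]*)\])?$")


def split_allele(allele: str) -> tuple[str, "str | None"]:
    """Split ``"14[t2]"`` into (length part, tag); tag None if absent."""
    m = _TAG_RE.match(str(allele))
    if m is None:
        raise ValidationError(f"malformed allele name {allele!r}")
    return m.group("length"), m.group("tag")


def length_allele(allele: str) -> str:
    return split_allele(allele)[0]


def has_sequence_tag(allele: str) -> bool:
    return split_allele(allele)[1] is not None


@dataclass(frozen=True)
class STRAllele:
    """An STR allele at sequence resolution.

    ``repeat_number`` is the decimal allele name (microvariants like 9.3
    allowed); ``sequence_tag`` distinguishes isoalleles of equal length.
    """

    locus: str
    repeat_number: float
    sequence_tag: "str | None" = None

    def __post_init__(self):
        if self.repeat_number <= 0:
            raise ValidationError("repeat_number must be positive")

    @classmethod
    def from_name(cls, locus: str, name: str) -> "STRAllele":
        length, tag = split_allele(name)
        return cls(locus=locus, repeat_number=float(length), sequence_tag=tag)

    @property
    def name(self) -> str:
        rep = (
            str(int(self.repeat_number))
            if self.repeat_number == int(self.repeat_number)
            else str(self.repeat_number)
        )
        return rep if self.sequence_tag is None else f"{rep}[{self.sequence_tag}]"


def collapse_to_length(table: GenotypeTable) -> GenotypeTable:
    """Strip sequence tags from STR alleles; SNP loci pass through.

    A sequence tag on a SNP allele is an error: isoalleles are an STR
    concept.
    """
    str_loci = {l.name for l in table.loci if l.is_str}
    cells = {}
    for (sample, locus), cell in table.cells.items():
        if cell is None:
            cells[(sample, locus)] = None
            continue
        if locus in str_loci:
            cells[(sample, locus)] = tuple(sorted(length_allele(a) for a in cell))
        else:
            for a in cell:
                if has_sequence_tag(a):
                    raise ValidationError(
                        f"non-STR locus {locus!r} carries sequence-tagged "
                        f"allele {a!r}"
                    )
            cells[(sample, locus)] = cell
    return GenotypeTable(
        samples=list(table.samples),
        populations=list(table.populations),
        loci=list(table.loci),
        cells=cells,
    )


def count_distinct_alleles(
    table: GenotypeTable, level: str = "sequence"
) -> tuple[dict, int]:
    """Distinct observed alleles per STR locus and the grand total.

    ``level`` is "sequence" (alleles as stored) or "length" (tags
    stripped before counting). Counts pool all samples; missing cells
    are ignored. An STR locus with no observed alleles counts 0 with a
    warning.
    """
    if level not in ("length", "sequence"):
        raise ValueError(f"level must be 'length' or 'sequence', got {level!r}")
    counts = {}
    for spec in table.loci:
        if not spec.is_str:
            continue
        observed = set()
        for sample in table.samples:
            cell = table.cells.get((sample, spec.name))
            if cell is None:
                continue
            for a in cell:
                observed.add(length_allele(a) if level == "length" else a)
        if not observed:
            warnings.warn(f"locus {spec.name!r}: no observed alleles", stacklevel=2)
        counts[spec.name] = len(observed)
    return counts, sum(counts.values())


def diversity_gain(n_length: int, n_sequence: int) -> float:
    """Percent increase of sequence-level over length-level allele counts."""
    if n_length < 1:
        raise ValidationError("n_length must be >= 1")
    if n_sequence < n_length:
        raise ValidationError(
            "collapsing cannot create alleles: n_sequence < n_length"
        )
    return 100.0 * (n_sequence - n_length) / n_length


def allele_count_report(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus length/sequence allele counts and gain percentages."""
    seq, _ = count_distinct_alleles(table, "sequence")
    length, _ = count_distinct_alleles(collapse_to_length(table), "length")
    rows = []
    for locus in seq:
        nl, ns = length[locus], seq[locus]
        rows.append(
            {
                "locus": locus,
                "n_length": nl,
                "n_sequence": ns,
                "gain_percent": diversity_gain(nl, ns) if nl >= 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def allele_frequencies(
    table: GenotypeTable, by_population: bool = True
) -> AlleleFrequencyTable:
    """Observed allele frequencies per (population,) locus.

    The denominator is the number of observed allele copies (2n for
    diploid and multi-copy loci, n for haploid); missing cells do not
    contribute. A locus with zero observed copies in a population is
    omitted with a warning.
    """
    groups: dict = {}
    for i, sample in enumerate(table.samples):
        pop = table.populations[i] if by_population else "ALL"
        groups.setdefault(pop, []).append(sample)

    rows = []
    for pop, members in groups.items():
        for spec in table.loci:
            tally: dict = {}
            for sample in members:
                cell = table.cells.get((sample, spec.name))
                if cell is None:
                    continue
                for a in cell:
                    tally[a] = tally.get(a, 0) + 1
            total = sum(tally.values())
            if total == 0:
                warnings.warn(
                    f"population {pop!r} locus {spec.name!r}: no observed "
                    "allele copies; omitted",
                    stacklevel=2,
                )
                continue
            for a, c in sorted(tally.items()):
                rows.append(
                    {
                        "population": pop,
                        "locus": spec.name,
                        "allele": a,
                        "frequency": c / total,
                        "n": total,
                    }
                )
    return AlleleFrequencyTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class MAFRecord:
    """Minor allele of a biallelic locus and its frequency."""

    locus: str
    allele: "str | None"
    frequency: float
    monomorphic: bool = False


def minor_allele_frequency(
    freqs: AlleleFrequencyTable,
    population: "str | None" = None,
    allow_multiallelic: bool = False,
) -> list[MAFRecord]:
    """MAF per locus of a (single-population) frequency table.

    Loci must be biallelic unless ``allow_multiallelic`` is set, in which
    case the least-frequent allele is reported. Ties at 0.5 report the
    lexicographically smaller allele; a monomorphic locus yields MAF 0
    with no allele name and the ``monomorphic`` flag set.
    """
    pops = freqs.populations
    if population is None:
        if len(pops) != 1:
            raise ValidationError(
                "frequency table has several populations; pass population="
            )
        population = pops[0]
    records = []
    for locus in freqs.loci:
        fmap = freqs.freqs(population, locus)
        if not fmap:
            continue
        if len(fmap) == 1:
            records.append(
                MAFRecord(locus=locus, allele=None, frequency=0.0, monomorphic=True)
            )
            continue
        if len(fmap) > 2 and not allow_multiallelic:
            raise ValidationError(
                f"locus {locus!r} is multiallelic; pass allow_multiallelic=True "
                "for least-frequent-allele mode"
            )
        # smallest frequency, ties broken by allele name
        allele, freq = min(fmap.items(), key=lambda kv: (kv[1], kv[0]))
        records.append(MAFRecord(locus=locus, allele=allele, frequency=freq))
    return records
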