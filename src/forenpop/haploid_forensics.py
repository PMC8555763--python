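"""Haplotype statistics for Y-STRs and X-STRs in males.

Per locus: gene diversity GD = (n/(n−1))(1 − Σp²). Whole haplotype,
with f_i the relative frequencies of the distinct multilocus haplotypes:
match probability PM = Σf², haplotype diversity HD = (n/(n−1))(1 − PM),
and discrimination capacity DC = distinct haplotypes / n.

Multi-copy loci (DYS385a-b convention) enter the haplotype as a sorted
tuple, making haplotype identity order-invariant. Individuals missing
any locus are excluded from whole-haplotype statistics (haplotype
identity is undefined under missingness) but still count toward
per-locus gene diversity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io_formats import GenotypeTable, ValidationError


@dataclass
class HaplotypeSet:
    """Multilocus haploid profiles for a set of male individuals.

    ``rows[i][j]`` is the tuple of repeat numbers individual i carries at
    locus j (length 1, or 2 for multi-copy loci, sorted), or None when
    missing.
    """

    individuals: list[str]
    loci: list[str]
    rows: list[tuple]
    label: str = ""

    def __post_init__(self):
        arity = len(self.loci)
        for ind, row in zip(self.individuals, self.rows):
            if len(row) != arity:
                raise ValidationError(
                    f"individual {ind!r}: haplotype arity {len(row)} != "
                    f"{arity} loci"
                )
        self.rows = [
            tuple(
                None if v is None else tuple(sorted(float(x) for x in v))
                for v in row
            )
            for row in self.rows
        ]

    @classmethod
    def from_genotype_table(
        cls, table: GenotypeTable, loci=None, label: str = ""
    ) -> "HaplotypeSet":
        """Build from the haploid loci of a genotype table.

        Allele names must have a numeric repeat-number prefix; sequence
        tags are dropped (haplotype repeat arithmetic is length-based).
        """
        from .mps_calling import repeat_number

        if loci is None:
            loci = [l.name for l in table.loci if l.ploidy_in_males == 1]
        specs = {l.name: l for l in table.loci}
        unknown = [l for l in loci if l not in specs]
        if unknown:
            raise ValidationError(f"unknown haploid loci {unknown}")
        diploid = [l for l in loci if specs[l].ploidy_in_males != 1]
        if diploid:
            raise ValidationError(f"loci {diploid} are diploid")
        rows = []
        for sample in table.samples:
            row = []
            for locus in loci:
                cell = table.cells.get((sample, locus))
                if cell is None:
                    row.append(None)
                else:
                    reps = [repeat_number(a) for a in cell]
                    if any(r is None for r in reps):
                        raise ValidationError(
                            f"sample {sample!r} locus {locus!r}: allele "
                            "without numeric repeat number"
                        )
                    row.append(tuple(reps))
            rows.append(tuple(row))
        return cls(
            individuals=list(table.samples), loci=list(loci), rows=rows,
            label=label,
        )

    def complete_rows(self) -> list[tuple]:
        """Haplotypes with no missing locus (listwise deletion)."""
        return [r for r in self.rows if all(v is not None for v in r)]

    def locus_allele_counts(self, locus: str) -> Counter:
        j = self.loci.index(locus)
        tally: Counter = Counter()
        for row in self.rows:
            if row[j] is None:
                continue
            for allele in row[j]:
                tally[allele] += 1
        return tally


def gene_diversity(freqs: dict, n: int) -> float:
    """Unbiased gene diversity GD = (n/(n−1))(1 − Σp²).

    ``n`` is the number of observed allele copies (chromosomes), which
    equals the number of individuals at single-copy male haploid loci.
    """
    if n < 2:
        raise ValidationError("gene diversity needs n >= 2")
    s = sum(p * p for p in freqs.values())
    return (n / (n - 1)) * (1.0 - s)


def locus_gene_diversity(h: HaplotypeSet) -> pd.DataFrame:
    """Per-locus GD table (locus, n allele copies, GD)."""
    rows = []
    for locus in h.loci:
        tally = h.locus_allele_counts(locus)
        n = sum(tally.values())
        if n < 2:
            raise ValidationError(f"locus {locus!r}: fewer than 2 allele copies")
        freqs = {a: c / n for a, c in tally.items()}
        rows.append({"locus": locus, "n": n, "GD": gene_diversity(freqs, n)})
    return pd.DataFrame(rows)


@dataclass
class HaplotypeStatistics:
    n: int
    distinct: int
    PM: float
    HD: float
    DC: float


def haplotype_statistics(h: HaplotypeSet) -> HaplotypeStatistics:
    """Whole-haplotype PM, HD and DC over complete profiles."""
    complete = h.complete_rows()
    n = len(complete)
    if n < 2:
        raise ValidationError("haplotype statistics need >= 2 complete profiles")
    counts = Counter(complete)
    pm = sum((c / n) ** 2 for c in counts.values())
    hd = (n / (n - 1)) * (1.0 - pm)
    return HaplotypeStatistics(
        n=n, distinct=len(counts), PM=pm, HD=hd, DC=len(counts) / n
    )


def haplotype_inventory(h: HaplotypeSet) -> pd.DataFrame:
    """Distinct complete haplotypes with their counts, most common first."""
    complete = h.complete_rows()
    counts = Counter(complete)
    rows = []
    for hap, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        rows.append(
            {
                "haplotype": ";".join(
                    "-".join(f"{x:g}" for x in locus_val) for locus_val in hap
                ),
                "count": c,
            }
        )
    return pd.DataFrame(rows)
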