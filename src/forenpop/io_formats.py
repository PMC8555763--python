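"""Tabular and matrix I/O for genotype, allele-frequency and distance data.

All readers validate on load and never silently drop rows; all writers
produce files their paired reader parses back to an identical object.
Text is UTF-8, decimal point ".", missing genotypes written as ``NA``
("0" is also accepted on read, a common forensic convention for STRs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MARKER_CLASSES = ("A-STR", "Y-STR", "X-STR", "IISNP", "AISNP", "PISNP")
STR_CLASSES = frozenset({"A-STR", "Y-STR", "X-STR"})
SNP_CLASSES = frozenset({"IISNP", "AISNP", "PISNP"})

#: tokens accepted as a missing genotype on read
MISSING_TOKENS = frozenset({"NA", "0", ""})
MISSING_OUT = "NA"

GENOTYPE_DIALECTS = ("slash", "two-column")


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line."""


def _default_ploidy(marker_class: str) -> int:
    # male cohort convention: Y and X markers are hemizygous
    return 1 if marker_class in ("Y-STR", "X-STR") else 2


@dataclass(frozen=True)
class LocusSpec:
    """A genetic marker: its name, class, male ploidy and copy number.

    ``copy_number`` is 2 for multi-copy Y loci (DYS385a-b, DYF387S1 style)
    whose single primer pair amplifies two chromosomal copies.
    """

    name: str
    marker_class: str
    ploidy_in_males: int = -1  # -1 → derive from marker class
    copy_number: int = 1

    def __post_init__(self):
        if self.marker_class not in MARKER_CLASSES:
            raise ValidationError(
                f"unknown marker class {self.marker_class!r} for locus {self.name!r}"
            )
        if self.ploidy_in_males == -1:
            object.__setattr__(
                self, "ploidy_in_males", _default_ploidy(self.marker_class)
            )
        if self.marker_class == "A-STR" and self.ploidy_in_males != 2:
            raise ValidationError(f"A-STR locus {self.name!r} must be diploid")
        if self.marker_class in ("Y-STR", "X-STR") and self.ploidy_in_males != 1:
            raise ValidationError(
                f"{self.marker_class} locus {self.name!r} must be haploid in males"
            )
        if self.copy_number not in (1, 2):
            raise ValidationError(f"copy_number must be 1 or 2 at {self.name!r}")

    @property
    def is_str(self) -> bool:
        return self.marker_class in STR_CLASSES

    @property
    def is_snp(self) -> bool:
        return self.marker_class in SNP_CLASSES

    @property
    def max_alleles(self) -> int:
        """Maximum alleles a non-missing cell may carry."""
        return self.ploidy_in_males * self.copy_number


# genotype cell: tuple of allele strings, or None for missing
Cell = "tuple[str, ...] | None"


@dataclass
class GenotypeTable:
    """Samples × loci genotype matrix.

    Cells are tuples of allele names: 2 for diploid loci (unordered,
    stored sorted), 1 for haploid single-copy, 1–2 for multi-copy
    haploid loci (stored sorted), or ``None`` for missing.
    """

    samples: list[str]
    populations: list[str]
    loci: list[LocusSpec]
    cells: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.samples) != len(set(self.samples)):
            dup = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValidationError(f"duplicate sample IDs: {dup}")
        if len(self.populations) != len(self.samples):
            raise ValidationError("one population label required per sample")
        names = [l.name for l in self.loci]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate locus names")
        by_name = {l.name: l for l in self.loci}
        for (sample, locus), cell in self.cells.items():
            if cell is None:
                continue
            spec = by_name.get(locus)
            if spec is None:
                raise ValidationError(f"cell references unknown locus {locus!r}")
            k = len(cell)
            if spec.copy_number == 1:
                if k != spec.ploidy_in_males:
                    raise ValidationError(
                        f"sample {sample!r} locus {locus!r}: expected "
                        f"{spec.ploidy_in_males} allele(s), got {k}"
                    )
            elif not 1 <= k <= spec.max_alleles:
                raise ValidationError(
                    f"sample {sample!r} locus {locus!r}: multi-copy cell "
                    f"must carry 1..{spec.max_alleles} alleles, got {k}"
                )

    # -- accessors ---------------------------------------------------------

    def locus(self, name: str) -> LocusSpec:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def genotype(self, sample: str, locus: str):
        return self.cells.get((sample, locus))

    def set_genotype(self, sample: str, locus: str, alleles) -> None:
        if alleles is None:
            self.cells[(sample, locus)] = None
        else:
            self.cells[(sample, locus)] = tuple(sorted(str(a) for a in alleles))

    def population_of(self, sample: str) -> str:
        return self.populations[self.samples.index(sample)]

    def loci_of_class(self, *classes: str) -> list[LocusSpec]:
        return [l for l in self.loci if l.marker_class in classes]

    def column(self, locus: str) -> list:
        """Genotypes of every sample at one locus, missing as None."""
        return [self.cells.get((s, locus)) for s in self.samples]

    def subset_samples(self, keep) -> "GenotypeTable":
        keep = list(keep)
        idx = {s: i for i, s in enumerate(self.samples)}
        cells = {
            (s, l): c for (s, l), c in self.cells.items() if s in set(keep)
        }
        return GenotypeTable(
            samples=keep,
            populations=[self.populations[idx[s]] for s in keep],
            loci=list(self.loci),
            cells=cells,
        )

    def __eq__(self, other):
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.populations == other.populations
            and self.loci == other.loci
            and {k: v for k, v in self.cells.items() if v is not None}
            == {k: v for k, v in other.cells.items() if v is not None}
        )


@dataclass
class AlleleFrequencyTable:
    """Long-format population × locus × allele frequency table.

    Backed by a DataFrame with columns population, locus, allele,
    frequency, n (sample size in allele copies at that population-locus).
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = ["population", "locus", "allele", "frequency", "n"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"frequency table missing columns {missing}")
        self.data = self.data[required].copy()
        self.data["population"] = self.data["population"].astype(str)
        self.data["locus"] = self.data["locus"].astype(str)
        self.data["allele"] = self.data["allele"].astype(str)
        self.validate()

    def validate(self, tol: float = 1e-6) -> None:
        if (self.data["frequency"] < 0).any():
            raise ValidationError("negative allele frequency")
        sums = self.data.groupby(["population", "locus"])["frequency"].sum()
        bad = sums[(sums - 1.0).abs() > tol]
        if len(bad):
            pop, loc = bad.index[0]
            raise ValidationError(
                f"frequencies at population {pop!r} locus {loc!r} sum to "
                f"{bad.iloc[0]:.8f}, not 1"
            )
        dup = self.data.duplicated(["population", "locus", "allele"])
        if dup.any():
            raise ValidationError("duplicate (population, locus, allele) rows")

    def renormalized(self) -> "AlleleFrequencyTable":
        df = self.data.copy()
        df["frequency"] = df.groupby(["population", "locus"])["frequency"].transform(
            lambda s: s / s.sum()
        )
        return AlleleFrequencyTable(df)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.data["population"]))

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.data["locus"]))

    def freqs(self, population: str, locus: str) -> dict:
        sub = self.data[
            (self.data["population"] == population) & (self.data["locus"] == locus)
        ]
        return dict(zip(sub["allele"], sub["frequency"]))

    def n(self, population: str, locus: str) -> int:
        sub = self.data[
            (self.data["population"] == population) & (self.data["locus"] == locus)
        ]
        if sub.empty:
            raise KeyError((population, locus))
        return int(sub["n"].iloc[0])

    def pop_freqs(self, locus: str) -> dict:
        """Map population → {allele: frequency} at one locus."""
        return {p: self.freqs(p, locus) for p in self.populations}

    def to_matrix(self) -> pd.DataFrame:
        """Populations × stacked ``locus:allele`` frequency columns.

        Alleles absent in a population get frequency 0; this is the PCA
        input layout.
        """
        wide = self.data.pivot_table(
            index="population",
            columns=["locus", "allele"],
            values="frequency",
            fill_value=0.0,
            aggfunc="first",
        )
        wide.columns = [f"{l}:{a}" for l, a in wide.columns]
        return wide.loc[self.populations]

    def __eq__(self, other):
        if not isinstance(other, AlleleFrequencyTable):
            return NotImplemented
        a = self.data.sort_values(["population", "locus", "allele"]).reset_index(
            drop=True
        )
        b = other.data.sort_values(["population", "locus", "allele"]).reset_index(
            drop=True
        )
        if not a[["population", "locus", "allele"]].equals(
            b[["population", "locus", "allele"]]
        ):
            return False
        return bool(
            np.allclose(a["frequency"], b["frequency"], atol=1e-9)
            and (a["n"].to_numpy() == b["n"].to_numpy()).all()
        )


@dataclass
class DistanceMatrix:
    """Square symmetric labelled distance matrix with a metric tag."""

    labels: list[str]
    values: np.ndarray
    metric: str = "OTHER"  # DA | RST | OTHER

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if self.metric == "DA" and (
            (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any()
        ):
            raise ValidationError("DA distances must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# genotype table I/O
# ---------------------------------------------------------------------------

_MULTI_SEP = ","
_DIP_SEP = "/"


def _format_cell(cell, spec: LocusSpec) -> str:
    if cell is None:
        return MISSING_OUT
    if spec.copy_number > 1:
        return _MULTI_SEP.join(cell)
    if spec.ploidy_in_males == 2:
        return _DIP_SEP.join(cell)
    return cell[0]


def _parse_cell(token: str, spec: LocusSpec, sample: str, line_no: int):
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    if spec.copy_number > 1:
        alleles = [t for t in token.split(_MULTI_SEP) if t != ""]
    elif spec.ploidy_in_males == 2:
        alleles = token.split(_DIP_SEP)
    else:
        alleles = [token]
    if spec.copy_number == 1 and len(alleles) != spec.ploidy_in_males:
        raise ValidationError(
            f"line {line_no}: sample {sample!r} locus {spec.name!r}: expected "
            f"{spec.ploidy_in_males} allele(s), got {len(alleles)} ({token!r})"
        )
    return tuple(sorted(alleles))


def write_genotype_table(table: GenotypeTable, path, dialect: str = "slash") -> None:
    """Write a genotype TSV; see :func:`read_genotype_table` for layouts."""
    if dialect not in GENOTYPE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = [f"## dialect {dialect}"]
    for spec in table.loci:
        lines.append(
            f"## locus {spec.name}\t{spec.marker_class}\t{spec.copy_number}"
        )
    if dialect == "slash":
        header = ["sample", "population"] + [l.name for l in table.loci]
        lines.append("\t".join(header))
        for i, sample in enumerate(table.samples):
            row = [sample, table.populations[i]]
            for spec in table.loci:
                row.append(_format_cell(table.cells.get((sample, spec.name)), spec))
            lines.append("\t".join(row))
    else:  # two-column
        header = ["sample", "population"]
        for spec in table.loci:
            if spec.max_alleles >= 2:
                header += [f"{spec.name}_1", f"{spec.name}_2"]
            else:
                header.append(spec.name)
        lines.append("\t".join(header))
        for i, sample in enumerate(table.samples):
            row = [sample, table.populations[i]]
            for spec in table.loci:
                cell = table.cells.get((sample, spec.name))
                if spec.max_alleles >= 2:
                    if cell is None:
                        row += [MISSING_OUT, MISSING_OUT]
                    elif len(cell) == 1:  # multi-copy single call duplicated
                        row += [cell[0], cell[0]]
                    else:
                        row += [cell[0], cell[1]]
                else:
                    row.append(MISSING_OUT if cell is None else cell[0])
            lines.append("\t".join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genotype_table(path, dialect: str = "slash", loci=None) -> GenotypeTable:
    """Read a genotype TSV written by :func:`write_genotype_table`.

    Two dialects: ``slash`` (one column per locus; diploid alleles joined
    by "/", multi-copy by ",", haploid bare) and ``two-column`` (two
    columns per diploid/multi-copy locus). Locus classes come from the
    ``## locus`` comment header unless ``loci`` overrides them.
    """
    if dialect not in GENOTYPE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    spec_by_name = {l.name: l for l in loci} if loci else {}
    header = None
    rows = []
    header_line = 0
    for ln, line in enumerate(raw, start=1):
        if not line.strip():
            continue
        if line.startswith("## locus "):
            body = line[len("## locus "):]
            parts = body.split("\t")
            if len(parts) != 3:
                raise ParseError(f"line {ln}: malformed locus header {line!r}")
            name, mclass, copies = parts
            if name not in spec_by_name:
                spec_by_name[name] = LocusSpec(
                    name=name, marker_class=mclass, copy_number=int(copies)
                )
            continue
        if line.startswith("##"):
            continue
        if header is None:
            header = line.split("\t")
            header_line = ln
            continue
        rows.append((ln, line.split("\t")))
    if header is None:
        raise ParseError("no header row found")
    if header[:2] != ["sample", "population"]:
        raise ParseError(
            f"line {header_line}: header must start with sample, population"
        )

    # map header columns → loci
    if dialect == "slash":
        locus_names = header[2:]
        col_of = {name: [2 + i] for i, name in enumerate(locus_names)}
    else:
        locus_names, col_of, i = [], {}, 2
        while i < len(header):
            col = header[i]
            if col.endswith("_1"):
                name = col[:-2]
                if i + 1 >= len(header) or header[i + 1] != f"{name}_2":
                    raise ParseError(
                        f"line {header_line}: column {col!r} lacks paired "
                        f"{name}_2 column"
                    )
                locus_names.append(name)
                col_of[name] = [i, i + 1]
                i += 2
            else:
                locus_names.append(col)
                col_of[col] = [i]
                i += 1
    unknown = [n for n in locus_names if n not in spec_by_name]
    if unknown:
        raise ParseError(
            f"no LocusSpec available for loci {unknown}; pass loci= or use a "
            "file with '## locus' headers"
        )
    loci_list = [spec_by_name[n] for n in locus_names]

    samples, populations, cells = [], [], {}
    for ln, fields in rows:
        if len(fields) != len(header):
            raise ParseError(
                f"line {ln}: expected {len(header)} fields, got {len(fields)}"
            )
        sample, population = fields[0], fields[1]
        if sample in samples:
            raise ValidationError(f"line {ln}: duplicate sample ID {sample!r}")
        samples.append(sample)
        populations.append(population)
        for spec in loci_list:
            cols = col_of[spec.name]
            if len(cols) == 1:
                cell = _parse_cell(fields[cols[0]], spec, sample, ln)
            else:
                a, b = fields[cols[0]].strip(), fields[cols[1]].strip()
                if a in MISSING_TOKENS and b in MISSING_TOKENS:
                    cell = None
                elif a in MISSING_TOKENS or b in MISSING_TOKENS:
                    raise ValidationError(
                        f"line {ln}: sample {sample!r} locus {spec.name!r}: "
                        "half-missing genotype"
                    )
                else:
                    cell = tuple(sorted((a, b)))
                    if spec.copy_number > 1 and a == b:
                        # duplicated single call collapses back to one allele?
                        # keep both copies: identity with writer convention
                        cell = (a, b)
            cells[(sample, spec.name)] = cell
    return GenotypeTable(
        samples=samples, populations=populations, loci=loci_list, cells=cells
    )


# ---------------------------------------------------------------------------
# frequency table I/O
# ---------------------------------------------------------------------------

def write_frequency_table(table: AlleleFrequencyTable, path) -> None:
    df = table.data.copy()
    df["frequency"] = df["frequency"].map(lambda x: repr(float(x)))
    df.to_csv(path, index=False)


def read_frequency_table(path, renormalize: bool = False) -> AlleleFrequencyTable:
    """Read a frequency CSV (population, locus, allele, frequency, n).

    Frequencies at each population-locus must sum to 1 ± 1e-6 unless
    ``renormalize`` is set, in which case they are rescaled.
    """
    df = pd.read_csv(
        path, dtype={"population": str, "locus": str, "allele": str}
    )
    required = ["population", "locus", "allele", "frequency", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"frequency CSV missing columns {missing}")
    if renormalize:
        df["frequency"] = df.groupby(["population", "locus"])["frequency"].transform(
            lambda s: s / s.sum()
        )
    return AlleleFrequencyTable(df)


# ---------------------------------------------------------------------------
# distance matrix I/O
# ---------------------------------------------------------------------------

def write_distance_matrix(m: DistanceMatrix, path, format: str = "PHYLIP-square") -> None:
    """Write PHYLIP square or CSV; values at 10 significant digits."""
    if format == "PHYLIP-square":
        lines = [f"{len(m.labels)}"]
        for i, lab in enumerate(m.labels):
            vals = " ".join(f"{v:.10g}" for v in m.values[i])
            lines.append(f"{lab}\t{vals}")
        text = "\n".join(lines) + "\n"
        if m.metric != "OTHER":
            text = f"# metric {m.metric}\n" + text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    elif format == "CSV":
        df = m.to_frame().map(lambda v: float(f"{v:.10g}"))
        df.index.name = f"metric={m.metric}"
        df.to_csv(path)
    else:
        raise ValueError(f"unknown distance-matrix format {format!r}")


def read_distance_matrix(path, format: str = "PHYLIP-square") -> DistanceMatrix:
    if format == "PHYLIP-square":
        with open(path, encoding="utf-8") as fh:
            lines = [l for l in fh.read().splitlines() if l.strip()]
        metric = "OTHER"
        if lines and lines[0].startswith("# metric"):
            metric = lines[0].split()[-1]
            lines = lines[1:]
        try:
            n = int(lines[0].strip())
        except (IndexError, ValueError) as exc:
            raise ParseError("PHYLIP matrix must start with taxon count") from exc
        if len(lines) - 1 != n:
            raise ParseError(f"expected {n} matrix rows, found {len(lines) - 1}")
        labels, rows = [], []
        for ln, line in enumerate(lines[1:], start=2):
            parts = line.replace("\t", " ").split()
            if len(parts) != n + 1:
                raise ParseError(f"line {ln}: expected label + {n} values")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        values = np.array(rows)
    elif format == "CSV":
        df = pd.read_csv(path, index_col=0)
        metric = "OTHER"
        if df.index.name and df.index.name.startswith("metric="):
            metric = df.index.name.split("=", 1)[1]
        labels = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown distance-matrix format {format!r}")
    if not np.allclose(values, values.T, atol=1e-9, rtol=0.0):
        raise ValidationError("asymmetric distance matrix in file")
    # symmetrize away the last-digit rounding from the 10-sig-digit writer
    values = (values + values.T) / 2.0
    return DistanceMatrix(labels=labels, values=values, metric=metric)
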