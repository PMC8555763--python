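"""Genotype calling from per-allele read counts.

Implements the standard MPS interpretation rule set for forensic panels:
an analytical threshold (AT) below which candidate alleles are dropped,
an interpretation threshold (IT) under which surviving alleles are
flagged for manual review, a stutter filter (SF) removing n−1 repeat
artifacts, an intra-locus balance (IB) check for heterozygotes, and a
minimum locus depth below which no call is attempted.

AT and IT are fractions of the total locus read count; SF is a fraction
of the putative parent allele's count; IB is the minimum acceptable
min/max count ratio between the two alleles of a heterozygote.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, LocusSpec, ValidationError

# per-allele status labels
CALLED = "called"
BELOW_AT = "below_AT_dropped"
FLAGGED = "between_AT_IT_flagged"
STUTTER = "stutter_removed"


@dataclass(frozen=True)
class CallingThresholds:
    """Interpretation thresholds with per-locus overrides.

    Defaults follow common MPS panel settings: AT 1.5% / IT 4.5% of locus
    depth (with the conventional DYS635, DYS389II and DYS448 overrides),
    a 19% stutter filter, 60%/50% intra-locus balance for STRs/SNPs and
    minimum depths of 10× (STR) and 5× (SNP).
    """

    at_default: float = 0.015
    at_overrides: dict = field(
        default_factory=lambda: {"DYS635": 0.033, "DYS389II": 0.05, "DYS448": 0.033}
    )
    it_default: float = 0.045
    it_overrides: dict = field(
        default_factory=lambda: {"DYS635": 0.10, "DYS389II": 0.15, "DYS448": 0.10}
    )
    sf_default: float = 0.19
    sf_overrides: dict = field(default_factory=dict)
    ib_str: float = 0.60
    ib_snp: float = 0.50
    min_depth_str: int = 10
    min_depth_snp: int = 5

    def __post_init__(self):
        for name in set(self.at_overrides) | {"__default__"}:
            at = self.at_overrides.get(name, self.at_default)
            it = self.it_overrides.get(name, self.it_default)
            if not 0 < at <= it < 1:
                raise ValidationError(
                    f"thresholds at locus {name!r} violate 0 < AT <= IT < 1"
                )
        for name, sf in list(self.sf_overrides.items()) + [("", self.sf_default)]:
            if not 0 < sf < 1:
                raise ValidationError("SF must lie in (0, 1)")
        if not (0 < self.ib_str <= 1 and 0 < self.ib_snp <= 1):
            raise ValidationError("IB must lie in (0, 1]")
        if self.min_depth_str < 1 or self.min_depth_snp < 1:
            raise ValidationError("min_depth must be >= 1")

    def at(self, locus: str) -> float:
        return self.at_overrides.get(locus, self.at_default)

    def it(self, locus: str) -> float:
        return self.it_overrides.get(locus, self.it_default)

    def sf(self, locus: str) -> float:
        return self.sf_overrides.get(locus, self.sf_default)

    def ib(self, spec: LocusSpec) -> float:
        return self.ib_str if spec.is_str else self.ib_snp

    def min_depth(self, spec: LocusSpec) -> int:
        return self.min_depth_str if spec.is_str else self.min_depth_snp

    # -- JSON round trip (CLI threshold files) -----------------------------

    def to_json(self, path) -> None:
        payload = {
            "AT": {"default": self.at_default, "overrides": self.at_overrides},
            "IT": {"default": self.it_default, "overrides": self.it_overrides},
            "SF": {"default": self.sf_default, "overrides": self.sf_overrides},
            "IB": {"STR": self.ib_str, "SNP": self.ib_snp},
            "min_depth": {"STR": self.min_depth_str, "SNP": self.min_depth_snp},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CallingThresholds":
        with open(path, encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(
            at_default=p["AT"]["default"],
            at_overrides=dict(p["AT"].get("overrides", {})),
            it_default=p["IT"]["default"],
            it_overrides=dict(p["IT"].get("overrides", {})),
            sf_default=p["SF"]["default"],
            sf_overrides=dict(p["SF"].get("overrides", {})),
            ib_str=p["IB"]["STR"],
            ib_snp=p["IB"]["SNP"],
            min_depth_str=p["min_depth"]["STR"],
            min_depth_snp=p["min_depth"]["SNP"],
        )


@dataclass
class CallResult:
    """Outcome of calling one locus in one sample."""

    alleles: tuple  # called alleles, () when NO_CALL
    no_call: bool
    allele_status: dict  # candidate allele → status label
    imbalance: bool = False
    ambiguous: bool = False
    depth: int = 0

    @property
    def genotype(self):
        return None if self.no_call else self.alleles


_REPEAT_RE = re.compile(r"^(\d+(?:\.\d+)?)")


def repeat_number(allele: str):
    """Leading numeric repeat count of an STR allele name, else None.

    Sequence isoalleles like ``"14[t2]"`` share the repeat number 14.0.
    """
    m = _REPEAT_RE.match(str(allele))
    return float(m.group(1)) if m else None


def call_locus(counts: dict, spec: LocusSpec, thr: CallingThresholds) -> CallResult:
    """Call one sample-locus from its candidate-allele read counts.

    Rule order: minimum depth, AT drop, stutter removal (STRs: candidate
    one full repeat below a surviving allele with count < SF × parent),
    AT–IT review flag, then ploidy-aware genotype assembly with the IB
    heterozygote-balance check.
    """
    for allele, c in counts.items():
        if c < 0:
            raise ValidationError(f"negative read count for allele {allele!r}")
        if int(c) != c:
            raise ValidationError(f"non-integer read count for allele {allele!r}")
    counts = {str(a): int(c) for a, c in counts.items()}
    depth = sum(counts.values())
    status = {a: None for a in counts}

    if depth < thr.min_depth(spec):
        return CallResult(
            alleles=(),
            no_call=True,
            allele_status={a: None for a in counts},
            depth=depth,
        )

    at_cut = thr.at(spec.name) * depth
    it_cut = thr.it(spec.name) * depth
    surviving = {}
    for a, c in counts.items():
        if c < at_cut:
            status[a] = BELOW_AT
        else:
            surviving[a] = c

    if spec.is_str:
        sf = thr.sf(spec.name)
        parents = {a: repeat_number(a) for a in surviving}
        removed = []
        for a in list(surviving):
            ra = repeat_number(a)
            if ra is None:
                continue
            for b, rb in parents.items():
                if b == a or b in removed or rb is None:
                    continue
                if math.isclose(rb, ra + 1.0) and surviving[a] < sf * surviving[b]:
                    removed.append(a)
                    break
        for a in removed:
            status[a] = STUTTER
            del surviving[a]

    for a, c in surviving.items():
        status[a] = FLAGGED if c < it_cut else CALLED

    order = sorted(surviving, key=lambda a: (-surviving[a], a))
    ib = thr.ib(spec)

    if not order:
        return CallResult(alleles=(), no_call=True, allele_status=status, depth=depth)

    if spec.ploidy_in_males == 2:  # diploid
        if len(order) == 1:
            return CallResult(
                alleles=(order[0], order[0]),
                no_call=False,
                allele_status=status,
                depth=depth,
            )
        if len(order) == 2:
            c1, c2 = surviving[order[0]], surviving[order[1]]
            return CallResult(
                alleles=tuple(sorted(order)),
                no_call=False,
                allele_status=status,
                imbalance=(min(c1, c2) / max(c1, c2)) < ib,
                depth=depth,
            )
        return CallResult(  # >2 survivors at a single-copy diploid locus
            alleles=(),
            no_call=True,
            allele_status=status,
            ambiguous=True,
            depth=depth,
        )

    if spec.copy_number == 1:  # haploid single copy
        return CallResult(
            alleles=(order[0],),
            no_call=False,
            allele_status=status,
            ambiguous=len(order) > 1,
            depth=depth,
        )

    # multi-copy haploid locus (DYS385a-b style): up to 2 alleles; a single
    # surviving allele is reported as a duplicated call
    if len(order) == 1:
        alleles = (order[0], order[0])
    else:
        alleles = tuple(sorted(order[:2]))
        if len(order) > 2:
            return CallResult(
                alleles=alleles,
                no_call=False,
                allele_status=status,
                ambiguous=True,
                depth=depth,
            )
    c_top = [surviving[a] for a in order[:2]]
    imbalance = (
        len(c_top) == 2 and (min(c_top) / max(c_top)) < ib and order[0] != order[1]
    )
    return CallResult(
        alleles=alleles,
        no_call=False,
        allele_status=status,
        imbalance=imbalance,
        depth=depth,
    )


# ---------------------------------------------------------------------------
# read-count tables and whole-table calling
# ---------------------------------------------------------------------------


@dataclass
class ReadCountTable:
    """Per (sample, locus) candidate-allele read counts."""

    samples: list[str]
    populations: list[str]
    loci: list[str]
    counts: dict  # (sample, locus) → {allele: count}

    def __post_init__(self):
        for (s, l), cmap in self.counts.items():
            if not cmap:
                raise ValidationError(
                    f"sample {s!r} locus {l!r}: empty candidate set"
                )
            for a, c in cmap.items():
                if c < 0:
                    raise ValidationError(
                        f"sample {s!r} locus {l!r} allele {a!r}: negative count"
                    )

    def depth(self, sample: str, locus: str) -> int:
        return sum(self.counts.get((sample, locus), {}).values())


def write_read_counts(rc: ReadCountTable, path) -> None:
    rows = []
    for sample, pop in zip(rc.samples, rc.populations):
        for locus in rc.loci:
            for allele, reads in sorted(rc.counts.get((sample, locus), {}).items()):
                rows.append((sample, pop, locus, allele, reads))
    pd.DataFrame(
        rows, columns=["sample", "population", "locus", "allele", "reads"]
    ).to_csv(path, sep="\t", index=False)


def read_read_counts(path) -> ReadCountTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample": str, "population": str, "locus": str, "allele": str}
    )
    required = ["sample", "locus", "allele", "reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"read-count TSV missing columns {missing}")
    if "population" not in df.columns:
        df["population"] = "pop1"
    samples = list(dict.fromkeys(df["sample"]))
    pop_of = dict(zip(df["sample"], df["population"]))
    loci = list(dict.fromkeys(df["locus"]))
    counts: dict = {}
    for row in df.itertuples(index=False):
        counts.setdefault((row.sample, row.locus), {})[row.allele] = int(row.reads)
    return ReadCountTable(
        samples=samples,
        populations=[pop_of[s] for s in samples],
        loci=loci,
        counts=counts,
    )


@dataclass
class QCReport:
    """Per-locus and per-sample depth / success-rate accounting."""

    locus_summary: pd.DataFrame  # locus, n_samples, n_called, success_rate, mean_depth, sd_depth
    sample_depth: pd.DataFrame  # sample, mean_depth
    total_depth: int
    mean_depth_per_sample: float
    mean_depth_per_locus: float
    mean_depth_per_locus_per_sample: float

    def success_rate(self, locus: str) -> float:
        row = self.locus_summary[self.locus_summary["locus"] == locus]
        if row.empty:
            raise KeyError(locus)
        return float(row["success_rate"].iloc[0])


def depth_accounting(total_depth: int, n_samples: int, n_loci: int) -> dict:
    """Grand mean depths from a total read count.

    Returns mean depth per sample (over loci), per locus (over samples)
    and per locus per sample.
    """
    return {
        "total_depth": int(total_depth),
        "mean_depth_per_sample": total_depth / n_samples,
        "mean_depth_per_locus": total_depth / n_loci,
        "mean_depth_per_locus_per_sample": total_depth / (n_samples * n_loci),
    }


def call_table(
    rc: ReadCountTable, specs: list[LocusSpec], thr: CallingThresholds
) -> tuple[GenotypeTable, QCReport]:
    """Call every (sample, locus) of a read-count table.

    A locus absent from a sample's read counts is treated as zero depth
    (NO_CALL). Success rate per locus is called / total samples × 100.
    """
    by_name = {s.name: s for s in specs}
    unknown = [l for l in rc.loci if l not in by_name]
    if unknown:
        raise ValidationError(f"no LocusSpec for read-count loci {unknown}")

    cells = {}
    locus_rows = []
    depth_matrix = np.zeros((len(rc.samples), len(rc.loci)), dtype=float)
    for j, locus in enumerate(rc.loci):
        spec = by_name[locus]
        n_called = 0
        depths = []
        for i, sample in enumerate(rc.samples):
            cmap = rc.counts.get((sample, locus), {})
            if not cmap:
                cells[(sample, locus)] = None
                depths.append(0)
                continue
            try:
                res = call_locus(cmap, spec, thr)
            except ValidationError as exc:
                raise ValidationError(
                    f"sample {sample!r} locus {locus!r}: {exc}"
                ) from exc
            depths.append(res.depth)
            depth_matrix[i, j] = res.depth
            if res.no_call:
                cells[(sample, locus)] = None
            else:
                cells[(sample, locus)] = tuple(sorted(res.alleles))
                n_called += 1
        depths_arr = np.asarray(depths, dtype=float)
        locus_rows.append(
            {
                "locus": locus,
                "n_samples": len(rc.samples),
                "n_called": n_called,
                "success_rate": 100.0 * n_called / len(rc.samples),
                "mean_depth": float(depths_arr.mean()),
                "sd_depth": float(depths_arr.std(ddof=1)) if len(depths_arr) > 1 else 0.0,
            }
        )

    total = int(depth_matrix.sum())
    acct = depth_accounting(total, len(rc.samples), len(rc.loci))
    qc = QCReport(
        locus_summary=pd.DataFrame(locus_rows),
        sample_depth=pd.DataFrame(
            {"sample": rc.samples, "mean_depth": depth_matrix.mean(axis=1)}
        ),
        total_depth=total,
        mean_depth_per_sample=acct["mean_depth_per_sample"],
        mean_depth_per_locus=acct["mean_depth_per_locus"],
        mean_depth_per_locus_per_sample=acct["mean_depth_per_locus_per_sample"],
    )
    table = GenotypeTable(
        samples=list(rc.samples),
        populations=list(rc.populations),
        loci=[by_name[l] for l in rc.loci],
        cells=cells,
    )
    return table, qc
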