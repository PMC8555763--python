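"""Synthetic cohorts with the statistical structure the analyses assume.

Generates every pipeline input without external data: Balding–Nichols
structured SNP allele frequencies, stepwise-mutation-model (SMM) STR
haplotypes, sequence isoalleles nested inside length alleles, HWE
genotype sampling, and stutter-bearing negative-binomial read counts.

The default cohort mirrors a forensic MPS panel study design: one study
population of 90 males plus reference populations at controlled
divergence, 27 diploid autosomal STRs, 24 haploid Y-STRs (two of them
multi-copy), 7 X-STRs and 150 biallelic SNPs.

Randomness: one integer seed per run; every operation derives an
independent sub-stream keyed by (module tag, population, locus), so
adding loci or populations does not perturb earlier draws.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haploid_forensics import HaplotypeSet
from .io_formats import (
    AlleleFrequencyTable,
    GenotypeTable,
    LocusSpec,
    ValidationError,
)
from .mps_calling import ReadCountTable, repeat_number
from .allele_model import length_allele


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic sub-stream keyed by arbitrary string/int tokens."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in keys
    ]
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_Y_SINGLE = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458", "DYS460",
    "DYS481", "DYS533", "DYS549", "DYS570", "DYS576", "DYS612", "DYS635",
    "Y-GATA-H4",
)
_Y_MULTI = ("DYS385a-b", "DYF387S1")


def default_marker_panel() -> list[LocusSpec]:
    """The default simulated marker inventory (58 STRs + 150 SNPs)."""
    loci = [LocusSpec(f"A-STR{i:02d}", "A-STR") for i in range(1, 28)]
    loci += [LocusSpec(name, "Y-STR") for name in _Y_SINGLE]
    loci += [LocusSpec(name, "Y-STR", copy_number=2) for name in _Y_MULTI]
    loci += [LocusSpec(f"X-STR{i}", "X-STR") for i in range(1, 8)]
    loci += [LocusSpec(f"rs1{i:04d}", "IISNP") for i in range(1, 95)]
    loci += [LocusSpec(f"rs2{i:04d}", "AISNP") for i in range(1, 57)]
    return loci


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    ``f_per_pop`` are Balding–Nichols divergence parameters for the SNP
    frequencies; ``generations`` scale the SMM divergence of the STR
    haplotypes from shared founders. Read-count parameters: negative
    binomial depth (mean, dispersion), Beta heterozygote balance,
    Beta-distributed true stutter rate and a spurious-allele rate.
    """

    seed: int = 0
    populations: tuple = ("STUDY", "REF_A", "REF_B", "REF_C", "REF_D")
    n_per_pop: int = 90
    f_per_pop: tuple = (0.01, 0.02, 0.05, 0.10, 0.15)
    mutation_rate: float = 0.002  # per locus per generation
    generations: int = 200
    drift_generations: int = 100  # shared population drift per divergence rank
    isoalleles_per_length: int = 3
    isoallele_concentration: float = 1.0
    depth_mean: float = 300.0
    depth_dispersion: float = 5.0
    balance_concentration: float = 30.0  # Beta(c, c) heterozygote balance
    stutter_mean: float = 0.10
    stutter_concentration: float = 200.0
    noise_rate: float = 0.05

    def __post_init__(self):
        if len(self.f_per_pop) != len(self.populations):
            raise ValidationError("one F value required per population")
        if any(not 0.0 <= f < 1.0 for f in self.f_per_pop):
            raise ValidationError("F must lie in [0, 1)")
        if not 0.0 <= self.mutation_rate <= 0.01:
            raise ValidationError("mutation rate must lie in [0, 0.01]")
        for r in (self.stutter_mean, self.noise_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# SNP frequencies and genotypes
# ---------------------------------------------------------------------------


def simulate_snp_frequencies(
    p_anc,
    f_per_pop: dict,
    seed: int,
    loci: "list[str] | None" = None,
    n_chromosomes: int = 180,
) -> AlleleFrequencyTable:
    """Balding–Nichols SNP frequencies for K populations.

    Each population's frequency at each SNP is drawn from
    Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral frequency p;
    F = 0 reproduces p exactly. Draws are clamped to [1e-6, 1−1e-6] so
    downstream tables stay polymorphic-valid. Allele names are a
    reference/alternate nucleotide pair chosen per locus.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if np.any((p_anc <= 0) | (p_anc >= 1)):
        raise ValidationError("ancestral frequencies must lie in (0, 1)")
    if any(f >= 1.0 for f in f_per_pop.values()):
        raise ValidationError("F = 1 is degenerate (fixation)")
    if loci is None:
        loci = [f"rs{i + 1:05d}" for i in range(len(p_anc))]
    nucs = np.array(list("ACGT"))
    pair_rng = _rng(seed, "snp-alleles")
    pairs = [
        tuple(nucs[pair_rng.choice(4, size=2, replace=False)]) for _ in loci
    ]
    rows = []
    for pop, F in f_per_pop.items():
        rng = _rng(seed, "snp-freq", pop)
        if F == 0.0:
            p = p_anc.copy()
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p = rng.beta(a, b)
        p = np.clip(p, 1e-6, 1.0 - 1e-6)
        for locus, (ref, alt), pi in zip(loci, pairs, p):
            rows.append((pop, locus, ref, float(pi), n_chromosomes))
            rows.append((pop, locus, alt, float(1.0 - pi), n_chromosomes))
    return AlleleFrequencyTable(
        pd.DataFrame(
            rows, columns=["population", "locus", "allele", "frequency", "n"]
        )
    )


def simulate_genotypes(
    freqs: AlleleFrequencyTable,
    n_per_pop: dict,
    specs: list[LocusSpec],
    seed: int,
) -> GenotypeTable:
    """HWE genotype sampling from a population frequency table.

    Diploid loci: two independent allele draws per individual; haploid:
    one draw per copy (multi-copy loci draw ``copy_number`` alleles).
    """
    by_name = {s.name: s for s in specs}
    samples, populations, cells = [], [], {}
    for pop in freqs.populations:
        n = n_per_pop[pop]
        ids = [f"{pop}_{i + 1:03d}" for i in range(n)]
        samples += ids
        populations += [pop] * n
        for locus in freqs.loci:
            spec = by_name[locus]
            fmap = freqs.freqs(pop, locus)
            if not fmap:
                continue
            alleles = sorted(fmap)
            probs = np.array([fmap[a] for a in alleles])
            probs = probs / probs.sum()
            rng = _rng(seed, "genotypes", pop, locus)
            k = spec.ploidy_in_males * spec.copy_number
            draws = rng.choice(len(alleles), size=(n, k), p=probs)
            for sid, row in zip(ids, draws):
                cells[(sid, locus)] = tuple(sorted(alleles[i] for i in row))
    table_specs = [by_name[l] for l in freqs.loci]
    return GenotypeTable(
        samples=samples, populations=populations, loci=table_specs, cells=cells
    )


# ---------------------------------------------------------------------------
# STR haplotypes under the stepwise mutation model
# ---------------------------------------------------------------------------


def simulate_str_haplotypes(
    founders: dict,
    mu: float,
    generations: int,
    n: int,
    seed: int,
    label: str = "",
) -> HaplotypeSet:
    """Independent lineages diverging from founder repeat counts.

    ``founders``: locus → tuple of integer founder repeats (length 1, or
    2 for multi-copy loci). Each lineage accumulates Poisson(μ·g)
    mutations per locus copy, each a ±1 repeat step with equal
    probability. μ·g > 5 warns (SMM saturation).
    """
    if mu * generations > 5:
        warnings.warn("mu * generations > 5: stepwise model near saturation",
                      stacklevel=2)
    loci = list(founders)
    for locus, reps in founders.items():
        if any(int(r) != r for r in reps):
            raise ValidationError(f"founder repeats at {locus!r} must be integers")
    rows = []
    per_locus_steps = {}
    for locus in loci:
        rng = _rng(seed, "smm", label, locus)
        reps = founders[locus]
        k = rng.poisson(mu * generations, size=(n, len(reps)))
        steps = np.zeros_like(k)
        flat = k.ravel()
        out = np.zeros(flat.shape, dtype=int)
        for idx, km in enumerate(flat):
            if km:
                out[idx] = int(rng.choice([-1, 1], size=km).sum())
        steps = out.reshape(k.shape)
        per_locus_steps[locus] = steps
    for i in range(n):
        row = []
        for locus in loci:
            reps = founders[locus]
            row.append(
                tuple(
                    float(max(int(r) + int(per_locus_steps[locus][i, c]), 3))
                    for c, r in enumerate(reps)
                )
            )
        rows.append(tuple(row))
    return HaplotypeSet(
        individuals=[f"{label or 'hap'}_{i + 1:03d}" for i in range(n)],
        loci=loci,
        rows=rows,
        label=label,
    )


def drift_founders(
    founders: dict, mu: float, generations: int, seed: int, label: str = ""
) -> dict:
    """One SMM random walk per locus copy: population-level drift.

    Applying this to a shared ancestral founder set gives each
    population its own modal haplotype; the squared distance between two
    populations' founders then grows with drift time, which is what
    creates a positive among-group variance component (individual
    lineages alone are independent and cannot).
    """
    out = {}
    for locus, reps in founders.items():
        rng = _rng(seed, "founder-drift", label, locus)
        new = []
        for r in reps:
            k = int(rng.poisson(mu * generations))
            step = int(rng.choice([-1, 1], size=k).sum()) if k else 0
            new.append(max(int(r) + step, 3))
        out[locus] = tuple(new)
    return out


def random_founders(loci: list[LocusSpec], seed: int) -> dict:
    """Founder repeat counts (10–30) for the STR loci of a panel."""
    founders = {}
    rng = _rng(seed, "founders")
    for spec in loci:
        if not spec.is_str:
            continue
        reps = tuple(int(rng.integers(10, 31)) for _ in range(spec.copy_number))
        founders[spec.name] = reps
    return founders


def haplotypes_to_genotypes(
    hs: HaplotypeSet, specs: list[LocusSpec], population: str
) -> GenotypeTable:
    """View an SMM haplotype set as a haploid genotype table."""
    by_name = {s.name: s for s in specs}
    loci = [by_name[l] for l in hs.loci]
    cells = {}
    for ind, row in zip(hs.individuals, hs.rows):
        for locus, v in zip(hs.loci, row):
            if v is None:
                cells[(ind, locus)] = None
            else:
                cells[(ind, locus)] = tuple(
                    sorted(f"{x:g}" for x in v)
                )
    return GenotypeTable(
        samples=list(hs.individuals),
        populations=[population] * len(hs.individuals),
        loci=loci,
        cells=cells,
    )


# ---------------------------------------------------------------------------
# sequence isoalleles
# ---------------------------------------------------------------------------


def assign_isoalleles(
    table: GenotypeTable,
    m: int,
    concentration: float,
    seed: int,
) -> GenotypeTable:
    """Split STR length alleles into Dirichlet-weighted sequence tags.

    Every length allele at a locus is associated with ``m`` isoalleles
    whose proportions are Dirichlet(concentration) distributed; each
    observed allele copy then samples its tag. ``m = 1`` leaves the
    table untouched (collapsing is the identity).
    """
    if m < 1:
        raise ValidationError("isoallele count must be >= 1")
    if m == 1:
        return table
    str_loci = [l.name for l in table.loci if l.is_str]
    # Dirichlet isoallele proportions per (locus, length allele)
    props: dict = {}

    def proportions(locus: str, length: str) -> np.ndarray:
        key = (locus, length)
        if key not in props:
            rng = _rng(seed, "isoallele-props", locus, length)
            props[key] = rng.dirichlet([concentration] * m)
        return props[key]

    cells = {}
    for (sample, locus), cell in table.cells.items():
        if cell is None or locus not in str_loci:
            cells[(sample, locus)] = cell
            continue
        rng = _rng(seed, "isoallele-draw", sample, locus)
        tagged = []
        for a in cell:
            length = length_allele(a)
            p = proportions(locus, length)
            tag = int(rng.choice(m, p=p))
            tagged.append(f"{length}[t{tag + 1}]")
        cells[(sample, locus)] = tuple(sorted(tagged))
    return GenotypeTable(
        samples=list(table.samples),
        populations=list(table.populations),
        loci=list(table.loci),
        cells=cells,
    )


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------


def simulate_read_counts(
    truth: GenotypeTable,
    seed: int,
    depth_mean: float = 300.0,
    depth_dispersion: float = 5.0,
    balance_concentration: float = 30.0,
    stutter_mean: float = 0.10,
    stutter_concentration: float = 200.0,
    noise_rate: float = 0.05,
) -> ReadCountTable:
    """Stutter-bearing read counts consistent with a truth table.

    Locus depth ~ NegBin(mean, dispersion); heterozygote reads are split
    by a Beta(c, c) balance draw; each STR allele diverts reads to an
    n−1 repeat stutter product at a Beta-distributed rate (so depth is
    conserved and the truth is recoverable when stutter and noise are
    switched off); spurious extra alleles appear at ``noise_rate`` with
    ~1% of locus depth.
    """
    counts: dict = {}
    spec_of = {l.name: l for l in truth.loci}
    for sample in truth.samples:
        for locus in spec_of:
            cell = truth.cells.get((sample, locus))
            if cell is None:
                continue
            spec = spec_of[locus]
            rng = _rng(seed, "reads", sample, locus)
            p = depth_dispersion / (depth_dispersion + depth_mean)
            depth = int(rng.negative_binomial(depth_dispersion, p))
            if depth <= 0:
                counts[(sample, locus)] = {str(cell[0]): 0}
                continue
            distinct = sorted(set(cell))
            if len(distinct) == 1:
                alloc = {distinct[0]: depth}
            else:
                bal = rng.beta(balance_concentration, balance_concentration)
                first = int(round(depth * bal))
                alloc = {distinct[0]: first, distinct[1]: depth - first}
            cmap: dict = {}
            for allele, reads in alloc.items():
                if reads <= 0:
                    cmap[allele] = cmap.get(allele, 0)
                    continue
                if spec.is_str and stutter_mean > 0:
                    a_conc = stutter_mean * stutter_concentration
                    b_conc = (1.0 - stutter_mean) * stutter_concentration
                    rate = rng.beta(a_conc, b_conc)
                    s_reads = int(rng.binomial(reads, rate))
                    rep = repeat_number(allele)
                    if s_reads > 0 and rep is not None and rep > 4:
                        # a sequence isoallele's stutter keeps its motif, so
                        # the product inherits the parent's sequence tag
                        from .allele_model import split_allele

                        _, tag = split_allele(allele)
                        stutter_name = f"{rep - 1:g}" + (
                            f"[{tag}]" if tag is not None else ""
                        )
                        cmap[stutter_name] = cmap.get(stutter_name, 0) + s_reads
                        reads -= s_reads
                cmap[allele] = cmap.get(allele, 0) + reads
            if noise_rate > 0 and rng.random() < noise_rate:
                noise_reads = max(int(round(depth * 0.01)), 1)
                if spec.is_str:
                    rep = repeat_number(distinct[0])
                    noise_allele = f"{(rep or 10) + 2:g}"
                else:
                    present = set("".join(distinct)) & set("ACGT")
                    candidates = [x for x in "ACGT" if x not in present]
                    noise_allele = candidates[0] if candidates else "N"
                if noise_allele not in cmap:
                    cmap[noise_allele] = noise_reads
            counts[(sample, locus)] = cmap
    return ReadCountTable(
        samples=list(truth.samples),
        populations=list(truth.populations),
        loci=[l.name for l in truth.loci],
        counts=counts,
    )


# ---------------------------------------------------------------------------
# whole-cohort preset
# ---------------------------------------------------------------------------


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the underlying truth."""

    config: SimulationConfig
    panel: list[LocusSpec]
    genotypes: GenotypeTable  # all populations, sequence-level STR alleles
    snp_frequencies: AlleleFrequencyTable
    y_haplotypes: dict  # population → HaplotypeSet
    read_counts: ReadCountTable  # study population only
    study_population: str = ""


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate the full default-study bundle from one config."""
    panel = default_marker_panel()
    seed = config.seed
    pops = list(config.populations)
    study = pops[0]
    f_map = dict(zip(pops, config.f_per_pop))

    snp_specs = [l for l in panel if l.is_snp]
    p_anc = _rng(seed, "anc-freq").uniform(0.1, 0.9, size=len(snp_specs))
    snp_freqs = simulate_snp_frequencies(
        p_anc,
        f_map,
        seed=seed,
        loci=[l.name for l in snp_specs],
        n_chromosomes=2 * config.n_per_pop,
    )
    snp_genos = simulate_genotypes(
        snp_freqs, {p: config.n_per_pop for p in pops}, snp_specs, seed=seed
    )

    # STRs: A/X via HWE sampling from per-population SMM-derived pools,
    # Y via explicit haplotype lineages
    str_specs = [l for l in panel if l.is_str]
    y_specs = [l for l in str_specs if l.marker_class == "Y-STR"]
    founders = random_founders(str_specs, seed)
    y_haps = {}
    for k, pop in enumerate(pops):
        # population-level shared drift scales with the population index,
        # mirroring the increasing F of the SNP model; lineage depth is fixed
        pop_founders = drift_founders(
            {s.name: founders[s.name] for s in y_specs},
            mu=config.mutation_rate,
            generations=config.drift_generations * k,
            seed=seed,
            label=pop,
        )
        y_haps[pop] = simulate_str_haplotypes(
            pop_founders,
            mu=config.mutation_rate,
            generations=config.generations,
            n=config.n_per_pop,
            seed=seed,
            label=pop,
        )
        y_haps[pop].individuals = [
            f"{pop}_{i + 1:03d}" for i in range(config.n_per_pop)
        ]

    ax_specs = [l for l in str_specs if l.marker_class in ("A-STR", "X-STR")]
    ax_cells = {}
    for pop in pops:
        ids = [f"{pop}_{i + 1:03d}" for i in range(config.n_per_pop)]
        for spec in ax_specs:
            rng = _rng(seed, "ax-str", pop, spec.name)
            founder = founders[spec.name][0]
            # SMM drift of the population allele pool: 8 ancestral lineages
            pool = founder + np.array(
                [
                    rng.choice([-1, 1], size=max(k, 1)).sum() if k else 0
                    for k in rng.poisson(
                        config.mutation_rate * config.generations, size=8
                    )
                ]
            )
            weights = rng.dirichlet([1.0] * len(pool))
            k_draws = spec.ploidy_in_males
            draws = rng.choice(len(pool), size=(config.n_per_pop, k_draws), p=weights)
            for sid, row in zip(ids, draws):
                ax_cells[(sid, spec.name)] = tuple(
                    sorted(f"{max(pool[i], 3):g}" for i in row)
                )

    samples = [f"{p}_{i + 1:03d}" for p in pops for i in range(config.n_per_pop)]
    populations = [p for p in pops for _ in range(config.n_per_pop)]
    cells = dict(ax_cells)
    for pop in pops:
        ygt = haplotypes_to_genotypes(y_haps[pop], y_specs, pop)
        cells.update(ygt.cells)
    for (s, l), c in snp_genos.cells.items():
        cells[(s, l)] = c
    genotypes = GenotypeTable(
        samples=samples, populations=populations, loci=panel, cells=cells
    )
    genotypes = assign_isoalleles(
        genotypes,
        m=config.isoalleles_per_length,
        concentration=config.isoallele_concentration,
        seed=seed,
    )

    study_table = genotypes.subset_samples(
        [s for s, p in zip(samples, populations) if p == study]
    )
    read_counts = simulate_read_counts(
        study_table,
        seed=seed,
        depth_mean=config.depth_mean,
        depth_dispersion=config.depth_dispersion,
        balance_concentration=config.balance_concentration,
        stutter_mean=config.stutter_mean,
        stutter_concentration=config.stutter_concentration,
        noise_rate=config.noise_rate,
    )
    return CohortBundle(
        config=config,
        panel=panel,
        genotypes=genotypes,
        snp_frequencies=snp_freqs,
        y_haplotypes=y_haps,
        read_counts=read_counts,
        study_population=study,
    )
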